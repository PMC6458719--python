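# Methods

This note records the models behind each stage, the parameters that
matter, what the synthetic generators do and do not emulate, and the
numerical choices a maintainer would want to know.

## Coordinates and the lncTU atlas

All internal coordinates are 0-based, half-open (BED convention); GFF3 is
shifted on read/write. This makes "book-ended" precise: two records touch
iff `a.end == b.start`. Source lncRNA records are partitioned into three
strand classes (+, −, NA) and merged within each class by a sort-and-sweep
over (chrom, start): a record joins the open unit while its start does not
exceed the unit's running end, so chains of overlapping or book-ended
records coalesce into one lncTU whose interval is the exact union span and
whose members record provenance (dataset, original id). NA records are
never reconciled with stranded ones — the three subsets are independent —
and records from different datasets merge freely, which is what makes the
atlas non-redundant. lncTU ids are synthesized from coordinates
(`chrom:start-end:strand`) so they are stable across runs. The test suite
checks the sweep against an independent O(n²) union-find oracle, plus
idempotence and permutation invariance.

## Differential expression

*Filter.* A feature is kept when CPM = count·10⁶/libsize ≥ 1 in at least
⌈n/2⌉ samples ("at least half", boundary inclusive, tested). Library
sizes are column sums computed before filtering and not recomputed.

*Normalization.* TMM: the reference sample is the one whose upper-quartile
CPM is closest to the mean upper-quartile; per sample, log2 ratios M
against the reference (features positive in both) are doubly trimmed (30%
on M, 5% on A) and averaged with inverse asymptotic binomial variance
weights; factors are rescaled to geometric mean 1. Effective library size
= raw library size × factor.

*Dispersion.* Counts are scaled to a common effective library size; each
feature's NB dispersion φ maximizes the Cox-Reid adjusted profile
likelihood on an 80-point log grid over [10⁻⁶, 5], with per-timepoint
means profiled out and the CR term −½ log(n·μ/(1+φμ)) per group correcting
the plug-in bias. Raw estimates are shrunk toward the all-feature median
with weight 0.7 and floored at 10⁻⁶. A plain method-of-moments estimator
was rejected: at three replicates it is biased low enough (≈ −20%) to
visibly inflate the type-I error of the downstream exact test, while the
CR-adjusted estimate keeps the 5%-level rejection rate of null NB data
near nominal (≈ 0.05–0.06 in the calibration tests). Single-replicate
designs fall back to the common dispersion.

*Test.* For a timepoint pair, replicate counts are scaled to the common
(geometric-mean) effective library size, rounded, and summed per group;
the group-A sum is tested conditionally on the total, with the sum of n
NB(μ, φ) replicates treated as NB(nμ, φ/n). The two-sided p sums the
probabilities of all outcomes no more likely than the observed one
(minlike construction), which makes identical groups give p = 1 exactly
and reduces, as φ → 0, to the exact binomial test of the group-A sum
versus the pooled sum (oracle-checked to 10⁻⁸). log2FC is the ratio of
per-replicate normalized group means with a 0.125 prior count. Note that
an exact count test is *not* invariant to rescaling counts and library
sizes jointly: deeper counts carry more information and sharpen p. The
CPM filter and the fold-change estimate are scale-free.

*Calls.* BH within each contrast (a global-adjustment switch exists, off
by default); DE iff adjusted p < α, strictly, α = 0.05. The six unordered
timepoint pairs are tested by default; "DE in ≥ 1 of 6 comparisons"
accumulates false positives across contrasts by construction, which the
examples demonstrate deliberately.

## Co-expression clustering

DE-feature counts are normalized, converted to per-feature proportions
(rows sum to 1) and transformed y = arcsin√p, which stabilizes the
variance of proportions and maps into [0, π/2]. The mixture model is a
diagonal-covariance Gaussian mixture fitted by EM: seeded k-means++
initialization, best of `n_restarts` (default 10) by log-likelihood,
convergence at relative log-likelihood change < 10⁻⁸ or 500 iterations,
variance floor 10⁻⁸. An EM run that empties a component is abandoned and
restarted with a fresh initialization (bounded at 10 attempts); the
retained run's log-likelihood trace is therefore monotone, which tests
assert. Model selection maximizes ICL = LL − ½·#par·log n − Σ τ log τ.
The real-data default sweep is K = 10…40; the synthetic study uses K =
2…6 because it plants four profile clusters and a wider sweep would only
fit models the data cannot support. Diagonal covariances keep the
parameter count linear in dimension, which stabilizes ICL at small n.

Cluster families: with per-timepoint centroids (arithmetic mean of
replicate columns on the transformed scale) and d_t = centroid(T_t) −
centroid(T0), a cluster is transient-up (CF1) if max d_t > θ while
|d_last| ≤ θ/2, mirrored for CF2; otherwise stable by the sign of d_last,
high if |d_last| ≥ θ_high else low (CF3–CF6). Defaults θ = 0.05, θ_high =
0.15 on the arcsin scale; these thresholds are a package convention (the
original grouping was visual), are configuration-exposed, and every
classification carries a margin score with near-flat centroids flagged
weak (assigned to the stable-low family of their sign).

DE-lncTU hierarchical clustering uses 1 − Pearson distance with average
linkage; zero-variance profiles get distance 1 to everything and are
flagged. A feature is "dynamic" iff its significant contrasts include
both positive and negative log2FC, else up/down. Leaf-order optimization
is a display concern and is not implemented. Term enrichment is a generic
annotated-term operation (any feature → term map): one-sided
hypergeometric per (cluster, term), terms with < 10 cluster entries
dropped before testing, BH within cluster, enriched at FDR < 0.01.

## Preferentially located motifs

Windows, in transcription orientation (reverse-complemented for − genes):
learning = TSS−1000 … TSS−300, target = TSS−300 … 5′UTR end, or the TSS
itself when no 5′UTR is annotated. Genes whose learning window is fully
clipped at a chromosome edge are excluded and listed; partial clipping
just shortens the effective position count (length − k + 1, floored at 0,
summed over genes). Matching is single-strand on the promoter-forward
sequence and counts overlapping occurrences; the IUPAC dialect is the
standard 15-letter code.

The test statistic is a position-uniform binomial null: conditional on n =
n_T + n_L total occurrences, the target count is Binomial(n,
P_T/(P_T+P_L)) and p is its upper tail. This is exact and fast; its
discreteness makes the achieved level at nominal 0.05 slightly
conservative when occurrence totals are small (≈ 0.045 at n ≈ 770), which
the calibration tests account for by using promoter sets large enough that
n ≈ 1500 per tetramer. Discovery tests every exact k-mer for k = 4…11
(absent k-mers have p = 1 and are never significant, so only observed
k-mers are materialized; the 4-mer space is exhaustively present in any
realistic promoter set, asserted in tests), keeps p < 0.05, and greedily
collapses: walking candidates by ascending p, each absorbs remaining
same-length k-mers at Hamming distance ≤ 1 into an IUPAC consensus, which
is re-tested; output is p-sorted with deterministic lexicographic
tie-breaks, and a ≥ 7-mer view is also emitted. Collapsing can produce a
wildcard-shifted representation of a planted motif (e.g. `NTGACGTC` from
the one-base-shifted occurrences of `TGACGTCA`) scoring marginally better
than the exact k-mer — both represent the same signal, and recovery tests
accept either. Headline significance is uncorrected by design; a BH
column is always emitted. Library mode scores target-window *presence*
(gene carries ≥ 1 occurrence) in a cluster versus a background gene set
with a one-sided hypergeometric test.

## Regulatory context

*Chromatin states.* The state track is a gap-free, overlap-free labeled
segmentation per chromosome. The observed statistic per state is either
the number of lncTUs with ≥ 1 bp in the state (count mode, default) or
total overlap bp (bp mode); the mode is stamped into the output. The null
re-places every lncTU-length interval uniformly on its own chromosome
(length- and chromosome-preserving; shuffled intervals may overlap each
other), n_shuffles = 1000 by default. Fold change = observed/null mean;
empirical p = (1 + #{null ≥ observed})/(1 + n) for enrichment, mirrored
for depletion. A GC- or gap-aware null is out of scope. With a state
covering fraction f of the genome and all intervals inside it, the
bp-mode fold change approaches 1/f up to edge effects.

*NAT couples.* Candidates are (lncTU, gene) pairs with ≥ 1 bp overlap and
opposite strands; NA-strand lncTUs are excluded, and no minimum overlap
beyond 1 bp is imposed. Per contrast: "opposite"/"same" require both
members called DE (sign comparison of log2FC), "one-sided" exactly one,
"neither" otherwise; a couple is flagged when opposite in ≥ 1 contrast.
Features absent from the DE table count as not called.

*TFBS scanning.* The search region anchors to the lncTU body: window_up
(default 3000 bp) beyond the 5′ end and window_down (default 1000 bp)
beyond the 3′ end, in lncTU orientation; both genomic strands are scanned.
Hits are classified relative to the body — entirely upstream → 5′,
straddling the 5′ boundary → overlap-5′, inside, straddling the 3′
boundary → overlap-3′, entirely downstream → 3′ — the five classes
partition the window, and classes are reported in transcription
orientation. The body-anchored reading was chosen over a literal fixed
4-kb window because hits are classified relative to the body, including
"inside". The shipped default motifs are CArG-box-style consensi for
MADS-domain factors (SVP/FLC/SOC1) and are placeholders: real analyses
should supply motif definitions from ChIP experiments.

## Endoreduplication

EI = Σ w_c · fraction_c with weights (0, 1, 2, 3, 4) over classes 2C…32C;
EI ∈ [0, 4] and is linear under mixing of distributions. Percentages must
sum to 100 ± 0.5 (rounding tolerance). Replicate summaries report mean ±
SEM (sd/√n, undefined for single replicates); between-condition
significance uses a two-sided Welch t-test on replicate EIs (the choice of
test is a package convention and is configuration-exposed). Raw cytometry
gating is out of scope; input is the classed percentage table.

## Synthetic data

The generators emit everything the pipeline consumes, with truth:

- `make_genome` — uniform-ACGT chromosomes (a GC-bias knob exists, off by
  default, because a uniform background makes the motif binomial null
  exact); genes of 1–3 kb placed left-to-right with ≥ 1 kb flanks on both
  sides and between neighbours, slack distributed multinomially; strand
  and 5′UTR length (50–300 bp) random; capacity violations raise.
- `make_lnc_sources` — chains of 1–3 overlapping/book-ended records seed
  the base dataset; a configurable fraction is placed antisense over genes
  (NAT truth) and a fraction carries no strand; additional datasets repeat
  each record identically with probability `redundancy`, else as a shifted
  overlapping variant. Truth holds the union-find merged counts and the
  all-pairs antisense couples, both computed with independent brute-force
  code.
- `make_counts` — NB counts with mean = profile(cluster, timepoint) ×
  lognormal feature abundance (sd 0.5) × base mean (100) × per-sample
  depth factor uniform on [0.8, 1.2]; the design is 4 timepoints × 3
  replicates. Truth records cluster assignments and the true log2FC of
  every timepoint pair. Planted DE in benchmark simulations is balanced
  up/down: one-sided planting at a 10% DE fraction measurably biases the
  TMM trimmed mean (the trim window becomes asymmetric over null
  features), which is a property of TMM, not of this implementation, and
  balanced regulation matches the observed biology (cluster families come
  in up and down pairs).
- `make_promoters` — writes sampled concrete occurrences of an IUPAC
  motif into the chosen promoter window of a random fraction of a
  cluster's genes, directly into the genome sequence (reverse-complemented
  on − strands), so window extraction is exercised end to end.
- `make_chromatin_states` — segments of 2–10 kb tile each chromosome with
  random CS1–CS9 labels (no immediate repeats); placement bias is realized
  by rejection sampling on the state at the proposed interval midpoint.
- `make_ploidy` — truncated-Gaussian noise on class percentages,
  renormalized to 100; truth EI from the noiseless profile. The default
  condition profiles are chosen so the noiseless EIs sit at the reported
  leaves-3/4 endpoints (1.95 without transfer, 2.35 after transfer).

What the generators do **not** emulate: real genome composition and
repeats, gene-density structure, strand-specific library artifacts, raw
reads/alignment, GC-dependent coverage, correlated replicate effects, or
batch covariates such as harvest date. Passing recovery tests therefore
demonstrates correctness of the statistical machinery under its stated
assumptions, not performance on real libraries.

## Pipeline and reproducibility

One global seed fans out per stage via `SeedSequence(seed, spawn_key)`
(counter-based, stable, < 2³¹), so stages can be re-run in isolation.
Every stage writes plain-text outputs (FASTA/GFF3/BED/TSV/Newick/YAML)
under one output directory and the manifest records parameters, stage
seeds and SHA-256 checksums; re-running a config reproduces the checksums
byte-for-byte, which the tests assert. The synthetic study runs at desk
scale by choice — 2 × 300 kb chromosomes, 120 genes, ~60 lncRNA chains,
a K = 2…6 clustering sweep — sized so that every planted signal is
recoverable with comfortable statistical margin. Real-data mode provides
the same operations through the library and per-stage CLI on user files;
`run_all` currently orchestrates the synthetic study only.

## Known limitations

- The DE stage is a per-contrast exact test with moderated dispersions,
  not a GLM; covariates (e.g. harvest date) cannot be adjusted for, and
  bit-compatibility with any particular GLM fit is not a goal.
- The PLM statistic is this package's position-uniform binomial
  construction; per-occurrence counting is used for discovery and
  per-gene presence for library mode.
- TMM develops a small systematic offset when differential expression is
  large, common, and one-directional (see above).
- The chromatin-state shuffle null ignores composition and accessibility;
  fold changes near coverage boundaries inherit its simplicity.
- Welch's t on a handful of replicate EIs has limited power; the printed
  degrees of freedom should be read alongside the p-value.
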