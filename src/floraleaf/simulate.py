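"""Seeded synthetic data with planted ground truth.

Generates every input the analysis consumes — a toy multi-chromosome
genome with stranded genes and 5'UTRs, redundant overlapping lncRNA source
datasets on three strand classes, NB counts with library-size variation
and planted cluster profiles, promoters with positionally planted motifs,
a 9-state chromatin segmentation with optional placement bias, and ploidy
class percentages — together with a truth record for every planted signal,
so each downstream stage can be tested against known answers without any
external download.

Background sequence composition is uniform over ACGT, which makes the
positional binomial null for motif tests exact; an optional GC-bias knob
exists but is off by default. All generators are deterministic for a fixed
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .diffexpr import SampleDesign, all_contrasts
from .intervals import GeneModel, GenomicInterval, LncTU, SourceRecord
from .plm import IUPAC, LEARNING_UP, TARGET_UP, revcomp
from .context import ChromatinStateTrack

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class GenomeBundle:
    """In-memory genome: chromosome sequences plus gene models."""

    sequences: Dict[str, str]
    genes: List[GeneModel]

    def gene(self, gid: str) -> GeneModel:
        for g in self.genes:
            if g.id == gid:
                return g
        raise KeyError(gid)


@dataclass
class SyntheticTruth:
    """Ground truth planted by the generators."""

    planted_cluster_of_feature: Dict[str, int] = field(default_factory=dict)
    planted_motifs: List[dict] = field(default_factory=list)
    planted_state_bias: Dict[str, float] = field(default_factory=dict)
    planted_nat_pairs: List[Tuple[str, str, str]] = field(default_factory=list)
    planted_de: Dict[Tuple[str, str], float] = field(default_factory=dict)
    extras: dict = field(default_factory=dict)


def _random_sequence(rng: np.random.Generator, length: int,
                     gc_bias: float = 0.0) -> str:
    """Uniform ACGT sequence; gc_bias > 0 tilts toward G/C."""
    p = np.array([1 - gc_bias, 1 + gc_bias, 1 + gc_bias, 1 - gc_bias]) / 4.0
    idx = rng.choice(4, size=length, p=p)
    return _BASES[idx].tobytes().decode()


class CapacityError(ValueError):
    """Requested features cannot be placed without violating flanks."""


def make_genome(n_chrom: int, chrom_len: int, n_genes: int, seed: int,
                gene_len_range: Tuple[int, int] = (1000, 3000),
                utr_len_range: Tuple[int, int] = (50, 300),
                flank: int = 1000, gc_bias: float = 0.0) -> GenomeBundle:
    """Random genome with non-overlapping genes and guaranteed 1-kb flanks.

    Genes are spread evenly over chromosomes; on each chromosome they are
    placed left to right with at least ``flank`` bp before the first gene,
    between genes, and after the last, the slack distributed at random.
    Raises CapacityError when the genes do not fit.
    """
    if n_genes < 0:
        raise ValueError("n_genes must be >= 0")
    rng = np.random.default_rng(seed)
    chrom_names = [f"chr{i + 1}" for i in range(n_chrom)]
    sequences = {c: _random_sequence(rng, int(chrom_len), gc_bias) for c in chrom_names}

    per_chrom = [n_genes // n_chrom + (1 if i < n_genes % n_chrom else 0)
                 for i in range(n_chrom)]
    genes: List[GeneModel] = []
    gi = 0
    for chrom, n in zip(chrom_names, per_chrom):
        if n == 0:
            continue
        lengths = rng.integers(gene_len_range[0], gene_len_range[1] + 1, size=n)
        needed = int(lengths.sum()) + (n + 1) * flank
        if needed > chrom_len:
            raise CapacityError(
                f"{n} genes need {needed} bp on {chrom} but only {chrom_len} available"
            )
        slack = int(chrom_len) - needed
        extra = rng.multinomial(slack, np.full(n + 1, 1.0 / (n + 1)))
        pos = flank + int(extra[0])
        for j in range(n):
            start, end = pos, pos + int(lengths[j])
            strand = "+" if rng.random() < 0.5 else "-"
            utr = int(rng.integers(utr_len_range[0], utr_len_range[1] + 1))
            utr = min(utr, int(lengths[j]) - 1)
            utr5_end = start + utr if strand == "+" else end - utr
            genes.append(GeneModel(f"g{gi:04d}",
                                   GenomicInterval(chrom, start, end, strand),
                                   utr5_end=utr5_end))
            gi += 1
            pos = end + flank + int(extra[j + 1])
    return GenomeBundle(sequences, genes)


def make_lnc_sources(bundle: GenomeBundle, n_datasets: int = 3,
                     n_chains: int = 120, redundancy: float = 0.5,
                     strand_na_fraction: float = 0.2,
                     antisense_fraction: float = 0.3, seed: int = 0,
                     length_range: Tuple[int, int] = (200, 2000)
                     ) -> Tuple[List[List[SourceRecord]], SyntheticTruth]:
    """Redundant, overlapping lncRNA source datasets plus merge/NAT truth.

    The base dataset is built from chains of 1-3 records that overlap or
    book-end each other (so merging is exercised); a fraction of chains is
    placed antisense over a gene (future NAT truth) and a fraction of
    records carries no strand information. Additional datasets repeat each
    base record either identically (probability ``redundancy``) or as a
    shifted overlapping variant.
    """
    for frac in (redundancy, strand_na_fraction, antisense_fraction):
        if not 0.0 <= frac <= 1.0:
            raise ValueError("fractions must lie in [0, 1]")
    if n_datasets < 2:
        raise ValueError("need at least 2 source datasets")
    rng = np.random.default_rng(seed)
    chroms = list(bundle.sequences)
    chrom_len = {c: len(s) for c, s in bundle.sequences.items()}
    genes_by_chrom: Dict[str, List[GeneModel]] = {}
    for g in bundle.genes:
        genes_by_chrom.setdefault(g.interval.chrom, []).append(g)

    base: List[GenomicInterval] = []
    for _ in range(n_chains):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        antisense = rng.random() < antisense_fraction and bundle.genes
        if antisense:
            g = bundle.genes[int(rng.integers(len(bundle.genes)))]
            giv = g.interval
            # guarantee >= 1 bp overlap with the gene body
            lo = max(0, giv.start - length + 1)
            hi = min(chrom_len[giv.chrom] - length, giv.end - 1)
            start = int(rng.integers(lo, hi + 1)) if hi >= lo else giv.start
            strand = "-" if giv.strand == "+" else "+"
            chrom = giv.chrom
        else:
            chrom = chroms[int(rng.integers(len(chroms)))]
            start = int(rng.integers(0, chrom_len[chrom] - length))
            strand = "+" if rng.random() < 0.5 else "-"
        if rng.random() < strand_na_fraction:
            strand = "NA"
        first = GenomicInterval(chrom, start, start + length, strand)
        base.append(first)
        prev = first
        for _ in range(int(rng.integers(0, 3))):  # chain extensions
            ext_len = int(rng.integers(length_range[0], length_range[1] + 1))
            if rng.random() < 0.5:  # book-ended
                s = prev.end
            else:  # overlapping
                s = int(rng.integers(prev.start + 1, prev.end))
            e = min(s + ext_len, chrom_len[chrom])
            if e - s < 1:
                continue
            prev = GenomicInterval(chrom, s, e, prev.strand)
            base.append(prev)

    datasets: List[List[SourceRecord]] = []
    for d in range(n_datasets):
        ds_name = f"lnc_src{d + 1}"
        recs: List[SourceRecord] = []
        for i, iv in enumerate(base):
            if d == 0 or rng.random() < redundancy:
                out = iv
            else:
                shift = int(rng.integers(1, max(2, iv.length // 5)))
                s = max(0, iv.start - shift)
                e = min(chrom_len[iv.chrom], iv.end - shift + iv.length // 10)
                out = GenomicInterval(iv.chrom, s, max(e, s + 1), iv.strand)
            recs.append(SourceRecord(ds_name, f"{ds_name}_r{i:04d}", out))
        datasets.append(recs)

    truth = SyntheticTruth()
    all_records = [r for ds in datasets for r in ds]
    merged = brute_force_merge(all_records)
    truth.extras["n_lnctus_per_strand"] = {
        s: len(us) for s, us in merged.items()
    }
    truth.extras["n_lnctus_total"] = sum(len(us) for us in merged.values())
    truth.planted_nat_pairs = brute_force_nat_pairs(merged, bundle.genes)
    return datasets, truth


def brute_force_merge(records: Sequence[SourceRecord]) -> Dict[str, List[LncTU]]:
    """Independent O(n^2) union-find merge oracle (same contract as atlas)."""
    out: Dict[str, List[LncTU]] = {}
    for strand in ("+", "-", "NA"):
        recs = [r for r in records if r.interval.strand == strand]
        n = len(recs)
        parent = list(range(n))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                a, b = recs[i].interval, recs[j].interval
                if a.chrom == b.chrom and a.start <= b.end and b.start <= a.end:
                    ri, rj = find(i), find(j)
                    if ri != rj:
                        parent[ri] = rj
        groups: Dict[int, List[SourceRecord]] = {}
        for i in range(n):
            groups.setdefault(find(i), []).append(recs[i])
        units = []
        for members in groups.values():
            start = min(r.interval.start for r in members)
            end = max(r.interval.end for r in members)
            chrom = members[0].interval.chrom
            units.append(LncTU(GenomicInterval(chrom, start, end, strand),
                               members=sorted(members, key=lambda r: (r.dataset, r.record_id))))
        units.sort(key=lambda u: (u.interval.chrom, u.interval.start))
        out[strand] = units
    return out


def brute_force_nat_pairs(atlas: Dict[str, List[LncTU]], genes: Sequence[GeneModel]
                          ) -> List[Tuple[str, str, str]]:
    """All antisense-overlapping (lncTU, gene) pairs by all-pairs scan."""
    pairs = []
    for strand in ("+", "-"):
        for u in atlas.get(strand, []):
            for g in genes:
                a, b = u.interval, g.interval
                if (a.chrom == b.chrom and b.strand != strand
                        and min(a.end, b.end) - max(a.start, b.start) >= 1):
                    pairs.append((u.id, g.id, "antisense"))
    return pairs


def make_counts(features: Sequence[str], design: SampleDesign,
                cluster_profiles: np.ndarray, dispersion: float = 0.1,
                libsize_range: Tuple[float, float] = (0.8, 1.2),
                seed: int = 0, base_mean: float = 100.0,
                abundance_sd: float = 0.5,
                cluster_assignment: Optional[Sequence[int]] = None
                ) -> Tuple[pd.DataFrame, SyntheticTruth]:
    """NB counts with library-size variation and planted cluster profiles.

    ``cluster_profiles`` is a (K, T) array of relative per-timepoint means,
    one row per cluster (include a flat row for null features). Each
    feature is assigned a cluster (uniformly unless given), gets a
    lognormal abundance factor, and counts are drawn
    NB(mean = profile * abundance * base_mean * depth_s, dispersion) with a
    per-sample depth factor uniform over ``libsize_range``. Truth records
    the assignment and the true log2FC of every timepoint pair.
    """
    if dispersion <= 0:
        raise ValueError("dispersion must be > 0")
    profiles = np.asarray(cluster_profiles, dtype=float)
    tps = design.timepoint_order
    if profiles.ndim != 2 or profiles.shape[1] != len(tps):
        raise ValueError(f"cluster_profiles must be (K, {len(tps)})")
    rng = np.random.default_rng(seed)
    n_feat = len(features)
    if cluster_assignment is None:
        assignment = rng.integers(0, profiles.shape[0], size=n_feat)
    else:
        assignment = np.asarray(cluster_assignment, dtype=int)
        if assignment.shape != (n_feat,):
            raise ValueError("cluster_assignment length mismatch")

    depth = rng.uniform(libsize_range[0], libsize_range[1], size=len(design.samples))
    abund = np.exp(rng.normal(0.0, abundance_sd, size=n_feat))
    tp_idx = np.array([tps.index(t) for t in design.timepoints])

    mean = (profiles[assignment][:, tp_idx] * abund[:, None]
            * base_mean * depth[None, :])
    size = 1.0 / dispersion
    with np.errstate(divide="ignore"):
        p = size / (size + mean)
    counts = np.where(mean > 0, rng.negative_binomial(size, np.clip(p, 1e-12, 1.0)), 0)
    df = pd.DataFrame(counts.astype(np.int64), index=list(features),
                      columns=design.samples)

    truth = SyntheticTruth()
    truth.planted_cluster_of_feature = {f: int(c) for f, c in zip(features, assignment)}
    for ta, tb in all_contrasts(tps):
        ia, ib = tps.index(ta), tps.index(tb)
        for f, c in zip(features, assignment):
            ma, mb = profiles[c, ia], profiles[c, ib]
            if ma > 0 and mb > 0:
                lfc = float(np.log2(mb / ma))
            else:
                lfc = float("nan")
            truth.planted_de[(f, f"{ta}/{tb}")] = lfc
    truth.extras["depth_factors"] = {s: float(d) for s, d in zip(design.samples, depth)}
    return df, truth


def _sample_concrete(motif: str, rng: np.random.Generator) -> str:
    return "".join(
        c if len(IUPAC[c]) == 1 else IUPAC[c][int(rng.integers(len(IUPAC[c])))]
        for c in motif.upper()
    )


def _window_bounds(g: GeneModel, window: str) -> Tuple[int, int, bool]:
    """Genomic slice of a promoter window; bool = needs revcomp (- strand)."""
    iv = g.interval
    if iv.strand == "+":
        if window == "learning":
            return g.tss - LEARNING_UP, g.tss - TARGET_UP, False
        t_end = g.utr5_end if g.utr5_end is not None else g.tss
        return g.tss - TARGET_UP, t_end, False
    if window == "learning":
        return g.tss + 1 + TARGET_UP, g.tss + 1 + LEARNING_UP, True
    t_start = g.utr5_end if g.utr5_end is not None else g.tss + 1
    return t_start, g.tss + 1 + TARGET_UP, True


def make_promoters(bundle: GenomeBundle, motif_plants: Sequence[dict],
                   cluster_of_gene: Dict[str, int], seed: int = 0
                   ) -> SyntheticTruth:
    """Plant motif occurrences into promoter windows, in place.

    Each plant is ``{"cluster": int, "motif": IUPAC str, "fraction": float,
    "window": "target"|"learning"}``. Carrier genes are a random fraction
    of the cluster's genes; each carrier receives one concrete occurrence
    at a uniformly random position inside the window, written into the
    genome sequence (reverse-complemented for - genes). The genome
    background is already i.i.d. uniform ACGT from make_genome.
    """
    rng = np.random.default_rng(seed)
    seqs = {c: bytearray(s, "ascii") for c, s in bundle.sequences.items()}
    truth = SyntheticTruth()
    for plant in motif_plants:
        cluster = plant["cluster"]
        motif = plant["motif"].upper()
        fraction = float(plant["fraction"])
        window = plant.get("window", "target")
        if not 0.0 <= fraction <= 1.0:
            raise ValueError("carrier fraction must lie in [0, 1]")
        members = [g for g in bundle.genes if cluster_of_gene.get(g.id) == cluster]
        n_carriers = int(round(fraction * len(members)))
        order = rng.permutation(len(members))
        carriers = [members[i] for i in order[:n_carriers]]
        placed = []
        for g in carriers:
            lo, hi, flip = _window_bounds(g, window)
            lo = max(0, lo)
            hi = min(len(seqs[g.interval.chrom]), hi)
            width = hi - lo
            if width < len(motif):
                raise ValueError(
                    f"motif {motif} longer than {window} window of gene {g.id}"
                )
            concrete = _sample_concrete(motif, rng)
            offset = int(rng.integers(0, width - len(motif) + 1))
            insert = revcomp(concrete) if flip else concrete
            pos = lo + offset
            seqs[g.interval.chrom][pos:pos + len(insert)] = insert.encode()
            placed.append({"gene": g.id, "pos": pos, "sequence": concrete})
        truth.planted_motifs.append({
            "cluster": cluster, "motif": motif, "fraction": fraction,
            "window": window, "carriers": placed,
        })
    bundle.sequences = {c: b.decode() for c, b in seqs.items()}
    return truth


def make_chromatin_states(bundle: GenomeBundle, n_states: int = 9,
                          seed: int = 0,
                          seg_len_range: Tuple[int, int] = (2000, 10000)
                          ) -> ChromatinStateTrack:
    """Random state segmentation tiling each chromosome without gaps."""
    rng = np.random.default_rng(seed)
    labels_all = [f"CS{i + 1}" for i in range(n_states)]
    intervals, labels = [], []
    for chrom, seq in bundle.sequences.items():
        pos = 0
        n = len(seq)
        prev = None
        while pos < n:
            seg = int(rng.integers(seg_len_range[0], seg_len_range[1] + 1))
            end = min(pos + seg, n)
            lab = labels_all[int(rng.integers(n_states))]
            while lab == prev and n_states > 1:
                lab = labels_all[int(rng.integers(n_states))]
            intervals.append(GenomicInterval(chrom, pos, end))
            labels.append(lab)
            prev = lab
            pos = end
    return ChromatinStateTrack.from_intervals(intervals, labels)


def place_intervals_with_bias(track: ChromatinStateTrack,
                              lengths: Sequence[Tuple[str, int]],
                              bias: Dict[str, float], seed: int = 0,
                              max_tries: int = 10000) -> List[GenomicInterval]:
    """Place intervals with state-dependent rejection sampling.

    Proposal is uniform on the interval's chromosome; acceptance
    probability is bias[state at the interval midpoint] / max(bias).
    States absent from ``bias`` get multiplier 1.
    """
    mults = {s: float(bias.get(s, 1.0)) for s in track.states}
    if any(m < 0 for m in mults.values()):
        raise ValueError("multipliers must be >= 0")
    mmax = max(mults.values())
    if mmax <= 0:
        raise ValueError("at least one multiplier must be positive")
    rng = np.random.default_rng(seed)
    out = []
    for chrom, length in lengths:
        lo = int(track.boundaries[chrom][0])
        span = track.chrom_length(chrom) - length
        if span < 0:
            raise ValueError(f"interval of {length} bp exceeds {chrom}")
        for _ in range(max_tries):
            s = lo + int(rng.integers(0, span + 1))
            mid = s + length // 2
            b = track.boundaries[chrom]
            seg = int(np.searchsorted(b, mid, side="right") - 1)
            seg = min(max(seg, 0), len(track.labels[chrom]) - 1)
            state = track.labels[chrom][seg]
            if rng.random() < mults[state] / mmax:
                out.append(GenomicInterval(chrom, s, s + length))
                break
        else:
            raise RuntimeError("rejection sampling failed to place an interval")
    return out


def make_ploidy(percent_profiles: Dict[str, Sequence[float]],
                noise_sd: float = 1.0, n_reps: int = 3, seed: int = 0
                ) -> Tuple[pd.DataFrame, Dict[str, float]]:
    """Replicate ploidy-class percentage tables plus noiseless truth EI.

    Each profile (percentages over 2C..32C summing to 100) yields
    ``n_reps`` replicates with truncated-Gaussian noise, renormalized to
    sum to 100. Truth EIs are computed from the noiseless profiles.
    """
    from .ploidy import PLOIDY_CLASSES, endoreduplication_index

    rng = np.random.default_rng(seed)
    rows = []
    truth: Dict[str, float] = {}
    for cond, profile in percent_profiles.items():
        p = np.asarray(profile, dtype=float)
        if p.shape != (5,):
            raise ValueError("profiles must have 5 class percentages")
        if abs(p.sum() - 100.0) > 1e-6:
            raise ValueError(f"profile for {cond} sums to {p.sum()}, not 100")
        truth[cond] = endoreduplication_index(p)
        for r in range(1, n_reps + 1):
            noisy = np.clip(p + rng.normal(0.0, noise_sd, size=5), 0.0, None)
            if noisy.sum() <= 0:
                raise ValueError("all-zero ploidy vector after noise")
            noisy = noisy * 100.0 / noisy.sum()
            row = {"condition": cond, "replicate": r}
            row.update({f"pct_{c}": float(v) for c, v in zip(PLOIDY_CLASSES, noisy)})
            rows.append(row)
    return pd.DataFrame(rows), truth
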