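"""Preferentially located motif (PLM) discovery in promoters.

For each gene the promoter is split, in transcription orientation, into a
*learning* window (TSS-1000 .. TSS-300) and a *target* window (TSS-300 ..
5'UTR end, or the TSS when no 5'UTR is annotated). A motif preferentially
located near the TSS is one whose occurrences concentrate in the target
window beyond what a position-uniform null allows: with n_T and n_L
occurrences over P_T and P_L scannable positions, the one-sided p-value is
the upper tail of Binomial(n_T + n_L, P_T / (P_T + P_L)) at n_T.

Discovery enumerates every exact k-mer (k = 4..11) actually present in the
windows of a cluster's promoters, keeps significant ones, and greedily
collapses Hamming-distance-1 neighbours of equal length into IUPAC
consensus motifs which are re-tested. Library mode instead tests a fixed
IUPAC motif list for target-window *presence* enrichment in a cluster
versus all genes (one-sided Fisher).

Matching is single-strand on the promoter-forward (transcribed) strand and
counts overlapping occurrences.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust
from .intervals import GeneModel

LEARNING_UP = 1000   # learning window: TSS-1000 .. TSS-300
TARGET_UP = 300      # target window:   TSS-300  .. 5'UTR end (or TSS)

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_CODE_OF = {frozenset(v): k for k, v in IUPAC.items()}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_regex(motif: str) -> re.Pattern:
    try:
        body = "".join(
            c if len(IUPAC[c]) == 1 else "[" + IUPAC[c] + "]" for c in motif.upper()
        )
    except KeyError as e:
        raise ValueError(f"non-IUPAC character in motif {motif!r}: {e}") from None
    # lookahead so overlapping occurrences are all counted
    return re.compile(f"(?=({body}))")


def count_matches(seq: str, motif: str) -> int:
    """Overlapping occurrences of an IUPAC motif on the given strand."""
    return sum(1 for _ in iupac_regex(motif).finditer(seq))


def match_positions(seq: str, motif: str) -> List[int]:
    return [m.start() for m in iupac_regex(motif).finditer(seq)]


@dataclass
class PromoterWindows:
    """Learning and target sequences, transcription-oriented, per gene."""

    learning: Dict[str, str]
    target: Dict[str, str]
    excluded: Dict[str, str] = field(default_factory=dict)  # gene -> reason

    def genes(self) -> List[str]:
        return sorted(self.learning)

    def subset(self, gene_ids: Iterable[str]) -> "PromoterWindows":
        ids = [g for g in gene_ids if g in self.learning]
        return PromoterWindows(
            {g: self.learning[g] for g in ids},
            {g: self.target[g] for g in ids},
        )

    def effective_positions(self, k: int) -> Tuple[int, int]:
        """Scannable positions per window for a k-mer, floored at 0 per gene."""
        p_t = sum(max(0, len(s) - k + 1) for s in self.target.values())
        p_l = sum(max(0, len(s) - k + 1) for s in self.learning.values())
        return p_t, p_l


def extract_windows(genes: Sequence[GeneModel], genome: Dict[str, str],
                    learning_up: int = LEARNING_UP, target_up: int = TARGET_UP
                    ) -> PromoterWindows:
    """Cut strand-corrected learning/target windows out of the genome.

    Genes whose learning window is fully clipped off the chromosome are
    excluded and listed with a reason. Partial clipping is applied silently
    (the clipped length shows up in the effective position counts).
    """
    learning: Dict[str, str] = {}
    target: Dict[str, str] = {}
    excluded: Dict[str, str] = {}
    for g in genes:
        iv = g.interval
        if iv.chrom not in genome:
            raise KeyError(f"chromosome {iv.chrom} of gene {g.id} missing from FASTA")
        seq = genome[iv.chrom]
        if iv.strand == "+":
            t_end = g.utr5_end if g.utr5_end is not None else g.tss
            l_lo, l_hi = g.tss - learning_up, g.tss - target_up
            t_lo, t_hi = g.tss - target_up, t_end
            if l_hi <= 0:
                excluded[g.id] = "learning window fully clipped at chromosome start"
                continue
            learning[g.id] = seq[max(0, l_lo):l_hi]
            target[g.id] = seq[max(0, t_lo):t_hi]
        else:
            # on -, upstream means larger coordinates; windows are revcomped
            t_start = g.utr5_end if g.utr5_end is not None else g.tss + 1
            l_lo, l_hi = g.tss + 1 + target_up, g.tss + 1 + learning_up
            t_lo, t_hi = t_start, g.tss + 1 + target_up
            n = len(seq)
            if l_lo >= n:
                excluded[g.id] = "learning window fully clipped at chromosome end"
                continue
            learning[g.id] = revcomp(seq[l_lo:min(n, l_hi)])
            target[g.id] = revcomp(seq[t_lo:min(n, t_hi)])
    return PromoterWindows(learning, target, excluded)


def count_occurrences(windows: PromoterWindows, motif: str
                      ) -> Tuple[int, int, Tuple[int, int]]:
    """Total (target, learning) occurrence counts and effective positions."""
    k = len(motif)
    n_t = sum(count_matches(s, motif) for s in windows.target.values())
    n_l = sum(count_matches(s, motif) for s in windows.learning.values())
    return n_t, n_l, windows.effective_positions(k)


def positional_test(n_target: int, n_learning: int,
                    positions_target: int, positions_learning: int) -> float:
    """Upper-tail binomial p for target-window over-representation.

    Under the null, each of the n_T + n_L occurrences falls on a uniformly
    chosen effective position, so the target count is Binomial with
    success probability P_T / (P_T + P_L).
    """
    if positions_target <= 0 or positions_learning <= 0:
        raise ValueError("both windows need at least one effective position")
    n = n_target + n_learning
    if n == 0:
        return 1.0
    pi = positions_target / (positions_target + positions_learning)
    return float(stats.binom.sf(n_target - 1, n, pi))


@dataclass
class MotifCandidate:
    """An exact or IUPAC-collapsed motif with its positional statistics."""

    consensus: str
    members: List[str]
    n_target: int
    n_learning: int
    pvalue: float

    @property
    def k(self) -> int:
        return len(self.consensus)

    @property
    def significant(self) -> bool:
        return self.pvalue < 0.05


def _kmer_window_counts(seqs: Iterable[str], k: int) -> Dict[str, int]:
    counts: Dict[str, int] = {}
    for s in seqs:
        for i in range(len(s) - k + 1):
            w = s[i:i + k]
            if "N" in w:
                continue
            counts[w] = counts.get(w, 0) + 1
    return counts


def _hamming1(a: str, b: str) -> bool:
    if len(a) != len(b):
        return False
    return sum(x != y for x, y in zip(a, b)) == 1


def _consensus(kmers: Sequence[str]) -> str:
    out = []
    for chars in zip(*kmers):
        letters = frozenset(itertools.chain.from_iterable(IUPAC[c] for c in chars))
        out.append(_CODE_OF[letters])
    return "".join(out)


def discover(windows: PromoterWindows, k_range: Sequence[int] = range(4, 12),
             alpha: float = 0.05, collapse: bool = True) -> List[MotifCandidate]:
    """Exhaustive k-mer PLM discovery over a cluster's promoter windows.

    Every exact k-mer is tested (absent k-mers have p = 1 and can never be
    significant, so only k-mers present in the windows are materialized).
    Significant k-mers are greedily collapsed: walking candidates by
    ascending p, each absorbs remaining same-length k-mers at Hamming
    distance <= 1 into an IUPAC consensus, which is re-tested. Output is
    sorted by p ascending. Deterministic: ties break lexicographically.
    """
    if not windows.learning:
        raise ValueError("empty promoter window set")
    candidates: List[MotifCandidate] = []
    for k in k_range:
        p_t, p_l = windows.effective_positions(k)
        if p_t <= 0 or p_l <= 0:
            continue
        tc = _kmer_window_counts(windows.target.values(), k)
        lc = _kmer_window_counts(windows.learning.values(), k)
        sig: List[MotifCandidate] = []
        for kmer in set(tc) | set(lc):
            n_t, n_l = tc.get(kmer, 0), lc.get(kmer, 0)
            p = positional_test(n_t, n_l, p_t, p_l)
            if p < alpha:
                sig.append(MotifCandidate(kmer, [kmer], n_t, n_l, p))
        if not collapse:
            candidates.extend(sig)
            continue
        sig.sort(key=lambda c: (c.pvalue, c.consensus))
        remaining = {c.consensus: c for c in sig}
        for cand in sig:
            if cand.consensus not in remaining:
                continue
            del remaining[cand.consensus]
            absorbed = [m for m in sorted(remaining) if _hamming1(cand.consensus, m)]
            if absorbed:
                for m in absorbed:
                    del remaining[m]
                members = cand.members + absorbed
                cons = _consensus(members)
                n_t = sum(count_matches(s, cons) for s in windows.target.values())
                n_l = sum(count_matches(s, cons) for s in windows.learning.values())
                p = positional_test(n_t, n_l, p_t, p_l)
                candidates.append(MotifCandidate(cons, members, n_t, n_l, p))
            else:
                candidates.append(cand)
    candidates.sort(key=lambda c: (c.pvalue, c.consensus))
    return candidates


def candidates_table(candidates: Sequence[MotifCandidate]) -> pd.DataFrame:
    rows = [
        {"consensus": c.consensus, "k": c.k, "n_target": c.n_target,
         "n_learning": c.n_learning, "pvalue": c.pvalue,
         "members": ",".join(c.members)}
        for c in candidates
    ]
    df = pd.DataFrame(rows, columns=["consensus", "k", "n_target", "n_learning",
                                     "pvalue", "members"])
    if len(df):
        df["padj"] = bh_adjust(df["pvalue"].to_numpy())
    else:
        df["padj"] = pd.Series(dtype=float)
    return df


def long_motifs(df: pd.DataFrame, min_k: int = 7) -> pd.DataFrame:
    """The >= 7-mer filtered view of a discovery table."""
    return df[df["k"] >= min_k].reset_index(drop=True)


def scan_library(library: pd.DataFrame, cluster_windows: PromoterWindows,
                 background_windows: PromoterWindows, alpha: float = 0.05
                 ) -> pd.DataFrame:
    """Target-window presence enrichment of a fixed motif list.

    ``library`` has columns (name, motif). For each motif, genes carrying
    >= 1 target-window occurrence are counted in the cluster and in the
    background gene set, and a one-sided Fisher (hypergeometric) test asks
    whether presence is enriched in the cluster.
    """
    if len(library) == 0:
        raise ValueError("empty motif library")
    cluster_genes = set(cluster_windows.target)
    bg_genes = set(background_windows.target)
    if not cluster_genes <= bg_genes:
        raise ValueError("background must contain every cluster gene")
    rows = []
    for _, rec in library.iterrows():
        name, motif = rec["name"], rec["motif"]
        carriers = {g for g, s in background_windows.target.items()
                    if count_matches(s, motif) > 0}
        k_cl = len(carriers & cluster_genes)
        k_bg = len(carriers)
        p = float(stats.hypergeom.sf(k_cl - 1, len(bg_genes), k_bg, len(cluster_genes)))
        rows.append({"name": name, "motif": motif,
                     "carriers_cluster": k_cl, "carriers_background": k_bg,
                     "pvalue": min(p, 1.0)})
    out = pd.DataFrame(rows)
    out["padj"] = bh_adjust(out["pvalue"].to_numpy())
    out["significant"] = out["pvalue"] < alpha
    return out.sort_values("pvalue", kind="stable").reset_index(drop=True)
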