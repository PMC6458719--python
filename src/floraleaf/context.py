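"""Regulatory context of lncTUs: chromatin states, NATs, TFBS scanning.

Chromatin-state enrichment compares an observed lncTU/state intersection
statistic with a null built by reshuffling: each lncTU-length interval is
re-placed uniformly on its own chromosome, preserving length and
chromosome, overlaps among shuffled intervals allowed. Fold change is
observed / null mean and the empirical p uses the add-one permutation
convention.

NAT couples are antisense-overlapping (lncTU, gene) pairs; a couple is
flagged when both members are called DE with opposite log2FC signs in at
least one contrast. TFBS scanning searches IUPAC motifs (both genomic
strands) in a window anchored to the lncTU body (default 3 kb beyond the
5' end, 1 kb beyond the 3' end) and classifies each hit into exactly one
of five position classes: 5', overlap-5', inside, overlap-3', 3'.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .intervals import GeneModel, GenomicInterval, LncTU, overlap_bp
from .plm import iupac_regex, revcomp

STATE_LABELS = tuple(f"CS{i}" for i in range(1, 10))
POSITION_CLASSES = ("5prime", "overlap-5prime", "inside", "overlap-3prime", "3prime")


@dataclass
class ChromatinStateTrack:
    """Labeled state segments tiling each chromosome (no gaps/overlaps)."""

    boundaries: Dict[str, np.ndarray]  # chrom -> sorted segment starts + final end
    labels: Dict[str, np.ndarray]      # chrom -> label per segment

    @classmethod
    def from_intervals(cls, intervals: Sequence[GenomicInterval],
                       labels: Sequence[str]) -> "ChromatinStateTrack":
        per_chrom: Dict[str, List[Tuple[int, int, str]]] = {}
        for iv, lab in zip(intervals, labels):
            per_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, lab))
        boundaries, labs = {}, {}
        for chrom, segs in per_chrom.items():
            segs.sort()
            for (s0, e0, _), (s1, _, _) in zip(segs, segs[1:]):
                if s1 < e0:
                    raise ValueError(f"overlapping states on {chrom} at {s1}")
            boundaries[chrom] = np.array([s for s, _, _ in segs] + [segs[-1][1]])
            labs[chrom] = np.array([l for _, _, l in segs])
        return cls(boundaries, labs)

    @classmethod
    def read_bed(cls, path) -> "ChromatinStateTrack":
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        ivs = [GenomicInterval(r[0], int(r[1]), int(r[2])) for r in df.itertuples(index=False)]
        return cls.from_intervals(ivs, [str(r[3]) for r in df.itertuples(index=False)])

    @property
    def states(self) -> List[str]:
        out: set = set()
        for labs in self.labels.values():
            out.update(labs.tolist())
        return sorted(out)

    def chrom_length(self, chrom: str) -> int:
        b = self.boundaries[chrom]
        return int(b[-1] - b[0])

    def coverage_bp(self) -> Dict[str, int]:
        cov: Dict[str, int] = {s: 0 for s in self.states}
        for chrom, b in self.boundaries.items():
            widths = np.diff(b)
            for lab, w in zip(self.labels[chrom], widths):
                cov[lab] += int(w)
        return cov

    def segment_range(self, chrom: str, start: int, end: int) -> Tuple[int, int]:
        """Indices [i, j) of segments overlapping [start, end)."""
        b = self.boundaries[chrom]
        i = int(np.searchsorted(b, start, side="right") - 1)
        j = int(np.searchsorted(b, end, side="left"))
        return max(i, 0), max(j, 0)

    def overlap_by_state(self, chrom: str, start: int, end: int) -> Dict[str, int]:
        """bp of [start, end) falling in each state label."""
        b = self.boundaries[chrom]
        i, j = self.segment_range(chrom, start, end)
        out: Dict[str, int] = {}
        for seg in range(i, j):
            lo = max(start, int(b[seg]))
            hi = min(end, int(b[seg + 1]))
            if hi > lo:
                lab = self.labels[chrom][seg]
                out[lab] = out.get(lab, 0) + (hi - lo)
        return out


def _statistic(track: ChromatinStateTrack, intervals: Sequence[Tuple[str, int, int]],
               states: Sequence[str], metric: str) -> np.ndarray:
    """Per-state statistic: lncTU count with >=1 bp overlap, or total bp."""
    idx = {s: i for i, s in enumerate(states)}
    out = np.zeros(len(states))
    for chrom, start, end in intervals:
        ov = track.overlap_by_state(chrom, start, end)
        for lab, bp in ov.items():
            if lab not in idx:
                continue
            out[idx[lab]] += 1 if metric == "count" else bp
    return out


def state_enrichment(lnctus: Sequence[LncTU], track: ChromatinStateTrack,
                     n_shuffles: int = 1000, metric: str = "count",
                     seed: int = 0, set_label: str = "all") -> pd.DataFrame:
    """Interval-shuffle enrichment of a lncTU set in each chromatin state.

    Returns one row per state with the observed statistic, null mean/SD
    over shuffles, fold change observed/null-mean and two empirical
    p-values (enrichment and depletion), each (1 + #extreme) / (1 + n).
    """
    if metric not in ("count", "bp"):
        raise ValueError("metric must be 'count' or 'bp'")
    states = track.states
    obs_iv = []
    for u in lnctus:
        iv = u.interval
        if iv.chrom not in track.boundaries:
            raise KeyError(f"lncTU chromosome {iv.chrom} absent from state track")
        if iv.length > track.chrom_length(iv.chrom):
            raise ValueError(f"lncTU {u.id} longer than its chromosome")
        obs_iv.append((iv.chrom, iv.start, iv.end))
    observed = _statistic(track, obs_iv, states, metric)

    rng = np.random.default_rng(seed)
    null = np.zeros((n_shuffles, len(states)))
    chrom_origin = {c: int(track.boundaries[c][0]) for c in track.boundaries}
    chrom_len = {c: track.chrom_length(c) for c in track.boundaries}
    for b in range(n_shuffles):
        shuffled = []
        for chrom, start, end in obs_iv:
            length = end - start
            lo = chrom_origin[chrom]
            s = lo + int(rng.integers(0, chrom_len[chrom] - length + 1))
            shuffled.append((chrom, s, s + length))
        null[b] = _statistic(track, shuffled, states, metric)

    null_mean = null.mean(axis=0)
    null_sd = null.std(axis=0, ddof=1) if n_shuffles > 1 else np.zeros(len(states))
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(null_mean > 0, observed / null_mean, np.nan)
    p_enrich = (1 + (null >= observed[None, :]).sum(axis=0)) / (1 + n_shuffles)
    p_deplete = (1 + (null <= observed[None, :]).sum(axis=0)) / (1 + n_shuffles)
    return pd.DataFrame({
        "set": set_label, "state": states, "observed": observed,
        "null_mean": null_mean, "null_sd": null_sd, "fold_change": fold,
        "p_enrich": p_enrich, "p_deplete": p_deplete,
        "metric": metric, "n_shuffles": n_shuffles, "seed": seed,
    })


def find_nat_couples(lnctus: Sequence[LncTU], genes: Sequence[GeneModel],
                     de_table: Optional[pd.DataFrame] = None,
                     contrasts: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Antisense-overlapping (lncTU, gene) couples with concordance labels.

    Geometric candidates are pairs with >= 1 bp overlap on opposite strands
    (NA-strand lncTUs are excluded). Per contrast the label is
    ``opposite`` / ``same`` when both members are called DE (by log2FC sign
    agreement), ``one-sided`` when exactly one is, else ``neither``. A
    couple is flagged when opposite in at least one contrast.
    """
    by_chrom: Dict[str, List[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.interval.chrom, []).append(g)
    for gl in by_chrom.values():
        gl.sort(key=lambda g: g.interval.start)

    calls: Dict[Tuple[str, str], Tuple[bool, float]] = {}
    if de_table is not None:
        for rec in de_table.itertuples(index=False):
            calls[(rec.feature, rec.contrast)] = (bool(rec.call), float(rec.log2fc))
        if contrasts is None:
            contrasts = sorted(de_table["contrast"].unique())
    contrasts = list(contrasts or [])

    rows = []
    for u in lnctus:
        if u.strand_class == "NA":
            continue
        iv = u.interval
        for g in by_chrom.get(iv.chrom, []):
            giv = g.interval
            if giv.start >= iv.end:
                break
            if giv.strand == iv.strand:
                continue
            ov = overlap_bp(iv, giv)
            if ov < 1:
                continue
            labels = {}
            flagged = False
            for c in contrasts:
                lnc = calls.get((u.id, c))
                gen = calls.get((g.id, c))
                lnc_called = lnc is not None and lnc[0]
                gen_called = gen is not None and gen[0]
                if lnc_called and gen_called:
                    lab = "opposite" if np.sign(lnc[1]) != np.sign(gen[1]) else "same"
                elif lnc_called or gen_called:
                    lab = "one-sided"
                else:
                    lab = "neither"
                labels[c] = lab
                flagged = flagged or lab == "opposite"
            row = {"lnctu": u.id, "gene": g.id, "overlap_bp": ov, "flagged": flagged}
            for c in contrasts:
                row[f"label_{c}"] = labels[c]
            rows.append(row)
    cols = ["lnctu", "gene", "overlap_bp", "flagged"] + [f"label_{c}" for c in contrasts]
    return pd.DataFrame(rows, columns=cols)


def _classify_hit(hit_start: int, hit_end: int, body_start: int, body_end: int) -> str:
    """One of the five position classes relative to the lncTU body."""
    if hit_end <= body_start:
        return "5prime"
    if hit_start < body_start:
        return "overlap-5prime"
    if hit_end <= body_end:
        return "inside"
    if hit_start < body_end:
        return "overlap-3prime"
    return "3prime"


def tfbs_scan(lnctus: Sequence[LncTU], genome: Dict[str, str],
              motifs: pd.DataFrame, window_up: int = 3000,
              window_down: int = 1000) -> pd.DataFrame:
    """Scan IUPAC motifs around lncTUs and classify hit positions.

    The search region extends ``window_up`` beyond the 5' end and
    ``window_down`` beyond the 3' end of the body, in lncTU orientation
    (NA-strand units use the + reading; both genomic strands are scanned
    either way, so only the up/down anchoring depends on orientation).
    Position classes are reported in transcription orientation: a hit
    upstream of the 5' end is ``5prime`` also for - strand units.
    """
    if window_up < 0 or window_down < 0:
        raise ValueError("window sizes must be >= 0")
    rows = []
    for u in lnctus:
        iv = u.interval
        seq = genome[iv.chrom]
        if iv.strand == "-":
            lo = iv.start - window_down
            hi = iv.end + window_up
        else:
            lo = iv.start - window_up
            hi = iv.end + window_down
        lo_c, hi_c = max(0, lo), min(len(seq), hi)
        region = seq[lo_c:hi_c]
        clipped = (lo_c != lo) or (hi_c != hi)
        for rec in motifs.itertuples(index=False):
            name, motif = rec.name, rec.motif
            hits = set()
            for m in iupac_regex(motif).finditer(region):
                s = lo_c + m.start()
                hits.add((s, s + len(motif), "+"))
            rc = revcomp(motif)
            for m in iupac_regex(rc).finditer(region):
                s = lo_c + m.start()
                hits.add((s, s + len(motif), "-"))
            for s, e, strand in sorted(hits):
                cls = _classify_hit(s, e, iv.start, iv.end)
                if iv.strand == "-":
                    cls = {"5prime": "3prime", "3prime": "5prime",
                           "overlap-5prime": "overlap-3prime",
                           "overlap-3prime": "overlap-5prime"}.get(cls, cls)
                rows.append({"lnctu": u.id, "motif_name": name, "motif": motif,
                             "chrom": iv.chrom, "start": s, "end": e,
                             "match_strand": strand, "position_class": cls,
                             "window_clipped": clipped})
    return pd.DataFrame(rows, columns=["lnctu", "motif_name", "motif", "chrom",
                                       "start", "end", "match_strand",
                                       "position_class", "window_clipped"])


def tfbs_site_counts(hits: pd.DataFrame) -> pd.DataFrame:
    """Per-lncTU TFBS hit counts, total and per position class."""
    if hits.empty:
        return pd.DataFrame(columns=["lnctu", "n_sites"] + list(POSITION_CLASSES))
    counts = hits.groupby("lnctu").size().rename("n_sites").reset_index()
    per_class = (hits.groupby(["lnctu", "position_class"]).size()
                 .unstack(fill_value=0))
    for c in POSITION_CLASSES:
        if c not in per_class.columns:
            per_class[c] = 0
    per_class = per_class[list(POSITION_CLASSES)].reset_index()
    return counts.merge(per_class, on="lnctu")
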