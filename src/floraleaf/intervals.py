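"""Stranded genomic intervals and gene/lncTU data model.

All coordinates are 0-based, half-open (BED convention). GFF3 input is
converted on read (start - 1) and on write (start + 1). Under this
convention two intervals are *book-ended* exactly when ``a.end == b.start``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

STRANDS = ("+", "-", "NA")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open interval on a chromosome.

    strand is one of ``+``, ``-`` or ``NA`` (unknown/unstranded, written
    as ``.`` in BED output).
    """

    chrom: str
    start: int
    end: int
    strand: str = "NA"

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


def overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    """Strand-agnostic overlap in bp; 0 for different chromosomes."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


@dataclass(frozen=True)
class GeneModel:
    """A protein-coding gene with a strand-aware TSS and optional 5'UTR end.

    ``tss`` is the first transcribed base: ``interval.start`` on the +
    strand, ``interval.end - 1`` on the - strand. ``utr5_end`` is the
    half-open genomic boundary of the 5'UTR (exclusive on +, i.e. the UTR
    occupies [start, utr5_end); on - it is the inclusive-start boundary,
    the UTR occupying [utr5_end, end)).
    """

    id: str
    interval: GenomicInterval
    utr5_end: Optional[int] = None

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError(f"gene {self.id}: strand must be + or -")
        if self.utr5_end is not None:
            iv = self.interval
            if iv.strand == "+":
                ok = iv.start < self.utr5_end <= iv.end
            else:
                ok = iv.start <= self.utr5_end < iv.end
            if not ok:
                raise ValueError(
                    f"gene {self.id}: 5'UTR end {self.utr5_end} outside gene body"
                )

    @property
    def tss(self) -> int:
        iv = self.interval
        return iv.start if iv.strand == "+" else iv.end - 1

    @property
    def utr5_length(self) -> int:
        if self.utr5_end is None:
            return 0
        iv = self.interval
        return (self.utr5_end - iv.start) if iv.strand == "+" else (iv.end - self.utr5_end)


@dataclass(frozen=True)
class SourceRecord:
    """One lncRNA annotation record from one source dataset."""

    dataset: str
    record_id: str
    interval: GenomicInterval


@dataclass
class LncTU:
    """A merged long non-coding transcription unit.

    The interval is the exact union span of the member records; all
    members share the unit's strand class. The id is synthesized from the
    coordinates so it is stable across runs: ``chrom:start-end:strand``.
    """

    interval: GenomicInterval
    members: list = field(default_factory=list)  # list[SourceRecord]

    @property
    def id(self) -> str:
        iv = self.interval
        return f"{iv.chrom}:{iv.start}-{iv.end}:{iv.strand}"

    @property
    def strand_class(self) -> str:
        return self.interval.strand


def span(intervals: Iterable[GenomicInterval]) -> GenomicInterval:
    """Union span of same-chromosome, same-strand intervals."""
    ivs = list(intervals)
    if not ivs:
        raise ValueError("empty interval list")
    chroms = {iv.chrom for iv in ivs}
    strands = {iv.strand for iv in ivs}
    if len(chroms) != 1 or len(strands) != 1:
        raise ValueError("span requires a single chromosome and strand")
    return GenomicInterval(
        ivs[0].chrom, min(iv.start for iv in ivs), max(iv.end for iv in ivs), ivs[0].strand
    )
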