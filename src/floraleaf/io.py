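"""Readers and writers for the plain-text formats the pipeline exchanges.

BED is 0-based half-open; GFF3 is 1-based closed and converted to the
internal half-open convention on read (start - 1) and back on write.
FASTA goes through Biopython.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import GeneModel, GenomicInterval, SourceRecord

_BED_STRAND = {"+": "+", "-": "-", ".": "NA"}
_OUT_STRAND = {"+": "+", "-": "-", "NA": "."}


def read_fasta(path) -> Dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, sequences: Dict[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_bed(path, dataset: Optional[str] = None) -> List[SourceRecord]:
    """Read BED3/BED6 into source records.

    Missing name fields are synthesized as ``<basename>:<line index>``;
    missing strand is NA.
    """
    path = Path(path)
    ds = dataset if dataset is not None else path.stem
    records = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}:{i + 1}: BED line with <3 fields")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            if start >= end:
                raise ValueError(f"{path}:{i + 1}: start >= end ({start} >= {end})")
            name = f[3] if len(f) > 3 and f[3] not in ("", ".") else f"{ds}:{i}"
            strand = _BED_STRAND.get(f[5], "NA") if len(f) > 5 else "NA"
            records.append(
                SourceRecord(ds, name, GenomicInterval(chrom, start, end, strand))
            )
    return records


def write_bed(path, intervals: Sequence[GenomicInterval], names: Optional[Sequence[str]] = None,
              scores: Optional[Sequence] = None) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else f"iv{i}"
            score = scores[i] if scores is not None else 0
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{_OUT_STRAND[iv.strand]}\n"
            )


_GFF_ATTR = re.compile(r"([^;=]+)=([^;]*)")


def parse_gff_attributes(attr: str) -> Dict[str, str]:
    return {k.strip(): v for k, v in _GFF_ATTR.findall(attr)}


def read_genes_gff3(path) -> List[GeneModel]:
    """Read gene models (``gene`` + optional ``five_prime_UTR`` features)."""
    genes: Dict[str, dict] = {}
    utr_bounds: Dict[str, List[int]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            chrom, _src, ftype, start, end, _score, strand, _frame, attrs = f
            start0, end0 = int(start) - 1, int(end)
            a = parse_gff_attributes(attrs)
            if ftype == "gene":
                gid = a.get("ID")
                if gid is None:
                    raise ValueError("gene feature without ID attribute")
                genes[gid] = dict(chrom=chrom, start=start0, end=end0, strand=strand)
            elif ftype == "five_prime_UTR":
                parent = a.get("Parent")
                utr_bounds.setdefault(parent, []).extend([start0, end0])
    out = []
    for gid, g in genes.items():
        utr5_end = None
        if gid in utr_bounds:
            b = utr_bounds[gid]
            utr5_end = max(b) if g["strand"] == "+" else min(b)
        out.append(
            GeneModel(
                gid,
                GenomicInterval(g["chrom"], g["start"], g["end"], g["strand"]),
                utr5_end=utr5_end,
            )
        )
    return out


def write_genes_gff3(path, genes: Sequence[GeneModel], source: str = "floraleaf") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            iv = g.interval
            fh.write(
                f"{iv.chrom}\t{source}\tgene\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\tID={g.id}\n"
            )
            if g.utr5_end is not None:
                if iv.strand == "+":
                    s0, e0 = iv.start, g.utr5_end
                else:
                    s0, e0 = g.utr5_end, iv.end
                fh.write(
                    f"{iv.chrom}\t{source}\tfive_prime_UTR\t{s0 + 1}\t{e0}\t.\t{iv.strand}\t.\tParent={g.id}\n"
                )


def read_counts_tsv(path) -> pd.DataFrame:
    """Counts as features x samples with the feature id in the first column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df


def write_counts_tsv(path, counts: pd.DataFrame) -> None:
    counts.to_csv(path, sep="\t", index_label="feature")


def read_design_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "timepoint": str})
    required = {"sample", "timepoint", "replicate"}
    if not required.issubset(df.columns):
        raise ValueError(f"design table must have columns {sorted(required)}")
    return df
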