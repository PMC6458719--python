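"""Assembly of the non-redundant lncTU atlas.

Source lncRNA annotations (from any number of datasets, possibly
redundant) are partitioned into three strand classes (+, -, NA) and, within
each class, overlapping or book-ended records are merged into single
transcription units (lncTUs). Book-ended means touching without overlap,
i.e. ``a.end == b.start`` in half-open coordinates. NA-strand records are
never bridged into stranded units.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Sequence

import pandas as pd

from . import io
from .intervals import GenomicInterval, LncTU, SourceRecord, STRANDS


def merge_to_lnctus(sources: Iterable[SourceRecord]) -> Dict[str, List[LncTU]]:
    """Merge source records into strand-partitioned lncTUs.

    Returns a dict keyed by strand class (``+``, ``-``, ``NA``), each value
    a list of lncTUs sorted by (chrom, start). Two records end up in the
    same unit iff a chain of pairwise overlapping-or-book-ended records of
    the same strand class connects them.
    """
    by_strand: Dict[str, List[SourceRecord]] = {s: [] for s in STRANDS}
    for rec in sources:
        by_strand[rec.interval.strand].append(rec)

    atlas: Dict[str, List[LncTU]] = {}
    for strand in STRANDS:
        recs = sorted(by_strand[strand], key=lambda r: (r.interval.chrom, r.interval.start, r.interval.end))
        units: List[LncTU] = []
        cur_members: List[SourceRecord] = []
        cur_chrom = None
        cur_end = -1
        for rec in recs:
            iv = rec.interval
            # book-ended counts as touching: extend while start <= current end
            if cur_members and iv.chrom == cur_chrom and iv.start <= cur_end:
                cur_members.append(rec)
                cur_end = max(cur_end, iv.end)
            else:
                if cur_members:
                    units.append(_close_unit(cur_members, cur_chrom, cur_end, strand))
                cur_members = [rec]
                cur_chrom = iv.chrom
                cur_end = iv.end
        if cur_members:
            units.append(_close_unit(cur_members, cur_chrom, cur_end, strand))
        atlas[strand] = units
    return atlas


def _close_unit(members: List[SourceRecord], chrom: str, end: int, strand: str) -> LncTU:
    start = min(r.interval.start for r in members)
    return LncTU(GenomicInterval(chrom, start, end, strand), members=list(members))


def atlas_units(atlas: Dict[str, List[LncTU]]) -> List[LncTU]:
    """Flatten a strand-partitioned atlas, +/-/NA order, positional within."""
    out: List[LncTU] = []
    for strand in STRANDS:
        out.extend(atlas.get(strand, []))
    return out


def build_atlas(source_paths: Sequence[str]) -> Dict[str, List[LncTU]]:
    """Read lncRNA source files (BED or GFF3 by extension) and merge."""
    records: List[SourceRecord] = []
    for path in source_paths:
        p = str(path)
        if p.endswith((".gff", ".gff3")):
            for g in io.read_genes_gff3(p):
                records.append(SourceRecord(p, g.id, g.interval))
        else:
            records.extend(io.read_bed(p))
    return merge_to_lnctus(records)


def write_atlas(atlas: Dict[str, List[LncTU]], bed_path, membership_path) -> None:
    """Write the atlas as BED6 plus a TSV membership (provenance) table."""
    units = atlas_units(atlas)
    io.write_bed(bed_path, [u.interval for u in units], names=[u.id for u in units])
    rows = [
        {"lnctu": u.id, "dataset": m.dataset, "record_id": m.record_id}
        for u in units
        for m in u.members
    ]
    pd.DataFrame(rows, columns=["lnctu", "dataset", "record_id"]).to_csv(
        membership_path, sep="\t", index=False
    )
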