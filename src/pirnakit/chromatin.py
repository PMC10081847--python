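"""Chromatin-state partitions and read-density summaries.

Given per-mark peak sets (e.g. H3K9me2, H3K9me3, Rhino), the genome is
partitioned into the 2^n disjoint presence/absence cells; cell lengths,
genome fractions, per-region mark coverage and per-cell piRNA densities
(RPKM) follow by exact interval algebra.  Reads are assigned to cells by
their genomic 5' end, the same rule used for binning, so both bases and
reads are conserved exactly across a partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import AlignedRead, GenomicInterval, IntervalSet, ValidationError
from .discovery import Region

__all__ = [
    "ChromatinStateMap",
    "genome_fraction",
    "state_partition",
    "region_state_coverage",
    "density_by_state",
    "intron_exon_density",
]


def _cell_label(present: Tuple[str, ...]) -> str:
    return "+".join(present) if present else "none"


@dataclass
class ChromatinStateMap:
    """Named mark sets and the derived disjoint co-enrichment partition.

    ``partition`` maps a cell label ("H3K9me2+Rhino", ..., "none") to the
    interval set of bases carrying exactly that mark combination.  Cells are
    pairwise disjoint and tile the genome.
    """

    marks: Dict[str, IntervalSet]
    partition: Dict[str, IntervalSet]
    genome_length: int

    def cell_lengths(self) -> pd.Series:
        return pd.Series({label: s.total_length
                          for label, s in self.partition.items()})

    def summary(self) -> pd.DataFrame:
        lengths = self.cell_lengths()
        return pd.DataFrame({
            "bases": lengths,
            "percent": 100.0 * lengths / self.genome_length,
        }).rename_axis("state")


def genome_fraction(mark: IntervalSet, genome_length: int) -> float:
    """Percent of the genome covered by a mark's peak set."""
    if genome_length <= 0:
        raise ValidationError("genome_length must be positive")
    return 100.0 * mark.total_length / genome_length


def state_partition(marks: Mapping[str, IntervalSet],
                    chrom_sizes: Mapping[str, int]) -> ChromatinStateMap:
    """All 2^n presence/absence cells of the given marks.

    Cell intervals are computed by interval intersection/subtraction against
    the genome, so cell lengths sum exactly to the genome length.
    """
    if len(marks) > 8:
        raise ValidationError("at most 8 marks supported (2^n cells)")
    genome_length = int(sum(chrom_sizes.values()))
    genome = IntervalSet.from_tuples(
        (c, 0, n) for c, n in chrom_sizes.items() if n > 0)
    names = list(marks)
    partition: Dict[str, IntervalSet] = {}
    for r in range(len(names), -1, -1):
        for present in combinations(names, r):
            cell = genome
            for m in present:
                cell = cell.intersect(marks[m])
            for m in names:
                if m not in present:
                    cell = cell.subtract(marks[m])
            partition[_cell_label(present)] = cell
    return ChromatinStateMap(marks=dict(marks), partition=partition,
                             genome_length=genome_length)


def region_state_coverage(
    regions: Sequence[Region],
    marks: Mapping[str, IntervalSet],
    reads: Optional[Sequence[AlignedRead]] = None,
    focal_mark: Optional[str] = "Rhino",
) -> Dict[str, object]:
    """Mark coverage of a called region set.

    Returns a dict with:

    * ``per_mark``: DataFrame of covered bases within the union of regions
      and percent of total region bases, per mark and per mark combination;
    * ``per_region``: DataFrame with each region's covered fraction per mark
      and a ``has_<focal_mark>_peak`` flag;
    * ``focal``: count of regions with at least one focal-mark peak, their
      summed length, and (when reads are given) the share of region reads
      they produce.
    """
    region_set = IntervalSet.from_intervals([r.interval for r in regions])
    total = region_set.total_length
    names = list(marks)

    rows = []
    for r in range(1, len(names) + 1):
        for present in combinations(names, r):
            inter = region_set
            for m in present:
                inter = inter.intersect(marks[m])
            rows.append({"marks": _cell_label(present),
                         "bases": inter.total_length,
                         "percent": 100.0 * inter.total_length / total
                         if total else 0.0})
    per_mark = pd.DataFrame(rows)

    reg_rows = []
    for i, region in enumerate(regions):
        iv_set = IntervalSet.from_intervals([region.interval])
        row: Dict[str, object] = {
            "region": i, "chrom": region.interval.chrom,
            "start": region.interval.start, "end": region.interval.end,
            "direction": region.direction,
        }
        for m in names:
            cov = iv_set.intersect(marks[m]).total_length
            row[f"frac_{m}"] = cov / region.length
        if focal_mark in marks:
            row[f"has_{focal_mark}_peak"] = bool(
                iv_set.intersect(marks[focal_mark]).total_length > 0)
        reg_rows.append(row)
    per_region = pd.DataFrame(reg_rows)

    focal: Dict[str, object] = {}
    if focal_mark in marks and len(per_region):
        flag = per_region[f"has_{focal_mark}_peak"]
        flagged = [regions[i] for i in per_region.index[flag]]
        focal["n_regions"] = int(flag.sum())
        focal["total_length"] = int(sum(r.length for r in flagged))
        focal["length_percent"] = (100.0 * focal["total_length"] / total
                                   if total else 0.0)
        if reads is not None:
            flagged_set = IntervalSet.from_intervals(
                [r.interval for r in flagged])
            in_regions = in_flagged = 0
            by_chrom: Dict[str, List[int]] = {}
            for rd in reads:
                by_chrom.setdefault(rd.chrom, []).append(rd.five_prime)
            for chrom, pos in by_chrom.items():
                pos = np.asarray(pos)
                in_regions += int(region_set.contains_points(chrom, pos).sum())
                in_flagged += int(flagged_set.contains_points(chrom, pos).sum())
            focal["read_share_percent"] = (100.0 * in_flagged / in_regions
                                           if in_regions else float("nan"))
    return {"per_mark": per_mark, "per_region": per_region, "focal": focal}


def density_by_state(
    reads: Sequence[AlignedRead],
    statemap: ChromatinStateMap,
    library_total: int,
) -> pd.DataFrame:
    """Unique-mapper density (RPKM) per chromatin-state cell.

    Each read is assigned to the unique partition cell containing its 5'
    end; cells with zero bases are omitted.  RPKM = reads * 1e9 /
    (bases * library_total).
    """
    by_chrom: Dict[str, List[int]] = {}
    for r in reads:
        by_chrom.setdefault(r.chrom, []).append(r.five_prime)
    rows = []
    for label, cell in statemap.partition.items():
        bases = cell.total_length
        if bases == 0:
            continue
        n = 0
        for chrom, pos in by_chrom.items():
            n += int(cell.contains_points(chrom, np.asarray(pos)).sum())
        rpkm = n * 1e9 / (bases * library_total) if library_total else 0.0
        rows.append({"state": label, "bases": bases, "reads": n, "rpkm": rpkm})
    return pd.DataFrame(rows)


def intron_exon_density(
    reads: Sequence[AlignedRead],
    genes: Sequence,
    library_total: int,
    restrict_to: Optional[IntervalSet] = None,
) -> pd.DataFrame:
    """Pooled intron vs exon read density (RPKM), optionally restricted to a
    region set.

    Intron and exon bases are pooled across genes (exons win where an exon
    of one gene overlaps an intron of another, mirroring feature-level
    pooling); reads are assigned by 5' end.
    """
    exon_set = IntervalSet.from_intervals(
        [e for g in genes for e in g.exons])
    intron_set = IntervalSet.from_intervals(
        [i for g in genes for i in g.introns]).subtract(exon_set)
    if restrict_to is not None:
        exon_set = exon_set.intersect(restrict_to)
        intron_set = intron_set.intersect(restrict_to)

    by_chrom: Dict[str, List[int]] = {}
    for r in reads:
        by_chrom.setdefault(r.chrom, []).append(r.five_prime)

    rows = []
    for label, feats in (("introns", intron_set), ("exons", exon_set)):
        bases = feats.total_length
        if bases == 0:
            import logging
            logging.getLogger(__name__).warning(
                "feature class %r has zero bases; record omitted", label)
            continue
        n = 0
        for chrom, pos in by_chrom.items():
            n += int(feats.contains_points(chrom, np.asarray(pos)).sum())
        rpkm = n * 1e9 / (bases * library_total) if library_total else 0.0
        rows.append({"feature": label, "bases": bases, "reads": n,
                     "rpkm": rpkm})
    return pd.DataFrame(rows)
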