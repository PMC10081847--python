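"""Core genomic primitives: intervals, aligned small-RNA reads, gene models,
and exact interval-set algebra.

All coordinates are 0-based, half-open, on the genomic (plus-strand) axis.
BED input is native to this convention; GFF3 is converted on read.  A single
convention throughout removes the usual off-by-one failure modes when bins,
peaks, gene features and read 5' ends are combined.

Minus-strand reads store their sequence in *read orientation* (the 5'->3'
sequence of the RNA itself); the genomic position of the 5' end of a minus
read is ``interval.end - 1``.  Every positional statistic downstream (1U/10A
bias, ping-pong overlap, bin assignment) is defined from the read's own
5' end, so this orientation rule is load-bearing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "ValidationError",
    "ParseError",
    "ConfigurationError",
    "GenomicInterval",
    "AlignedRead",
    "GeneModel",
    "IntervalSet",
    "intersect",
    "merge_within_gap",
    "revcomp",
]


class ValidationError(ValueError):
    """A domain invariant was violated (coordinates, strand, alphabet...)."""


class ParseError(ValueError):
    """A standard-format input file could not be parsed."""


class ConfigurationError(ValueError):
    """Inputs or options are inconsistent (e.g. missing mapping multiplicity)."""


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval, optionally stranded.

    ``strand`` is ``'+'``, ``'-'`` or ``'.'`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("interval chrom must be nonempty")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        s = f"{self.chrom}:{self.start}-{self.end}"
        return s if self.strand == "." else f"{s}({self.strand})"


@dataclass(frozen=True)
class AlignedRead:
    """One mapped small-RNA read.

    ``sequence`` is in read orientation (5'->3' of the RNA); for a minus-strand
    read it is the reverse complement of the genomic slice.  ``n_hits`` is the
    number of genomic loci the read maps to; a *unique mapper* has
    ``n_hits == 1``.
    """

    interval: GenomicInterval
    sequence: str
    n_hits: int = 1

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValidationError("read strand must be '+' or '-'")
        if len(self.sequence) != self.interval.length:
            raise ValidationError(
                f"sequence length {len(self.sequence)} != interval length "
                f"{self.interval.length}"
            )
        if set(self.sequence.upper()) - set("ACGTN"):
            raise ValidationError(f"bad read alphabet in {self.sequence!r}")
        if self.n_hits < 1:
            raise ValidationError("n_hits must be >= 1")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def length(self) -> int:
        return self.interval.length

    @property
    def five_prime(self) -> int:
        """Genomic coordinate of the read's own 5' end."""
        if self.interval.strand == "+":
            return self.interval.start
        return self.interval.end - 1

    @property
    def is_unique(self) -> bool:
        return self.n_hits == 1


@dataclass
class GeneModel:
    """A gene span with merged exons; introns are always derived on demand.

    Exons are canonicalized (sorted, merged) at construction; introns are the
    complement of the exons within the span, so exons and introns tile the
    span exactly by construction.
    """

    gene_id: str
    span: GenomicInterval
    exons: List[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        merged = IntervalSet.from_intervals(self.exons)
        for iv in merged:
            if iv.start < self.span.start or iv.end > self.span.end:
                raise ValidationError(
                    f"exon {iv} outside span of gene {self.gene_id}"
                )
            if iv.chrom != self.span.chrom:
                raise ValidationError(
                    f"exon chrom {iv.chrom} != gene chrom {self.span.chrom}"
                )
        self.exons = list(merged)

    @property
    def introns(self) -> List[GenomicInterval]:
        span_set = IntervalSet.from_intervals([self.span])
        exon_set = IntervalSet.from_intervals(self.exons)
        return list(span_set.subtract(exon_set))


def _canonical(pairs: np.ndarray) -> np.ndarray:
    """Sort (n,2) start/end pairs and merge overlapping or abutting runs."""
    if len(pairs) == 0:
        return pairs.reshape(0, 2)
    order = np.argsort(pairs[:, 0], kind="stable")
    pairs = pairs[order]
    out: List[Tuple[int, int]] = []
    cs, ce = int(pairs[0, 0]), int(pairs[0, 1])
    for s, e in pairs[1:]:
        s, e = int(s), int(e)
        if s <= ce:  # overlap or abut -> fuse
            ce = max(ce, e)
        else:
            out.append((cs, ce))
            cs, ce = s, e
    out.append((cs, ce))
    return np.asarray(out, dtype=np.int64)


class IntervalSet:
    """A canonical, per-chromosome sorted set of disjoint intervals.

    Canonical form: per chromosome, intervals are sorted by start and no two
    intervals overlap or abut.  All algebra (union, intersection, subtraction,
    gap-merging, complement) preserves canonical form.  Strand is not tracked:
    peak sets, bins and merged regions are strandless interval masses.
    """

    def __init__(self, data: Optional[Mapping[str, np.ndarray]] = None,
                 _canonical_input: bool = False):
        self._data: Dict[str, np.ndarray] = {}
        if data:
            for chrom, arr in data.items():
                arr = np.asarray(arr, dtype=np.int64).reshape(-1, 2)
                if len(arr) == 0:
                    continue
                if np.any(arr[:, 0] < 0) or np.any(arr[:, 0] >= arr[:, 1]):
                    raise ValidationError(f"invalid interval bounds on {chrom}")
                self._data[chrom] = arr if _canonical_input else _canonical(arr)

    # -- construction -------------------------------------------------------

    @classmethod
    def from_intervals(cls, intervals: Iterable[GenomicInterval]) -> "IntervalSet":
        grouped: Dict[str, List[Tuple[int, int]]] = {}
        for iv in intervals:
            grouped.setdefault(iv.chrom, []).append((iv.start, iv.end))
        return cls({c: np.asarray(v, dtype=np.int64) for c, v in grouped.items()})

    @classmethod
    def from_tuples(cls, tuples: Iterable[Tuple[str, int, int]]) -> "IntervalSet":
        grouped: Dict[str, List[Tuple[int, int]]] = {}
        for chrom, s, e in tuples:
            grouped.setdefault(chrom, []).append((s, e))
        return cls({c: np.asarray(v, dtype=np.int64) for c, v in grouped.items()})

    # -- basic queries -------------------------------------------------------

    @property
    def chroms(self) -> List[str]:
        return sorted(self._data)

    @property
    def total_length(self) -> int:
        return int(sum((arr[:, 1] - arr[:, 0]).sum() for arr in self._data.values()))

    def __len__(self) -> int:
        return sum(len(arr) for arr in self._data.values())

    def __bool__(self) -> bool:
        return len(self) > 0

    def __iter__(self) -> Iterator[GenomicInterval]:
        for chrom in self.chroms:
            for s, e in self._data[chrom]:
                yield GenomicInterval(chrom, int(s), int(e))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        if self.chroms != other.chroms:
            return False
        return all(np.array_equal(self._data[c], other._data[c]) for c in self.chroms)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"IntervalSet({len(self)} intervals, {self.total_length} bp)"

    def chrom_array(self, chrom: str) -> np.ndarray:
        """(n,2) array of start/end pairs for one chromosome (may be empty)."""
        return self._data.get(chrom, np.empty((0, 2), dtype=np.int64))

    def contains_points(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Boolean mask: which positions fall inside the set (vectorized)."""
        arr = self.chrom_array(chrom)
        positions = np.asarray(positions)
        if len(arr) == 0:
            return np.zeros(len(positions), dtype=bool)
        edges = arr.ravel()
        idx = np.searchsorted(edges, positions, side="right")
        return idx % 2 == 1

    # -- algebra -------------------------------------------------------------

    def union(self, other: "IntervalSet") -> "IntervalSet":
        out: Dict[str, np.ndarray] = {}
        for chrom in set(self._data) | set(other._data):
            stacked = np.vstack([self.chrom_array(chrom), other.chrom_array(chrom)])
            out[chrom] = stacked
        return IntervalSet(out)

    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        out: Dict[str, np.ndarray] = {}
        for chrom in set(self._data) & set(other._data):
            a, b = self._data[chrom], other._data[chrom]
            hits: List[Tuple[int, int]] = []
            i = j = 0
            while i < len(a) and j < len(b):
                s = max(a[i, 0], b[j, 0])
                e = min(a[i, 1], b[j, 1])
                if s < e:
                    hits.append((int(s), int(e)))
                if a[i, 1] <= b[j, 1]:
                    i += 1
                else:
                    j += 1
            if hits:
                out[chrom] = np.asarray(hits, dtype=np.int64)
        return IntervalSet(out, _canonical_input=True)

    def subtract(self, other: "IntervalSet") -> "IntervalSet":
        out: Dict[str, np.ndarray] = {}
        for chrom, a in self._data.items():
            b = other.chrom_array(chrom)
            if len(b) == 0:
                out[chrom] = a.copy()
                continue
            kept: List[Tuple[int, int]] = []
            for s, e in a:
                s, e = int(s), int(e)
                cur = s
                # first b interval whose end exceeds s (b ends are sorted)
                k = int(np.searchsorted(b[:, 1], s, side="right"))
                while k < len(b) and b[k, 0] < e:
                    bs, be = int(b[k, 0]), int(b[k, 1])
                    if bs > cur:
                        kept.append((cur, bs))
                    cur = max(cur, be)
                    if cur >= e:
                        break
                    k += 1
                if cur < e:
                    kept.append((cur, e))
            if kept:
                out[chrom] = np.asarray(kept, dtype=np.int64)
        return IntervalSet(out, _canonical_input=True)

    def complement(self, chrom_sizes: Mapping[str, int]) -> "IntervalSet":
        genome = IntervalSet({c: np.asarray([[0, n]], dtype=np.int64)
                              for c, n in chrom_sizes.items() if n > 0})
        return genome.subtract(self)

    def merge_within_gap(self, max_gap: int) -> "IntervalSet":
        """Fuse consecutive intervals whose gap is *strictly* less than max_gap.

        A gap of exactly ``max_gap`` bases is NOT fused ("distant from less
        than" is read strictly).  Idempotent.
        """
        if max_gap < 0:
            raise ValidationError("max_gap must be >= 0")
        out: Dict[str, np.ndarray] = {}
        for chrom, arr in self._data.items():
            fused: List[Tuple[int, int]] = []
            cs, ce = int(arr[0, 0]), int(arr[0, 1])
            for s, e in arr[1:]:
                s, e = int(s), int(e)
                if s - ce < max_gap:
                    ce = max(ce, e)
                else:
                    fused.append((cs, ce))
                    cs, ce = s, e
            fused.append((cs, ce))
            out[chrom] = np.asarray(fused, dtype=np.int64)
        return IntervalSet(out, _canonical_input=True)


def intersect(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Bases present in both sets (commutative)."""
    return a.intersect(b)


def merge_within_gap(s: IntervalSet, max_gap: int) -> IntervalSet:
    """Module-level alias for :meth:`IntervalSet.merge_within_gap`."""
    return s.merge_within_gap(max_gap)
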