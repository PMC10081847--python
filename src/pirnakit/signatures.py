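"""Read-level piRNA signatures.

Four diagnostics characterize a bona fide dual-strand piRNA cluster:

* a strand-resolved size spectrum concentrated in the 23-29 nt range;
* an enrichment of uridine at read position 1 (the "1U" bias);
* an excess of opposite-strand read pairs whose 5' ends overlap by exactly
  10 nt (the ping-pong signature), summarized as a z-score of the 10-nt
  overlap count against the background of overlap sizes 1..29;
* among those 10-nt paired reads, an adenine enrichment at position 10
  ("10A"), the complement of the partner's 1U.

Pairing is defined purely on genomic 5'-end geometry: a plus-strand read
with 5' end at ``p+`` and a minus-strand read with 5' end at ``p-`` (on the
same chromosome) overlap by ``k = p- - p+ + 1`` nucleotides, counted for
``1 <= k <= 29``.  Duplicate read positions contribute multiplicatively to
pair counts (reads are counted, not distinct positions).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import AlignedRead, GenomicInterval, ValidationError

__all__ = [
    "SizeStrandHistogram",
    "OverlapSignature",
    "PositionalBias",
    "size_strand_distribution",
    "overlap_histogram",
    "pingpong_zscore",
    "positional_bias",
]

KMAX = 29  # largest 5'-overlap size considered


@dataclass
class SizeStrandHistogram:
    """Read counts by (length, strand); ``normalization`` is 'raw' or 'rpm'."""

    counts: pd.DataFrame  # index: length, columns: '+', '-'
    normalization: str = "raw"

    @property
    def total(self) -> float:
        return float(self.counts.values.sum())


@dataclass
class OverlapSignature:
    """5'-overlap pair-count histogram for overlaps 1..29 nt.

    ``pair_counts[k]`` (1-based series) is the number of (plus, minus) read
    pair combinations with overlap exactly k.  ``paired_reads`` is the
    multiset of input reads participating in at least one pair of overlap
    exactly 10.
    """

    pair_counts: pd.Series  # index 1..29
    paired_reads: List[AlignedRead] = field(default_factory=list)

    @property
    def z10(self) -> float:
        return pingpong_zscore(self)


@dataclass
class PositionalBias:
    """Positional nucleotide frequencies and the 1U / 10A percentages.

    ``freq`` holds per-position base frequencies over reads 3'-trimmed to
    23 nt (positions 1..23, read orientation); N bases are excluded from the
    denominator.  ``pct_1U`` is over all input reads; ``pct_10A_paired`` is
    over the 10-overlap paired reads only (NaN when there are none).
    """

    freq: pd.DataFrame  # index: position 1..23, columns A/C/G/T
    pct_1U: float
    pct_10A_paired: float
    n_reads: int
    n_paired: int


def size_strand_distribution(
    reads: Sequence[AlignedRead],
    norm_total: Optional[int] = None,
    relative_to: Optional[GenomicInterval] = None,
    length_range: Tuple[int, int] = (18, 30),
) -> SizeStrandHistogram:
    """Histogram of read counts by (length, strand).

    Strand is genomic unless ``relative_to`` supplies a stranded reference
    feature, in which case reads are counted sense/antisense to it.  With
    ``norm_total``, counts are scaled to reads per million (rpm).
    """
    if norm_total is not None and norm_total <= 0:
        raise ValidationError("norm_total must be positive for rpm scaling")
    lo, hi = length_range
    tallies = np.zeros((hi - lo + 1, 2))
    flip = relative_to is not None and relative_to.strand == "-"
    for r in reads:
        if not (lo <= r.length <= hi):
            continue
        col = 0 if r.strand == "+" else 1
        if flip:
            col = 1 - col
        tallies[r.length - lo, col] += 1
    counts = pd.DataFrame(tallies, index=list(range(lo, hi + 1)),
                          columns=["+", "-"])
    counts.index.name = "length"
    if norm_total is not None:
        counts *= 1e6 / norm_total
        return SizeStrandHistogram(counts, "rpm")
    return SizeStrandHistogram(counts, "raw")


def overlap_histogram(reads: Sequence[AlignedRead]) -> OverlapSignature:
    """Count opposite-strand 5'-overlap pairs for overlaps 1..29 nt.

    All reads must be 23-29 nt (the piRNA size window).  Pair counting is
    positional: the count for overlap k is the sum over 5'-position pairs of
    the product of read multiplicities at those positions, so duplicated
    reads count multiplicatively.
    """
    plus: Dict[str, Counter] = {}
    minus: Dict[str, Counter] = {}
    for r in reads:
        if not (23 <= r.length <= 29):
            raise ValidationError(
                f"overlap_histogram expects 23-29 nt reads, got {r.length} nt")
        table = plus if r.strand == "+" else minus
        table.setdefault(r.chrom, Counter())[r.five_prime] += 1

    tallies = np.zeros(KMAX + 1)  # index k, entry 0 unused
    paired_plus: Dict[str, set] = {}
    paired_minus: Dict[str, set] = {}
    for chrom in set(plus) & set(minus):
        cp, cm = plus[chrom], minus[chrom]
        get = cm.get
        for p, np_ in cp.items():
            for k in range(1, KMAX + 1):
                nm = get(p + k - 1, 0)
                if nm:
                    tallies[k] += np_ * nm
                    if k == 10:
                        paired_plus.setdefault(chrom, set()).add(p)
                        paired_minus.setdefault(chrom, set()).add(p + 9)
    pair_counts = pd.Series(tallies[1:],
                            index=pd.RangeIndex(1, KMAX + 1, name="overlap"))

    paired_reads = [
        r for r in reads
        if (r.strand == "+" and r.five_prime in paired_plus.get(r.chrom, ()))
        or (r.strand == "-" and r.five_prime in paired_minus.get(r.chrom, ()))
    ]
    return OverlapSignature(pair_counts, paired_reads)


def pingpong_zscore(sig: OverlapSignature, k: int = 10,
                    window: Tuple[int, int] = (1, KMAX)) -> float:
    """z-score of the overlap-k pair count against all overlap sizes.

    The background window includes k itself by default (mean and population
    standard deviation over overlaps 1..29).  Returns NaN when all counts in
    the window are equal (sigma = 0: the score is undefined).
    """
    lo, hi = window
    values = sig.pair_counts.loc[lo:hi].to_numpy(dtype=float)
    sigma = values.std()  # population SD
    if sigma == 0:
        return float("nan")
    return float((sig.pair_counts.loc[k] - values.mean()) / sigma)


def positional_bias(reads: Sequence[AlignedRead],
                    sig: Optional[OverlapSignature] = None) -> PositionalBias:
    """Positional nucleotide frequencies plus the 1U and 10A percentages.

    The frequency matrix is computed from reads 3'-trimmed to 23 nt, in read
    orientation (for a minus read, position 1 is its own 5' end).  pct_1U is
    over all input reads; pct_10A_paired over ``sig.paired_reads``.
    """
    trim = 23
    bases = ("A", "C", "G", "T")
    tallies = np.zeros((trim, 4), dtype=float)
    n_1u = 0
    for r in reads:
        seq = r.sequence.upper()
        if seq.startswith("T"):
            n_1u += 1
        for pos, base in enumerate(seq[:trim]):
            if base in bases:
                tallies[pos, bases.index(base)] += 1
    row_sums = tallies.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(row_sums > 0, tallies / row_sums, np.nan)
    freq_df = pd.DataFrame(freq, index=pd.RangeIndex(1, trim + 1, name="position"),
                           columns=list(bases))

    pct_1u = 100.0 * n_1u / len(reads) if reads else float("nan")

    paired = sig.paired_reads if sig is not None else []
    n_10a = 0
    for r in paired:
        seq = r.sequence.upper()
        if len(seq) >= 10 and seq[9] == "A":  # guarded; sizes are >= 23 anyway
            n_10a += 1
    pct_10a = 100.0 * n_10a / len(paired) if paired else float("nan")

    return PositionalBias(freq=freq_df, pct_1U=pct_1u, pct_10A_paired=pct_10a,
                          n_reads=len(reads), n_paired=len(paired))
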