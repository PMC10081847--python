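"""Shared test utilities: independent brute-force oracles and random
fixture builders.

The oracles here deliberately avoid the library's own interval/pairing code:
interval algebra is checked against per-base boolean arrays, and the
5'-overlap histogram against an all-pairs double loop.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np

from pirnakit.core import AlignedRead, GenomicInterval, IntervalSet


# ---------------------------------------------------------------------------
# per-base boolean-array oracle


def mask_from_tuples(tuples: Iterable[Tuple[str, int, int]],
                     chrom_sizes: Mapping[str, int]) -> Dict[str, np.ndarray]:
    masks = {c: np.zeros(n, dtype=bool) for c, n in chrom_sizes.items()}
    for chrom, s, e in tuples:
        masks[chrom][s:e] = True
    return masks


def mask_of(iset: IntervalSet,
            chrom_sizes: Mapping[str, int]) -> Dict[str, np.ndarray]:
    return mask_from_tuples(((iv.chrom, iv.start, iv.end) for iv in iset),
                            chrom_sizes)


def set_from_mask(masks: Mapping[str, np.ndarray]) -> IntervalSet:
    tuples = []
    for chrom, m in masks.items():
        padded = np.concatenate([[False], m, [False]]).astype(np.int8)
        d = np.diff(padded)
        starts = np.flatnonzero(d == 1)
        ends = np.flatnonzero(d == -1)
        tuples.extend((chrom, int(s), int(e)) for s, e in zip(starts, ends))
    return IntervalSet.from_tuples(tuples)


def random_tuples(rng: np.random.Generator, chrom_sizes: Mapping[str, int],
                  n: int, max_len: int = 5000) -> List[Tuple[str, int, int]]:
    chroms = list(chrom_sizes)
    out = []
    for _ in range(n):
        chrom = chroms[rng.integers(0, len(chroms))]
        size = chrom_sizes[chrom]
        start = int(rng.integers(0, size - 1))
        length = int(rng.integers(1, min(max_len, size - start) + 1))
        out.append((chrom, start, start + length))
    return out


# ---------------------------------------------------------------------------
# O(n^2) overlap-pair oracle


def brute_force_overlap_counts(reads: Sequence[AlignedRead],
                               kmax: int = 29) -> np.ndarray:
    """All-pairs pair counts for overlaps 1..kmax (index 0 unused)."""
    counts = np.zeros(kmax + 1)
    plus = [r for r in reads if r.strand == "+"]
    minus = [r for r in reads if r.strand == "-"]
    for p in plus:
        for m in minus:
            if p.chrom != m.chrom:
                continue
            k = m.five_prime - p.five_prime + 1
            if 1 <= k <= kmax:
                counts[k] += 1
    return counts


# ---------------------------------------------------------------------------
# random read builders


def random_read(rng: np.random.Generator, chrom: str, chrom_len: int,
                length: int | None = None,
                strand: str | None = None) -> AlignedRead:
    length = length or int(rng.integers(23, 30))
    strand = strand or ("+" if rng.random() < 0.5 else "-")
    start = int(rng.integers(0, chrom_len - length))
    seq = "".join(rng.choice(list("ACGT"), size=length))
    return AlignedRead(GenomicInterval(chrom, start, start + length, strand),
                       seq)


def random_reads(rng: np.random.Generator, n: int, chrom: str = "chr1",
                 chrom_len: int = 10_000) -> List[AlignedRead]:
    return [random_read(rng, chrom, chrom_len) for _ in range(n)]


def make_read(chrom: str, five_prime: int, strand: str, length: int = 25,
              seq: str | None = None) -> AlignedRead:
    """Build a read from its 5'-end coordinate (the natural frame for
    ping-pong geometry)."""
    if strand == "+":
        start = five_prime
    else:
        start = five_prime - length + 1
    seq = seq or "A" * length
    return AlignedRead(GenomicInterval(chrom, start, start + length, strand),
                       seq)


def condition_map(samples: Iterable[str]) -> Dict[str, str]:
    return {s: ("control" if s.startswith("control") else "knockdown")
            for s in samples}
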