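"""De novo piRNA-region discovery.

The genome is tiled with fixed-width bins (1 kb by default; the last bin of
a chromosome may be shorter), unique 23-29-nt reads are assigned to the bin
containing their genomic 5' end (both strands pooled), and per-bin counts
are tested for differential production between two replicated conditions
with a negative-binomial Wald test.  Selected bins (fold change >= 8 and
p < 0.001 by default) are merged into regions when they are separated by
strictly less than 3 kb, up- and down-regulated bins separately.

The differential engine is a self-contained NB Wald test with moment-based,
globally shrunk dispersion estimates:

* normalized counts  x = K / s  with per-sample size factors s (rpm by
  default: library total / 1e6; a median-of-ratios mode is also available);
* log2 fold change  log2((mean_B + c) / (mean_A + c))  with pseudo-count c
  (0.5 by default) so bins with zeros in one condition stay finite;
* per-bin dispersion phi by method of moments on the pooled within-condition
  variance, shrunk toward the count-weighted global mean with weight
  n / (n + 4) (n = total replicates);
* Wald z = lfc / se with NB variance mu + phi * mu^2 propagated through the
  log; the mean entering the variance is floored at the pseudo-count so a
  zero-count condition never yields a zero standard error.

The p-value used for selection is the raw two-sided Wald probability; a
Benjamini-Hochberg adjusted column is emitted alongside but not used to
select.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import (
    AlignedRead,
    ConfigurationError,
    GeneModel,
    GenomicInterval,
    IntervalSet,
    ValidationError,
)

__all__ = [
    "BinCountTable",
    "Region",
    "count_bins",
    "estimate_size_factors",
    "differential_bins",
    "call_regions",
    "gene_level_counts",
    "reference_set_counts",
]


@dataclass
class BinCountTable:
    """Per-bin, per-sample counts of (already filtered) unique 23-29-nt reads.

    ``bins`` tiles each chromosome without gaps or overlaps; ``counts`` has
    one row per bin (same order) and one column per sample.  ``conditions``
    maps sample -> condition label; ``size_factors`` is filled by
    :func:`estimate_size_factors`.
    """

    bins: pd.DataFrame          # columns: chrom, start, end
    counts: pd.DataFrame        # rows align with bins; columns: samples
    conditions: Dict[str, str]
    size_factors: Optional[pd.Series] = None
    normalization: Optional[str] = None
    library_totals: Optional[pd.Series] = None

    @property
    def samples(self) -> List[str]:
        return list(self.counts.columns)

    def condition_samples(self, condition: str) -> List[str]:
        return [s for s, c in self.conditions.items() if c == condition]

    def bin_intervals(self) -> List[GenomicInterval]:
        return [GenomicInterval(r.chrom, int(r.start), int(r.end))
                for r in self.bins.itertuples()]


@dataclass
class Region:
    """A merged run of same-direction differential bins."""

    interval: GenomicInterval
    direction: str                       # 'up' or 'down'
    member_bins: List[GenomicInterval]
    read_mass: Dict[str, float] = field(default_factory=dict)  # condition -> rpm
    genes: List[str] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.interval.length


def _make_bins(chrom_sizes: Mapping[str, int], bin_width: int) -> pd.DataFrame:
    rows = []
    for chrom, size in chrom_sizes.items():
        starts = np.arange(0, size, bin_width)
        ends = np.minimum(starts + bin_width, size)
        for s, e in zip(starts, ends):
            rows.append((chrom, int(s), int(e)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def count_bins(
    reads_by_sample: Mapping[str, Sequence[AlignedRead]],
    chrom_sizes: Mapping[str, int],
    conditions: Mapping[str, str],
    bin_width: int = 1000,
    library_totals: Optional[Mapping[str, int]] = None,
) -> BinCountTable:
    """Assign each read to the bin containing its genomic 5' end.

    Both strands are pooled.  Reads are expected to be pre-filtered (23-29 nt
    unique mappers); a read whose 5' end lies beyond its chromosome is a
    validation error.  ``library_totals`` optionally records full library
    sizes for rpm normalization (defaults to the number of assigned reads).
    """
    bins = _make_bins(chrom_sizes, bin_width)
    n_bins_per_chrom = {c: math.ceil(s / bin_width) for c, s in chrom_sizes.items()}
    offsets: Dict[str, int] = {}
    off = 0
    for chrom in chrom_sizes:
        offsets[chrom] = off
        off += n_bins_per_chrom[chrom]

    counts = pd.DataFrame(0, index=bins.index,
                          columns=list(reads_by_sample), dtype=np.int64)
    for sample, reads in reads_by_sample.items():
        idx = np.empty(len(reads), dtype=np.int64)
        for i, r in enumerate(reads):
            if r.chrom not in chrom_sizes:
                raise ValidationError(f"read on unknown chromosome {r.chrom}")
            p5 = r.five_prime
            if p5 >= chrom_sizes[r.chrom]:
                raise ValidationError(
                    f"read 5' end {r.chrom}:{p5} beyond chromosome end")
            idx[i] = offsets[r.chrom] + p5 // bin_width
        binned = np.bincount(idx, minlength=len(bins)) if len(reads) else \
            np.zeros(len(bins), dtype=np.int64)
        counts[sample] = binned

    totals = pd.Series({s: (library_totals[s] if library_totals is not None
                            else len(reads_by_sample[s]))
                        for s in reads_by_sample}, dtype=float)
    return BinCountTable(bins=bins, counts=counts, conditions=dict(conditions),
                         library_totals=totals)


def estimate_size_factors(table: BinCountTable, mode: str = "rpm") -> pd.Series:
    """Per-sample normalization factors; counts / factor puts samples on a
    common scale.

    ``rpm``: factor = library total / 1e6 (reads-per-million scaling).
    ``median-of-ratios``: factor = median over bins (with nonzero geometric
    mean) of count / geometric mean, rescaled to geometric mean 1.
    """
    if not len(table.samples):
        raise ConfigurationError("need at least one sample")
    if mode == "rpm":
        totals = table.library_totals
        if totals is None:
            totals = table.counts.sum(axis=0).astype(float)
        if (totals <= 0).any():
            raise ConfigurationError("all-zero sample: cannot scale to rpm")
        factors = totals / 1e6
    elif mode == "median-of-ratios":
        counts = table.counts.to_numpy(dtype=float)
        with np.errstate(divide="ignore"):
            log_counts = np.log(counts)
        log_gm = log_counts.mean(axis=1)
        ok = np.isfinite(log_gm)
        if not ok.any():
            raise ConfigurationError("no bin has all-nonzero counts")
        ratios = log_counts[ok] - log_gm[ok, None]
        factors = pd.Series(np.exp(np.median(ratios, axis=0)),
                            index=table.samples)
        factors /= np.exp(np.log(factors).mean())  # geometric mean 1
    else:
        raise ConfigurationError(f"unknown normalization mode {mode!r}")
    factors = pd.Series(np.asarray(factors, dtype=float), index=table.samples)
    if (factors <= 0).any():
        raise ConfigurationError("nonpositive size factor")
    table.size_factors = factors
    table.normalization = mode
    return factors


LN2 = math.log(2.0)
_SHRINK_PRIOR = 4  # shrinkage weight n / (n + 4)


def differential_bins(
    table: BinCountTable,
    condition_a: str = "control",
    condition_b: str = "knockdown",
    pseudo: float = 0.5,
    fc_threshold: float = 8.0,
    p_threshold: float = 1e-3,
) -> pd.DataFrame:
    """NB Wald test of per-bin differential read production (B vs A).

    Returns one row per tested bin (bins with zero mean in both conditions
    are skipped) with columns chrom, start, end, base_mean, log2fc, pvalue,
    padj, selected.  ``selected`` requires both |log2fc| >= log2(fc_threshold)
    and pvalue < p_threshold.
    """
    samples_a = table.condition_samples(condition_a)
    samples_b = table.condition_samples(condition_b)
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ConfigurationError(
            "differential testing needs >= 2 replicates per condition")
    if table.size_factors is None:
        estimate_size_factors(table)
    sf = table.size_factors

    xa = table.counts[samples_a].to_numpy(float) / sf[samples_a].to_numpy()
    xb = table.counts[samples_b].to_numpy(float) / sf[samples_b].to_numpy()
    na, nb = xa.shape[1], xb.shape[1]
    n = na + nb
    ma, mb = xa.mean(axis=1), xb.mean(axis=1)
    keep = (ma > 0) | (mb > 0)

    base_mean = (xa.sum(axis=1) + xb.sum(axis=1)) / n
    lfc = np.log2((mb + pseudo) / (ma + pseudo))

    # method-of-moments dispersion on pooled within-condition variance
    ss = ((xa - ma[:, None]) ** 2).sum(axis=1) + ((xb - mb[:, None]) ** 2).sum(axis=1)
    pooled_var = ss / (n - 2)
    inv_sf = float((1.0 / sf).mean())  # Poisson part of Var(K/s) ~ mu / s
    with np.errstate(divide="ignore", invalid="ignore"):
        phi_hat = np.where(base_mean > 0,
                           (pooled_var - inv_sf * base_mean) / base_mean ** 2,
                           0.0)
    phi_hat = np.clip(phi_hat, 0.0, None)
    if keep.any() and base_mean[keep].sum() > 0:
        phi_global = float(np.average(phi_hat[keep], weights=base_mean[keep]))
    else:
        phi_global = 0.0
    w = n / (n + _SHRINK_PRIOR)
    phi = w * phi_hat + (1 - w) * phi_global

    # Wald variance of lfc via the delta method; means floored at the
    # pseudo-count so zero-mean conditions keep a finite standard error
    ma_eff = np.maximum(ma, pseudo)
    mb_eff = np.maximum(mb, pseudo)
    var_ma = (inv_sf * ma_eff + phi * ma_eff ** 2) / na
    var_mb = (inv_sf * mb_eff + phi * mb_eff ** 2) / nb
    se2 = (var_ma / (ma + pseudo) ** 2 + var_mb / (mb + pseudo) ** 2) / LN2 ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se2 > 0, lfc / np.sqrt(se2), 0.0)
    pvalue = 2.0 * stats.norm.sf(np.abs(z))

    out = table.bins.loc[keep, ["chrom", "start", "end"]].copy()
    out["base_mean"] = base_mean[keep]
    out["log2fc"] = lfc[keep]
    out["dispersion"] = phi[keep]
    out["pvalue"] = pvalue[keep]
    out["padj"] = multipletests(out["pvalue"], method="fdr_bh")[1] \
        if len(out) else np.array([])
    out["selected"] = ((np.abs(out["log2fc"]) >= np.log2(fc_threshold))
                       & (out["pvalue"] < p_threshold))
    return out.reset_index(drop=True)


def call_regions(
    diffs: pd.DataFrame,
    table: Optional[BinCountTable] = None,
    genes: Optional[Sequence[GeneModel]] = None,
    max_gap: int = 3000,
    condition_a: str = "control",
    condition_b: str = "knockdown",
) -> List[Region]:
    """Merge selected bins into directional regions.

    Up- and down-selected bins are merged separately (directions are never
    merged together) with the strict < ``max_gap`` rule.  When a count table
    is supplied, each region records its rpm read mass per condition; when
    gene models are supplied, genes whose span overlaps the region are
    annotated.
    """
    regions: List[Region] = []
    for direction, mask in (("up", diffs["selected"] & (diffs["log2fc"] > 0)),
                            ("down", diffs["selected"] & (diffs["log2fc"] < 0))):
        chosen = diffs.loc[mask]
        if not len(chosen):
            continue
        bin_set = IntervalSet.from_tuples(
            (r.chrom, int(r.start), int(r.end)) for r in chosen.itertuples())
        merged = bin_set.merge_within_gap(max_gap)
        for iv in merged:
            members = [GenomicInterval(r.chrom, int(r.start), int(r.end))
                       for r in chosen.itertuples()
                       if r.chrom == iv.chrom and r.start >= iv.start
                       and r.end <= iv.end]
            regions.append(Region(interval=iv, direction=direction,
                                  member_bins=members))
    regions.sort(key=lambda r: (r.interval.chrom, r.interval.start))

    if table is not None:
        # read mass is reported in rpm regardless of the size-factor mode
        # used for testing
        if table.library_totals is not None:
            sf = table.library_totals / 1e6
        else:
            sf = table.size_factors
            if sf is None:
                sf = estimate_size_factors(table)
        bins_by_key = {(r.chrom, int(r.start)): i
                       for i, r in enumerate(table.bins.itertuples())}
        for region in regions:
            rows = [bins_by_key[(b.chrom, b.start)] for b in region.member_bins]
            for cond in sorted(set(table.conditions.values())):
                cols = table.condition_samples(cond)
                norm = (table.counts.iloc[rows][cols] / sf[cols]).sum(axis=0)
                region.read_mass[cond] = float(norm.mean())
    if genes is not None:
        for region in regions:
            region.genes = [
                g.gene_id for g in genes
                if g.span.chrom == region.interval.chrom
                and g.span.start < region.interval.end
                and g.span.end > region.interval.start
            ]
    return regions


def regions_to_dataframe(regions: Sequence[Region]) -> pd.DataFrame:
    rows = []
    for i, r in enumerate(regions, start=1):
        row = {
            "name": f"R{i}", "chrom": r.interval.chrom,
            "start": r.interval.start, "end": r.interval.end,
            "direction": r.direction, "length": r.length,
            "n_bins": len(r.member_bins),
            "genes": ",".join(r.genes),
        }
        for cond, mass in r.read_mass.items():
            row[f"rpm_{cond}"] = mass
        rows.append(row)
    return pd.DataFrame(rows)


def gene_level_counts(
    reads_by_sample: Mapping[str, Sequence[AlignedRead]],
    genes: Sequence[GeneModel],
) -> pd.DataFrame:
    """Per-gene read counts: a read counts toward every gene whose span
    contains its 5' end (both strands; overlapping genes each count it)."""
    by_chrom: Dict[str, List[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.span.chrom, []).append(g)
    starts = {c: np.array([g.span.start for g in gs])
              for c, gs in by_chrom.items()}

    table = pd.DataFrame(0, index=[g.gene_id for g in genes],
                         columns=list(reads_by_sample), dtype=np.int64)
    for sample, reads in reads_by_sample.items():
        col = table[sample].to_dict()
        for r in reads:
            gs = by_chrom.get(r.chrom)
            if not gs:
                continue
            p5 = r.five_prime
            for g in gs:
                if g.span.start <= p5 < g.span.end:
                    col[g.gene_id] += 1
        table[sample] = pd.Series(col)
    return table


def reference_set_counts(
    reads_by_sample: Mapping[str, Sequence[AlignedRead]],
    sets: Mapping[str, IntervalSet],
    library_totals: Optional[Mapping[str, int]] = None,
    conditions: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Reads-per-million falling (by 5' end) into each named reference set.

    Returns one row per (set, sample) with rpm, plus per-condition mean and
    SD columns when a condition map is given.  The caller decides whether
    the supplied reads are all mappers or unique mappers.
    """
    rows = []
    for set_name, iset in sets.items():
        for sample, reads in reads_by_sample.items():
            total = (library_totals[sample] if library_totals is not None
                     else len(reads))
            n_in = 0
            by_chrom: Dict[str, List[int]] = {}
            for r in reads:
                by_chrom.setdefault(r.chrom, []).append(r.five_prime)
            for chrom, positions in by_chrom.items():
                n_in += int(iset.contains_points(chrom, np.asarray(positions)).sum())
            rpm = 1e6 * n_in / total if total else 0.0
            rows.append({"set": set_name, "sample": sample, "reads": n_in,
                         "rpm": rpm,
                         "condition": (conditions or {}).get(sample, "")})
    df = pd.DataFrame(rows)
    if conditions:
        agg = df.groupby(["set", "condition"])["rpm"].agg(["mean", "std"])
        df = df.merge(agg, on=["set", "condition"], how="left")
        df = df.rename(columns={"mean": "rpm_mean", "std": "rpm_sd"})
    return df
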