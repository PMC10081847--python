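"""Synthetic genomes, annotations, replicate small-RNA libraries and ChIP
peak sets, with full ground-truth bookkeeping.

The generator emulates the data profile of a germline-knockdown small-RNA
study: two conditions (control and knockdown) with replicate libraries, a
set of planted dual-strand read clusters whose per-replicate read counts are
negative-binomial, a planted ping-pong pairing fraction (pairs of
opposite-strand reads whose 5' ends overlap by exactly 10 nt), a 1U bias on
read sequences and a 10A bias among planted pairs, all over a uniform
background of both strands.  Every emitted read carries exactly one
provenance label (its cluster id or ``background``, plus whether it belongs
to a planted ping-pong pair), so downstream callers can be scored against
construction truth rather than against themselves.

Biases are imposed on the *recorded read sequence* (substituting the base at
the biased position), not on the genome, so genome composition stays
neutral and bias injection is decoupled from read placement.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np

from .core import (
    AlignedRead,
    ConfigurationError,
    GenomicInterval,
    IntervalSet,
    revcomp,
)

__all__ = [
    "PlantedCluster",
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_genome",
    "simulate_reads",
    "simulate_peaks",
    "default_study_config",
]

READ_LENGTHS = np.arange(23, 30)  # uniform 23..29 nt
_MIN_CLUSTER = 40  # smallest interval hosting a 10-nt-overlap pair of 23-29-mers


@dataclass(frozen=True)
class PlantedCluster:
    """One planted dual-strand cluster with per-condition read budgets.

    ``reads_a`` / ``reads_b`` are mean read counts per replicate in the
    control (A) and knockdown (B) conditions; ``pingpong_fraction`` of a
    replicate's reads are emitted as 10-nt 5'-overlap pairs; ``u1_prob`` is
    the probability that a recorded read starts with T (U in the RNA);
    ``a10_prob`` is the probability that a planted-pair read carries A at
    position 10.
    """

    interval: GenomicInterval
    reads_a: float
    reads_b: float
    pingpong_fraction: float = 0.5
    u1_prob: float = 0.65
    a10_prob: float = 0.55

    @property
    def planted_log2fc(self) -> float:
        return float(np.log2(self.reads_b / self.reads_a)) if self.reads_a else float("inf")


@dataclass
class SimulationConfig:
    """Conditions of a synthetic small-RNA study.

    Defaults mirror the study design the pipeline targets: three replicates
    per condition and negative-binomial replicate noise with shared
    dispersion phi (phi = 0 degenerates to Poisson).  ``background_rate`` is
    uniform background reads per megabase per replicate (same in both
    conditions).
    """

    genome_length: int = 2_000_000
    n_chroms: int = 1
    clusters: List[PlantedCluster] = field(default_factory=list)
    background_rate: float = 10_000.0
    n_replicates: int = 3
    nb_dispersion: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length < 10_000:
            raise ConfigurationError("genome_length must be >= 10 kb")
        if self.nb_dispersion < 0:
            raise ConfigurationError("nb_dispersion must be >= 0")
        per_chrom = self.genome_length // self.n_chroms
        for c in self.clusters:
            if c.interval.length < _MIN_CLUSTER:
                raise ConfigurationError(
                    f"cluster {c.interval} shorter than {_MIN_CLUSTER} bases "
                    "cannot host 10-nt-overlap pairs of 23-29-nt reads")
            if c.interval.end > per_chrom or c.interval.start < 30:
                raise ConfigurationError(
                    f"cluster {c.interval} outside genome (chrom length "
                    f"{per_chrom}; keep a 30-bp margin at chromosome starts)")
            for p in (c.pingpong_fraction, c.u1_prob, c.a10_prob):
                if not 0 <= p <= 1:
                    raise ConfigurationError("probabilities must be in [0,1]")

    @property
    def chrom_sizes(self) -> Dict[str, int]:
        per_chrom = self.genome_length // self.n_chroms
        return {f"chr{i + 1}": per_chrom for i in range(self.n_chroms)}


@dataclass
class SyntheticTruth:
    """Construction-time ground truth for a simulated study.

    ``clusters`` records planted intervals and fold changes; ``labels`` maps
    each sample name to one provenance label per emitted read, aligned with
    the read list: ``"c<i>"`` (cluster index), ``"c<i>:pair"`` (member of a
    planted ping-pong pair) or ``"bg"``.
    """

    clusters: List[Dict]
    labels: Dict[str, List[str]]

    def cluster_set(self) -> IntervalSet:
        return IntervalSet.from_tuples(
            (c["chrom"], c["start"], c["end"]) for c in self.clusters)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"clusters": self.clusters, "labels": self.labels}, fh)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(clusters=d["clusters"], labels=d["labels"])


def default_study_config(seed: int = 0, n_clusters: int = 13,
                         cluster_length: int = 4_000,
                         mean_per_bin_a: float = 100.0,
                         fold_change: float = 16.0,
                         pingpong_fraction: float = 0.5,
                         u1_prob: float = 0.65,
                         a10_prob: float = 0.55,
                         genome_length: int = 2_000_000,
                         background_rate: float = 10_000.0) -> SimulationConfig:
    """The flagship study conditions: 13 strongly induced dual-strand
    clusters (emulating the major de novo piRNA regions of a knockdown
    ovary) on a 2-Mb single-chromosome genome, 3 vs 3 replicates.

    Control clusters carry ``mean_per_bin_a`` reads per kb bin per replicate;
    knockdown clusters are ``fold_change`` times stronger, comfortably above
    the >= 8-fold selection threshold the caller applies (a cluster planted
    exactly at the threshold would be selected only half of the time).
    """
    n_bins = cluster_length // 1000
    spacing = genome_length // (n_clusters + 1)
    clusters = []
    for i in range(n_clusters):
        start = (i + 1) * spacing
        # align to bin boundaries so planted intervals coincide with bins
        start -= start % 1000
        clusters.append(PlantedCluster(
            interval=GenomicInterval("chr1", start, start + cluster_length),
            reads_a=mean_per_bin_a * n_bins,
            reads_b=mean_per_bin_a * n_bins * fold_change,
            pingpong_fraction=pingpong_fraction,
            u1_prob=u1_prob,
            a10_prob=a10_prob,
        ))
    return SimulationConfig(genome_length=genome_length, n_chroms=1,
                            clusters=clusters, background_rate=background_rate,
                            seed=seed)


# ---------------------------------------------------------------------------
# genome


def simulate_genome(config: SimulationConfig) -> Dict[str, str]:
    """i.i.d. uniform A/C/G/T sequences, deterministic under the seed."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xFA57A]))
    out: Dict[str, str] = {}
    for chrom, n in config.chrom_sizes.items():
        codes = rng.integers(0, 4, size=n)
        out[chrom] = "".join(np.array(list("ACGT"))[codes])
    return out


# ---------------------------------------------------------------------------
# reads


def _nb_draw(rng: np.random.Generator, mean: float, phi: float) -> int:
    """Negative binomial with mean/dispersion parameterization
    (var = mean + phi * mean^2); phi = 0 gives Poisson."""
    if mean <= 0:
        return 0
    if phi <= 0:
        return int(rng.poisson(mean))
    r = 1.0 / phi
    p = r / (r + mean)
    return int(rng.negative_binomial(r, p))


def _bias_base(rng: np.random.Generator, seq: str, pos: int, base: str,
               prob: float) -> str:
    """Set seq[pos] to `base` with probability prob, else to a uniform draw
    from the other three bases, so the recorded rate is exactly `prob`."""
    others = [b for b in "ACGT" if b != base]
    new = base if rng.random() < prob else others[rng.integers(0, 3)]
    return seq[:pos] + new + seq[pos + 1:]


def _read(genome: Mapping[str, str], chrom: str, start: int, length: int,
          strand: str) -> AlignedRead:
    seq = genome[chrom][start:start + length]
    if strand == "-":
        seq = revcomp(seq)
    return AlignedRead(GenomicInterval(chrom, start, start + length, strand), seq)


def simulate_reads(
    config: SimulationConfig,
    genome: Mapping[str, str],
) -> Tuple[Dict[str, List[AlignedRead]], SyntheticTruth]:
    """Emit per-replicate alignment sets for both conditions plus truth.

    Sample names are ``control_1..n`` and ``knockdown_1..n``.  Per planted
    cluster and replicate, the read count is drawn NB(mean, phi); a fraction
    ``pingpong_fraction`` of those reads form 10-nt 5'-overlap pairs, the
    rest are strand-balanced singletons uniform over the cluster.  Background
    reads are uniform over the genome at ``background_rate`` per Mb per
    replicate.  All reads are unique mappers (n_hits = 1).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5EED]))
    per_chrom = config.genome_length // config.n_chroms
    chrom_names = list(config.chrom_sizes)

    samples: Dict[str, List[AlignedRead]] = {}
    labels: Dict[str, List[str]] = {}
    cluster_records = []
    for ci, c in enumerate(config.clusters):
        cluster_records.append({
            "id": f"c{ci}", "chrom": c.interval.chrom,
            "start": c.interval.start, "end": c.interval.end,
            "reads_a": c.reads_a, "reads_b": c.reads_b,
            "planted_log2fc": c.planted_log2fc,
            "pingpong_fraction": c.pingpong_fraction,
            "u1_prob": c.u1_prob, "a10_prob": c.a10_prob,
        })

    for cond, key in (("control", "a"), ("knockdown", "b")):
        for rep in range(config.n_replicates):
            name = f"{cond}_{rep + 1}"
            reads: List[AlignedRead] = []
            labs: List[str] = []
            for ci, c in enumerate(config.clusters):
                mean = c.reads_a if key == "a" else c.reads_b
                n = _nb_draw(rng, mean, config.nb_dispersion)
                # round half-up so pingpong_fraction = 1 leaves no singleton
                n_pairs = int(np.floor(c.pingpong_fraction * n / 2 + 0.5))
                n_singles = max(n - 2 * n_pairs, 0)
                iv = c.interval
                for _ in range(n_pairs):
                    len_p = int(rng.choice(READ_LENGTHS))
                    len_m = int(rng.choice(READ_LENGTHS))
                    # initiator plus read; responder minus 5' end 10 nt inside
                    p_plus = int(rng.integers(iv.start, iv.end - 29))
                    r_plus = _read(genome, iv.chrom, p_plus, len_p, "+")
                    m_end = p_plus + 10         # minus 5' at p_plus + 9
                    m_start = m_end - len_m
                    r_minus = _read(genome, iv.chrom, m_start, len_m, "-")
                    pair = []
                    for r in (r_plus, r_minus):
                        seq = _bias_base(rng, r.sequence, 0, "T", c.u1_prob)
                        seq = _bias_base(rng, seq, 9, "A", c.a10_prob)
                        pair.append(AlignedRead(r.interval, seq))
                    reads.extend(pair)
                    labs.extend([f"c{ci}:pair"] * 2)
                for _ in range(n_singles):
                    length = int(rng.choice(READ_LENGTHS))
                    strand = "+" if rng.random() < 0.5 else "-"
                    start = int(rng.integers(iv.start, iv.end - length + 1))
                    r = _read(genome, iv.chrom, start, length, strand)
                    seq = _bias_base(rng, r.sequence, 0, "T", c.u1_prob)
                    reads.append(AlignedRead(r.interval, seq))
                    labs.append(f"c{ci}")
            n_bg = int(rng.poisson(config.background_rate *
                                   config.genome_length / 1e6))
            # background is the bulk of a null library; draw vectorized
            bg_chrom = rng.integers(0, config.n_chroms, size=n_bg)
            bg_len = rng.choice(READ_LENGTHS, size=n_bg)
            bg_start = rng.integers(0, per_chrom - 29, size=n_bg)
            bg_strand = rng.random(size=n_bg) < 0.5
            for i in range(n_bg):
                reads.append(_read(genome, chrom_names[bg_chrom[i]],
                                   int(bg_start[i]), int(bg_len[i]),
                                   "+" if bg_strand[i] else "-"))
            labs.extend(["bg"] * n_bg)
            samples[name] = reads
            labels[name] = labs

    return samples, SyntheticTruth(clusters=cluster_records, labels=labels)


# ---------------------------------------------------------------------------
# ChIP peaks


def simulate_peaks(
    truth: SyntheticTruth,
    chrom_sizes: Mapping[str, int],
    coverage_fraction: Union[float, Mapping[str, float]] = 1.0,
    decoy_fraction: Union[float, Mapping[str, float]] = 0.0,
    marks: Sequence[str] = ("H3K9me2", "H3K9me3", "Rhino"),
    seed: int = 0,
    decoy_length: int = 2_000,
) -> Dict[str, IntervalSet]:
    """Per-mark peak sets covering a fraction of each planted cluster plus
    decoy peaks elsewhere.

    Cluster coverage is a deterministic prefix (``[start, start +
    round(f * length))``), so the per-region covered fraction equals
    ``coverage_fraction`` up to base rounding.  Decoys are random
    ``decoy_length``-bp intervals placed outside the planted clusters until
    they total ``decoy_fraction`` of the genome.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x9EA5]))
    genome_length = sum(chrom_sizes.values())
    cluster_set = truth.cluster_set()
    chrom_names = list(chrom_sizes)

    def frac(spec, mark):
        return spec[mark] if isinstance(spec, Mapping) else spec

    out: Dict[str, IntervalSet] = {}
    for mark in marks:
        cov = frac(coverage_fraction, mark)
        dec = frac(decoy_fraction, mark)
        pieces: List[Tuple[str, int, int]] = []
        for c in truth.clusters:
            n_cov = int(round(cov * (c["end"] - c["start"])))
            if n_cov > 0:
                pieces.append((c["chrom"], c["start"], c["start"] + n_cov))
        peaks = IntervalSet.from_tuples(pieces)
        target = dec * genome_length
        guard = 0
        while peaks.total_length - cov * cluster_set.total_length < target \
                and guard < 100_000:
            guard += 1
            chrom = chrom_names[int(rng.integers(0, len(chrom_names)))]
            start = int(rng.integers(0, chrom_sizes[chrom] - decoy_length))
            decoy = IntervalSet.from_tuples([(chrom, start, start + decoy_length)])
            if decoy.intersect(cluster_set).total_length:
                continue
            peaks = peaks.union(decoy)
        out[mark] = peaks
    return out
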