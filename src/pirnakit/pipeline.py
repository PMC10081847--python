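"""End-to-end orchestration: signatures -> discovery -> chromatin overlap.

A single YAML config names the inputs (chrom.sizes, per-sample alignments
with condition labels, optional genome FASTA, GFF3 annotation and per-mark
peak BEDs) and the analysis parameters.  Parameter defaults are the
reference study's printed values: 23-29 nt size window, unique mappers,
1-kb bins, rpm normalization, fold change >= 8 and p < 0.001 for selection,
< 3-kb gap merging.  Every stage logs record counts in/out, and every number
in the summary is recomputable from the emitted stage TSVs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import (
    AlignedRead,
    ConfigurationError,
    GeneModel,
    GenomicInterval,
    IntervalSet,
)
from . import io as pio
from .chromatin import (
    density_by_state,
    genome_fraction,
    intron_exon_density,
    region_state_coverage,
    state_partition,
)
from .discovery import (
    call_regions,
    count_bins,
    differential_bins,
    estimate_size_factors,
    regions_to_dataframe,
)
from .signatures import (
    overlap_histogram,
    pingpong_zscore,
    positional_bias,
    size_strand_distribution,
)
from .simulate import (
    SimulationConfig,
    SyntheticTruth,
    simulate_genome,
    simulate_peaks,
    simulate_reads,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "make_fixtures"]


@dataclass
class PipelineConfig:
    """Inputs plus analysis parameters; defaults are the reference values."""

    chrom_sizes: str = "chrom.sizes"
    samples: Dict[str, Dict[str, str]] = field(default_factory=dict)
    genome: Optional[str] = None
    annotation: Optional[str] = None
    peaks: Dict[str, str] = field(default_factory=dict)

    min_len: int = 23
    max_len: int = 29
    unique_only: bool = True
    bin_width: int = 1000
    merge_gap: int = 3000
    fc_threshold: float = 8.0
    p_threshold: float = 1e-3
    pseudo: float = 0.5
    # Differential testing normalizes like DESeq2 (median-of-ratios): size
    # factors then track the unchanged background rather than total library
    # mass, so a handful of strong de novo clusters cannot drag every other
    # bin into apparent depletion.  rpm stays the unit for read-mass
    # reporting and tracks.
    normalization: str = "median-of-ratios"
    z_window: Tuple[int, int] = (1, 29)
    condition_a: str = "control"
    condition_b: str = "knockdown"

    seed: int = 0
    outdir: str = "pirnakit_out"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        base = Path(path).parent
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        inputs = raw.get("inputs", {})
        params = raw.get("parameters", {})

        def resolve(p):
            return str(base / p) if p else None

        samples = {
            name: {"path": resolve(spec["path"]),
                   "condition": spec["condition"]}
            for name, spec in inputs.get("samples", {}).items()
        }
        peaks = {m: resolve(p) for m, p in inputs.get("peaks", {}).items()}
        kwargs = dict(
            chrom_sizes=resolve(inputs.get("chrom_sizes", "chrom.sizes")),
            genome=resolve(inputs.get("genome")),
            annotation=resolve(inputs.get("annotation")),
            samples=samples,
            peaks=peaks,
            seed=int(raw.get("seed", 0)),
            outdir=str(base / raw["outdir"]) if "outdir" in raw
            else str(base / "pirnakit_out"),
        )
        for key in ("min_len", "max_len", "unique_only", "bin_width",
                    "merge_gap", "fc_threshold", "p_threshold", "pseudo",
                    "normalization", "condition_a", "condition_b"):
            if key in params:
                kwargs[key] = params[key]
        if "z_window" in params:
            kwargs["z_window"] = tuple(params["z_window"])
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        base = Path(path).parent

        def rel(p):
            return os.path.relpath(p, base) if p else None

        doc = {
            "inputs": {
                "chrom_sizes": rel(self.chrom_sizes),
                "genome": rel(self.genome),
                "annotation": rel(self.annotation),
                "samples": {
                    name: {"path": rel(spec["path"]),
                           "condition": spec["condition"]}
                    for name, spec in self.samples.items()
                },
                "peaks": {m: rel(p) for m, p in self.peaks.items()},
            },
            "parameters": {
                "min_len": self.min_len, "max_len": self.max_len,
                "unique_only": self.unique_only,
                "bin_width": self.bin_width, "merge_gap": self.merge_gap,
                "fc_threshold": self.fc_threshold,
                "p_threshold": self.p_threshold, "pseudo": self.pseudo,
                "normalization": self.normalization,
                "z_window": list(self.z_window),
                "condition_a": self.condition_a,
                "condition_b": self.condition_b,
            },
            "seed": self.seed,
            "outdir": os.path.relpath(self.outdir, base),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _reads_in_set(reads: Sequence[AlignedRead], iset: IntervalSet) -> List[AlignedRead]:
    by_chrom: Dict[str, List[int]] = {}
    for i, r in enumerate(reads):
        by_chrom.setdefault(r.chrom, []).append(i)
    keep: List[AlignedRead] = []
    for chrom, idx in by_chrom.items():
        pos = np.array([reads[i].five_prime for i in idx])
        mask = iset.contains_points(chrom, pos)
        keep.extend(reads[i] for i, m in zip(idx, mask) if m)
    return keep


def run_pipeline(config: PipelineConfig) -> Dict[str, object]:
    """Run the full analysis and write the output bundle.

    Emits per-condition size-spectrum TSVs, the bin table, regions (TSV and
    BED), the signature summary for the de novo up-regions, chromatin
    partition/coverage/density tables (when peaks are given), intron/exon
    densities (when an annotation is given), per-condition bedGraph tracks,
    a summary JSON and a run manifest.  Any stage failure aborts with the
    stage name and cause.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: Dict[str, object] = {
        "tool": "pirnakit", "version": __version__,
        "config": {f.name: getattr(config, f.name)
                   for f in dataclasses.fields(config)},
        "inputs": {}, "stages": {}, "warnings": [],
    }
    summary: Dict[str, object] = {}

    stage = "load"
    try:
        chrom_sizes = pio.read_chrom_sizes(config.chrom_sizes)
        manifest["inputs"][config.chrom_sizes] = _sha256(config.chrom_sizes)
        reads_by_sample: Dict[str, List[AlignedRead]] = {}
        conditions: Dict[str, str] = {}
        library_totals: Dict[str, int] = {}
        for name, spec in config.samples.items():
            reads = pio.load_alignments(spec["path"], config.min_len,
                                        config.max_len, config.unique_only)
            reads_by_sample[name] = reads
            conditions[name] = spec["condition"]
            library_totals[name] = len(reads)
            manifest["inputs"][spec["path"]] = _sha256(spec["path"])
            logger.info("loaded %s: %d reads after %d-%d nt unique filter",
                        name, len(reads), config.min_len, config.max_len)
        genes: Optional[List[GeneModel]] = None
        if config.annotation:
            genes = pio.read_gff_genes(config.annotation)
            manifest["inputs"][config.annotation] = _sha256(config.annotation)
        marks: Dict[str, IntervalSet] = {}
        for mark, path in config.peaks.items():
            marks[mark] = pio.read_bed(path)
            manifest["inputs"][path] = _sha256(path)
        manifest["stages"][stage] = {
            "samples": {s: len(r) for s, r in reads_by_sample.items()},
            "genes": len(genes) if genes is not None else 0,
            "marks": {m: len(s) for m, s in marks.items()},
        }

        stage = "size_spectra"
        for cond in sorted(set(conditions.values())):
            pooled = [r for s, rs in reads_by_sample.items()
                      if conditions[s] == cond for r in rs]
            hist = size_strand_distribution(
                pooled, norm_total=sum(library_totals[s]
                                       for s in conditions
                                       if conditions[s] == cond) or None)
            df = hist.counts.reset_index().melt(
                id_vars="length", var_name="strand", value_name="rpm")
            df.to_csv(out / f"size_spectrum_{cond}.tsv", sep="\t", index=False)
        manifest["stages"][stage] = {"conditions": sorted(set(conditions.values()))}

        stage = "discovery"
        table = count_bins(reads_by_sample, chrom_sizes, conditions,
                           bin_width=config.bin_width,
                           library_totals=library_totals)
        estimate_size_factors(table, mode=config.normalization)
        diffs = differential_bins(table, config.condition_a,
                                  config.condition_b, pseudo=config.pseudo,
                                  fc_threshold=config.fc_threshold,
                                  p_threshold=config.p_threshold)
        diffs.to_csv(out / "bins.tsv", sep="\t", index=False)
        regions = call_regions(diffs, table=table, genes=genes,
                               max_gap=config.merge_gap,
                               condition_a=config.condition_a,
                               condition_b=config.condition_b)
        rdf = regions_to_dataframe(regions)
        rdf.to_csv(out / "regions.tsv", sep="\t", index=False)
        pio.write_bed([r.interval for r in regions], out / "regions.bed",
                      names=[r.direction for r in regions],
                      scores=[r.read_mass.get(config.condition_b, 0.0)
                              for r in regions])
        ups = [r for r in regions if r.direction == "up"]
        downs = [r for r in regions if r.direction == "down"]
        summary["regions"] = {
            "total": len(regions), "up": len(ups), "down": len(downs),
            "up_span": int(sum(r.length for r in ups)),
            "down_span": int(sum(r.length for r in downs)),
            "selected_bins": int(diffs["selected"].sum()),
            "tested_bins": int(len(diffs)),
        }
        manifest["stages"][stage] = summary["regions"]

        stage = "signatures"
        b_samples = [s for s, c in conditions.items()
                     if c == config.condition_b]
        pooled_b = [r for s in b_samples for r in reads_by_sample[s]]
        if ups:
            up_set = IntervalSet.from_intervals([r.interval for r in ups])
            up_reads = _reads_in_set(pooled_b, up_set)
        else:
            up_reads = []
        if up_reads:
            sig = overlap_histogram(up_reads)
            sig.pair_counts.rename("pairs").reset_index().to_csv(
                out / "overlap_histogram.tsv", sep="\t", index=False)
            bias = positional_bias(up_reads, sig)
            z10 = pingpong_zscore(sig, window=config.z_window)
            summary["signature"] = {
                "z10": z10, "pct_1U": bias.pct_1U,
                "pct_10A_paired": bias.pct_10A_paired,
                "n_reads": bias.n_reads, "n_paired": bias.n_paired,
            }
            pd.DataFrame([summary["signature"]]).to_csv(
                out / "signature_summary.tsv", sep="\t", index=False)
        else:
            summary["signature"] = None
        manifest["stages"][stage] = {"up_region_reads": len(up_reads)}

        stage = "chromatin"
        if marks:
            genome_length = int(sum(chrom_sizes.values()))
            statemap = state_partition(marks, chrom_sizes)
            statemap.summary().to_csv(out / "partition.tsv", sep="\t")
            summary["genome_fractions"] = {
                m: genome_fraction(s, genome_length)
                for m, s in marks.items()}
            if regions:
                cov = region_state_coverage(regions, marks, reads=pooled_b)
                cov["per_mark"].to_csv(out / "region_mark_coverage.tsv",
                                       sep="\t", index=False)
                cov["per_region"].to_csv(out / "region_coverage.tsv",
                                         sep="\t", index=False)
                summary["region_coverage"] = {
                    row["marks"]: row["percent"]
                    for _, row in cov["per_mark"].iterrows()}
                summary["focal"] = cov["focal"]
            dens = density_by_state(pooled_b, statemap, len(pooled_b))
            dens.to_csv(out / "density_by_state.tsv", sep="\t", index=False)
            manifest["stages"][stage] = {"cells": len(statemap.partition)}
        if genes:
            ie = intron_exon_density(pooled_b, genes, len(pooled_b))
            ie.to_csv(out / "intron_exon_density.tsv", sep="\t", index=False)
            summary["intron_exon_rpkm"] = {
                row["feature"]: row["rpkm"] for _, row in ie.iterrows()}

        stage = "tracks"
        sf = table.size_factors
        bin_ivs = table.bin_intervals()
        for cond in sorted(set(conditions.values())):
            cols = table.condition_samples(cond)
            mean_rpm = (table.counts[cols] / sf[cols]).mean(axis=1).to_numpy()
            pio.write_bedgraph(bin_ivs, mean_rpm,
                               out / f"density_{cond}.bedGraph",
                               name=f"23-29nt rpm {cond}")
        manifest["stages"][stage] = {"bins": len(bin_ivs)}
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return summary


# ---------------------------------------------------------------------------
# fixtures


def _fixture_genes(sim: SimulationConfig) -> List[GeneModel]:
    """Simple two-exon gene models over each planted cluster plus
    intergenic decoy genes, for gene-level counting and intron/exon density."""
    genes: List[GeneModel] = []
    for i, c in enumerate(sim.clusters):
        iv = c.interval
        third = iv.length // 3
        exons = [GenomicInterval(iv.chrom, iv.start, iv.start + third),
                 GenomicInterval(iv.chrom, iv.end - third, iv.end)]
        genes.append(GeneModel(f"gene_c{i}",
                               GenomicInterval(iv.chrom, iv.start, iv.end, "+"),
                               exons))
    # decoys midway between consecutive clusters
    per_chrom = sim.genome_length // sim.n_chroms
    cluster_set = IntervalSet.from_intervals([c.interval for c in sim.clusters])
    for i in range(len(sim.clusters)):
        left = sim.clusters[i].interval.end
        right = (sim.clusters[i + 1].interval.start
                 if i + 1 < len(sim.clusters) else per_chrom)
        mid = (left + right) // 2
        if right - left < 4000:
            continue
        span = GenomicInterval(sim.clusters[i].interval.chrom,
                               mid - 1000, mid + 1000, "-")
        if IntervalSet.from_intervals([span]).intersect(cluster_set):
            continue
        exons = [GenomicInterval(span.chrom, span.start, span.start + 600),
                 GenomicInterval(span.chrom, span.end - 600, span.end)]
        genes.append(GeneModel(f"gene_bg{i}", span, exons))
    return genes


def make_fixtures(sim: SimulationConfig, outdir,
                  coverage_fraction=0.8, decoy_fraction=0.01) -> PipelineConfig:
    """Write a self-contained input bundle (genome, chrom.sizes, alignments,
    peaks, annotation, truth JSON and pipeline config) for ``run_pipeline``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    genome = simulate_genome(sim)
    pio.write_fasta(genome, out / "genome.fa")
    pio.write_chrom_sizes(sim.chrom_sizes, out / "chrom.sizes")
    reads_by_sample, truth = simulate_reads(sim, genome)
    samples = {}
    for name, reads in reads_by_sample.items():
        path = out / f"{name}.tsv"
        pio.write_alignments_tsv(reads, path)
        samples[name] = {
            "path": str(path),
            "condition": "control" if name.startswith("control") else "knockdown",
        }
    truth.to_json(out / "truth.json")
    peaks = simulate_peaks(truth, sim.chrom_sizes,
                           coverage_fraction=coverage_fraction,
                           decoy_fraction=decoy_fraction, seed=sim.seed)
    peak_paths = {}
    for mark, iset in peaks.items():
        path = out / f"peaks_{mark}.bed"
        pio.write_bed(list(iset), path)
        peak_paths[mark] = str(path)
    genes = _fixture_genes(sim)
    pio.write_gff_genes(genes, out / "genes.gff3")

    config = PipelineConfig(
        chrom_sizes=str(out / "chrom.sizes"),
        genome=str(out / "genome.fa"),
        annotation=str(out / "genes.gff3"),
        samples=samples,
        peaks=peak_paths,
        seed=sim.seed,
        outdir=str(out / "results"),
    )
    config.to_yaml(out / "config.yaml")
    return config
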