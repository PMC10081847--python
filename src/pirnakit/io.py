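"""Standard-format I/O: BED, GFF3, chrom.sizes, FASTA, alignments, bedGraph.

The alignment tabular dialect is a TSV with header
``chrom  start  end  strand  sequence  n_hits`` (0-based half-open
coordinates, sequence in read orientation).  BAM input is supported through
pysam and requires NH tags when unique-mapper filtering is requested; the
multiplicity of a read is never silently defaulted.
"""

from __future__ import annotations

import logging
import os
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np

from .core import (
    AlignedRead,
    ConfigurationError,
    GeneModel,
    GenomicInterval,
    IntervalSet,
    ParseError,
    ValidationError,
    revcomp,
)

logger = logging.getLogger(__name__)

ALIGNMENT_COLUMNS = ("chrom", "start", "end", "strand", "sequence", "n_hits")

PathLike = Union[str, "os.PathLike[str]"]


# ---------------------------------------------------------------------------
# BED and chrom.sizes


def read_bed(path: PathLike) -> IntervalSet:
    """Read a BED3+ file into a canonical :class:`IntervalSet`.

    Coordinates are taken as-is (BED is natively 0-based half-open).
    Overlapping or abutting records are merged.
    """
    records: List[Tuple[str, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 tab-separated "
                                 f"columns, got {len(fields)}")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end or start < 0:
                raise ValidationError(
                    f"{path}:{lineno}: invalid interval {fields[0]}:{start}-{end}")
            records.append((fields[0], start, end))
    return IntervalSet.from_tuples(records)


def write_bed(intervals: Iterable[GenomicInterval], path: PathLike,
              names: Optional[Sequence[str]] = None,
              scores: Optional[Sequence[float]] = None) -> None:
    """Write intervals as BED3 (or BED6 when names/scores are given)."""
    intervals = list(intervals)
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            if names is None and scores is None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                name = names[i] if names is not None else "."
                score = scores[i] if scores is not None else 0
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score:g}"
                         f"\t{iv.strand}\n")


def read_chrom_sizes(path: PathLike) -> Dict[str, int]:
    """Read a two-column ``chrom<TAB>size`` file."""
    sizes: Dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns")
            sizes[fields[0]] = int(fields[1])
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path: PathLike) -> None:
    with open(path, "w") as fh:
        for chrom, n in sizes.items():
            fh.write(f"{chrom}\t{n}\n")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: PathLike) -> Dict[str, str]:
    """Load a genome FASTA into memory as plain uppercase strings."""
    import pyfaidx

    fa = pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True,
                       rebuild=True)
    return {name: str(fa[name][:]) for name in fa.keys()}


def write_fasta(seqs: Mapping[str, str], path: PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3 gene models


def read_gff_genes(path: PathLike) -> List[GeneModel]:
    """Parse GFF3 gene/exon features into :class:`GeneModel` objects.

    GFF3 1-based closed coordinates are converted to 0-based half-open.
    Exons are linked to genes through Parent chains (directly or via
    mRNA/transcript features); exons with no resolvable gene ancestor are
    skipped with a warning.  An exon outside its gene span is an error.
    """
    import gffutils

    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique",
                            sort_attribute_values=True)
    genes: List[GeneModel] = []
    gene_ids = set()
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        gene_ids.add(gene.id)
        span = GenomicInterval(gene.seqid, gene.start - 1, gene.end,
                               gene.strand if gene.strand in "+-" else ".")
        exons = [
            GenomicInterval(ex.seqid, ex.start - 1, ex.end)
            for ex in db.children(gene, featuretype="exon")
        ]
        genes.append(GeneModel(gene_id=gene.id, span=span, exons=exons))

    # orphan exons: no gene among ancestors
    for ex in db.features_of_type("exon"):
        ancestors = {p.id for p in db.parents(ex)}
        if not ancestors & gene_ids:
            logger.warning("skipping orphan exon %s:%d-%d (no parent gene)",
                           ex.seqid, ex.start - 1, ex.end)
    return genes


def write_gff_genes(genes: Iterable[GeneModel], path: PathLike) -> None:
    """Write gene models as minimal GFF3 (gene + exon features)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            strand = g.span.strand if g.span.strand in "+-" else "."
            fh.write(f"{g.span.chrom}\tpirnakit\tgene\t{g.span.start + 1}\t"
                     f"{g.span.end}\t.\t{strand}\t.\tID={g.gene_id}\n")
            for i, ex in enumerate(g.exons, start=1):
                fh.write(f"{ex.chrom}\tpirnakit\texon\t{ex.start + 1}\t{ex.end}"
                         f"\t.\t{strand}\t.\tID={g.gene_id}.e{i};"
                         f"Parent={g.gene_id}\n")


# ---------------------------------------------------------------------------
# Alignments


def _reads_from_tsv(path: PathLike, unique_only: bool) -> Iterable[AlignedRead]:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != ALIGNMENT_COLUMNS:
            raise ParseError(
                f"{path}: expected header {' '.join(ALIGNMENT_COLUMNS)}, "
                f"got {' '.join(header)}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise ParseError(f"{path}:{lineno}: expected 6 columns")
            chrom, start, end, strand, seq, n_hits = fields
            if n_hits in (".", ""):
                if unique_only:
                    raise ConfigurationError(
                        f"{path}:{lineno}: n_hits missing but unique-mapper "
                        "filtering requested")
                hits = 1
            else:
                hits = int(n_hits)
            yield AlignedRead(
                GenomicInterval(chrom, int(start), int(end), strand), seq, hits)


def _reads_from_bam(path: PathLike, unique_only: bool) -> Iterable[AlignedRead]:
    import pysam

    with pysam.AlignmentFile(str(path), "rb") as bam:
        for rec in bam.fetch(until_eof=True):
            if rec.is_unmapped or rec.reference_name is None:
                continue
            try:
                n_hits = int(rec.get_tag("NH"))
            except KeyError:
                if unique_only:
                    raise ConfigurationError(
                        f"{path}: read {rec.query_name} lacks an NH tag; "
                        "cannot apply unique-mapper filtering")
                n_hits = 1
            strand = "-" if rec.is_reverse else "+"
            seq = rec.query_sequence or ""
            # pysam reports query_sequence in reference orientation for
            # reverse reads; flip back to read orientation.
            if rec.is_reverse:
                seq = revcomp(seq)
            yield AlignedRead(
                GenomicInterval(rec.reference_name, rec.reference_start,
                                rec.reference_end, strand), seq, n_hits)


def load_alignments(path: PathLike, min_len: int = 23, max_len: int = 29,
                    unique_only: bool = True) -> List[AlignedRead]:
    """Load aligned reads from BAM or the TSV dialect, with size and
    unique-mapper filtering.

    Only reads with ``min_len <= length <= max_len`` are retained; with
    ``unique_only``, only reads with ``n_hits == 1``.
    """
    source = (_reads_from_bam if str(path).endswith(".bam") else _reads_from_tsv)
    out: List[AlignedRead] = []
    for read in source(path, unique_only):
        if not (min_len <= read.length <= max_len):
            continue
        if unique_only and not read.is_unique:
            continue
        out.append(read)
    return out


def write_alignments_tsv(reads: Iterable[AlignedRead], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(ALIGNMENT_COLUMNS) + "\n")
        for r in reads:
            fh.write(f"{r.chrom}\t{r.interval.start}\t{r.interval.end}\t"
                     f"{r.strand}\t{r.sequence}\t{r.n_hits}\n")


# ---------------------------------------------------------------------------
# bedGraph


def write_bedgraph(bins, values, path: PathLike, name: str = "coverage") -> None:
    """Write per-bin values as a minimal bedGraph track.

    ``bins`` is an iterable of :class:`GenomicInterval`; zero bins are kept so
    the track tiles the genome.
    """
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{name}"\n')
        for iv, v in zip(bins, values):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{v:.6g}\n")
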