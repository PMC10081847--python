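"""Interval algebra, BED/GFF/alignment I/O and domain-type invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pirnakit.core import (
    AlignedRead,
    ConfigurationError,
    GeneModel,
    GenomicInterval,
    IntervalSet,
    ParseError,
    ValidationError,
    intersect,
    merge_within_gap,
)
from pirnakit import io as pio

from helpers import mask_from_tuples, mask_of, random_tuples, set_from_mask

CHROMS = {"chr1": 100_000, "chr2": 60_000}


# ---------------------------------------------------------------------------
# domain types


@pytest.mark.parametrize("start,end", [(-1, 10), (10, 10), (20, 10)])
def test_interval_bounds_are_validated(start, end):
    with pytest.raises(ValidationError):
        GenomicInterval("chr1", start, end)


def test_read_invariants():
    iv = GenomicInterval("chr1", 100, 125, "-")
    read = AlignedRead(iv, "A" * 25)
    assert read.five_prime == 124  # minus-strand 5' end is end - 1
    assert read.is_unique
    with pytest.raises(ValidationError):
        AlignedRead(iv, "A" * 24)  # length mismatch
    with pytest.raises(ValidationError):
        AlignedRead(iv, "A" * 25, n_hits=0)
    with pytest.raises(ValidationError):
        AlignedRead(GenomicInterval("chr1", 0, 25, "."), "A" * 25)


def test_gene_model_exons_merge_and_introns_derive():
    span = GenomicInterval("chr1", 0, 300, "+")
    gene = GeneModel("g1", span, [GenomicInterval("chr1", 0, 100),
                                  GenomicInterval("chr1", 50, 120),
                                  GenomicInterval("chr1", 200, 300)])
    assert [(e.start, e.end) for e in gene.exons] == [(0, 120), (200, 300)]
    assert [(i.start, i.end) for i in gene.introns] == [(120, 200)]
    with pytest.raises(ValidationError):
        GeneModel("bad", span, [GenomicInterval("chr1", 250, 350)])


# ---------------------------------------------------------------------------
# interval-set algebra vs the per-base boolean oracle


def test_canonicalization_merges_overlap_and_abutment():
    s = IntervalSet.from_tuples([("chr1", 0, 100), ("chr1", 50, 200),
                                 ("chr1", 200, 250), ("chr1", 300, 400)])
    assert [(iv.start, iv.end) for iv in s] == [(0, 250), (300, 400)]
    assert s.total_length == 350


@pytest.mark.parametrize("op", ["union", "intersect", "subtract"])
def test_algebra_matches_boolean_oracle(op):
    rng = np.random.default_rng(42)
    for _ in range(40):
        ta = random_tuples(rng, CHROMS, int(rng.integers(1, 40)))
        tb = random_tuples(rng, CHROMS, int(rng.integers(1, 40)))
        a, b = IntervalSet.from_tuples(ta), IntervalSet.from_tuples(tb)
        ma, mb = mask_from_tuples(ta, CHROMS), mask_from_tuples(tb, CHROMS)
        got = getattr(a, op)(b)
        if op == "union":
            want = {c: ma[c] | mb[c] for c in CHROMS}
        elif op == "intersect":
            want = {c: ma[c] & mb[c] for c in CHROMS}
        else:
            want = {c: ma[c] & ~mb[c] for c in CHROMS}
        assert got == set_from_mask(want)
        assert got.total_length == sum(int(m.sum()) for m in want.values())


def test_intersect_is_commutative_and_bounded():
    rng = np.random.default_rng(7)
    a = IntervalSet.from_tuples(random_tuples(rng, CHROMS, 30))
    b = IntervalSet.from_tuples(random_tuples(rng, CHROMS, 30))
    ab, ba = intersect(a, b), intersect(b, a)
    assert ab == ba
    assert ab.total_length <= min(a.total_length, b.total_length)
    assert intersect(a, IntervalSet()).total_length == 0


def test_union_total_length_equals_occupancy():
    # 1,000 random intervals against the brute-force per-base count
    rng = np.random.default_rng(3)
    tuples = random_tuples(rng, CHROMS, 1000)
    s = IntervalSet.from_tuples(tuples)
    masks = mask_from_tuples(tuples, CHROMS)
    assert s.total_length == sum(int(m.sum()) for m in masks.values())


def test_merge_within_gap_strict_boundary():
    s = IntervalSet.from_tuples([("chr1", 0, 1000), ("chr1", 2000, 3000)])
    merged = s.merge_within_gap(3000)
    assert [(iv.start, iv.end) for iv in merged] == [(0, 3000)]
    # a gap of exactly max_gap is NOT fused
    t = IntervalSet.from_tuples([("chr1", 0, 1000), ("chr1", 4000, 5000)])
    assert t.merge_within_gap(3000) == t


def test_merge_within_gap_matches_dilation_erosion_oracle():
    rng = np.random.default_rng(11)
    for _ in range(30):
        tuples = random_tuples(rng, CHROMS, int(rng.integers(2, 50)))
        gap = int(rng.integers(1, 8000))
        s = IntervalSet.from_tuples(tuples)
        got = s.merge_within_gap(gap)
        # oracle: pad right ends by gap-1, canonicalize, shave the padding
        dilated = IntervalSet.from_tuples(
            [(iv.chrom, iv.start, iv.end + gap - 1) for iv in s])
        want = IntervalSet.from_tuples(
            [(iv.chrom, iv.start, iv.end - gap + 1) for iv in dilated])
        assert got == want
        assert got.merge_within_gap(gap) == got  # idempotent


@settings(derandomize=True, max_examples=50, deadline=None)
@given(st.lists(st.tuples(st.integers(0, 5000), st.integers(1, 500)),
                min_size=1, max_size=30),
       st.integers(0, 2000))
def test_merge_idempotence_property(pairs, gap):
    s = IntervalSet.from_tuples([("chr1", a, a + b) for a, b in pairs])
    once = s.merge_within_gap(gap)
    assert once.merge_within_gap(gap) == once
    assert once.total_length >= s.total_length


def test_complement_partitions_genome():
    rng = np.random.default_rng(5)
    s = IntervalSet.from_tuples(random_tuples(rng, CHROMS, 25))
    comp = s.complement(CHROMS)
    assert s.intersect(comp).total_length == 0
    assert s.total_length + comp.total_length == sum(CHROMS.values())


# ---------------------------------------------------------------------------
# BED


def test_read_bed_single_and_merge(tmp_path):
    p = tmp_path / "a.bed"
    p.write_text("chr1\t0\t100\n")
    s = pio.read_bed(p)
    assert s.total_length == 100
    p.write_text("chr1\t0\t100\nchr1\t50\t200\n")
    s = pio.read_bed(p)
    assert [(iv.start, iv.end) for iv in s] == [(0, 200)]


def test_read_bed_errors_name_line(tmp_path):
    p = tmp_path / "bad.bed"
    p.write_text("chr1\t0\t100\nchr1\t50\n")
    with pytest.raises(ParseError, match=":2"):
        pio.read_bed(p)
    p.write_text("chr1\t100\t100\n")
    with pytest.raises(ValidationError):
        pio.read_bed(p)


def test_bed_roundtrip_bit_identical(tmp_path):
    rng = np.random.default_rng(9)
    s = IntervalSet.from_tuples(random_tuples(rng, CHROMS, 200))
    p1, p2 = tmp_path / "r1.bed", tmp_path / "r2.bed"
    pio.write_bed(list(s), p1)
    again = pio.read_bed(p1)
    assert again == s
    pio.write_bed(list(again), p2)
    assert p1.read_bytes() == p2.read_bytes()


# ---------------------------------------------------------------------------
# GFF3 gene models


def _write_gff(path, body):
    path.write_text("##gff-version 3\n" + body)


def test_gff_intron_derivation(tmp_path):
    # 1-based closed gene [1,300] with exons [1,100] and [201,300]
    p = tmp_path / "g.gff3"
    _write_gff(p, "\n".join([
        "chr1\tsrc\tgene\t1\t300\t.\t+\t.\tID=g1",
        "chr1\tsrc\texon\t1\t100\t.\t+\t.\tID=g1.e1;Parent=g1",
        "chr1\tsrc\texon\t201\t300\t.\t+\t.\tID=g1.e2;Parent=g1",
        "chr1\tsrc\tgene\t400\t500\t.\t-\t.\tID=g2",
        "chr1\tsrc\texon\t400\t500\t.\t-\t.\tID=g2.e1;Parent=g2",
    ]) + "\n")
    genes = {g.gene_id: g for g in pio.read_gff_genes(p)}
    g1 = genes["g1"]
    assert (g1.span.start, g1.span.end) == (0, 300)
    assert [(i.start, i.end) for i in g1.introns] == [(100, 200)]
    assert genes["g2"].introns == []  # intronless


def test_gff_random_structures_tile_span(tmp_path):
    rng = np.random.default_rng(21)
    for trial in range(10):
        span_len = int(rng.integers(500, 5000))
        n_exons = int(rng.integers(1, 6))
        cuts = np.sort(rng.choice(np.arange(1, span_len), size=2 * n_exons,
                                  replace=False))
        exons = [(int(cuts[2 * i]), int(cuts[2 * i + 1]))
                 for i in range(n_exons)]
        lines = [f"chr1\tsrc\tgene\t1\t{span_len}\t.\t+\t.\tID=g"]
        lines += [f"chr1\tsrc\texon\t{s + 1}\t{e}\t.\t+\t.\tID=g.e{i};Parent=g"
                  for i, (s, e) in enumerate(exons)]
        p = tmp_path / f"t{trial}.gff3"
        _write_gff(p, "\n".join(lines) + "\n")
        gene = pio.read_gff_genes(p)[0]
        exon_mask = mask_from_tuples(
            [("chr1", e.start, e.end) for e in gene.exons],
            {"chr1": span_len})["chr1"]
        intron_mask = mask_from_tuples(
            [("chr1", i.start, i.end) for i in gene.introns],
            {"chr1": span_len})["chr1"]
        assert not (exon_mask & intron_mask).any()
        assert (exon_mask | intron_mask).all()  # tiles the whole span


def test_gff_roundtrip(tmp_path):
    span = GenomicInterval("chr1", 10, 500, "+")
    genes = [GeneModel("gX", span, [GenomicInterval("chr1", 10, 100),
                                    GenomicInterval("chr1", 300, 500)])]
    p = tmp_path / "w.gff3"
    pio.write_gff_genes(genes, p)
    back = pio.read_gff_genes(p)
    assert back[0].gene_id == "gX"
    assert [(e.start, e.end) for e in back[0].exons] == [(10, 100), (300, 500)]


# ---------------------------------------------------------------------------
# alignment loading


ALN_HEADER = "chrom\tstart\tend\tstrand\tsequence\tn_hits\n"


def test_load_alignments_size_and_uniqueness_filters(tmp_path):
    p = tmp_path / "r.tsv"
    p.write_text(ALN_HEADER + "\n".join([
        "chr1\t0\t21\t+\t" + "A" * 21 + "\t1",     # too short
        "chr1\t0\t25\t+\t" + "A" * 25 + "\t1",     # kept
        "chr1\t0\t30\t+\t" + "A" * 30 + "\t1",     # too long
        "chr1\t0\t25\t-\t" + "C" * 25 + "\t7",     # multimapper
    ]) + "\n")
    reads = pio.load_alignments(p, 23, 29, unique_only=True)
    assert len(reads) == 1 and reads[0].length == 25
    assert len(pio.load_alignments(p, 23, 29, unique_only=False)) == 2


def test_load_alignments_requires_multiplicity(tmp_path):
    p = tmp_path / "r.tsv"
    p.write_text(ALN_HEADER + "chr1\t0\t25\t+\t" + "A" * 25 + "\t.\n")
    with pytest.raises(ConfigurationError):
        pio.load_alignments(p, 23, 29, unique_only=True)
    assert len(pio.load_alignments(p, 23, 29, unique_only=False)) == 1


def test_alignment_tsv_roundtrip(tmp_path):
    from helpers import random_reads
    rng = np.random.default_rng(13)
    reads = random_reads(rng, 50)
    p = tmp_path / "rt.tsv"
    pio.write_alignments_tsv(reads, p)
    back = pio.load_alignments(p, 23, 29, unique_only=True)
    assert back == reads


def test_load_alignments_from_bam(tmp_path):
    pysam = pytest.importorskip("pysam")
    path = str(tmp_path / "r.bam")
    header = {"HD": {"VN": "1.6"}, "SQ": [{"SN": "chr1", "LN": 10_000}]}
    with pysam.AlignmentFile(path, "wb", header=header) as bam:
        fwd = pysam.AlignedSegment(bam.header)
        fwd.query_name = "r1"
        fwd.query_sequence = "A" * 25
        fwd.flag = 0
        fwd.reference_id = 0
        fwd.reference_start = 100
        fwd.cigar = [(0, 25)]
        fwd.set_tag("NH", 1)
        bam.write(fwd)
        rev = pysam.AlignedSegment(bam.header)
        rev.query_name = "r2"
        rev.query_sequence = "ACGTG" * 5  # stored in reference orientation
        rev.flag = 16
        rev.reference_id = 0
        rev.reference_start = 200
        rev.cigar = [(0, 25)]
        rev.set_tag("NH", 1)
        bam.write(rev)
        multi = pysam.AlignedSegment(bam.header)
        multi.query_name = "r3"
        multi.query_sequence = "C" * 25
        multi.flag = 0
        multi.reference_id = 0
        multi.reference_start = 300
        multi.cigar = [(0, 25)]
        multi.set_tag("NH", 4)
        bam.write(multi)
    reads = pio.load_alignments(path, 23, 29, unique_only=True)
    assert len(reads) == 2  # multimapper dropped
    rev_read = reads[1]
    assert rev_read.strand == "-" and rev_read.five_prime == 224
    # sequence flipped back into read orientation
    from pirnakit.core import revcomp
    assert rev_read.sequence == revcomp("ACGTG" * 5)
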