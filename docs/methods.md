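# Methods

## The analysis in one paragraph

Two replicated conditions of ovarian small-RNA libraries (a control and a
germline knockdown) are compared to find genomic regions that change their
production of 23–29 nt unique-mapper reads. The genome is tiled in 1-kb
bins; each read is assigned to the bin containing its own 5′ end (both
strands pooled); per-bin counts are tested with a negative-binomial Wald
test; bins passing fold change ≥ 8 and p < 0.001 are merged into regions
when separated by strictly less than 3 kb, separately for up- and
down-regulated bins. Called regions are then characterized by read-level
piRNA signatures (size spectrum, 1U, ping-pong z-score, 10A) and by their
overlap with chromatin marks (H3K9me2, H3K9me3, Rhino peak sets).

## Coordinate and orientation conventions

All coordinates are 0-based half-open on the genomic axis; BED is native,
GFF3 is converted on read. A read's sequence is stored in its own 5′→3′
orientation; the genomic 5′ end of a minus-strand read is `end − 1`. Every
positional statistic (1U, 10A, overlap pairing, bin and cell assignment)
is defined from the read's own 5′ end, which makes read-to-interval
assignment unambiguous and conservation exact: a partition of the genome
partitions both bases and reads.

## Ping-pong signature

For a plus-strand read with 5′ end p⁺ and a minus-strand read with 5′ end
p⁻ on the same chromosome, the 5′ overlap is k = p⁻ − p⁺ + 1, counted for
1 ≤ k ≤ 29. Pair counts are products of read multiplicities at the two
positions: duplicated reads count multiplicatively (reads, not distinct
positions, are counted — this is stated explicitly because it changes the
z-score). The ping-pong z-score is z₁₀ = (n₁₀ − μ)/σ with μ and the
population SD σ taken over the full window k = 1…29, k = 10 included; the
window is configurable because published analyses do not always state it.
If all counts in the window are equal, σ = 0 and the score is undefined
(NaN). Note that for a histogram dominated by a single overlap class the
score saturates at (n−μ)/σ → √28 ≈ 5.29, the maximum for a 29-bin window.

1U is the fraction of T-starting reads among all 23–29 nt input reads; 10A
is the A fraction at position 10 among reads participating in at least one
10-nt-overlap pair. Positional frequency matrices are computed over reads
3′-trimmed to 23 nt, with N bases excluded from denominators.

## Differential bin model

Counts K are modeled as NB with Var = μ + φμ². Normalized counts are
x = K/s with per-sample size factors s:

* `median-of-ratios` (default in the pipeline's differential stage): the
  DESeq2-style estimator, median over all-nonzero bins of the count over
  its across-sample geometric mean, rescaled to geometric mean 1. This is
  composition-robust: a handful of strongly induced clusters can multiply a
  library's total read count several-fold, and total-count (rpm) scaling
  would then shift every other bin into apparent depletion and compress the
  clusters' own fold change below threshold. Median-of-ratios tracks the
  unchanged background instead.
* `rpm` (library total / 10⁶) remains the unit for all *reporting*:
  read-mass of regions, reference-set tables, bedGraph tracks.

Per bin, log2FC = log₂((mean_B + c)/(mean_A + c)) with pseudo-count
c = 0.5 on normalized means, so bins with zeros in one condition — the
typical de novo cluster — stay finite. Dispersion is estimated per bin by
method of moments on the pooled within-condition variance,
φ̂ = (s²_pooled − a·μ)/μ² with a the mean reciprocal size factor (the
Poisson part of Var(K/s)), clipped at 0, then shrunk toward the
count-weighted global mean dispersion with weight n/(n+4) (n = total
replicates). No mean-dispersion trend curve is fitted; with six samples the
global mean is a stable anchor and the shrinkage weight keeps per-bin
information dominant.

The Wald statistic is z = log2FC/SE with SE propagated through the log by
the delta method from Var(mean_c) = (a·μ_c + φμ_c²)/n_c. The mean entering
the variance is floored at the pseudo-count so a zero-count condition never
produces a zero SE (and hence a spurious p ≈ 0 on null data). p-values are
two-sided normal tails; selection uses the *raw* p-value (< 0.001) together
with |log2FC| ≥ 3, matching the published rule; a Benjamini–Hochberg
adjusted column is emitted alongside but not used for selection. Bins with
zero mean in both conditions are skipped. Fewer than two replicates per
condition is an error — no single-replicate inference.

Region calling merges selected bins of the same direction whose gap is
strictly below 3 kb ("less than 3 kb" is read strictly: a 3,000-bp gap does
not merge). Directions never merge. Regions record their member bins, rpm
read mass per condition, and overlapping gene identifiers.

## Chromatin-state analysis

Peak sets are consumed as BED (peak calling itself is upstream; the
reference analysis used MACS2 with `--gsize 120000000 --nomodel`, narrow
peaks for Rhino and broad peaks for H3K9me2/me3). The 2ⁿ co-enrichment
partition is computed by exact interval intersection/subtraction against
the genome (taken as the sum of chrom.sizes of the supplied assembly, not a
hard-coded constant), so cell lengths sum exactly to the genome length.
Densities are RPKM = reads × 10⁹ / (bases × library_total) with reads
assigned by 5′ end. Intron/exon densities pool feature bases across genes;
introns are always derived as span minus merged exons, never stored.

A dimensional note on the reference numbers this mirrors: the published
statement that 69 Rhino-positive regions "totalize 1.855 kb" is read as
1,855 kb, which is the value consistent with the companion statement that
they represent 77.9% of the 2,382-kb up-region span.

## Synthetic data generator

The generator emulates the reference study design: three replicates per
condition, planted dual-strand clusters over a uniform-composition random
genome, uniform read lengths 23–29 nt, balanced strands, negative-binomial
replicate noise with shared dispersion φ (φ = 0 degenerates to Poisson;
default 0.05, a typical within-genotype overdispersion for replicated
sRNA-seq), and a uniform two-strand background (default 10,000 reads/Mb
per replicate, giving ≈10 reads per kb bin — enough that median-of-ratios
normalization and the null calibration operate on well-populated bins).
All simulated reads are unique mappers.

A fraction `pingpong_fraction` of each cluster's reads is emitted as pairs
whose 5′ ends overlap by exactly 10 nt on opposite strands. Nucleotide
biases are imposed on the *recorded read sequence* (position 1 set to T
with probability `u1_prob`, else a uniform other base; position 10 of
planted-pair members set to A with probability `a10_prob`), not on the
genome — this keeps genome composition neutral, decouples bias injection
from placement, and makes the recorded 1U/10A rates exactly the configured
probabilities. Defaults (`u1_prob` 0.65, `a10_prob` 0.55,
`pingpong_fraction` 0.5) sit in the middle of the ranges observed for
genuine dual-strand clusters in ovarian libraries.

The flagship configuration plants 13 clusters of 4 kb on a 2-Mb genome,
100 reads per kb bin per replicate in the control and 16× that in the
knockdown. Two deliberate choices here:

* **13 clusters at 16-fold, not 8-fold.** The caller's selection threshold
  is fold ≥ 8. An effect planted exactly at a threshold is selected with
  probability ½ by any unbiased estimator (at these depths the log2FC
  estimator has SD ≈ 0.28), so a calibration that demands complete recovery
  must plant effects clearly above threshold; 16× emulates the handful of
  strong "major" regions a real knockdown produces, while estimator
  unbiasedness at exactly 8-fold is verified separately (bias < 0.2).
* **2-Mb genome, 0.5-Mb null genomes.** Scaled-down stand-ins for a
  ~137-Mb assembly chosen so the full suite and the acceptance script run
  in minutes on one CPU; all statistics tested (recovery, false-positive
  rate, calibration of z₁₀) are per-bin or per-read quantities whose
  behavior does not depend on total genome size.

Simulated peak sets cover a deterministic prefix fraction of each planted
cluster (so per-region coverage equals the configured fraction up to base
rounding) plus random decoy peaks outside clusters up to a configured
genome fraction.

What the generator does *not* emulate — and hence what passing tests do not
show about real data: multimapping reads and their assignment ambiguity,
transposon-derived sequence structure, sequencing error, 3′-end length
heterogeneity from trimming chemistry, chromatin-dependent background
variation, and genuinely shared dispersion trends across the mean range.
Results on real libraries additionally depend on upstream alignment and
peak-calling choices that are out of scope here.

## Determinism and reporting

All randomness flows from a single integer seed through per-purpose child
seeds; identical configuration and seed give byte-identical outputs
(including the run manifest, which records the config snapshot, input
checksums and per-stage record counts, and contains no timestamps). Every
number in the summary report is recomputable from the emitted stage TSVs.

## Known limitations

* The NB Wald test is intentionally simpler than DESeq2 (no trend-fitted
  dispersion prior, no lfc shrinkage, normal rather than t null); it is
  calibrated for the regime the pipeline targets (≥ 2 replicates, bins with
  tens of reads) and validated by planted-truth recovery, not by agreement
  with any external implementation.
* Gene-level counting assigns a read to every gene span containing its 5′
  end; no fractional assignment for overlapping genes.
* Uni-strand vs dual-strand cluster classification, transposon-family
  assignment, and phasing (3′–5′ distance) signatures are out of scope.
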