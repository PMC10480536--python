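# Methods

## The screen statistic

A sample's repeat-read ratio is the fraction of its reads containing the
telomeric motif — the repeat unit TTAGGG concatenated 6 times (36 bases)
— as an exact, contiguous, mismatch-free substring. Classification is
boolean per read (the search stops at the first hit; overlapping or
multiple occurrences do not change it), reads are uppercased first, and
`N` matches nothing, so the "no mismatches" rule is literal. By default
the reverse-complement motif (CCCTAA)6 is also searched
(`strand_mode="both"`): shotgun reads come from both strands of the
repeat array, and a G-strand-only search would halve sensitivity on
unstranded libraries. `forward_only` is retained for the literal
single-strand reading. Both search strings are deduplicated if the motif
is self-reverse-complementary.

The denominator is ambiguous when the input is raw FASTQ ("total mapped
reads" is meaningless without alignments). The implementation makes the
choice explicit and records it in the output: `all_reads` for FASTQ,
`mapped_reads` for SAM/BAM (primary records not flagged unmapped;
secondary and supplementary alignments are never counted), with `auto`
picking whichever fits the input. Paired-end mates count as independent
reads, and no duplicate removal is performed. A sample with zero
denominator reads gets `ratio=None` and a QC flag — never a silent 0.

QC is per sample: at least `min_reads` denominator reads and a modal
read length of at least `min_read_length`. The `encode-k562` preset
(20 000 000 reads, 37 bp) encodes the cohort gate used for public
ENCODE K562 data — 37 is the shortest read that can contain the 36-mer
plus one flanking base. Per-read length filtering is deliberately not
applied: shorter reads simply cannot match and only dilute the ratio,
which the gate catches at the sample level. The `desk` preset disables
the gate for small synthetic cohorts.

## Cohort aggregation and candidate calling

Replicate ratios collapse to one score per target by the mean (median
and max are available); QC-failing and unscreenable samples are
excluded, and a target with no passing replicate is dropped with a
warning. The score distribution is summarized with quartiles by the
linear-interpolation convention (numpy's default percentile method) —
stated explicitly because Tukey fences depend on it — and a candidate is
a target whose score exceeds Q3 + 1.5·IQR, matching box-plot outlier
semantics; a z-score rule (mean + 3·sd) is available. Ranking sorts by
descending score with lexicographic tie-break on the target name so
results are deterministic and order-invariant. Samples carrying a
manifest `class` other than "protein" (e.g. histone markers) contribute
to the fence distribution but are not ranked or flagged, since the
candidate list is about proteins while the markers anchor the cohort
background.

No per-target p-value is defined: the screen is a ranking plus an
outlier call, not a significance test, and no input-control
normalization is attempted.

## Relative telomere length

T/S = 2^−ΔCt with ΔCt = ct_tel − ct_alb, exactly as monochrome
multiplex qPCR reports it; no standard-curve or efficiency machinery,
and no ΔΔCt normalization to a reference sample, is applied. Identities
that follow: T/S(ct, ct) = 1 for any ct; a joint shift of both Ct values
cancels; each extra telomere cycle halves T/S. Ct values outside (0, 45)
are flagged, not rejected.

Group comparisons: the Wilcoxon rank-sum test computes the Mann-Whitney
U of the first group from midranks. For combined n ≤ 10 (configurable)
the p-value is exact, by full enumeration over all C(n, n_a) assignments
of the observed midranks — this handles ties exactly, which off-the-shelf
exact implementations refuse; above that, the normal approximation with
tie correction and continuity correction (scipy). The one-sided
direction must be supplied by the caller — the package does not guess
which side a figure intends. Welch's t test and one-way fixed-effects
ANOVA (both via scipy) cover mean comparisons.

## Focus colocalization

Coordinates are 2D (microscopy projections); 3D is out of scope. Two
channels are matched one-to-one by mutual nearest neighbors: a pair is
matched iff each focus is the other's nearest cross-channel focus and
their distance is at most the threshold. Mutual-NN was chosen over
greedy-by-distance because it is deterministic, symmetric in channel
order, and honors "a focus colocalizes with at most one partner"; it can
fall below the maximum-cardinality matching on crowded fields (tests
assert mutual-NN ≤ brute-force maximum matching, with equality on
jitter-free planted data). Nearest-neighbor ties break to the lowest
index after a stable sort of each channel's foci by (x, y), making
results independent of input row order. A third channel extends a
matched pair to a triple iff an unclaimed focus lies within the
threshold of the pair midpoint; each focus is used at most once.

The matching threshold is expressed in the coordinate table's own units
and is required from the caller — no universal pixel/µm criterion
exists, and the right value depends on acquisition. The TIF ratio
divides a nucleus's matched (damage-marker × telomere) count by its
telomere-channel focus count, then averages per-nucleus ratios across
nuclei within a group (a pooled-total mode is what the per-nucleus
tables allow the caller to compute instead); the APB ratio treats a
PML–telomere pair the same way, with the telomere channel as reference.
Cofocus histograms use the reporting bins {0, 1–4, 5–8, 9–10, >10} by
default. The 2×2 chi-squared on positive-nucleus fractions uses the
Pearson statistic without continuity correction (Yates available); a
zero margin is a validation error, so callers must pick a positivity
cutoff that splits both groups.

## The synthetic-data generator

The generator defines the study conditions the tests exercise:

- **Reads**: uniform random bases at a configurable length (default
  50 bp) and depth, with a planted fraction of motif-bearing reads. In
  `exact_count` mode exactly floor(f·n) reads are planted, so the
  screened ratio is exact ground truth; `bernoulli` mode plants
  independently for stochastic checks. The motif sits at a uniform
  valid offset (exercising read-end positions), half the planted reads
  carry the reverse-complement motif by default, and background reads
  are rejection-resampled until motif-free on both strands (a chance
  36-mer is ~10⁻²⁰ per read — negligible but nonzero, and exactness is
  the point). Quality lines are constant `I` since the screen never
  reads them.
- **Cohorts**: default 20 targets × 3 replicates × 10 000 reads at a
  0.2% background ratio with one candidate planted at 2% — a 10×
  enrichment, the same order as a strong repeat-binder against a
  background of unrelated nuclear proteins, at roughly 1/2000 the read
  depth of the real cohort gate. Each sample draws its RNG stream from
  (master seed, sample index), so cohorts reproduce byte-identically
  and could be generated in parallel.
- **Ct tables**: ct_alb = base_ct + N(0, σ), ct_tel = ct_alb + offset +
  N(0, σ), so ΔCt ~ N(offset, σ) and group T/S is lognormal with
  noise-free mean 2^−offset. Defaults: base 20 cycles, σ = 0.1 cycles
  (typical replicate pipetting noise), KO offset −1 (T/S doubles).
- **Foci**: floor(colocalized_fraction × min channel count) anchors per
  nucleus, uniform over a 100-unit square field, one focus per channel
  at anchor + N(0, jitter_sd) per axis (default jitter 0.2 units vs a
  1.5-unit matching threshold); remaining foci uniform. Per-nucleus
  counts are fixed integers or Poisson.

What the generator does *not* emulate — base-quality and sequencing
error models, adapter contamination, genome-derived backgrounds with
interstitial telomeric repeats, paired-end structure, optical artifacts,
and over/under-segmentation of foci — bounds what passing tests show:
they certify the computations (exact counting, matching, statistics) on
their own terms, not robustness to real-data noise sources upstream of
them.

## Problem sizes and numerical choices

Simulation-based checks use 50 000-read samples for ratio recovery, 10
cohort seeds for candidate nomination, 100 seeds for the stochastic
planting band (3 binomial SEs, ≥95% coverage), and 1000 null replicates
for type-I-error calibration of the rank-sum test — sizes at which the
binomial error bars are decisive while the whole suite runs in about a
minute. Exact Wilcoxon enumeration is cross-checked against an
independent exact implementation everywhere ties are absent and against
symmetry identities where they are not. Floating-point comparisons in
the exact branch use a 10⁻⁹ rank-sum tolerance; JSON reports are written
with sorted keys and no timestamps so identical seeds give byte-identical
files.

## Known limitations

- Exact substring search only: a single sequencing error in the 36-mer
  drops a true telomeric read, so absolute ratios underestimate repeat
  content at realistic error rates; the screen's ranking is robust to
  this because the loss applies cohort-wide.
- No telomere-length estimation from read content (no length
  calibration a la TelSeq) and no absolute length in kb.
- Mutual-NN matching is a centroid-distance criterion; overlap-area or
  intensity-based colocalization coefficients are out of scope.
- The cohort aggregation assumes replicates are exchangeable; no
  batch/lab covariates are modeled.
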