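# teloscreen

Telomere-associated proteins (TAPs) can be nominated directly from
ChIP-seq read sets, without peak calling: a protein that binds telomeric
chromatin drags telomeric-repeat fragments into its immunoprecipitated
library, so the fraction of reads containing the exact human telomeric
motif — six tandem copies of TTAGGG, a 36-mer, searched with no
mismatches on both strands — is a per-dataset binding-intensity
statistic. Ranking a cohort of datasets by this **repeat-read ratio**

    ratio = (# reads containing (TTAGGG)6 exactly) / (# total reads)

and flagging targets above the Tukey upper fence (Q3 + 1.5·IQR) of the
cohort's score distribution yields candidate TAPs. `teloscreen`
implements that screen plus the downstream statistics such a study uses:

- **qPCR relative telomere length**: T/S = 2^−ΔCt with
  ΔCt = Ct(telomere) − Ct(albumin), and group comparisons by the
  Wilcoxon rank-sum test (exact by enumeration at small n, normal
  approximation with tie/continuity correction otherwise), Welch's t
  test, and one-way ANOVA.
- **Focus colocalization** from per-nucleus coordinate tables:
  one-to-one mutual-nearest-neighbor matching within a distance
  threshold, cofocus histograms, TIF/APB-style ratios (matched foci per
  telomere focus), and 2×2 chi-squared comparisons of positive-nucleus
  fractions.
- A **synthetic-data generator** that produces FASTQ read sets with an
  exactly known planted motif fraction (backgrounds are
  rejection-sampled to be motif-free on both strands), cohort manifests
  with a true-ratio sidecar, Ct tables with known group effects, and
  foci tables with a planted colocalized fraction — so every stage is
  testable against exact ground truth.

It is intended for people analyzing repeat-element enrichment in
short-read cohorts (e.g. public ENCODE ChIP-seq) and for teaching or
validating telomere-biology analysis pipelines at desk scale.

## Worked example

The numbered scripts under `analysis/` run the whole study shape on
synthetic data (large intermediates go to `scratch/`, tables to
`results/`):

```sh
python analysis/01_simulate_inputs.py --seed 0
python analysis/02_screen_and_rank.py
python analysis/03_telomere_length.py
python analysis/04_foci_colocalization.py
```

which prints (seed 0):

```
cohort: 60 samples -> .../scratch/analysis/cohort
  planted candidate TAP1 at ratio 0.02 vs background 0.002
...
screened 60 samples across 20 targets
cohort score distribution: median 0.002, IQR [0.002, 0.002], upper fence 0.002
top candidate: TAP1 (score 0.02, rank 1, outlier=True)
outlier calls: ['TAP1']
mean T/S: KO 1.998, WT 0.979 (fold change 2.04, simulated truth 2.0)
one-sided Wilcoxon (KO > WT): U=400, p=3.4e-08 (normal_approx)
WT: mean TIF ratio 0.200, 0/30 nuclei with >3 cofoci, ...
KO: mean TIF ratio 0.403, 30/30 nuclei with >3 cofoci, ...
Welch t (WT vs KO ratios): t=-61.00, p=3.55e-32
chi-squared on positive fractions: chi2=60.00, p=9.49e-15
```

Reading it: the one target planted at a 10× elevated repeat-read ratio
is recovered at rank 1 and called an outlier; the knockout arm's mean
T/S comes back at 2.04× wildtype against a simulated truth of 2 (one
cycle earlier telomere amplification), significant one-sided; and the
arm with a doubled planted colocalized fraction shows exactly the
doubled mean TIF ratio.

The same stages are available as one CLI
(`teloscreen simulate|screen|rank|lengths|foci|demo`), e.g.

```sh
teloscreen demo --seed 0 --out-dir demo_out   # full pipeline, one JSON report
teloscreen screen --manifest cohort/manifest.tsv --qc-preset desk --out screen.tsv
```

Real data drop in the same way: `screen` accepts FASTQ(.gz) or SAM/BAM
(where the denominator becomes mapped primary reads), and the
`encode-k562` QC preset enforces the cohort gate of ≥ 20 M reads with
read length ≥ 37 bp.

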