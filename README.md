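# profcorr

Do differentially expressed mRNAs track their protein products better than
mRNAs that are not differentially expressed?

Bulk mRNA–protein correlations are notoriously weak (r ≈ 0.1–0.4 across
most studies), yet differential-expression analysis of mRNA is used
everywhere on the implicit assumption that transcript changes translate
into protein changes. `profcorr` implements a per-gene, per-condition test
of that assumption for replicate-level two-layer time-course experiments —
the motivating design being an ovarian-cancer xenograft study with 29
genes measured on both layers across 5 harvest days in 4 conditions (two
tumour models × two drug regimes: platinum monotherapy vs platinum +
taxane), with pooled untreated controls per tumour model.

## The analysis

For each gene *g* and condition *c*, the *profile* is the time-ordered
vector of log₂ fold-changes vs pooled controls,
FC(g,c) = (x₁,…,x_T), T = 5 by default. The pipeline computes:

1. **Fold-changes and DE flags.** log FC = mean(treated replicates) −
   mean(pooled controls), with a pooled-variance t-statistic per contrast.
   Gene-wise variances are moderated by empirical-Bayes shrinkage toward a
   common prior (prior d.f. fitted by a method-of-moments fit on log s²),
   p-values are BH-adjusted across genes within each (condition, time)
   contrast, and a profile is flagged DE iff any time point has adjusted
   p < 0.05.
2. **Profile correlations.** Pearson r between the mRNA and protein
   fold-change profiles of each (gene, condition); with a complete
   29 × 4 design that is 116 correlations.
3. **The shift test.** Two-sample Kolmogorov–Smirnov and Wilcoxon
   rank-sum comparisons of DE vs non-DE correlation distributions
   (one-sided Wilcoxon: DE stochastically greater).
4. **A variance-matched null.** All genes share one linear relationship
   y = m·x + b + e, e ~ N(0, σ_e), fitted by OLS on all fold-change
   pairs; mRNA profiles are drawn from high- or low-variance normals
   matched to the DE / non-DE groups. 100,000 simulated comparisons give
   empirical p-values for the observed KS and Wilcoxon statistics — the
   control for "DE profiles correlate better merely because they have a
   larger dynamic range".
5. **A profile-shuffling null.** The mRNA→protein pairing is permuted
   across profiles (time order preserved) 1,000 times; the actual
   correlation distribution of a group is compared to the pooled shuffled
   one.
6. **FDR-cutoff sweep.** The shift test is repeated at FDR cutoffs
   0.01–0.50 (step 0.01) and each comparison p-value is regressed on the
   cutoff: a robust effect shows p rising with the cutoff.

A seeded synthetic-data generator reproduces the experiment's shape with
a tunable coupling between DE status and mRNA–protein profile correlation,
so every stage is testable against ground truth.

## Worked example

```bash
profcorr run-all --synthetic --seed 1 --reps-simple 100000 --reps-shuffle 1000 \
    --out-dir out/
```

prints

```
116 profile correlations, 51 DE; KS p=9.447e-16, Wilcoxon p=1.234e-15; summary in out/summary.json
```

On this synthetic experiment (coupling 0.8 between responsive genes' mRNA
and protein trajectories) 51 of the 116 profiles are flagged DE at
FDR < 0.05, and their correlations are decisively shifted above the
non-DE group (median r 0.81 vs −0.01) — the KS and Wilcoxon p-values are
essentially zero. `out/summary.json` additionally records the
variance-matched null (empirical p ≈ 2·10⁻⁴ and 2·10⁻⁵ at 100,000
repetitions: the shift is not a dynamic-range artifact), the shuffling
nulls (DE group far above its shuffled null, non-DE group
indistinguishable from its own, p ≈ 0.87 / 0.51), the genome-wide
correlations at three aggregation scales, and the 50-point FDR sweep with
positive p-vs-cutoff regression slopes (t with 48 d.f.).

The same pipeline runs on real data via `--mrna/--protein/--meta`
(delimited expression matrices plus a sample sheet; optional
`--probe-map` collapses array probes to genes by highest mean
expression). Library use:

```python
from profcorr import PipelineConfig, SimulationConfig, run_pipeline
summary = run_pipeline(PipelineConfig(simulation=SimulationConfig(), seed=1))
```

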