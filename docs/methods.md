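# Methods

## Design and data model

The pipeline targets experiments in which both mRNA and protein abundance
are measured for the same genes, in biological replicate, across an
ordered time course nested inside experimental conditions, with untreated
controls. Expression is analysed on the log₂ scale (normalized array
intensities for mRNA; log₂-transformed quantitative-immunofluorescence
scores for protein). Controls are *pooled per tumour model across harvest
days* and serve as the common baseline for every fold-change in that
model; no per-day control matching is attempted, since treated harvest
days (1, 2, 4, 7, 14) and control days (0, 1, 2, 7, 14) do not coincide.

Missing measurements are explicit (NaN), never silent. Downstream profile
correlations require complete T-vectors on both layers; incomplete or
constant profiles are dropped with a logged warning rather than imputed.
When multiple array probes map to one gene, the probe with the highest
mean expression over all its measurements is kept; ties break to the
lexicographically smallest probe id so the operation is deterministic.

## Differential expression

For gene g in contrast (condition, time): log FC = x̄₁ − x̄₀ with a
pooled-variance two-sample t-statistic (the common-variance-per-gene
model). With `moderation="empirical_bayes"` the gene-wise pooled
variances s²_g (df d_g) within a contrast are shrunk toward a prior:

    s̃²_g = (d₀ s₀² + d_g s²_g) / (d₀ + d_g),   t_g = logFC_g / (s̃_g √(1/n₁+1/n₀)),

with t_g referred to a t distribution on d₀ + d_g degrees of freedom.
The hyperparameters (d₀, s₀²) are fitted by the method of moments on
z = log s²: the mean and variance of z, corrected by digamma/trigamma
terms for the chi-square sampling distribution of each s², identify s₀²
and d₀ (d₀ via trigamma inversion by Newton iteration). If the excess
variance of z is non-positive, d₀ = ∞ and all variances collapse to s₀².
Genes with zero sample variance are excluded from the hyperparameter fit
but still squeezed, which floors their variance at a positive value; a
zero-residual-variance gene with a nonzero fold-change under
`moderation="none"` gets p = 0, matching the unmoderated t-test limit.
`moderation="none"` reproduces the textbook pooled t-test exactly and is
the oracle path in tests.

BH adjustment is applied across genes within each (condition, time)
contrast — the per-contrast convention of standard DE tooling. A
(gene, condition) profile is flagged DE iff min over its time points of
the adjusted p-value is below the cutoff (default 0.05). Protein
fold-changes are computed identically but protein p-values are never used
for flagging.

## Shift tests

The DE and non-DE profile-correlation samples are compared with a
two-sample Kolmogorov–Smirnov test (two-sided by default) and a Wilcoxon
rank-sum test (one-sided by default, alternative "DE greater", since the
scientific question is a shift toward higher correlations; both
sidednesses are configurable). Exact small-sample p-values are used when
the samples are small and untied, otherwise the asymptotic forms with
continuity correction — the switch is delegated to scipy. The stored
Wilcoxon statistic is the Mann–Whitney U of the DE (first) group, and the
same convention is used on both sides of every empirical-null comparison
so "null ≥ observed" is well defined.

## Variance-matched simple model

All profiles share one linear mRNA→protein correspondence y = m·x + b + e
with e ~ N(0, σ_e); (m, b) is the OLS fit of protein on mRNA fold-change
over all matched measurements and σ_e is the residual standard error of
that fit (ddof = 2; the residual sd of the regression). mRNA profiles are
drawn T at a time from N(μ_high, σ_high) for the DE-matched group
(n_high profiles) and N(μ_low, σ_low) for the non-DE-matched group
(n_low), each profile correlated with its model-generated protein
profile, and the two correlation samples compared by KS and rank-sum.
The observed statistics' empirical p-values are count(null ≥ observed)/N
over N = 100,000 repetitions by default — deliberately without +1
smoothing, so a value of exactly 0 is possible; a `plus_one` option
provides (k+1)/(N+1) when a nonzero bound is wanted. The repetitions are
vectorised (one argsort per repetition row yields both the tie-aware KS D
and the midrank U), so the full 100,000 run takes seconds. In the
noise-free limit σ_e = 0 every simulated correlation equals sign(m)
exactly (computed symbolically, not numerically).

## Profile shuffling

A shuffle reassigns entire mRNA profiles to protein profiles by a uniform
random permutation, preserving time order within each profile. Fixed
points are allowed: excluding them (derangements) would bias the null.
By default the permutation runs across the whole selected group,
including across conditions — profiles are (gene, condition) units; a
`within_condition` option restricts it. Each of the 1,000 shuffles
recomputes all group correlations; the pooled shuffled sample is compared
to the actual one with asymptotic KS/rank-sum tests (the pooled sample is
far too large for exact enumeration, and its members are not independent
across shuffles — the tests are used descriptively, as an empirical-null
comparison).

## FDR-cutoff sweep

DE flags are recomputed at cutoffs 0.01–0.50 in steps of 0.01 (profile
correlations are cutoff-independent and computed once), the shift tests
rerun per cutoff, and each p-value regressed on the cutoff by OLS
(slope, slope t-statistic, residual df = non-missing rows − 2, two-sided
p). Cutoffs with an empty group yield missing p-values; cutoffs with
fewer than ten DE profiles are kept but marked `small_de`, since those
comparisons are underpowered — the default regression includes them, and
`exclude_small_de` drops them.

## Synthetic generator

The generator emulates the experiment's shape: 29 genes, 4 conditions
(2 tumour models × 2 regimes), treated days (1, 2, 4, 7, 14), 3 treated
replicates per group (protein replicates overridable), 4 pooled controls
per tumour model per layer. A fraction of genes (default 0.4) is
*responsive*: their mRNA carries a latent treatment trajectory — a
smoothed standardized random curve (iid normals convolved with a
[1, 2, 1]/4 kernel, then standardized over the T points) scaled by
`effect_sd` — and their protein trajectory is ρ·z_mRNA + √(1−ρ²)·z_indep
scaled the same way, so the expected trajectory correlation is the
coupling ρ (default 0.8). Non-responsive genes have flat mRNA
trajectories and an independent protein drift of amplitude
`decoupled_noise_sd`. Every replicate value is baseline + latent + N(0,
`replicate_sd`); controls share the baseline only. Defaults
(`effect_sd` 0.6, `replicate_sd` 0.25, `decoupled_noise_sd` 0.3) keep
realised log fold-changes mostly within [−1, 1], the dynamic range
typical of this design. Trajectories are smoothed random curves, not
pharmacodynamic forms, because only the correlation structure matters to
the analyses; the generator does not attempt probe effects, imaging
artifacts, tumour growth dynamics, replicate-count imbalance beyond the
per-layer override, or time-delayed mRNA→protein coupling — so passing
tests demonstrate the statistical machinery, not biological realism.

All randomness flows from named substreams (`generator`, `simple_model`,
`shuffle_de`, `shuffle_nonde`) spawned from one master seed, so changing
one stage's repetition count never perturbs another's draws, and a full
pipeline run is byte-reproducible given its seed.

## Problem sizes and calibration checks

The test suite validates calibration at the design's own scale: 200
global-null datasets for the shift-test rejection rate (checked against
the exact binomial 95% interval at nominal 0.05, with a liberal flagging
cutoff of 0.5 so both groups stay populated — under the null the flags
are independent of the correlations, so the level is unaffected), 100
null datasets for uniformity of the shuffling-null p-values, 100 coupled
datasets (ρ = 0.9, `effect_sd` 1.0) for power and directionality, and
80 seeds × 400 repetitions for uniformity of the equal-variance
simple-model p-values. Oracle tests compare BH, Pearson, OLS and the
exact small-sample KS/rank-sum p-values to brute-force enumeration at
1e-10.

## Known limitations

- The moderated t approximates, but does not numerically replicate, the
  reference empirical-Bayes DE implementations; `moderation="none"` is
  exact against the textbook t-test.
- The shuffling-null tests treat the pooled shuffled correlations as a
  reference sample; their internal dependence makes the reported
  p-values approximate (empirically near-uniform under the null).
- Genome-wide correlations at the condition- and gene-mean scales are
  weak for the generator's default trajectories (mean-zero latent
  curves), which is faithful to fold-change space but means those two
  aggregation scales carry little signal in synthetic data.
- Empirical p-values without smoothing can be exactly 0; use `plus_one`
  where a conservative bound is needed.
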