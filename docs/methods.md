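# Methods

## Scope and data model

`devclock` operates on processed methylation matrices: probes × samples
beta values in [0, 1], optionally accompanied by methylated/unmethylated
intensity matrices and per-cell detection p-values. IDAT parsing and
control-probe diagnostics are deliberately out of scope — the toolkit
starts where array exports end. All tabular formats are delimited text;
clock coefficient sets are two-column `term, coefficient` tables with an
`(Intercept)` row and `#key=value` metadata lines, so published
supplementary coefficient tables drop in after trivial reshaping.

## Quality control

Detection-p filtering uses the two-pass rule with **strict** inequalities:
a sample is excluded iff strictly more than 1% of its probes have
detection p > 0.05; afterwards a probe is excluded iff strictly more than
1% of the *retained* samples fail it. Samples are filtered before probe
statistics so a single bad array cannot drag probes out with it; the
order is configurable (`order="probes_first"`). The rule is idempotent on
its own output except for pathological fixtures sitting exactly on the 1%
boundary, where removing a probe changes the denominator of a sample's
failure fraction.

Blacklist exclusion (SNP-affected and cross-hybridizing probes) is driven
entirely by a user-supplied annotation: the toolkit ships no probe list
of its own. Probes missing from the annotation are retained with a
counted warning rather than dropped — absence of evidence is not treated
as a flag.

An optional median-intensity floor for excluding low-signal samples
exists but is off by default; no principled universal threshold exists,
so it is a knob, not a policy.

## Normalization

The intensity-level normalization follows the probe-type-aware
quantile scheme used for Illumina arrays:

1. **Background equalization.** Type I and Type II chemistries have
   different background levels. Per sample, Type II methylated and
   unmethylated intensities are shifted by the offset that equates their
   5th-percentile (configurable) with Type I's. The per-sample offsets
   are smoothed by a linear fit against sample index before being
   applied; the exact smoothing used by the reference R implementation
   is under-documented, so the simplest reproducible choice (straight
   line over the sample sequence, configurable off) is used. Negative
   intensities created by the shift are clamped to zero and counted.
2. **Quantile normalization.** Methylated and unmethylated intensities
   are quantile-normalized *between samples*, separately within Type I
   and Type II probes — four independent normalizations. Each sets every
   sample's sorted values to the across-sample mean of order statistics;
   ties take the average rank, interpolated in the reference
   distribution. This makes within-probe-type value multisets identical
   across samples (to numerical precision) while preserving each
   sample's ranking.
3. **Betas.** beta = M / (M + U + 100). The offset of 100 is the
   conventional intensity stabilizer and is configurable.

A beta-level fallback (`beta_quantile_normalize`) applies step 2 directly
to betas for public datasets distributed without raw intensities.

## Age harmonization

All ages are expressed in days post-conception (dpc): `dpc` unchanged,
`weeks_pc × 7`, `years × 365 + 280` (birth = 280 dpc, so prenatal ages in
years are negative). One published description of the weeks conversion
says "dividing by 7", which is dimensionally inconsistent — 14 gestational
weeks would map to 2 dpc; multiplication reproduces the stated dataset
age ranges and is the default, while `weeks_rule="literal_divide"`
reproduces the literal wording for audit. Developmental stages partition
(0, ∞): embryonic < 63 dpc ≤ fetal < 280 dpc ≤ postnatal.

The log-linear output transform used by multi-tissue clocks is inverted
as: score < 0 → (1 + A)·exp(score) − 1, else (1 + A)·score + A, with
adult age A = 20 years by default (configurable). It is continuous and
strictly increasing, equals A at score 0, and tends to −1 year (i.e.
conception) as the score → −∞.

## Clock training

The elastic net minimizes

    (1/2n)·Σ(y − β₀ − Xβ)² + λ[α·Σ|βⱼ| + (1−α)/2·Σβⱼ²]

* α = 0.5 by default (equal ridge/lasso mixing, the convention for
  methylation clocks).
* Predictors are standardized internally (population SD) and
  coefficients back-transformed to the beta scale; `standardize=False`
  is available and used by the closed-form checks.
* The λ path has 100 log-spaced values from λ_max — the smallest λ at
  which every coefficient is zero, max|xⱼᵀ(y−ȳ)|/(n·α) — down to
  λ_max·10⁻⁴, or λ_max·10⁻² when probes outnumber samples (the usual
  path convention in that regime, where the deep tail only buys
  overfitting and solve time).
* Cross-validation: samples are shuffled under the seed and dealt
  round-robin into k = 10 folds (balanced, deterministic). λ is the
  CV-MSE minimizer by default; the one-standard-error rule
  (`lambda_rule="one_se"`) selects the sparsest model within one SE and
  is exposed because published clocks do not always state which rule
  produced their λ.
* Ages are regressed untransformed, in dpc. No response transform is
  applied at training time; log-linear transforms only matter when
  *applying* clocks published on that scale.
* The over-shrunk limit (λ ≥ λ_max) yields the intercept-only model with
  intercept exactly the mean training age; it is representable (and
  flagged) but refuses to serialize or predict.

Optimality of any returned solution can be verified independently of the
solver through `kkt_max_violation`, which evaluates the subgradient
stationarity conditions of the objective directly: on the active set the
penalized gradient must equal λα·sign(βⱼ); on the zero set its magnitude
must not exceed λα; the residual mean must be zero. The test suite holds
solutions to a 10⁻⁴ tolerance.

## Clock application

Prediction is the linear predictor over the clock's probes, then the
clock's output transform, then unit conversion to dpc. Missing-probe
policy is explicit — `fail` (default), `mean_impute` (0.5 or a supplied
reference mean), or `drop` — because cross-platform probe loss (450K vs
EPIC) silently changes the estimand; probe coverage is always reported
and low coverage (< 0.8 by default) is flagged. Predictions outside the
clock's training age range are **flagged, not clipped**: saturation
beyond the training window is itself a diagnostic of clock/tissue/age
mismatch and clipping would hide it.

## Evaluation

Accuracy is Pearson's r (n−1 covariance convention) and RMSE (plain
mean, no degrees-of-freedom correction), both in dpc. A range-restricted
variant confines scoring to samples whose true age lies within the
training window, separating in-range error from extrapolation failure.
The sex sensitivity analysis fits OLS of predicted age on age, sex and
their interaction (female reference, configurable) and reports the Wald
t-test on the interaction; an exclusion list supports the standard
refit without the most extreme predicted ages. Plain OLS standard errors
are used; no robust correction is applied.

## Cell-stage comparisons

Within one dataset, two stages are compared by a two-sample t-test —
Welch by default, since that is the common default of the statistical
environments these analyses are run in and group variances of predicted
ages genuinely differ; the pooled-variance Student test is a flag away.
Three stages use one-way ANOVA followed by Tukey HSD with Tukey–Kramer
standard errors for unbalanced groups; adjusted p-values come from the
studentized-range distribution.

Across datasets, a linear mixed model pools all samples: fixed dummies
for NPC-vs-iPSC and neuron-vs-iPSC and a random intercept per dataset,
fitted by REML. Fixed effects are tested with Wald z statistics; no
small-sample degrees-of-freedom correction (e.g. Satterthwaite) is
applied, which can make small-panel p-values slightly anti-conservative —
a documented limitation. A single-dataset table degenerates to OLS with
a warning; non-convergence is flagged and such fits should not be read
as primary.

## Synthetic data

The generator exists so the whole chain is testable offline, and its
defaults *are* the study conditions the rest of the package assumes:

* **Age-structured datasets**: ages uniform on 37–185 dpc (a fetal
  training window, so extrapolation tests can deliberately exceed it);
  50 of 2000 probes age-associated by default. Age effects live on the
  logit scale — logit(mean beta) = aⱼ + sⱼ·(age − mean age) with
  aⱼ ~ U(logit 0.2, logit 0.8), |sⱼ| ~ U(0.5, 1.5)·0.002 per dpc with
  random sign — so betas respect (0, 1) without clipping. Measurement
  noise is Gaussian on the logit scale, SD 0.02 by default. Intensities
  are constructed to invert exactly: U = (1 − beta)·T for lognormal
  per-sample depth T and M solves beta = M/(M + U + 100), so recomputed
  betas match stored ones to machine precision. Detection p-values are
  U(0, 0.01) with a configurable failure rate replaced by U(0.05, 1).
  Sample-level and probe-level draws use separate seeds so probe truth
  can be held fixed across replicates. Optional per-dataset platform
  masks blank probe subsets to emulate 450K/EPIC intersections.
* **Cell-stage panels**: predicted age = stage mean + dataset intercept
  (Normal, SD 5 dpc) + residual (Normal, SD 7 dpc). Default stage means
  are the observed cellular values (iPSC 75.6, NPC 79.1, neuron
  83.2 dpc) and the default five-dataset availability reproduces the
  pooled design of 30 iPSC / 4 NPC / 48 neuron samples, including
  datasets that lack a stage — exactly the generative model the
  random-intercept meta-analysis assumes.

What the generator does **not** emulate: array chemistry (dye bias, bead
counts), genetic mQTL structure, batch effects, cell-composition
heterogeneity, or spatially correlated probes. Passing tests therefore
demonstrate correctness of the algorithms under their stated model, not
robustness to every artifact of real arrays.

## Numerical choices

* Quantile-normalization ties: average rank with linear interpolation in
  the reference distribution (deterministic).
* Stratified split: per dataset, train count = floor(f·n) plus one when
  the fractional part ≥ 0.5 (round-half-up); singleton strata go to
  train with a warning.
* Coordinate-descent tolerance 1e-8 (scikit-learn dual-gap criterion),
  max 100 000 iterations; warm starts along the λ path. Coefficient
  counts along the path may wobble by a probe or two against strict
  monotonicity — a documented warm-start artifact.
* Degenerate inputs have defined behaviour rather than NaNs: zero
  variance in both t-test groups with equal means gives p = 1 with a
  flag; an all-constant ANOVA gives F = 0 and adjusted p = 1; zero
  variance in either accuracy vector reports r as missing with a
  reason.
* All randomness flows from explicit integer seeds; the pipeline
  expands one top-level seed into recorded per-step seeds, and reruns
  are byte-identical.

## Problem sizes used in the shipped checks

The test suite and the acceptance script use a 200-sample × 2000-probe
simulated design (50 causal probes, logit noise 0.02) for clock
training, 500 replicates for the null calibration of the sex-interaction
test, and 100 replicates of the five-dataset panel for the mixed-model
recovery check. These sizes give stable Monte-Carlo estimates for every
assertion while keeping a full run in the minutes range on one core.
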