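# Methods

`epimetab` implements a two-stage modelling strategy for metabolic ageing:
methylation surrogates for circulating metabolites, and an ageing clock built
from those surrogates.  This note documents the statistical procedures, the
synthetic data-generating model they are tested against, the numerical
choices, and the limitations of both.

## 1. The surrogate model

For each metabolite *m* with standardised level $y_m$ and standardised CpG
M-values $x_1,\dots,x_p$ (where $M = \log_2 \beta/(1-\beta)$), the surrogate
is a sparse linear predictor

$$\hat y_m = \hat\beta_0 + \sum_{j \in S_m} \hat\beta_j x_j$$

obtained in two steps on the training partition of a 4:1 train/test split:

1. **Marginal screen.** Each probe is regressed on the metabolite alone; the
   top 1% of probes by two-sided p-value of the slope (`top_fraction`,
   default 0.01, count = ⌈fraction · p⌉) proceed.  Ties in p are broken by
   |slope| then probe id for determinism.  Zero-variance probes are assigned
   p = 1 and never ranked.  The screen is unadjusted by default; a covariate
   hook exists (`ewas_screen` accepts pre-residualised inputs).
2. **Lasso.** L1-penalised regression on the screened probes.  The penalty
   λ is chosen by tenfold cross-validation at the minimum mean CV squared
   error; the one-standard-error rule is available via `rule="1se"`.  CV
   fold assignment is seeded; the per-metabolite seed is forked from the run
   seed.

Two filters follow:

* **Bimodality.** Surrogate predictions over the full cohort are tested with
  Hartigan's dip statistic (implemented in `epimetab._dip`; p-values by
  seeded Monte Carlo against the uniform null, the least-favourable unimodal
  distribution) together with a kernel-density mode count.  A surrogate is
  flagged when dip p < 0.05 **and** the KDE shows ≥ 2 modes.  A multimodal
  surrogate is the signature of a polymorphism driving the selected CpGs
  (methylation clusters at genotype classes) rather than metabolite biology.
  The conjunctive rule replaces subjective visual inspection with a
  reproducible criterion; the dip implementation is validated in the test
  suite against an exact linear-programming oracle that minimises the
  sup-norm distance to the unimodal CDF class directly.
* **Held-out correlation.** Pearson r between surrogate predictions and the
  measured metabolite in the test partition, Bonferroni-corrected over the
  number of surviving (non-bimodal) surrogates; the denominator is exposed
  as a parameter because the correction family is a design choice.  Kept
  surrogates require adjusted p < 0.05.  A kept surrogate with r < 0 is
  allowed but flagged.  `min_significant_r(n, alpha)` gives the analytic
  threshold: the smallest rounded r with
  $t = r\sqrt{n-2}/\sqrt{1-r^2}$ exceeding the two-sided α quantile — at
  n = 164 and α = 1e-4 this is r = 0.30.

## 2. Preprocessing

* Probes with missing fraction strictly > 1% are removed; the rest are
  completed by k-nearest-neighbour imputation (k = 10, neighbours among
  probes, the convention of expression-array kNN imputation; orientation
  configurable).
* β-values are transformed to M-values; values at exactly 0/1 are clamped to
  [ε, 1−ε] (ε = 1e-6) with a warning, or rejected in strict mode.
* Metabolites with > 20% missing-or-zero values, drug-linked metabolites,
  and the weaker member (larger sex-adjusted age-association p) of each
  cross-platform duplicate pair are removed, in that order; then samples
  with > 5% missing metabolites.
* NMR metabolites are treated as left-censored at the detection limit:
  missing values are drawn from the low tail of a per-feature normal model
  whose mean/SD are recovered by regressing the observed order statistics on
  their theoretical normal quantiles, with the censored mass occupying the
  lowest ranks (fitted on the log scale for raw abundances).  All draws fall
  below the feature's observed minimum.  Features with < 10 observed values
  fall back to half-minimum substitution with a warning.  MS metabolites are
  missing at random and are kNN-imputed.
* Metabolites are natural-log transformed, mean-centred and unit-scaled.
  **All scaling statistics (M-values and metabolites) are fitted on the
  training partition only and frozen** (`Scaler`), so test-partition
  information never leaks into training-scale decisions.

## 3. Clocks, transfer and age acceleration

A clock is an elastic-net regression of chronological age (in years, not
standardised) on one of three feature spaces: surrogate predictions,
measured metabolites, or CpG M-values.  The L1 mixing weight α is tuned over
{0.1, 0.25, 0.5, 0.75, 0.9, 1.0} jointly with the penalty path by tenfold
CV minimum mean squared error.  Elastic net (rather than pure lasso) is the
default because the feature count is comparable to the sample count in the
intended use, where correlated features make pure L1 selection unstable.

The trained clock stores the **training median of every feature** and
carries them in its file format.  When the clock is transferred to an
external matrix, absent features (or missing entries) are filled with those
training medians — never recomputed from the target cohort — with an error
below 50% feature coverage and a warning below 90%.  In-sample,
`predict_age` reproduces the fitted values exactly.

Age acceleration is the residual from OLS of clock-predicted age on
chronological age, scaled to unit variance.  The scaling is cohort-specific
(recomputed wherever the clock is applied).  By OLS orthogonality the
residual is uncorrelated with chronological age to machine precision, which
is asserted as an invariant.

## 4. Association battery

* **Per-feature age associations** (`mlm_age`): each standardised feature on
  age + sex by closed-form multi-response OLS; effects in feature SD per
  year; Bonferroni over features.
* **Risk factors** (`risk_factor_assoc`): scaled acceleration on a
  dummy-coded factor (reference = first level, explicit in the result) plus
  age, sex, ethnicity; BMI/smoking enter as an optional sensitivity set.
  Effects are in SD units of acceleration with 95% CI.
* **Outcomes** (`outcome_assoc`): Cox proportional hazards for time-to-event
  (lifelines, Efron tie handling), logistic for binary (GLM-IRLS, robust to
  quasi-separated covariate dummies), OLS for continuous, and NB2 negative
  binomial (variance μ + αμ²; dispersion by ML) for overdispersed counts —
  NB2 nests Poisson, which the tests exploit as a limit check.  The family
  is caller-specified per outcome, not auto-detected.  The exposure is
  standardised so effects are per SD.
* **Enrichment** (`enrich`): one-sided Fisher's exact test of the clock's
  top-k CpGs (k = 5,000 by |composite coefficient|, chaining clock weights
  through surrogate coefficients) against a user-supplied local probe→trait
  table, Benjamini–Hochberg FDR across traits.  A probability-weighted
  variant can be plugged in; the offline default is the plain exact test.

## 5. The synthetic cohort generator

`simdata.generate_cohort` emulates the joint structure the pipeline assumes;
it is the test bed, not a model of any particular population.

* **Methylation** is generated on the logit scale and inverse-transformed,
  guaranteeing β ∈ (0,1) with no clipping and making the M-transform exact.
  Per-probe baselines ~ N(0, 1.5²) logit units; measurement noise 0.3 logit
  units (defaults).
* **Ageing.** Ages are uniform on 21–65 y.  A latent per-sample ageing
  deviation (`accel_true`, unit SD, 3 y per SD) defines biological age =
  age + deviation; a configurable subset of probes drifts linearly in
  biological age with per-year slopes ~ N(0, age_effect_sd), default
  0.02 logit/y.  Categorical risk factors (alcohol, smoking, BMI class, at
  frequencies typical of a working-age occupational cohort) can shift the
  latent deviation (`risk_effects`), planting recoverable effects.
* **Metabolites.** Each metabolite is a weighted sum of a small CpG support
  (weights sign·U(0.5, 1.5) before unit-SD normalisation — magnitudes are
  bounded away from zero because a planted support member with ~0 weight is
  unrecoverable in principle) plus independent Gaussian noise, exponentiated
  to a lognormal abundance.  Supports are drawn from the age-drifting probes
  by default (so metabolites carry age signal, the premise of the hybrid
  clock); `support_from_age_probes=False` draws them from age-independent
  probes, the identifiable design used for support-recovery checks.
* **SNP probes** cluster at β ≈ 0.05/0.5/0.95 by Hardy–Weinberg genotype
  frequencies — the multimodal pattern the bimodality filter exists for.
* **Missingness.** NMR metabolites are left-censored below a per-feature
  quantile; MS metabolites are MCAR; probes get MCAR background missingness
  plus an optional high-missingness block for the probe filter.
* **Outcomes.** Survival times are exponential with hazard
  base·exp(loghr_age·(age−mid) + loghr_accel·accel), administratively
  censored at 15 y; binary (diabetes/CVD/disability), continuous
  (frailty/gait/grip) and gamma-Poisson count outcomes all load on age and
  on the same latent deviation, giving the association suite one known
  positive-control direction.

What the generator does **not** emulate: array chemistry and batch effects,
LD structure (SNP probes are independent), nonlinear age trajectories,
metabolite-metabolite correlation beyond shared CpG supports, and
covariate missingness.  Passing recovery tests therefore demonstrate
correctness of the estimators under the stated generative assumptions, not
performance on real cohort data.

## 6. Problem sizes and numerical choices

Simulation-based checks run at desk scale, chosen so each check exercises
the contract it targets: support recovery at n = 400, p = 2,000 over 20
seeds; clock recovery and permutation nulls at n = 500, p = 1,000 (100 age
probes, per-year effect SD 0.06 against probe noise 0.25, i.e. per-probe
signal-to-noise around 2) over 20 seeds; risk-factor coverage at n = 500
over 50 seeds; the acceleration→outcome type-I chain at n = 200 over 500
simulations; dip-test calibration and power at n = 500 over 100 seeds with
1,000 Monte Carlo null draws (cached per sample size).  Full array scale
(~834k probes) is exercised only where it is cheap and meaningful — the
probe-filter count arithmetic.

Other numerics: lasso/elastic-net paths use 100 automatic penalties with up
to 5·10⁴ coordinate-descent iterations; CV folds are seeded `KFold`
shuffles; the dip statistic returns 1/(2n) for degenerate ≤3-point samples
and 0 for constant input; KDE mode counting uses a Gaussian KDE on a
512-point grid with a 10% relative peak-height floor; file round-trips write
floats at 17 significant digits so clock coefficients survive exactly.

## 7. Known limitations

* The dip-test p-value is Monte Carlo (resolution 1/(B+1)); with B = 1,000
  the 0.05 decision is stable but p-values near the threshold carry ~0.007
  simulation error.
* The uniform null makes the dip test conservative for unimodal
  distributions with light tails (false-flag rates well under the nominal
  level) — acceptable here because the filter's cost asymmetry favours
  keeping surrogates.
* The censored-imputation tail model assumes (log-)normal features; heavy
  tails below the detection limit would bias imputed values upward.
* Cox, logistic and NB fits assume proportional hazards / linearity in the
  standardised exposure; no diagnostics are automated.
* The cross-platform duplicate rule needs a pre-supplied pair map; no name
  matching is attempted.
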