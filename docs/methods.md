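# Methods

## The statistical problem

Published feeding trials report group-level treatment means of potassium
excretion together with intake and production variables. Pooling such means
across publications has two structural features a plain regression ignores:
means from the same study share laboratory, herd and management conditions
(a study-level random effect), and means averaged over more animals are
more precise (heteroscedasticity known up to a constant). `kexmeta` models
both directly.

## Model

For treatment mean *j* of study *i*,

    y_ij = b0 + b1 * x_ij + s_i + e_ij
    s_i  ~ N(0, tau^2)
    e_ij ~ N(0, sigma^2 / w_ij)

with one candidate predictor per model (candidates: DMI kg/d, K intake g/d,
dietary K % of DM, water intake kg/d, urine volume kg/d, milk yield kg/d;
responses: urinary or fecal K excretion g/d). The weight `w_ij` is the
number of animals contributing to the mean, interpreted as a relative
residual precision — the standard treatment-mean weighting in
meta-regression and exactly what `lmer(..., weights = n)` does. Models stay
single-predictor deliberately: with a few dozen treatment means per
response, extra fixed effects have not earned their complexity here, and
random slopes or non-Gaussian responses are out of scope.

### Estimation

Variance components are estimated by REML (not ML), matching mixed-model
defaults and removing the fixed-effect bias in tau^2. Rather than a generic
two-dimensional optimizer, the criterion is profiled over the single
variance ratio theta = tau^2 / sigma^2:

- at fixed theta the marginal covariance is sigma^2 * V(theta) with
  V = diag(1/w) + theta * Z Z'; each study contributes a diagonal plus
  rank-one block, so Sherman–Morrison gives V^{-1} and log|V| in closed
  form and every criterion evaluation is O(n);
- the fixed effects are GLS and sigma^2(theta) = r'V^{-1}r / (n - p) in
  closed form (the residual quadratic form is computed from explicit
  residuals, not by subtracting cross-products, to survive the noiseless
  limit numerically);
- the profiled criterion (n-p)·log sigma^2 + log|V| + log|X'V^{-1}X| is
  minimized over log(theta) by bounded scalar search (relative tolerance
  1e-8 on theta), and theta = 0 is evaluated explicitly: a boundary
  estimate tau^2 = 0 is a legal, reported outcome, not an error.

Standard errors come from sigma^2 (X'V^{-1}X)^{-1} at the optimum; the
slope test is Wald (the simplest test consistent with reporting estimates
± SE). Study BLUPs are s_i = theta/(1 + theta*sw_i) * sum_j w_ij r_ij,
which sum to zero exactly by the intercept normal equation.

A consequence of the weighting convention worth stating: doubling every
weight leaves the fitted line and tau^2 unchanged and doubles the
unit-weight sigma^2, so the per-record residual variance sigma^2/w is
invariant — weights act only as *relative* precisions.

### Marginal R²

R²m = Var_f / (Var_f + tau^2 + sigma_bar^2), with Var_f the population
variance of fixed-effect predictions over the complete cases. The usual
formula assumes one residual variance; under weights we take
sigma_bar^2 = sigma^2 * mean(1/w), the average per-record residual
variance. This is a documented choice — the weighted case is not pinned
down by the standard formula — and only affects the descriptive R², not
estimation or ranking.

## Screening

Before modelling, each database is screened once with Tukey fences
Q1 − 1.5·IQR, Q3 + 1.5·IQR per variable (response, DMI, K intake, urine
volume where populated). Quartiles use linear interpolation between order
statistics (numpy's default) — fence membership depends on the quantile
rule, so it is fixed and stated. Records are removed whole, never
field-wise, and every removal is logged with its triggering variable and
value. Screening is deliberately single-pass: re-screening a screened set
tightens the fences and can cascade. Fewer than four values make quartiles
too unstable to act on and raise (the pipeline skips such sparse columns).
Study- or record-level exclusions that rest on subject-matter judgment
(implausible excretion at high intake, data reuse between papers) are
config-driven blocklists, never hard-coded.

## Cross-validation and metrics

Generalization is tested to *unseen studies*: leave-one-study-out CV, one
fold per publication, prediction by fixed effects only (a new study's
random intercept has expectation zero — the only defensible prediction).
Metrics are computed unweighted over the pooled observed/predicted pairs;
weights influence fitting only.

MSPE decomposes into MB = (Pbar − Obar)², SB = (S_p − r·S_o)²,
ED = (1 − r²)·S_o². With population SDs (divide by n) the identity
MB + SB + ED = MSPE is exact — that is why the three bias percentages sum
to 100. Two SD conventions therefore coexist on purpose: population SDs
inside the decomposition, sample SDs (n−1) for descriptive summaries and
for RSR's denominator (RSR = RMSPE / sample SD of observations, the usual
convention for that adequacy ratio). Bias significance follows the
standard MSPE companion: regress residuals (obs − pred) on mean-centered
predictions; the intercept t-test probes mean bias, the slope t-test slope
bias. Degenerate cases are explicit: constant predictions set r = 0 with a
flag; constant observations are an error.

Candidate models are ranked by ascending RSR, ties broken by descending
CCC, then ascending RMSPE%, then model name — a deterministic total order.

## Synthetic data

The generator draws exactly the model's generative process: per study
s_i ~ N(0, tau²); per record x ~ Uniform(predictor range),
w ~ UniformInteger(weight range), e ~ N(0, sigma²/w). Uniform predictor
marginals over the observed literature ranges were chosen over truncated
normals: the ranges are what the literature summary pins down, and uniform
spread is the stated convention. One root seed spawns independent
per-study streams, so adding or removing studies never perturbs another
study's draws.

Two presets define the standing study conditions for every recovery
simulation: urinary (b0 = 1.08, b1 = 0.65, x ∈ (105.3, 686.0) g/d,
tau = 30, sigma = 25 g/d) and fecal (b0 = 6.93, b1 = 0.126,
x ∈ (105.3, 583.0) g/d, tau = 8, sigma = 10 g/d), both with 17 studies of
2–4 means weighted by 4–12 animals — the scale of the real urinary/fecal
literature databases. Problem sizes in the test suite (200 replicate
databases for recovery checks, 25 datasets for the lme4 equivalence,
1,000 random pair sets for the metric identities) are the package's
chosen defaults for tight Monte Carlo error at interactive runtimes.

The multivariable generator couples predictors through a Gaussian copula
(uniform marginals, prescribed correlation matrix) and *sets*
k_intake = dmi × dietary_k × 10 so every record satisfies the database
consistency identity; the response is driven by one designated predictor,
which gives ranking tests a known ground truth.

What the generator does **not** emulate: within-study predictor design
(real studies place diets deliberately, not uniformly; within-study
dispersion is a parameter, not an estimate), physiological nonlinearity or
K homeostasis, correlated measurement error between intake and excretion,
and publication selection. Passing recovery tests therefore shows the
estimator and protocol are correct under the model's own assumptions — not
that the literature satisfies those assumptions. Physically implausible
parameter choices can yield negative excretion values; these are kept with
a warning, since the generator is statistical, not physiological.

## Database conventions

Units are fixed: DMI kg/d, dietary K % of DM, K intake g/d, so the
derivation constant is exactly 10, and a derived K intake is never allowed
to overwrite a reported one. Reported triples (dmi, dietary_k, k_intake)
must agree within a 5% relative tolerance (configurable) — source-paper
rounding makes exact agreement unrealistic. Missing data are handled
complete-case per response~predictor pair, which is why different candidate
models legitimately use different n. Validation rejects rows with a
per-row reasoned report rather than raising on the first problem or
silently dropping.

## Known limitations

- One predictor per model; no lactating/dry stratification (the data scale
  that motivates this package does not support it).
- The Wald slope test and the residual-regression bias tests are
  asymptotic; with very few studies their p-values are approximate.
- The marginal R² weighting convention above is one of several defensible
  choices.
- CV metrics carry no uncertainty intervals (no bootstrap), matching the
  reporting style of the field.
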