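# Methods

## The response model

Symptom severity during a course of TMS is modelled as an exponential
approach to a floor,

    D(t) = A · exp(−t / B) + C,

with `A` the total magnitude of improvement and `C` the end-of-treatment
floor, both in rating-scale points, and `B` the time constant in weeks.
Time is measured in weeks from the first (baseline) rating; daily
weekday TMS delivers five sessions per week, so session counts convert
at 5 sessions = 1 week. `A` may be negative — worsening patients are
valid members of the model class — while `B` is strictly positive and is
always estimated on the log scale. The predicted baseline is
`D(0) = A + C`; the fraction of total response realised by time `t` is
`1 − exp(−t/B)`, independent of `A` and `C` (≈63% at `t = B`, ≈95% at
`t = 3B`).

Two categorical outcome rules are attached to the fitted or predicted
floor: *response* is `C ≤ f · D(0)` with `f = 0.5` by default (the
boundary counts as response), and *remission* is `C <` a scale-specific
cutoff (strict; PHQ-9 < 5 by convention — cutoffs for other scales are
configurable defaults, not assertions).

## Mixed-effects estimation

Patient-level fits use a nonlinear mixed-effects model: subject *i*'s
parameters are `A_i = A + a_i`, `log B_i = log B + b_i`, `C_i = C + c_i`
with the random subset of `(a_i, b_i, c_i)` drawn from a zero-mean
Gaussian with covariance Ψ, plus iid Gaussian residuals of sd σ. All
fits maximize the *marginal* likelihood (maximum likelihood, not REML),
integrating the random effects out by a Laplace approximation at the
per-subject posterior modes. Modes are found by a damped, batched
Gauss-Newton iteration; the Gauss-Newton Hessian is used in the
log-determinant term, in the style of Lindstrom and Bates.

Two structural facts are exploited:

- When the random subset excludes `B`, the conditional mean is *linear*
  in the random effects, the marginal distribution of each subject's
  scores is exactly Gaussian, and the Laplace approximation is exact.
  This path evaluates the closed-form Gaussian marginal likelihood with
  the fixed effects (A, C) profiled out by generalized least squares;
  only `log B` and the covariance parameters are optimized numerically.
- The covariance is parameterized *relative* to the residual variance
  (Ψ = σ²G, with G through its log-Cholesky factor), and σ² is profiled
  out in closed form — for the Laplace path too, since the penalized
  least-squares problem that defines the modes is σ-free under this
  parameterization. This removes one parameter and, more importantly,
  the ill-conditioned joint σ–Ψ valley that appears when data are close
  to an exact fit.

The linear mixed-effects comparator (`score ~ intercept + slope·weeks`
with correlated random intercept and slope) runs on the same
linear-marginal engine, so its log-likelihood is exact and directly
comparable; it is cross-checked in the test suite against statsmodels'
`MixedLM` (ML) and against direct evaluation of the implied
multivariate-Gaussian density, and the NLME Laplace likelihood is
cross-checked against dense numerical quadrature on small instances.

Outer optimization is L-BFGS-B with finite-difference gradients over
bounded parameters (`log B ∈ [−7, 7]`, log-Cholesky diagonals in
`[−12, 12]`), with deterministic starting values: `C₀` = mean last
observation, `A₀` = mean first − mean last, `B₀` by a grid search over
{0.5, 1, 2, 4} weeks, covariance from the moments of crude per-subject
estimates. Convergence requires the optimizer's own criteria
(relative objective change ≲1e−11, projected-gradient norm 1e−8); a
line-search abort at a variance bound is retried once from the stopping
point and accepted as converged only if no further progress (relative
change < 1e−8) is possible. Repeated fits of the same data are
bit-identical; no randomness enters the fitting path. If an
unstructured random-effect covariance estimates as singular
(a near-±1 correlation or a vanishing variance), the fit is repeated
with a diagonal structure and a warning.

Parameter counts for information criteria include the fixed effects,
the free covariance entries, and σ: e.g. 7 for the NLME with
unstructured random (A, C), 10 with random (A, B, C), 6 for the LME.
`AIC = −2ℓ + 2k` and `BIC = −2ℓ + k log(n_obs)` with `n_obs` the total
number of observations. The likelihood-ratio statistic is reported as
computed (it may be negative if the nominally larger model fits worse);
its chi-square reference uses the parameter-count difference as df.
Comparing the NLME against the LME is a *non-nested* comparison: the
LRT is still reported, with a warning, and AIC/BIC carry the decision.
Fixed-effect p-values are Wald tests from the numerically
differentiated observed information (the test for `B` is performed
against zero on the natural scale via the delta method).

`select_random_effects` fits the nested {A,C} and {A,B,C}
specifications and retains the richer one only when the LRT is
significant at 0.05 *and* both AIC and BIC are lower. In simulations at
the default operating point this conjunction is conservative: with
log-B heterogeneity of sd 0.5 at 400 subjects the LRT and AIC favour
the full model but BIC's heavier penalty usually does not, so {A,C} is
kept. The rule is implemented as stated; users wanting AIC-driven
selection can compare the fits directly.

## Group-level fits

Arm-level mean trajectories are fitted by nonlinear least squares
(`scipy.optimize.least_squares`, `B` on the log scale) under a
homoscedastic Gaussian error model — arm sizes and standard errors of
the source trials are not modelled, matching an analysis of raw group
means. The Gaussian ML log-likelihood of the residuals (σ̂² = RSS/n)
makes AIC/BIC comparable with the straight-line fit (statsmodels OLS):
4 versus 3 parameters. A flat series is returned as `A = 0`,
`C =` the constant, with the time constant flagged unidentifiable;
boundary estimates of `log B` or near-zero amplitudes are likewise
flagged, not raised as errors. Fitting several trajectories jointly
(`fit_multigroup_nlme`) reuses the patient-level NLME with groups as
the grouping level; with ≤5 groups the variance components are weakly
identified and a warning says so.

## Early-response prediction

The cross-validation pipeline estimates the population time constant on
training patients and predicts each held-out patient's floor from two
numbers — the baseline and the score after `t_early` weeks — via the
rearranged model, clamping predictions to the scale range (the clamped
value is used for classification; the raw value is retained for
diagnostics). Schemes: k-fold (k = 5 or 10; uniform random permutation
split by seed, fold sizes as equal as possible, no stratification) and
leave-one-out. Training fits use the training subjects' *full* series.
"End of treatment" is each subject's last observation, since
naturalistic series end at different visits. A subject is eligible when
it has a baseline, an observation at `t_early`, and at least one later
observation; intermediate visits are not required (the weaker of the
two possible completeness rules). A fold whose training fit fails
aborts the run — folds are never silently dropped.

Continuous accuracy is the adjusted R² of a univariate regression of
observed final scores on predicted floors,
`1 − (1−R²)(n−1)/(n−2)`. Categorical accuracy uses observed response
`final ≤ 0.5·baseline` (the same ≤ rule as the prediction) and reports
the full confusion set; an empty predicted-positive or -negative margin
makes PPV or NPV undefined and they are reported as NaN, never as 0.
Subjects whose baseline sits at the scale floor are excluded from
categorical evaluation (a fractional reduction from zero is undefined)
and counted separately.

## Synthetic cohorts

The generator emulates a naturalistic TMS clinic sample rated on the
PHQ-9 at baseline and after every five sessions. Defaults: 97
subjects on the weekly grid 0–6; population amplitude 5.8 points and
time constant 1.2 weeks; floor 11.0 points, giving a mean baseline of
16.8 (moderately-severe depression — the floor and baseline are this
package's own modelling choices, configurable in `CohortConfig`);
patient-level (amplitude, floor) drawn from a bivariate Gaussian with
sds 4 and 4 and correlation 0.3; optional log-normal time-constant
heterogeneity (off by default, matching a model with random effects on
amplitude and floor only); residual sd 2; scores rounded to integers
and clamped to 0–27. Dropout is monotone — once a visit is missed all
later visits are missed — with two guaranteed visits and a retention
probability of 0.85 per subsequent visit, giving a median of 6
observations per subject within a 2–9 envelope; clinical
discontinuation, not intermittent missingness, is the dominant
real-world mechanism. Group-level trajectories are the decay curve on
a ≥4-point schedule plus iid Gaussian noise.

What the generator does *not* emulate: item-level scoring,
informative (outcome-dependent) dropout, rater effects, visit-time
jitter, and — deliberately — any non-exponential shape. Passing
recovery tests on these cohorts therefore demonstrates correctness of
the estimators under the model's own assumptions, not robustness to
real-world misspecification.

One misspecification *is* present by design: clamping to the scale
range censors roughly 6% of baseline draws at the PHQ-9 ceiling under
the default configuration, and the Gaussian likelihood does not model
censoring. The consequence, measured by large-sample runs and
replicated simulation, is a small asymptotic bias in the fitted fixed
effects (amplitude ≈ −0.2 points, time constant ≈ +0.05 weeks at the
defaults); on an effectively unbounded scale the same estimators are
unbiased to Monte-Carlo precision. Rounding to integers, by contrast,
is innocuous — it behaves as additional uniform measurement noise
absorbed by σ.

## Problem sizes and numerical choices

Simulation studies in the test suite and the acceptance script use 200
replicates for recovery distributions (recovery of the clinical
operating point at n = 97; group-level NLS at the published group
operating points with noise sd 0.3), 100–500 replicates for cheaper
Monte-Carlo moment checks, and 10–40 replicates where each replicate
requires a full mixed-model fit; these sizes give Monte-Carlo standard
errors comfortably below the tolerances being asserted. Dense
quadrature oracles integrate over ±12 posterior sds with
`scipy.integrate.quad`. The inner Gauss-Newton mode search stops when
the step falls below 1e−10 (at most 200 iterations, 20 step-halvings);
inner solutions are warm-started across outer iterations, which leaves
the outer finite-difference gradient (step 1e−7) smooth. The residual
variance profile is floored at 1e−24 so exact-fit data stay finite;
fixed effects remain correct at that boundary while the likelihood
itself diverges, as it must.
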