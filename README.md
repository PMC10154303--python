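# tmsdecay

Exponential-decay modelling of the antidepressant response to repetitive
transcranial magnetic stimulation (TMS).

Depression symptoms during a course of TMS typically fall fast at first
and then level off. `tmsdecay` models a patient's (or a trial arm's)
longitudinal symptom ratings as

```
D(t) = A · exp(−t / B) + C
```

where `A` is the total magnitude of improvement (rating-scale points),
`B` the time constant of the response (weeks; 5 weekday sessions = 1
week), and `C` the severity floor approached at the end of treatment.
At `t = B` a patient has realised `1 − 1/e` (≈63%) of the total
response; at `t = 3B`, about 95%. Rearranging the model predicts the
end-of-treatment score from the baseline `D(0)`, an early observation
`D(t)`, and a population time constant:

```
C = (D(t) − D(0)·exp(−t/B)) / (1 − exp(−t/B))
```

The package is aimed at biostatisticians and brain-stimulation
researchers who want to fit this model to longitudinal rating data
(PHQ-9, HAM-D, QIDS-C), compare it against linear trends, and evaluate
early-response outcome prediction. It provides:

- **`ExponentialDecayModel`** — nonlinear mixed-effects (NLME) fitting
  by maximum marginal likelihood, with patient-level random effects on
  a chosen subset of {A, B, C} (Laplace approximation, exact when B
  carries no random effect), log-Cholesky covariance, Wald tests, and
  empirical-Bayes per-patient curves.
- **`LinearResponseModel`** — the linear mixed-effects comparator
  (correlated random intercept and slope), plus `compare_models`
  (LRT, ΔAIC, ΔBIC) and `select_random_effects`.
- **`GroupDecayModel` / `GroupLinearModel`** — nonlinear least-squares
  and straight-line fits to arm-level mean trajectories, and
  `fit_multigroup_nlme` for modelling several trajectories jointly.
- **`crossval_predict`** — k-fold / leave-one-out cross-validated
  prediction of final scores from week-1 or week-2 response, with
  adjusted R² and the full confusion-matrix metric set
  (accuracy/sensitivity/specificity/NPV/PPV) for 50%-reduction
  response.
- **`generate_cohort` / `generate_group_trajectories`** — synthetic
  cohorts with the structure of naturalistic TMS clinic data (weekly
  PHQ-9 grid, correlated patient-level amplitude and floor, monotone
  dropout, integer scores), so the whole pipeline is testable without
  clinical data.
- a CLI (`tmsdecay simulate | fit | compare | predict | groupfit`) over
  long-format ratings CSV files.

## Worked example

```python
from tmsdecay import (CohortConfig, ExponentialDecayModel,
                      LinearResponseModel, compare_models,
                      crossval_predict, generate_cohort)

cohort = generate_cohort(CohortConfig(seed=42))   # 97 synthetic patients
res = ExponentialDecayModel(cohort).fit(random_effects="AC")
print(res.summary())
```

```
NLME(exponential decay, RE={A,C})  [random effects: A, C; unstructured]
  subjects: 97   observations: 464   converged: True
  loglik: -1144.198   AIC: 2302.4   BIC: 2331.4
  fixed effects (est, se, p):
    amplitude A          6.465     0.471  5.84e-43
    time constant B      1.383     0.141  9.42e-23
    floor C             10.270     0.432  7.48e-125
  residual sd: 1.910
  random-effect covariance:
             A        C
    A  12.3961   4.8901
    C   4.8901  11.9439
```

The population curve for this cohort drops 6.5 PHQ-9 points with a time
constant of 1.4 weeks towards a floor of 10.3 points (the generating
values were 5.8, 1.2 and 11.0); the covariance block is the estimated
between-patient spread of amplitude and floor. Comparing against the
linear mixed model:

```python
comp = compare_models(res, LinearResponseModel(cohort).fit())
print(comp.summary())
```

```
NLME(exponential decay, RE={A,C}) vs LME(linear trend)  [non-nested: LRT is heuristic; prefer AIC/BIC]
  LRT = 136.22  df = 1  p = 1.79e-31
  delta AIC = -134.22  delta BIC = -130.08
  preferred: AIC -> NLME(...), BIC -> NLME(...), LRT -> NLME(...)
```

— the decay model fits far better than a straight line. Early-response
prediction with 5-fold cross-validation:

```python
pred = crossval_predict(cohort, "kfold5", t_early=1.0)
m = pred.classification_metrics()
print(pred.b_mean, pred.adjusted_r2(), m.accuracy)
```

prints a fold-averaged time constant of 1.404 weeks (sd 0.071 across
folds), an adjusted R² of 0.247 between predicted floors and observed
final scores, and 60% classification accuracy for 50%-reduction
response on the 77 patients with baseline, week-1 and later
observations (week-2 predictions are typically more accurate).

The same analyses run from the shell:

```bash
tmsdecay simulate --seed 42 --out run/
tmsdecay fit --ratings run/ratings.csv --random-effects AC
tmsdecay predict --ratings run/ratings.csv --scheme kfold5 --t-early 1
```

## Limitations

Synthetic cohorts clamp scores to the rating-scale range; because the
Gaussian likelihood does not model this censoring, recovered amplitudes
are a few percent low (and time constants slightly high) whenever an
appreciable share of baselines sits near the scale ceiling. See
`docs/methods.md` for the model, algorithms, and numerical choices.
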