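"""Cross-validated prediction of end-of-treatment outcomes from early response.

The pipeline mirrors measurement-based care: estimate the population
time constant B on training patients, then, for each held-out patient,
invert the decay model using only the baseline score and the score
after one (or two) weeks of treatment to predict the end-of-treatment
floor C.  Predictions are clamped to the rating scale's range, and
evaluated continuously (adjusted R^2 of observed final scores on
predicted C) and categorically (50%-reduction response, with the full
confusion-matrix metric set).

Supported schemes: k-fold (k = 5 or 10) and leave-one-out
cross-validation.  Training fits use each training subject's full
series; "end of treatment" is a subject's last observation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .decay import classify_response, predict_final
from .nlme import ExponentialDecayModel
from .scales import ScaleSpec
from .series import RatingSeries

__all__ = [
    "CVScheme",
    "PredictionResult",
    "ClassificationMetrics",
    "eligible_subjects",
    "crossval_predict",
    "evaluate_continuous",
    "evaluate_categorical",
]


@dataclass(frozen=True)
class CVScheme:
    """Cross-validation scheme: k-fold or leave-one-out.

    ``seed`` controls the random fold assignment (uniform permutation,
    fold sizes as equal as possible); it is ignored for leave-one-out,
    where every subject is its own test fold.
    """

    kind: str = "kfold"
    k: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("kfold", "loo"):
            raise ValueError("kind must be 'kfold' or 'loo'")
        if self.kind == "kfold" and self.k < 2:
            raise ValueError("k must be at least 2")

    @classmethod
    def kfold(cls, k: int, seed: int = 0) -> "CVScheme":
        return cls(kind="kfold", k=k, seed=seed)

    @classmethod
    def loo(cls) -> "CVScheme":
        return cls(kind="loo", k=0)

    @classmethod
    def coerce(cls, value) -> "CVScheme":
        if isinstance(value, cls):
            return value
        name = str(value).lower()
        if name in ("loo", "loocv", "leave-one-out"):
            return cls.loo()
        if name.startswith("kfold"):
            return cls.kfold(int(name[5:] or 5))
        raise ValueError(f"unknown CV scheme {value!r}")

    def label(self) -> str:
        return "LOOCV" if self.kind == "loo" else f"{self.k}-fold"

    def folds(self, n: int) -> list[np.ndarray]:
        """Partition indices 0..n-1 into test folds."""
        if self.kind == "loo":
            return [np.array([i]) for i in range(n)]
        if self.k > n:
            raise ValueError(f"cannot split {n} subjects into {self.k} folds")
        perm = np.random.default_rng(self.seed).permutation(n)
        return [np.sort(f) for f in np.array_split(perm, self.k)]


@dataclass
class ClassificationMetrics:
    """Confusion counts and the derived accuracy/sensitivity/specificity/NPV/PPV.

    Undefined ratios (an empty margin) are reported as NaN, never as 0.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    n_excluded: int = 0

    @staticmethod
    def _ratio(num: int, den: int) -> float:
        return num / den if den > 0 else float("nan")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return self._ratio(self.tp + self.tn, self.n)

    @property
    def sensitivity(self) -> float:
        return self._ratio(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self._ratio(self.tn, self.tn + self.fp)

    @property
    def npv(self) -> float:
        return self._ratio(self.tn, self.tn + self.fn)

    @property
    def ppv(self) -> float:
        return self._ratio(self.tp, self.tp + self.fp)

    @classmethod
    def from_labels(cls, observed, predicted, n_excluded: int = 0):
        observed = np.asarray(observed, dtype=bool)
        predicted = np.asarray(predicted, dtype=bool)
        if observed.shape != predicted.shape:
            raise ValueError("observed and predicted labels must align")
        return cls(
            tp=int(np.sum(predicted & observed)),
            fp=int(np.sum(predicted & ~observed)),
            tn=int(np.sum(~predicted & ~observed)),
            fn=int(np.sum(~predicted & observed)),
            n_excluded=n_excluded,
        )

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "n": self.n,
            "n_excluded": self.n_excluded,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "npv": self.npv,
            "ppv": self.ppv,
        }


@dataclass
class PredictionResult:
    """Per-subject cross-validated predictions plus fold-wise B estimates.

    ``table`` has one row per eligible subject: baseline ``d0``, the
    early score, the raw and clamped predicted C, the observed final
    score, and the fold (with its training-fit time constant) the
    subject was held out in.
    """

    table: pd.DataFrame
    fold_b: np.ndarray
    t_early: float
    scheme: CVScheme
    scale: ScaleSpec
    n_eligible: int

    @property
    def b_mean(self) -> float:
        return float(np.mean(self.fold_b))

    @property
    def b_sd(self) -> float:
        return float(np.std(self.fold_b, ddof=1)) if self.fold_b.size > 1 else 0.0

    def adjusted_r2(self) -> float:
        return evaluate_continuous(self)

    def classification_metrics(self) -> ClassificationMetrics:
        return evaluate_categorical(self)

    def to_metrics_dict(self) -> dict:
        return {
            "scheme": self.scheme.label(),
            "seed": self.scheme.seed,
            "t_early_weeks": self.t_early,
            "n_eligible": self.n_eligible,
            "fold_b_mean": self.b_mean,
            "fold_b_sd": self.b_sd,
            "adjusted_r2": self.adjusted_r2(),
            "classification": self.classification_metrics().to_dict(),
        }

    def plot(self, ax=None):
        """Observed final score against predicted floor C."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.table["c_pred"], self.table["observed_final"], "o", mfc="none")
        lim = [self.scale.min_score, self.scale.max_score]
        ax.plot(lim, lim, "--", color="grey")
        ax.set_xlabel("predicted C")
        ax.set_ylabel("observed final score")
        return ax


def eligible_subjects(cohort, t_early: float) -> list[RatingSeries]:
    """Subjects usable for early prediction at ``t_early`` weeks.

    Requires a baseline observation, an observation at ``t_early``, and
    at least one later observation to serve as the end-of-treatment
    score.  (Intermediate visits are not required.)
    """
    out = []
    for s in cohort:
        if s.has_time(0.0) and s.has_time(t_early) and s.final_time > t_early + 1e-9:
            out.append(s)
    return out


def crossval_predict(
    cohort,
    scheme="kfold5",
    t_early: float = 1.0,
    random_effects="AC",
) -> PredictionResult:
    """Cross-validated early-response predictions of the final score.

    For each fold, the NLME is fitted to the training subjects' full
    series; the fixed-effect time constant is then used to invert the
    decay model for every held-out subject from (baseline, score at
    ``t_early``).  A fold whose training fit fails to converge aborts
    the whole computation — folds are never silently skipped.
    """
    scheme = CVScheme.coerce(scheme)
    elig = eligible_subjects(cohort, t_early)
    if not elig:
        raise ValueError(f"no subjects eligible for prediction at t_early={t_early}")
    scale = elig[0].scale
    folds = scheme.folds(len(elig))
    # warm start for fold fits: one fit on the full eligible cohort
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full_fit = ExponentialDecayModel(elig).fit(random_effects=random_effects)
    rows = []
    fold_b = []
    for fold_idx, test in enumerate(folds):
        train = [s for i, s in enumerate(elig) if i not in set(test.tolist())]
        fit = ExponentialDecayModel(train).fit(
            random_effects=random_effects, start=full_fit
        )
        if not fit.converged:
            raise RuntimeError(
                f"training fit for fold {fold_idx} did not converge: {fit.message}"
            )
        b = fit.fixed.time_constant
        fold_b.append(b)
        for i in test:
            s = elig[i]
            d0 = s.baseline
            dt = s.score_at(t_early)
            pred = predict_final(d0, dt, t_early, b, scale)
            rows.append(
                {
                    "subject_id": s.subject_id,
                    "d0": d0,
                    "early_score": dt,
                    "c_pred_unclamped": pred.unclamped,
                    "c_pred": pred.clamped,
                    "observed_final": s.final,
                    "final_time": s.final_time,
                    "fold": fold_idx,
                    "fold_b": b,
                }
            )
    table = pd.DataFrame(rows)
    ids = table["subject_id"]
    if ids.duplicated().any() or len(table) != len(elig):
        raise AssertionError("folds failed to partition the eligible subjects")
    return PredictionResult(
        table=table,
        fold_b=np.asarray(fold_b),
        t_early=t_early,
        scheme=scheme,
        scale=scale,
        n_eligible=len(elig),
    )


def evaluate_continuous(result: PredictionResult) -> float:
    """Adjusted R^2 of observed final scores regressed on predicted C.

    Univariate OLS; adjusted R^2 = 1 - (1 - R^2)(n - 1)/(n - 2).
    """
    x = result.table["c_pred"].to_numpy(dtype=float)
    y = result.table["observed_final"].to_numpy(dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("at least 3 subjects are required for adjusted R^2")
    if np.ptp(x) == 0:
        raise ValueError("predictions have zero variance: R^2 undefined")
    sxx = np.sum((x - x.mean()) ** 2)
    sxy = np.sum((x - x.mean()) * (y - y.mean()))
    syy = np.sum((y - y.mean()) ** 2)
    if syy == 0:
        raise ValueError("observed finals have zero variance: R^2 undefined")
    r2 = sxy**2 / (sxx * syy)
    return float(1.0 - (1.0 - r2) * (n - 1) / (n - 2))


def evaluate_categorical(
    result: PredictionResult, scale: ScaleSpec | None = None
) -> ClassificationMetrics:
    """Confusion metrics of the predicted 50%-reduction response.

    Observed response: final <= response_fraction * baseline; predicted
    response via the clamped predicted C.  Subjects whose baseline is at
    the scale floor are excluded (the fractional rule is undefined) and
    counted in ``n_excluded``.
    """
    scale = scale or result.scale
    observed, predicted = [], []
    n_excluded = 0
    for row in result.table.itertuples():
        if row.d0 <= scale.min_score:
            n_excluded += 1
            continue
        observed.append(row.observed_final <= scale.response_fraction * row.d0)
        predicted.append(classify_response(row.d0, row.c_pred, scale))
    return ClassificationMetrics.from_labels(observed, predicted, n_excluded=n_excluded)
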