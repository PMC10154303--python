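"""The exponential-decay model of antidepressant treatment response.

Symptom severity during a course of TMS is modelled as

    D(t) = A * exp(-t / B) + C

where ``A`` is the total magnitude of improvement (score points), ``B``
the time constant of the response (weeks), and ``C`` the severity floor
approached at the end of treatment.  The predicted baseline is
``D(0) = A + C``; at ``t = B`` a patient has realised ``1 - 1/e``
(~63%) of the total response, at ``t = 3B`` about 95%.

Rearranging the model gives an early-response predictor of the final
score: given the baseline ``D(0)``, an early observation ``D(t)`` and a
population time constant ``B``,

    C = (D(t) - D(0) * exp(-t/B)) / (1 - exp(-t/B)).

This module houses those two closed forms plus the categorical
response/remission rules used to dichotomize predicted outcomes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .scales import ScaleSpec

__all__ = [
    "DecayParams",
    "FinalPrediction",
    "predict_score",
    "response_fraction",
    "predict_final",
    "classify_response",
    "classify_remission",
]


@dataclass(frozen=True)
class DecayParams:
    """Parameter triple (A, B, C) of the exponential-decay response curve.

    ``amplitude`` (A) and ``floor`` (C) are in score points of the rating
    scale; ``time_constant`` (B) is in weeks and must be strictly
    positive.  ``amplitude`` may be negative: a worsening patient is a
    valid member of the model class.
    """

    amplitude: float
    time_constant: float
    floor: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.time_constant) or self.time_constant <= 0:
            raise ValueError(
                f"time_constant must be strictly positive, got {self.time_constant}"
            )

    # terse aliases for use in formulas
    @property
    def a(self) -> float:
        return self.amplitude

    @property
    def b(self) -> float:
        return self.time_constant

    @property
    def c(self) -> float:
        return self.floor

    @property
    def baseline(self) -> float:
        """Predicted score at t = 0, i.e. A + C."""
        return self.amplitude + self.floor

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.amplitude, self.time_constant, self.floor)


class FinalPrediction(NamedTuple):
    """Early-response prediction of the end-of-treatment floor C.

    ``unclamped`` is the raw rearranged-model value; ``clamped`` is the
    same value clipped into the rating scale's range (the value used for
    categorical classification and reporting).
    """

    unclamped: float
    clamped: float


def predict_score(params: DecayParams, t):
    """Evaluate D(t) = A*exp(-t/B) + C at time ``t`` (weeks).

    ``t`` may be a scalar or array; all times must be nonnegative.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be nonnegative")
    out = params.a * np.exp(-t / params.b) + params.c
    return float(out) if out.ndim == 0 else out


def response_fraction(params: DecayParams, t):
    """Fraction of the total response realised by time ``t``.

    Returns ``(D(0) - D(t)) / A = 1 - exp(-t/B)``, which involves only
    the time constant: at ``t = B`` it equals ``1 - 1/e`` (~63%) and at
    ``t = 3B`` about 95%, for any amplitude and floor (including A = 0,
    for which the same closed form is returned).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be nonnegative")
    out = 1.0 - np.exp(-t / params.b)
    return float(out) if out.ndim == 0 else out


def predict_final(
    d0: float,
    dt: float,
    t: float,
    b: float,
    scale: ScaleSpec,
) -> FinalPrediction:
    """Predict the end-of-treatment score C from an early observation.

    Inverts the decay model under the constraint A = D(0) - C:

        C = (D(t) - D(0) * exp(-t/B)) / (1 - exp(-t/B))

    Parameters
    ----------
    d0 : float
        Baseline score D(0).
    dt : float
        Observed score at the early time point, D(t).
    t : float
        Elapsed time in weeks; must be strictly positive.
    b : float
        Population time constant in weeks.
    scale : ScaleSpec
        Rating scale; the clamped value is clipped to its range.

    Returns
    -------
    FinalPrediction
        Both the raw and the range-clamped prediction.
    """
    if t <= 0:
        raise ValueError("prediction undefined at t <= 0 (no elapsed time)")
    if b <= 0:
        raise ValueError("time constant must be strictly positive")
    decay = np.exp(-t / b)
    raw = (dt - d0 * decay) / (1.0 - decay)
    return FinalPrediction(unclamped=float(raw), clamped=float(scale.clamp(raw)))


def classify_response(d0: float, c_pred: float, scale: ScaleSpec) -> bool:
    """Categorical treatment response from a (predicted) final score.

    A responder attains at least the scale's fractional reduction from
    baseline, i.e. ``c_pred <= response_fraction * d0`` (boundary
    included).  A baseline at the scale floor makes the rule undefined
    and raises ``ValueError``.
    """
    if d0 <= scale.min_score:
        raise ValueError(
            f"baseline {d0} at or below scale minimum {scale.min_score}: "
            "fractional response is undefined"
        )
    return c_pred <= scale.response_fraction * d0


def classify_remission(c_pred: float, scale: ScaleSpec) -> bool:
    """Remission rule: final score strictly below the scale's cutoff."""
    return c_pred < scale.remission_cutoff
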