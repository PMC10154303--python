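"""Longitudinal rating-series container.

A :class:`RatingSeries` holds one patient's (or one treatment group's
mean) symptom ratings over a course of TMS, with time in weeks from
baseline.  Daily-weekday TMS delivers five sessions per week, so
session counts convert at 5 sessions = 1 week.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .scales import ScaleSpec

__all__ = ["RatingSeries", "SESSIONS_PER_WEEK", "cohort_to_frame"]

SESSIONS_PER_WEEK = 5.0


@dataclass(frozen=True)
class RatingSeries:
    """One subject's (or group's) longitudinal ratings.

    Invariants enforced on construction: at least two observations;
    times strictly increasing with the first at 0 (baseline); scores
    within the scale's range.
    """

    subject_id: str
    times: np.ndarray
    scores: np.ndarray
    scale: ScaleSpec

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        scores = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "scores", scores)
        if times.ndim != 1 or scores.ndim != 1 or times.size != scores.size:
            raise ValueError(
                f"subject {self.subject_id}: times and scores must be equal-length 1-d arrays"
            )
        if times.size < 2:
            raise ValueError(
                f"subject {self.subject_id}: at least 2 observations required, got {times.size}"
            )
        if not np.all(np.diff(times) > 0):
            raise ValueError(
                f"subject {self.subject_id}: times must be strictly increasing "
                "(duplicate visits are not allowed)"
            )
        if times[0] != 0:
            raise ValueError(
                f"subject {self.subject_id}: first observation must be at baseline (t=0), "
                f"got t={times[0]}"
            )
        if not self.scale.contains(scores):
            raise ValueError(
                f"subject {self.subject_id}: scores outside {self.scale.name} range "
                f"[{self.scale.min_score}, {self.scale.max_score}]"
            )

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def n_obs(self) -> int:
        return len(self)

    @property
    def baseline(self) -> float:
        return float(self.scores[0])

    @property
    def final(self) -> float:
        """Last observed score — the end-of-treatment measurement."""
        return float(self.scores[-1])

    @property
    def final_time(self) -> float:
        return float(self.times[-1])

    def score_at(self, t: float, atol: float = 1e-8) -> float | None:
        """Score observed at time ``t`` (weeks), or None if no such visit."""
        hit = np.flatnonzero(np.isclose(self.times, t, atol=atol))
        return float(self.scores[hit[0]]) if hit.size else None

    def has_time(self, t: float, atol: float = 1e-8) -> bool:
        return self.score_at(t, atol=atol) is not None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "time": self.times,
                "score": self.scores,
                "scale": self.scale.name,
            }
        )


def cohort_to_frame(cohort) -> pd.DataFrame:
    """Stack a collection of series into one long-format table."""
    return pd.concat([s.to_frame() for s in cohort], ignore_index=True)
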