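"""Synthetic longitudinal cohorts with the structure of naturalistic TMS data.

The generator emulates a clinic sample of patients rated on the PHQ-9 at
baseline and after every five daily TMS sessions (a weekly grid): each
subject follows an exponential-decay trajectory with patient-specific
amplitude and floor drawn from a correlated bivariate Gaussian,
optionally a patient-specific time constant (log-normal), additive
Gaussian residual noise, monotone dropout after two guaranteed visits,
and integer discretization of the recorded scores.

Defaults reproduce the study conditions this package is exercised
under: 97 subjects, weeks 0-6, population amplitude 5.8 and time
constant 1.2 weeks, floor 11 (baseline ~16.8, moderately-severe
depression), between-patient sds of 4 on amplitude and floor with
correlation 0.3, residual sd 2, rounding to PHQ-9 integers, and a
retention probability of 0.85 per visit beyond the second (median 6
observations per subject, range within 2-9).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .decay import DecayParams, predict_score
from .scales import PHQ9, ScaleSpec
from .series import RatingSeries

__all__ = [
    "CohortConfig",
    "generate_cohort",
    "generate_group_trajectories",
    "DEFAULT_SCHEDULE",
]

DEFAULT_SCHEDULE = (0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0)


@dataclass(frozen=True)
class CohortConfig:
    """Generating configuration for a synthetic patient cohort.

    Attributes
    ----------
    n_subjects : int
        Cohort size.
    schedule : tuple of float
        Visit times in weeks; strictly increasing, starting at 0.
    fixed : DecayParams
        Population (fixed-effect) curve parameters.
    sd_amplitude, sd_floor : float
        Between-patient sds of amplitude and floor (score points).
    corr_amplitude_floor : float
        Correlation of the patient-level (amplitude, floor) pair.
    sd_log_time_constant : float
        sd of the patient-level log time constant; 0 disables
        time-constant heterogeneity (the default, matching a model with
        random effects on amplitude and floor only).
    residual_sd : float
        sd of the additive Gaussian measurement noise (score points).
    scale : ScaleSpec
        Rating scale; emitted scores are always clipped to its range.
    discretize : bool
        Round scores to integers (measurement rounding) before clipping.
    retention : float or tuple of float
        Probability of attending each visit beyond the guaranteed first
        two, given the previous visit was attended (monotone dropout).
        A tuple gives per-visit probabilities for visits 2, 3, ...
    seed : int
        Seed for the cohort's private random generator.
    """

    n_subjects: int = 97
    schedule: tuple = DEFAULT_SCHEDULE
    fixed: DecayParams = field(
        default_factory=lambda: DecayParams(amplitude=5.8, time_constant=1.2, floor=11.0)
    )
    sd_amplitude: float = 4.0
    sd_floor: float = 4.0
    corr_amplitude_floor: float = 0.3
    sd_log_time_constant: float = 0.0
    residual_sd: float = 2.0
    scale: ScaleSpec = PHQ9
    discretize: bool = True
    retention: float | tuple = 0.85
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        sched = tuple(float(t) for t in self.schedule)
        object.__setattr__(self, "schedule", sched)
        if len(sched) < 2 or sched[0] != 0 or not np.all(np.diff(sched) > 0):
            raise ValueError("schedule must start at 0 and be strictly increasing")
        for name in ("sd_amplitude", "sd_floor", "sd_log_time_constant", "residual_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not abs(self.corr_amplitude_floor) < 1:
            raise ValueError("corr_amplitude_floor must lie strictly in (-1, 1)")
        baseline = self.fixed.baseline
        if not (self.scale.min_score <= baseline <= self.scale.max_score):
            raise ValueError(
                f"implied mean baseline {baseline} lies outside the "
                f"{self.scale.name} range [{self.scale.min_score}, {self.scale.max_score}]"
            )
        ret = self.retention
        probs = (
            tuple(float(p) for p in ret)
            if isinstance(ret, (tuple, list, np.ndarray))
            else (float(ret),) * max(0, len(sched) - 2)
        )
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("retention probabilities must lie in [0, 1]")
        object.__setattr__(self, "retention", probs)

    def replace(self, **kwargs) -> "CohortConfig":
        return replace(self, **kwargs)


def _n_visits(rng: np.random.Generator, config: CohortConfig) -> int:
    """Draw the number of attended visits: 2 guaranteed, then monotone dropout."""
    n = 2
    for k, p in enumerate(config.retention):
        if 2 + k >= len(config.schedule):
            break
        if rng.random() < p:
            n += 1
        else:
            break
    return min(n, len(config.schedule))


def generate_cohort(config: CohortConfig) -> list[RatingSeries]:
    """Simulate a cohort of rating series; fully reproducible from the seed."""
    rng = np.random.default_rng(config.seed)
    f = config.fixed
    cov = np.array(
        [
            [config.sd_amplitude**2,
             config.corr_amplitude_floor * config.sd_amplitude * config.sd_floor],
            [config.corr_amplitude_floor * config.sd_amplitude * config.sd_floor,
             config.sd_floor**2],
        ]
    )
    amp_floor = rng.multivariate_normal([f.amplitude, f.floor], cov, size=config.n_subjects)
    log_b = np.log(f.time_constant) + config.sd_log_time_constant * rng.standard_normal(
        config.n_subjects
    )
    schedule = np.asarray(config.schedule)
    width = len(str(config.n_subjects))
    cohort = []
    for i in range(config.n_subjects):
        n_vis = _n_visits(rng, config)
        t = schedule[:n_vis]
        params = DecayParams(amp_floor[i, 0], float(np.exp(log_b[i])), amp_floor[i, 1])
        y = predict_score(params, t) + config.residual_sd * rng.standard_normal(n_vis)
        if config.discretize:
            y = np.rint(y)
        y = config.scale.clamp(y)
        cohort.append(
            RatingSeries(
                subject_id=f"S{i + 1:0{width}d}",
                times=t,
                scores=y,
                scale=config.scale,
            )
        )
    return cohort


def generate_group_trajectories(
    params_list,
    schedule=DEFAULT_SCHEDULE,
    noise_sd: float = 0.0,
    scale: ScaleSpec = None,
    seed: int = 0,
    names=None,
) -> list[RatingSeries]:
    """Simulate group-level mean trajectories from given decay parameters.

    Each group's series is the decay curve evaluated on ``schedule``
    plus iid Gaussian noise of sd ``noise_sd``, clipped to the scale
    range.  At least four time points are required so that a
    three-parameter fit is not underdetermined.
    """
    from .scales import HAMD17  # default scale for trial-style mean tables

    if scale is None:
        scale = HAMD17
    schedule = np.asarray(schedule, dtype=float)
    if schedule.size < 4:
        raise ValueError("schedule must contain at least 4 time points")
    if schedule[0] != 0 or not np.all(np.diff(schedule) > 0):
        raise ValueError("schedule must start at 0 and be strictly increasing")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    params_list = list(params_list)
    if names is None:
        names = [f"group-{k + 1}" for k in range(len(params_list))]
    rng = np.random.default_rng(seed)
    out = []
    for name, params in zip(names, params_list):
        y = predict_score(params, schedule) + noise_sd * rng.standard_normal(schedule.size)
        out.append(
            RatingSeries(subject_id=name, times=schedule, scores=scale.clamp(y), scale=scale)
        )
    return out
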