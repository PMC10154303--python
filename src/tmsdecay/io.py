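"""Reading and writing long-format rating tables and fit reports.

The on-disk format is a plain CSV with columns ``subject_id``,
``time``, ``score`` and ``scale`` — one row per subject-visit.  Time
may be recorded in weeks (the internal unit) or in TMS session counts,
which convert at 5 sessions = 1 week.  Readers validate rather than
coerce: duplicate visits, out-of-range scores and unknown scale names
each raise a distinct error naming the offending row.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .scales import ScaleSpec, get_scale
from .series import SESSIONS_PER_WEEK, RatingSeries, cohort_to_frame

__all__ = [
    "read_ratings",
    "write_ratings",
    "frame_to_cohort",
    "cohort_to_frame",
    "read_cohort_config",
    "write_json",
]

_REQUIRED = ("subject_id", "time", "score")


class RatingsFormatError(ValueError):
    """Malformed ratings table (missing columns, bad rows, range violations)."""


def frame_to_cohort(
    df: pd.DataFrame,
    scale: ScaleSpec | str | None = None,
    time_unit: str = "weeks",
) -> list[RatingSeries]:
    """Convert a long-format table into a list of RatingSeries.

    ``scale`` overrides (or supplies, when the table has no ``scale``
    column) the rating scale; rows may also name their scale, which is
    looked up in the registry.  ``time_unit`` is ``"weeks"`` or
    ``"sessions"``.
    """
    if time_unit not in ("weeks", "sessions"):
        raise ValueError("time_unit must be 'weeks' or 'sessions'")
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise RatingsFormatError(f"missing required column(s): {missing}")
    if scale is None and "scale" not in df.columns:
        raise RatingsFormatError("no 'scale' column and no scale override given")
    if isinstance(scale, str):
        scale = get_scale(scale)

    df = df.reset_index(drop=True)
    rows = df.to_dict("records")
    resolved: list[ScaleSpec] = []
    for i, row in enumerate(rows):
        if scale is not None:
            resolved.append(scale)
        else:
            try:
                resolved.append(get_scale(str(row["scale"])))
            except KeyError as exc:
                raise RatingsFormatError(f"row {i + 2}: {exc.args[0]}") from None
    for i, (row, sc) in enumerate(zip(rows, resolved)):
        t, y = row["time"], row["score"]
        if not np.isfinite(t) or t < 0:
            raise RatingsFormatError(f"row {i + 2}: invalid time {t!r}")
        if not np.isfinite(y) or not (sc.min_score <= y <= sc.max_score):
            raise RatingsFormatError(
                f"row {i + 2}: score {y!r} outside {sc.name} range "
                f"[{sc.min_score}, {sc.max_score}]"
            )
    dup = df.duplicated(subset=["subject_id", "time"], keep=False)
    if dup.any():
        bad = ", ".join(str(i + 2) for i in df.index[dup][:10])
        raise RatingsFormatError(
            f"duplicate (subject_id, time) visits at row(s) {bad}"
        )

    factor = 1.0 / SESSIONS_PER_WEEK if time_unit == "sessions" else 1.0
    cohort = []
    for sid, sub in df.groupby("subject_id", sort=True):
        sub = sub.sort_values("time")
        sc = (
            scale
            if scale is not None
            else get_scale(str(sub["scale"].iloc[0]))
        )
        try:
            cohort.append(
                RatingSeries(
                    subject_id=str(sid),
                    times=sub["time"].to_numpy(dtype=float) * factor,
                    scores=sub["score"].to_numpy(dtype=float),
                    scale=sc,
                )
            )
        except ValueError as exc:
            raise RatingsFormatError(str(exc)) from None
    return cohort


def read_ratings(
    path,
    time_unit: str = "weeks",
    scale: ScaleSpec | str | None = None,
) -> list[RatingSeries]:
    """Read a ratings CSV into a cohort of series (sorted by subject)."""
    df = pd.read_csv(path)
    return frame_to_cohort(df, scale=scale, time_unit=time_unit)


def write_ratings(cohort, path) -> None:
    """Write a cohort as long-format CSV, time in weeks (RFC-4180 quoting)."""
    cohort_to_frame(cohort).to_csv(path, index=False, lineterminator="\r\n")


def read_cohort_config(path):
    """Load a flat key-value (YAML) cohort configuration file.

    Recognized keys mirror :class:`tmsdecay.simulate.CohortConfig`;
    ``scale`` is a registry name and ``amplitude``/``time_constant``/
    ``floor`` populate the fixed effects.  Unknown keys are rejected.
    """
    from .decay import DecayParams
    from .simulate import CohortConfig

    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise RatingsFormatError("config file must be a flat key-value mapping")
    fixed_keys = {"amplitude", "time_constant", "floor"}
    kwargs = {}
    fixed = {"amplitude": 5.8, "time_constant": 1.2, "floor": 11.0}
    valid = {
        "n_subjects", "schedule", "sd_amplitude", "sd_floor",
        "corr_amplitude_floor", "sd_log_time_constant", "residual_sd",
        "discretize", "retention", "seed", "scale",
    }
    for key, value in raw.items():
        if key in fixed_keys:
            fixed[key] = float(value)
        elif key == "scale":
            kwargs["scale"] = get_scale(str(value))
        elif key in ("schedule", "retention") and isinstance(value, (list, tuple)):
            kwargs[key] = tuple(value)
        elif key in valid:
            kwargs[key] = value
        else:
            raise RatingsFormatError(f"unknown config key {key!r}")
    return CohortConfig(fixed=DecayParams(**fixed), **kwargs)


def write_json(obj, path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=_default, allow_nan=True))
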