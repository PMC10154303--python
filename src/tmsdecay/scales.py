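"""Depression rating-scale definitions.

A :class:`ScaleSpec` carries the score range of a clinical rating
instrument together with the conventions used to dichotomize outcomes:
the fractional-reduction threshold defining categorical *response*
(default 50%) and the score cutoff below which a patient is considered
in *remission*.

The built-in registry covers the scales used by TMS trials in this
literature (PHQ-9, HAM-D 17- and 6-item, QIDS-C).  Remission cutoffs
other than the PHQ-9 convention (< 5) are configurable defaults, not
assertions; use :func:`register_scale` to add or override definitions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "ScaleSpec",
    "PHQ9",
    "HAMD17",
    "HAMD6",
    "QIDSC",
    "get_scale",
    "register_scale",
]


@dataclass(frozen=True)
class ScaleSpec:
    """Score range and outcome conventions for a symptom rating scale.

    Parameters
    ----------
    name : str
        Scale identifier, e.g. ``"PHQ-9"``.
    min_score, max_score : float
        Inclusive bounds of the instrument's score range.
    response_fraction : float, default 0.5
        Categorical response is defined as a final (or predicted final)
        score at or below ``response_fraction * baseline``.
    remission_cutoff : float
        Remission is defined as a score strictly below this cutoff.
    """

    name: str
    min_score: float
    max_score: float
    response_fraction: float = 0.5
    remission_cutoff: float = 5.0

    def __post_init__(self) -> None:
        if not self.min_score < self.max_score:
            raise ValueError(
                f"{self.name}: min_score ({self.min_score}) must be below "
                f"max_score ({self.max_score})"
            )
        if not 0.0 < self.response_fraction < 1.0:
            raise ValueError("response_fraction must lie strictly in (0, 1)")
        if not self.min_score <= self.remission_cutoff <= self.max_score:
            raise ValueError(
                f"{self.name}: remission_cutoff ({self.remission_cutoff}) "
                f"outside score range [{self.min_score}, {self.max_score}]"
            )

    @property
    def span(self) -> float:
        return self.max_score - self.min_score

    def clamp(self, scores):
        """Clip ``scores`` into the scale's valid range."""
        return np.clip(scores, self.min_score, self.max_score)

    def contains(self, scores) -> bool:
        scores = np.asarray(scores, dtype=float)
        return bool(
            np.all(scores >= self.min_score) and np.all(scores <= self.max_score)
        )

    def with_cutoff(self, remission_cutoff: float) -> "ScaleSpec":
        return replace(self, remission_cutoff=remission_cutoff)


PHQ9 = ScaleSpec("PHQ-9", 0, 27, remission_cutoff=5)
HAMD17 = ScaleSpec("HAM-D-17", 0, 52, remission_cutoff=8)
HAMD6 = ScaleSpec("HAM-D-6", 0, 22, remission_cutoff=5)
QIDSC = ScaleSpec("QIDS-C", 0, 27, remission_cutoff=6)

_REGISTRY: dict[str, ScaleSpec] = {}


def register_scale(spec: ScaleSpec) -> None:
    """Add (or replace) a scale definition in the registry."""
    _REGISTRY[spec.name.upper()] = spec


for _spec in (PHQ9, HAMD17, HAMD6, QIDSC):
    register_scale(_spec)
# common aliases
_REGISTRY["PHQ9"] = PHQ9
_REGISTRY["HAMD17"] = HAMD17
_REGISTRY["HAM-D"] = HAMD17
_REGISTRY["HAMD6"] = HAMD6
_REGISTRY["QIDS-C16"] = QIDSC
_REGISTRY["QIDSC"] = QIDSC


def get_scale(name: str) -> ScaleSpec:
    """Look up a scale by name (case-insensitive, common aliases accepted)."""
    try:
        return _REGISTRY[name.upper()]
    except KeyError:
        known = sorted({s.name for s in _REGISTRY.values()})
        raise KeyError(f"unknown rating scale {name!r}; known scales: {known}") from None
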