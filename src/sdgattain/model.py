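"""Domain types and transform-space helpers.

Indicators are scored on a 0-100 attainment scale anchored at the
outlier-trimmed worst historical value (0) and the resolved target (100).
Rates (incidence, mortality) are handled in log space, proportions
bounded in [0, 1] in logit space, everything else linearly.  The same
transform drives both anchoring and trend projection so a constant
annual rate of change is a straight line in transform space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .errors import DomainError

TOPICS = (
    "child_nutrition",
    "mchrh",
    "infectious",
    "ncd_mortality",
    "ncd_risk",
    "road_injury",
    "env_outcome",
    "env_exposure",
    "uhc",
)

DIRECTIONS = ("lower_better", "higher_better")
TRANSFORMS = ("log", "logit", "linear")
TARGET_TYPES = ("absolute", "relative_reduction", "no_increase", "elimination")
TARGET_YEARS = (2020, 2025, 2030)
SEXES = ("male", "female", "both")
REGIONS = ("eastern", "central", "western", "national", "SAR")

ANCHOR_WINDOW = (1990, 2015)
YEAR_BOUNDS = (1990, 2030)

PANEL_COLUMNS = ["location_id", "region", "indicator_id", "sex", "year", "value"]
SCORE_COLUMNS = [
    "location_id", "indicator_id", "sex", "year", "score", "worst", "target",
]
TOPIC_COLUMNS = ["location_id", "topic", "year", "index", "n_members", "members"]
PROJECTION_COLUMNS = [
    "location_id", "indicator_id", "sex", "year", "value", "omega",
]


def _logit(x):
    x = np.asarray(x, dtype=float)
    return np.log(x) - np.log1p(-x)


def _expit(y):
    y = np.asarray(y, dtype=float)
    return 1.0 / (1.0 + np.exp(-y))


_FORWARD: dict[str, Callable] = {
    "log": np.log,
    "logit": _logit,
    "linear": lambda x: np.asarray(x, dtype=float),
}
_INVERSE: dict[str, Callable] = {
    "log": np.exp,
    "logit": _expit,
    "linear": lambda y: np.asarray(y, dtype=float),
}


def transform_forward(transform: str, x):
    """Map indicator units into transform space (ln, logit, or identity)."""
    check_domain(transform, x)
    return _FORWARD[transform](x)


def transform_inverse(transform: str, y):
    """Map transform-space values back to indicator units."""
    return _INVERSE[transform](y)


def check_domain(transform: str, x, context: str = "") -> None:
    """Raise :class:`DomainError` when a value cannot be transformed.

    Strict interiors: log needs x > 0, logit needs 0 < x < 1.  Zeros on
    log indicators are legal in *panels* (they mark elimination) and are
    imputed before scaling; by the time values reach a transform they
    must be interior.
    """
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise DomainError(f"non-finite value{': ' + context if context else ''}")
    if transform == "log" and np.any(arr <= 0):
        raise DomainError(f"log transform needs positive values{': ' + context if context else ''}")
    if transform == "logit" and (np.any(arr <= 0) or np.any(arr >= 1)):
        raise DomainError(f"logit transform needs values in (0, 1){': ' + context if context else ''}")


@dataclass(frozen=True)
class IndicatorDefinition:
    """One row of the indicator registry.

    ``target_value`` is in indicator units for absolute targets and a
    fraction in (0, 1) for relative reductions; ``baseline_year``
    applies to relative-reduction and no-increase targets.
    """

    indicator_id: str
    name: str
    topic: str
    direction: str
    transform: str
    target_type: str
    target_value: Optional[float]
    baseline_year: Optional[int]
    target_year: int
    units: str = ""
    assumed: bool = False

    def __post_init__(self):
        if self.topic not in TOPICS:
            raise ValueError(f"{self.indicator_id}: unknown topic {self.topic!r}")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"{self.indicator_id}: unknown direction {self.direction!r}")
        if self.transform not in TRANSFORMS:
            raise ValueError(f"{self.indicator_id}: unknown transform {self.transform!r}")
        if self.target_type not in TARGET_TYPES:
            raise ValueError(f"{self.indicator_id}: unknown target_type {self.target_type!r}")
        if self.target_year not in TARGET_YEARS:
            raise ValueError(f"{self.indicator_id}: target_year must be one of {TARGET_YEARS}")
        if self.target_type == "relative_reduction":
            if self.target_value is None or not (0 < self.target_value < 1):
                raise ValueError(
                    f"{self.indicator_id}: relative_reduction needs target_value in (0, 1)"
                )
            if self.baseline_year is None:
                raise ValueError(f"{self.indicator_id}: relative_reduction needs baseline_year")
        if self.target_type == "no_increase" and self.baseline_year is None:
            raise ValueError(f"{self.indicator_id}: no_increase needs baseline_year")
        if self.target_type == "absolute" and self.target_value is None:
            raise ValueError(f"{self.indicator_id}: absolute target needs target_value")


@dataclass(frozen=True)
class AnchorPair:
    """Scale anchors for one (location, indicator) series: worst -> 0, target -> 100."""

    worst_value: float
    target_value_resolved: float
    anchor_window: tuple[int, int] = ANCHOR_WINDOW


@dataclass(frozen=True)
class ProjectionConfig:
    """Settings for the weighted annual-rate-of-change projection."""

    transform: str
    horizon_year: int
    omega: Optional[float] = None
    omega_grid: Sequence[float] = field(
        default_factory=lambda: tuple(np.arange(0.0, 3.0 + 1e-9, 0.25))
    )
    holdout_years: int = 3

    def __post_init__(self):
        if self.transform not in TRANSFORMS:
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.holdout_years < 1:
            raise ValueError("holdout_years must be positive")
        if self.omega is not None and self.omega < 0:
            raise ValueError("omega must be non-negative")


@dataclass(frozen=True)
class ProjectionResult:
    """Projected value for one series at the horizon year."""

    location_id: str
    indicator_id: str
    sex: str
    horizon_year: int
    projected_value: float
    omega_used: float
    fit_window: tuple[int, int]
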