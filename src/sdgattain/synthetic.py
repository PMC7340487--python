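"""Synthetic province x indicator x sex x year panels.

The generator emulates the statistical structure the projection model
assumes: each series is log-linear (more generally, linear in the
indicator's transform space) with an optional quadratic acceleration,
constant additive region and sex effects, a per-province offset, and
i.i.d. Gaussian noise, all in transform space:

    f(x_{p,i,s,t}) = f(baseline) + r (t - 1990) + a (t - 1990)^2
                     + delta_region + delta_sex + delta_province + eps,
    eps ~ Normal(0, sigma^2).

Additive-in-transform noise keeps log indicators positive and logit
indicators inside (0, 1), matching the model's assumptions exactly;
what it does not emulate is burden-of-disease-study cross-indicator covariance or
uncertainty intervals.  The sex effect is carried entirely by males
(females sit at the base level), so on a log indicator a sex effect of
ln k yields a male/female ratio of k at every year.  The "both" sex is
the transform-space midpoint of male and female.

Default levels and trends are set to the magnitudes national series
report for China around 1990-2016 (e.g. under-5 mortality falling from
~54 to ~10 per 1,000; overweight rising; PM2.5 near 50 ug/m3), so the
default scenario is a caricature of the study conditions, not a fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import SdgAttainError
from .model import IndicatorDefinition, PANEL_COLUMNS, transform_forward, transform_inverse
from .registry import load_registry, registry_index

# Provincial grouping into eastern/central/western follows the official
# statistical categorisation; the two SARs are tagged separately and
# excluded from regional means.
PROVINCES: dict[str, str] = {
    "Beijing": "eastern", "Tianjin": "eastern", "Hebei": "eastern",
    "Liaoning": "eastern", "Shanghai": "eastern", "Jiangsu": "eastern",
    "Zhejiang": "eastern", "Fujian": "eastern", "Shandong": "eastern",
    "Guangdong": "eastern", "Hainan": "eastern",
    "Shanxi": "central", "Jilin": "central", "Heilongjiang": "central",
    "Anhui": "central", "Jiangxi": "central", "Henan": "central",
    "Hubei": "central", "Hunan": "central", "Inner Mongolia": "central",
    "Chongqing": "western", "Guangxi": "western", "Sichuan": "western",
    "Guizhou": "western", "Yunnan": "western", "Tibet": "western",
    "Shaanxi": "western", "Gansu": "western", "Qinghai": "western",
    "Ningxia": "western", "Xinjiang": "western",
}

NATIONAL_LOCATION = "China"


def region_map(include_national: bool = False) -> dict[str, str]:
    m = dict(PROVINCES)
    if include_national:
        m[NATIONAL_LOCATION] = "national"
    return m


@dataclass(frozen=True)
class IndicatorScenario:
    """Per-indicator generating parameters, all in transform space
    except ``baseline`` (indicator units at 1990)."""

    baseline: float
    rate: float
    accel: float = 0.0
    sex_effect: float = 0.0
    region_effect: float = 0.0  # +region_effect for western, - for eastern
    sigma: float = 0.0


@dataclass(frozen=True)
class ScenarioSpec:
    """Full panel scenario; ``seed`` is mandatory and fully determines output."""

    seed: int
    indicators: Mapping[str, IndicatorScenario]
    n_provinces: int = 31
    years: tuple[int, int] = (1990, 2016)
    sexes: tuple[str, ...] = ("male", "female", "both")
    include_national: bool = True
    province_jitter: float = 0.03

    def __post_init__(self):
        if not (1 <= self.n_provinces <= len(PROVINCES)):
            raise SdgAttainError(f"n_provinces must be in [1, {len(PROVINCES)}]")
        for ind, sc in self.indicators.items():
            if sc.sigma < 0:
                raise SdgAttainError(f"{ind}: sigma must be non-negative")


_REGION_SIGN = {"eastern": -1.0, "central": 0.0, "western": 1.0, "national": 0.0, "SAR": 0.0}

# Baseline 1990 levels and transform-space annual drifts of the default
# scenario, by indicator.  Rising risk-factor trends (overweight,
# alcohol) and falling mortality mirror the direction of the national
# series; magnitudes are round numbers of the right order.
_DEFAULT_PARAMS: dict[str, tuple[float, float, float, float, float]] = {
    # indicator_id: (baseline, rate, accel, sex_effect, region_effect)
    "2.2.1": (33.0, -1.00, 0.0, 1.0, 3.0),
    "2.2.2a": (3.5, -0.06, 0.0, 0.1, 0.4),
    "2.2.2b": (3.0, 0.20, 0.002, 0.8, -0.5),
    "3.1.1": (95.0, -0.060, 0.0, 0.0, 0.35),
    "3.1.2": (0.50, 0.150, 0.0, 0.0, -0.4),
    "3.2.1": (54.0, -0.064, 0.0, math.log(1.15), 0.40),
    "3.2.2": (30.0, -0.070, 0.0, math.log(1.15), 0.40),
    "3.b.1": (0.70, 0.120, 0.0, 0.0, -0.3),
    "3.7.1": (0.60, 0.030, 0.0, 0.0, -0.2),
    "3.3.1": (2.0, 0.020, 0.0, math.log(3.5), 0.30),
    "3.3.2": (120.0, -0.025, 0.0, math.log(1.8), 0.25),
    "3.3.3": (2.0, -0.120, 0.0, math.log(1.3), 0.30),
    "3.3.4": (90.0, -0.010, 0.0, math.log(1.7), 0.10),
    "3.3.5": (5.0, -0.12, 0.0, 0.3, 0.8),
    "3.4.1": (650.0, -0.012, 0.0, math.log(1.5), 0.10),
    "3.4.2": (14.0, -0.035, 0.0, math.log(1.2), 0.10),
    "3.5.2": (4.0, 0.15, 0.0, 5.0, -0.5),
    "3.a.1": (30.0, -0.15, 0.0, 25.0, -1.0),
    "3.6.1": (20.0, -0.010, -0.0008, math.log(2.8), 0.15),
    "3.9.1": (120.0, -0.020, 0.0, math.log(1.4), 0.15),
    "3.9.2": (6.0, -0.080, 0.0, math.log(1.1), 0.35),
    "3.9.3": (4.0, -0.040, 0.0, math.log(1.3), 0.20),
    "6.1.1": (40.0, -0.90, 0.0, 0.0, 6.0),
    "6.2.1a": (60.0, -1.40, 0.0, 0.0, 8.0),
    "6.2.1b": (50.0, -1.00, 0.0, 0.0, 6.0),
    "7.1.2": (60.0, -1.50, 0.0, 0.0, 8.0),
    "11.6.2": (70.0, -0.50, 0.0, 0.0, -8.0),
    "3.8.1": (40.0, 0.90, 0.0, 0.0, -5.0),
}

_DEFAULT_SIGMA = {"log": 0.02, "logit": 0.02, "linear": None}  # linear: 1% of baseline


def default_scenario(
    seed: int,
    registry: Iterable[IndicatorDefinition] | None = None,
    sigma_scale: float = 1.0,
) -> ScenarioSpec:
    """The standard 31-province, 28-indicator, 1990-2016 scenario."""
    registry = load_registry() if registry is None else list(registry)
    defs = registry_index(registry)
    indicators = {}
    for ind, (baseline, rate, accel, sex, region) in _DEFAULT_PARAMS.items():
        transform = defs[ind].transform
        sigma = _DEFAULT_SIGMA[transform]
        if sigma is None:
            sigma = 0.01 * baseline
        indicators[ind] = IndicatorScenario(
            baseline=baseline, rate=rate, accel=accel, sex_effect=sex,
            region_effect=region, sigma=sigma * sigma_scale,
        )
    return ScenarioSpec(seed=seed, indicators=indicators)


def _clip_to_domain(transform: str, f_values: np.ndarray) -> np.ndarray:
    """Guard logit saturation for numerical safety; other transforms are
    unbounded in transform space."""
    if transform == "logit":
        return np.clip(f_values, -12.0, 12.0)
    return f_values


def generate_panel(
    spec: ScenarioSpec,
    registry: Iterable[IndicatorDefinition] | None = None,
) -> pd.DataFrame:
    """Generate a long-format panel from a scenario.

    Deterministic for a given seed.  Raises when a scenario baseline
    violates its indicator's transform domain.
    """
    registry = load_registry() if registry is None else list(registry)
    defs = registry_index(registry)
    rng = np.random.default_rng(spec.seed)
    y0, y1 = spec.years
    years = np.arange(y0, y1 + 1)
    t = (years - 1990).astype(float)

    locations = [(NATIONAL_LOCATION, "national")] if spec.include_national else []
    locations += list(PROVINCES.items())[: spec.n_provinces]

    jitter = {
        loc: (0.0 if region == "national" else rng.normal(0.0, spec.province_jitter))
        for loc, region in locations
    }

    rows = []
    for ind, sc in spec.indicators.items():
        if ind not in defs:
            raise SdgAttainError(f"scenario indicator {ind!r} not in registry")
        definition = defs[ind]
        transform = definition.transform
        f0 = float(transform_forward(transform, sc.baseline))
        base_scale = 1.0 if transform != "linear" else max(abs(sc.baseline), 1.0)
        for loc, region in locations:
            trend = f0 + sc.rate * t + sc.accel * t ** 2
            trend = trend + _REGION_SIGN[region] * sc.region_effect
            trend = trend + jitter[loc] * base_scale
            eps_m = rng.normal(0.0, sc.sigma, size=len(years)) if sc.sigma > 0 else 0.0
            eps_f = rng.normal(0.0, sc.sigma, size=len(years)) if sc.sigma > 0 else 0.0
            f_male = _clip_to_domain(transform, trend + sc.sex_effect + eps_m)
            f_female = _clip_to_domain(transform, trend + eps_f)
            f_both = (f_male + f_female) / 2.0
            by_sex = {"male": f_male, "female": f_female, "both": f_both}
            for sex in spec.sexes:
                values = np.asarray(transform_inverse(transform, by_sex[sex]), dtype=float)
                if transform == "linear":
                    values = np.maximum(values, 0.0)
                for year, value in zip(years, values):
                    rows.append((loc, region, ind, sex, int(year), float(value)))
    return pd.DataFrame(rows, columns=PANEL_COLUMNS)


def scenario_from_yaml(path) -> ScenarioSpec:
    """Load a scenario from a YAML config.

    Top-level keys mirror :class:`ScenarioSpec`; ``indicators`` maps
    indicator ids to :class:`IndicatorScenario` fields.  ``seed`` is
    required.
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if "seed" not in raw:
        raise SdgAttainError("scenario config must set a seed")
    indicators = {
        ind: IndicatorScenario(**params)
        for ind, params in raw.pop("indicators").items()
    }
    if "years" in raw:
        raw["years"] = tuple(raw["years"])
    if "sexes" in raw:
        raw["sexes"] = tuple(raw["sexes"])
    return ScenarioSpec(indicators=indicators, **raw)


# ---------------------------------------------------------------------------
# Designed achievement scenarios


def _achieved_rate(definition: IndicatorDefinition, baseline: float) -> tuple[float, float]:
    """(rate, baseline) in transform space making the indicator clear its
    target comfortably by its target year under constant-rate projection."""
    ty = definition.target_year
    span = ty - 1990
    if definition.target_type == "relative_reduction":
        # for a pure exponential the 2015-referenced target moves with the
        # series: need e^{r (ty - baseline_year)} <= margin * (1 - v)
        margin = 0.7
        byr = definition.baseline_year
        rate = math.log(margin * (1.0 - definition.target_value)) / (ty - byr)
        if definition.transform == "linear":
            # same geometry executed on the raw scale via a log-shaped path is
            # unnecessary; a straight line through margin*(1-v)*x(byr) works
            # because the target is resolved from the realised 2015 value.
            slope = baseline * (margin * (1.0 - definition.target_value) - 1.0) / (ty - byr)
            # anchor the line so x(byr) = baseline
            return slope, baseline - slope * (byr - 1990)
        return rate, baseline
    if definition.target_type == "no_increase":
        return (-0.02, baseline) if definition.transform != "linear" else (-0.01 * baseline, baseline)
    if definition.target_type == "elimination":
        slope = -0.95 * baseline / span
        return slope, baseline
    # absolute
    target = float(definition.target_value)
    if definition.direction == "higher_better":
        if definition.transform == "logit":
            goal = min(0.999, target + 0.6 * (1.0 - target))
            f0 = transform_forward("logit", baseline)
            f1 = transform_forward("logit", goal)
            return float(f1 - f0) / span, baseline
        goal = target - 0.05 * abs(target)  # e.g. UHC index target 100 -> 95
        return (goal - baseline) / span, baseline
    if definition.transform == "log":
        return math.log(0.7 * target / baseline) / span, baseline
    return (0.7 * target - baseline) / span, baseline


def make_achievement_scenario(
    n_achieved_target: int,
    seed: int,
    registry: Iterable[IndicatorDefinition] | None = None,
    n_provinces: int = 31,
) -> pd.DataFrame:
    """Panel designed so the full pipeline (scale -> project -> threshold)
    counts exactly ``n_achieved_target`` achieved indicators nationally.

    The first ``n_achieved_target`` registry indicators get trends that
    clear their targets well before the target year (scores clip to
    100); the rest get near-flat or adversarial trends whose projected
    scores stay far below the 90-point threshold.  Noiseless by design
    so the count is exact; the seed only fixes province offsets, which
    are zero here.
    """
    registry = load_registry() if registry is None else list(registry)
    if not (0 <= n_achieved_target <= len(registry)):
        raise SdgAttainError(
            f"n_achieved_target must be within [0, {len(registry)}]"
        )
    achieved_ids = {d.indicator_id for d in registry[:n_achieved_target]}

    y0, y1 = 1990, 2016
    years = np.arange(y0, y1 + 1)
    t = (years - 1990).astype(float)
    locations = [(NATIONAL_LOCATION, "national")] + list(PROVINCES.items())[:n_provinces]

    rows = []
    for definition in registry:
        ind = definition.indicator_id
        transform = definition.transform
        baseline, _, _, _, _ = _DEFAULT_PARAMS[ind]
        if ind in achieved_ids:
            rate, b0 = _achieved_rate(definition, baseline)
            f0 = float(transform_forward(transform, b0)) if transform != "linear" else b0
            f_path = f0 + rate * t
        else:
            f_path = _failed_path(definition, baseline, t)
        f_path = _clip_to_domain(transform, np.asarray(f_path, dtype=float))
        values = np.asarray(transform_inverse(transform, f_path), dtype=float)
        if transform == "linear":
            values = np.maximum(values, 0.0)
        for loc, region in locations:
            for year, value in zip(years, values):
                rows.append((loc, region, ind, "both", int(year), float(value)))
    return pd.DataFrame(rows, columns=PANEL_COLUMNS)


def _failed_path(definition: IndicatorDefinition, baseline: float, t: np.ndarray) -> np.ndarray:
    """Transform-space path whose projected score stays far below 90."""
    transform = definition.transform
    if definition.target_type == "no_increase":
        # constant at baseline with a 10% dip in the baseline year and a
        # rebound after: target = 0.9 baseline, worst = baseline, projection
        # hovers at the worst anchor -> score near 0
        f0 = float(transform_forward(transform, baseline)) if transform != "linear" else baseline
        dip = math.log(0.9) if transform != "linear" else -0.1 * baseline
        path = np.full_like(t, f0, dtype=float)
        byr_idx = int(definition.baseline_year - 1990)
        if 0 <= byr_idx < len(path):
            path[byr_idx] += dip
        return path
    if (
        definition.target_type == "absolute"
        and definition.direction == "lower_better"
        and baseline <= float(definition.target_value)
    ):
        # history already at/below the target would score 100 however flat
        # the trend; start the failing series on the bad side instead
        baseline = 1.6 * float(definition.target_value)
    f0 = float(transform_forward(transform, baseline)) if transform != "linear" else baseline
    drift = -0.002 if transform != "linear" else -0.002 * max(abs(baseline), 1.0)
    return f0 + drift * t
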