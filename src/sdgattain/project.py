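"""Trend projection by recency-weighted mean annual rate of change.

The drift of a series is estimated in transform space as a weighted
mean of consecutive-year changes r_t = f(x_t) - f(x_{t-1}).  Weights
rise with recency as (t - first_year + 1)^omega, normalised to sum 1;
omega = 0 is the uniform-weight annualised rate of change and larger
omega leans harder on recent years.  omega is chosen per series from a
grid by backcasting: the series is refit without its final
``holdout_years`` observations, each candidate omega projects those
years, and the omega with the smallest mean absolute error (in
indicator units) wins, ties going to the smallest omega.  Projection
then extends the full series linearly in transform space,
f(x_{T+h}) = f(x_T) + h * rbar, and back-transforms, so log indicators
stay positive and logit indicators stay inside (0, 1) by construction.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, SdgAttainError
from .model import (
    IndicatorDefinition, PROJECTION_COLUMNS, ProjectionConfig, ProjectionResult,
    transform_forward, transform_inverse,
)
from .registry import registry_index
from .scaling import fill_log_zeros

logger = logging.getLogger(__name__)

DEFAULT_OMEGA_GRID: tuple[float, ...] = tuple(np.arange(0.0, 3.0 + 1e-9, 0.25))
DEFAULT_HOLDOUT_YEARS = 3
FALLBACK_OMEGA = 1.0
MAX_GAP_YEARS = 5


def _prepare(series: pd.Series, transform: str) -> pd.Series:
    """Sort by year, impute log-zeros, interpolate interior gaps in transform space."""
    series = series.sort_index()
    if transform == "log":
        series = fill_log_zeros(series)
    years = series.index.to_numpy(dtype=int)
    if len(years) >= 2:
        gaps = np.diff(years)
        if gaps.max(initial=1) > MAX_GAP_YEARS + 1:
            raise InsufficientDataError(
                f"more than {MAX_GAP_YEARS} consecutive missing years in series"
            )
        if gaps.max(initial=1) > 1:
            full = np.arange(years[0], years[-1] + 1)
            fy = np.asarray(transform_forward(transform, series.to_numpy()), dtype=float)
            interp = np.interp(full, years, fy)
            series = pd.Series(transform_inverse(transform, interp), index=full)
    return series


def annual_log_changes(series: pd.Series, transform: str) -> np.ndarray:
    """Consecutive-year changes f(x_t) - f(x_{t-1}) in transform space.

    Interior gaps are linearly interpolated in transform space first;
    runs of more than five missing years raise.
    """
    series = _prepare(series, transform)
    if len(series) < 2:
        raise InsufficientDataError("need >= 2 years to form annual changes")
    f = np.asarray(transform_forward(transform, series.to_numpy()), dtype=float)
    return np.diff(f)


def recency_weights(years: Sequence[int], omega: float) -> np.ndarray:
    """Normalised weights w_t proportional to (t - first_year + 1)^omega."""
    if omega < 0:
        raise ValueError("omega must be non-negative")
    years = np.asarray(years, dtype=float)
    ranks = years - years.min() + 1.0
    w = ranks ** float(omega)
    return w / w.sum()


def weighted_mean_aroc(changes: Sequence[float], weights: Sequence[float]) -> float:
    """Weighted mean annual rate of change, sum_t w_t r_t."""
    changes = np.asarray(changes, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if changes.shape != weights.shape:
        raise ValueError("changes and weights must have equal length")
    return float(np.dot(weights, changes))


def _series_rate(series: pd.Series, transform: str, omega: float) -> float:
    changes = annual_log_changes(series, transform)
    change_years = _prepare(series, transform).index.to_numpy(dtype=int)[1:]
    return weighted_mean_aroc(changes, recency_weights(change_years, omega))


def select_omega(
    series: pd.Series,
    transform: str,
    omega_grid: Sequence[float] = DEFAULT_OMEGA_GRID,
    holdout_years: int = DEFAULT_HOLDOUT_YEARS,
) -> float:
    """Pick omega by backcast mean absolute error on the final held-out years.

    Falls back to omega = 1 (with a warning) when the series is too
    short to hold anything out.  Ties break toward the smallest omega;
    an exactly constant-rate series therefore returns the grid minimum.
    """
    series = _prepare(series, transform)
    if len(series) <= holdout_years + 2:
        logger.warning("series too short for omega selection (n=%d); fallback omega=%s",
                       len(series), FALLBACK_OMEGA)
        return FALLBACK_OMEGA
    train = series.iloc[:-holdout_years]
    held = series.iloc[-holdout_years:]
    last_year = int(train.index[-1])
    f_last = float(transform_forward(transform, train.iloc[-1]))
    best_omega, best_mae = None, np.inf
    for omega in sorted(omega_grid):
        rate = _series_rate(train, transform, omega)
        preds = [
            float(transform_inverse(transform, f_last + (int(y) - last_year) * rate))
            for y in held.index
        ]
        mae = float(np.mean(np.abs(np.asarray(preds) - held.to_numpy(dtype=float))))
        if mae < best_mae * (1.0 - 1e-12) - 1e-300:
            best_omega, best_mae = float(omega), mae
    return best_omega if best_omega is not None else FALLBACK_OMEGA


def project_series(series: pd.Series, config: ProjectionConfig) -> tuple[pd.Series, float]:
    """Project a year-indexed series to ``config.horizon_year``.

    Returns the yearly projected path (last observed year + 1 through
    the horizon, in indicator units) and the omega used.  omega comes
    from ``config.omega`` when set, otherwise from backcast selection.
    """
    series = _prepare(series, config.transform)
    last_year = int(series.index[-1])
    if last_year >= config.horizon_year:
        raise SdgAttainError(
            f"last observed year {last_year} is not before horizon {config.horizon_year}"
        )
    omega = config.omega
    if omega is None:
        omega = select_omega(series, config.transform, config.omega_grid, config.holdout_years)
    rate = _series_rate(series, config.transform, omega)
    f_last = float(transform_forward(config.transform, series.iloc[-1]))
    horizon = np.arange(last_year + 1, config.horizon_year + 1)
    path = transform_inverse(config.transform, f_last + (horizon - last_year) * rate)
    return pd.Series(np.asarray(path, dtype=float), index=horizon), float(omega)


def project_panel(
    panel: pd.DataFrame,
    registry: Iterable[IndicatorDefinition],
    omega_grid: Sequence[float] = DEFAULT_OMEGA_GRID,
    holdout_years: int = DEFAULT_HOLDOUT_YEARS,
    horizon_year: int = 2030,
) -> tuple[pd.DataFrame, list[ProjectionResult]]:
    """Project every (location, indicator, sex) series of a panel.

    Returns (a) a long projections frame with the yearly paths from the
    first unobserved year through ``horizon_year`` and (b) per-series
    :class:`ProjectionResult` records at each indicator's own target
    year.  Per-series failures are logged and skipped.
    """
    defs = registry_index(registry)
    rows = []
    results: list[ProjectionResult] = []
    failures = []
    for (loc, ind, sex), sub in panel.groupby(
        ["location_id", "indicator_id", "sex"], sort=False
    ):
        definition = defs[ind]
        series = sub.set_index("year")["value"].sort_index()
        config = ProjectionConfig(
            transform=definition.transform,
            horizon_year=horizon_year,
            omega_grid=tuple(omega_grid),
            holdout_years=holdout_years,
        )
        try:
            path, omega = project_series(series, config)
        except SdgAttainError as exc:
            failures.append((loc, ind, sex, str(exc)))
            continue
        for year, value in path.items():
            rows.append((loc, ind, sex, int(year), float(value), omega))
        ty = definition.target_year
        value_at_target = float(path.loc[ty]) if ty in path.index else float(series.loc[ty])
        results.append(ProjectionResult(
            location_id=loc, indicator_id=ind, sex=sex, horizon_year=ty,
            projected_value=value_at_target, omega_used=omega,
            fit_window=(int(series.index[0]), int(series.index[-1])),
        ))
    if failures:
        logger.warning(
            "project_panel skipped %d series: %s", len(failures),
            "; ".join(f"{l}/{i}/{s}: {m}" for l, i, s, m in failures[:5]),
        )
    return pd.DataFrame(rows, columns=PROJECTION_COLUMNS), results
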