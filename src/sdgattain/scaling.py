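"""Attainment-index scaling: raw indicator values -> 0-100 scores.

The index anchors each indicator at two points: the worst value the
location recorded over 1990-2015 (after trimming Tukey-fence outliers)
maps to 0, and the resolved SDG/WHO target maps to 100.  Scores
interpolate linearly between the anchors in the indicator's transform
space (log for incidence and mortality rates, logit for bounded
proportions, identity otherwise) and are clipped to [0, 100], so
over-achievement reads 100 and post-window deterioration reads 0.

Target resolution follows the registry's target_type:

* ``absolute``            -> the stated value in indicator units
* ``relative_reduction``  -> baseline-year value x (1 - fraction)
* ``no_increase``         -> the baseline-year value itself
* ``elimination``         -> 0 (linear-transform indicators only)
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegenerateAnchorError, DomainError, InsufficientDataError, SdgAttainError,
)
from .model import (
    ANCHOR_WINDOW, AnchorPair, IndicatorDefinition, SCORE_COLUMNS,
    transform_forward,
)
from .registry import registry_index

logger = logging.getLogger(__name__)


def tukey_outlier_mask(values: Sequence[float]) -> np.ndarray:
    """Boolean mask of values outside the Tukey fences Q1/Q3 +/- 1.5 IQR.

    Quartiles use linear interpolation between order statistics (the
    numpy default, "type 7").  Single pass: the mask is computed once on
    the input, never iterated on the retained values.  Requires at
    least four observations.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError("values must be one-dimensional")
    if arr.size < 4:
        raise InsufficientDataError(f"need >= 4 values for Tukey fences, got {arr.size}")
    if not np.all(np.isfinite(arr)):
        raise DomainError("non-finite value in outlier screen")
    q1, q3 = np.percentile(arr, [25.0, 75.0])
    iqr = q3 - q1
    return (arr < q1 - 1.5 * iqr) | (arr > q3 + 1.5 * iqr)


def resolve_target(
    definition: IndicatorDefinition,
    series: pd.Series | None = None,
) -> float:
    """Resolve the 100-anchor in indicator units.

    ``series`` (year-indexed values) is required for relative-reduction
    and no-increase targets whose baseline year must be looked up.
    """
    tt = definition.target_type
    if tt == "absolute":
        return float(definition.target_value)
    if tt == "elimination":
        if definition.transform == "log":
            raise DomainError(
                f"{definition.indicator_id}: elimination target incompatible with log transform"
            )
        return 0.0
    if series is None:
        raise SdgAttainError(
            f"{definition.indicator_id}: {tt} target needs the location's series"
        )
    by = definition.baseline_year
    if by not in series.index:
        raise InsufficientDataError(
            f"{definition.indicator_id}: baseline year {by} missing from series"
        )
    baseline = float(series.loc[by])
    if tt == "relative_reduction":
        return baseline * (1.0 - float(definition.target_value))
    if tt == "no_increase":
        return baseline
    raise ValueError(f"unknown target_type {tt!r}")


def resolve_anchors(
    series: pd.Series,
    definition: IndicatorDefinition,
    anchor_window: tuple[int, int] = ANCHOR_WINDOW,
) -> AnchorPair:
    """Compute the (worst, target) anchor pair for one series.

    ``series`` is indexed by calendar year in indicator units.  The
    worst anchor is the max (lower-better) or min (higher-better) of
    the within-window values that survive the Tukey screen.
    """
    lo, hi = anchor_window
    window = series.loc[(series.index >= lo) & (series.index <= hi)].sort_index()
    if len(window) < 4:
        raise InsufficientDataError(
            f"{definition.indicator_id}: need >= 4 anchor-window years, got {len(window)}"
        )
    mask = tukey_outlier_mask(window.to_numpy())
    retained = window.to_numpy()[~mask]
    if retained.size == 0:  # cannot happen with 1.5-IQR fences, kept for safety
        retained = window.to_numpy()
    worst = float(retained.max() if definition.direction == "lower_better" else retained.min())
    target = resolve_target(definition, series)
    if np.allclose(retained, target, rtol=1e-12, atol=0.0):
        # an entire history flat at the target carries no scale information
        raise DegenerateAnchorError(
            f"{definition.indicator_id}: all retained values equal resolved target ({target})"
        )
    return AnchorPair(worst_value=worst, target_value_resolved=target, anchor_window=anchor_window)


def scale_value(x: float, anchors: AnchorPair, definition: IndicatorDefinition) -> float:
    """Scale one raw value onto the 0-100 attainment index.

    score = 100 * (f(x) - f(worst)) / (f(target) - f(worst)), with f the
    indicator's transform, clipped to [0, 100].  An elimination target
    of exactly 0 on a linear scale is handled by the identity transform;
    log-transform inputs must be strictly positive (zeros are imputed
    upstream, see :func:`fill_log_zeros`).
    """
    worst, target = anchors.worst_value, anchors.target_value_resolved
    if definition.direction == "lower_better":
        meets = x <= target
        ill_posed = worst <= target
    else:
        meets = x >= target
        ill_posed = worst >= target
    if ill_posed:
        # the anchor window already met the target throughout (e.g. child
        # wasting never above the 5% goal), or the worst value IS the
        # no-increase baseline on a monotonically worsening series: the
        # 0-anchor does not sit on the bad side of the 100-anchor and
        # interpolation is undefined, so score by target attainment alone
        return 100.0 if meets else 0.0
    transform = definition.transform
    fx = float(transform_forward(transform, x))
    f_worst = float(transform_forward(transform, anchors.worst_value))
    f_target = float(transform_forward(transform, anchors.target_value_resolved))
    denom = f_target - f_worst
    if denom == 0.0:
        raise DegenerateAnchorError(f"{definition.indicator_id}: degenerate anchors")
    score = 100.0 * (fx - f_worst) / denom
    return float(np.clip(score, 0.0, 100.0))


def fill_log_zeros(series: pd.Series) -> pd.Series:
    """Replace zeros in a log-indicator series by half its smallest positive value.

    Keeps elimination successes (e.g. a disease driven to zero incidence)
    scorable: the imputed value lies beyond any positive target, so the
    score clips to 100.
    """
    vals = series.to_numpy(dtype=float)
    if np.all(vals > 0):
        return series
    positive = vals[vals > 0]
    if positive.size == 0:
        raise DomainError("series is identically zero; log scale undefined")
    out = series.copy()
    out[out == 0] = positive.min() / 2.0
    return out


def scale_series(
    series: pd.Series,
    definition: IndicatorDefinition,
    anchors: AnchorPair | None = None,
    anchor_window: tuple[int, int] = ANCHOR_WINDOW,
) -> tuple[pd.Series, AnchorPair]:
    """Scale a year-indexed series; resolves anchors from it when not given."""
    zeros = None
    if definition.transform == "log":
        zeros = series == 0
        series = fill_log_zeros(series)
    if anchors is None:
        anchors = resolve_anchors(series, definition, anchor_window)
    if zeros is not None and zeros.any() and anchors.target_value_resolved > 0:
        # a true zero meets any positive target: cap the imputed value at
        # half the target so elimination successes clip to 100
        fill = min(float(series[zeros].iloc[0]), anchors.target_value_resolved / 2.0)
        series = series.copy()
        series[zeros] = fill
    scores = series.map(lambda x: scale_value(x, anchors, definition))
    return scores, anchors


def scale_panel(
    panel: pd.DataFrame,
    registry: Iterable[IndicatorDefinition],
    national_anchors: bool = False,
    national_location: str = "China",
    anchor_window: tuple[int, int] = ANCHOR_WINDOW,
) -> pd.DataFrame:
    """Scale every (location, indicator, sex) series of a panel.

    Anchors are resolved per series from that stratum's own 1990-2015
    history; with ``national_anchors=True`` every location borrows the
    national series' anchors instead, reproducing a single-country
    reading of the scale.  Per-series failures are logged and skipped
    so one bad series does not poison the panel.

    Returns a scores frame with audit columns ``worst`` and ``target``.
    """
    defs = registry_index(registry)
    national = {}
    if national_anchors:
        nat = panel[panel["location_id"] == national_location]
        for (ind, sex), sub in nat.groupby(["indicator_id", "sex"], sort=False):
            series = sub.set_index("year")["value"].sort_index()
            try:
                if defs[ind].transform == "log":
                    series = fill_log_zeros(series)
                national[(ind, sex)] = resolve_anchors(series, defs[ind], anchor_window)
            except SdgAttainError as exc:
                logger.warning("national anchors for %s/%s failed: %s", ind, sex, exc)

    rows = []
    failures = []
    for (loc, ind, sex), sub in panel.groupby(
        ["location_id", "indicator_id", "sex"], sort=False
    ):
        definition = defs[ind]
        series = sub.set_index("year")["value"].sort_index()
        anchors = national.get((ind, sex)) if national_anchors else None
        try:
            scores, anchors = scale_series(series, definition, anchors, anchor_window)
        except SdgAttainError as exc:
            failures.append((loc, ind, sex, str(exc)))
            continue
        for year, score in scores.items():
            rows.append((loc, ind, sex, int(year), score,
                         anchors.worst_value, anchors.target_value_resolved))
    if failures:
        logger.warning(
            "scale_panel skipped %d series: %s", len(failures),
            "; ".join(f"{l}/{i}/{s}: {m}" for l, i, s, m in failures[:5]),
        )
    return pd.DataFrame(rows, columns=SCORE_COLUMNS)
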