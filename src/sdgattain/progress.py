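"""Achievement counts, annual change rates, and disparity ratios.

An indicator counts as achieved when its attainment score at the
indicator's own target year is at or above 90 (inclusive).  Annual
change rates are endpoint arithmetic, (end - start) / years.
Disparity ratios are plain quotients reported in the stated
numerator/denominator order (rural/urban, male/female,
western/eastern), never auto-flipped.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import pandas as pd

from .errors import SdgAttainError
from .model import IndicatorDefinition
from .registry import registry_index, topic_members

logger = logging.getLogger(__name__)

ACHIEVEMENT_THRESHOLD = 90.0


def count_achieved(
    scores_at_target_year: Mapping[str, float] | pd.Series,
    threshold: float = ACHIEVEMENT_THRESHOLD,
    expected: int | None = None,
) -> int:
    """Count indicators whose score meets or exceeds ``threshold``."""
    if isinstance(scores_at_target_year, pd.Series):
        scores_at_target_year = scores_at_target_year.to_dict()
    if expected is not None and len(scores_at_target_year) < expected:
        logger.warning("count_achieved over %d of %d expected indicators",
                       len(scores_at_target_year), expected)
    return int(sum(1 for s in scores_at_target_year.values() if s >= threshold))


def annual_change_rate(
    index_start: float, index_end: float, year_start: int, year_end: int
) -> float:
    """Index points per year: (end - start) / (year_end - year_start)."""
    if year_end == year_start:
        raise SdgAttainError("zero year span in annual change rate")
    return (index_end - index_start) / (year_end - year_start)


def disparity_ratio(value_a: float, value_b: float) -> float:
    """Stratum ratio a/b (e.g. rural/urban, male/female)."""
    if value_b == 0:
        raise SdgAttainError("disparity ratio with zero denominator")
    return value_a / value_b


def achievement_summary(
    scores: pd.DataFrame,
    registry: Iterable[IndicatorDefinition],
    threshold: float = ACHIEVEMENT_THRESHOLD,
    sex: str = "both",
) -> pd.DataFrame:
    """Per-location achieved counts at each indicator's target year.

    ``scores`` must cover the target years (i.e. include projected
    years).  Returns columns location_id, n_achieved, n_total.
    """
    defs = registry_index(registry)
    sub = scores[scores["sex"] == sex]
    rows = []
    for loc, group in sub.groupby("location_id", sort=True):
        at_target = {}
        for ind, g in group.groupby("indicator_id", sort=False):
            ty = defs[ind].target_year
            hit = g[g["year"] == ty]
            if len(hit):
                at_target[ind] = float(hit["score"].iloc[0])
        n = count_achieved(at_target, threshold, expected=len(defs))
        rows.append((loc, n, len(defs)))
    return pd.DataFrame(rows, columns=["location_id", "n_achieved", "n_total"])


def topic_change_rates(
    topics: pd.DataFrame,
    registry: Iterable[IndicatorDefinition],
    start_year: int = 2016,
) -> pd.DataFrame:
    """Annual change rate of each topic index from ``start_year`` to the
    topic's horizon (the latest target year among its members)."""
    horizons = {
        t: max(d.target_year for d in registry if d.topic == t)
        for t in topic_members(registry)
    }
    rows = []
    for (loc, topic), group in topics.groupby(["location_id", "topic"], sort=True):
        end_year = horizons[topic]
        g = group.set_index("year")["index"]
        if start_year not in g.index or end_year not in g.index:
            continue
        rate = annual_change_rate(g.loc[start_year], g.loc[end_year], start_year, end_year)
        rows.append((loc, topic, start_year, end_year,
                     float(g.loc[start_year]), float(g.loc[end_year]), rate))
    return pd.DataFrame(rows, columns=[
        "location_id", "topic", "year_start", "year_end",
        "index_start", "index_end", "annual_change_rate",
    ])


def regional_summary(
    topic_indices: pd.DataFrame,
    region_map: Mapping[str, str],
) -> pd.DataFrame:
    """Unweighted per-region mean/min/max of topic indices.

    Every location must appear in ``region_map``; mappings to "SAR" or
    "national" are excluded from the regional means, anything unmapped
    raises.
    """
    unmapped = set(topic_indices["location_id"]) - set(region_map)
    if unmapped:
        raise SdgAttainError(f"locations without a region mapping: {sorted(unmapped)}")
    rows = []
    for (topic, year), group in topic_indices.groupby(["topic", "year"], sort=True):
        by_region: dict[str, list[float]] = {}
        for loc, idx in zip(group["location_id"], group["index"]):
            region = region_map[loc]
            if region in ("SAR", "national"):
                continue
            by_region.setdefault(region, []).append(float(idx))
        for region, vals in sorted(by_region.items()):
            s = pd.Series(vals)
            rows.append((region, topic, int(year), s.mean(), s.min(), s.max(), len(vals)))
    return pd.DataFrame(rows, columns=[
        "region", "topic", "year", "mean", "min", "max", "n_provinces",
    ])
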