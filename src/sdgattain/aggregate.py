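"""Thematic-topic indices: equal-weight geometric means with a floor at 1.

Member scores below 1 are raised to 1 before taking logs so the
geometric mean stays defined when an indicator bottoms out at 0; the
floor is applied to the unrounded scores.  Weights are equal across a
topic's members.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InsufficientDataError
from .model import IndicatorDefinition, TOPIC_COLUMNS
from .registry import topic_members

logger = logging.getLogger(__name__)

SCORE_FLOOR = 1.0


def floored_geometric_mean(scores: Sequence[float]) -> float:
    """exp(mean(ln(max(s, 1)))) over equal-weight member scores in [0, 100]."""
    arr = np.asarray(scores, dtype=float)
    if arr.size == 0:
        raise InsufficientDataError("geometric mean of an empty score list")
    if np.any(~np.isfinite(arr)) or np.any(arr < 0) or np.any(arr > 100):
        raise ValueError("scores must be finite and within [0, 100]")
    floored = np.maximum(arr, SCORE_FLOOR)
    return float(math.exp(np.mean(np.log(floored))))


def aggregate_topics(
    scores: pd.DataFrame,
    registry: Iterable[IndicatorDefinition],
    sex: str = "both",
) -> pd.DataFrame:
    """One floored-geometric-mean index per (location, topic, year).

    Aggregates the ``sex`` stratum of a scores frame (as produced by
    :func:`sdgattain.scaling.scale_panel`).  A topic with some members
    missing for a (location, year) aggregates over the available ones
    with a logged warning; a topic with none is skipped.
    """
    members = topic_members(registry)
    ind_topic = {i: t for t, ids in members.items() for i in ids}
    sub = scores[scores["sex"] == sex]
    rows = []
    short = 0
    for (loc, year), group in sub.groupby(["location_id", "year"], sort=True):
        by_ind = dict(zip(group["indicator_id"], group["score"]))
        for topic, ids in members.items():
            present = [i for i in ids if i in by_ind]
            if not present:
                continue
            if len(present) < len(ids):
                short += 1
            index = floored_geometric_mean([by_ind[i] for i in present])
            rows.append((loc, topic, int(year), index, len(present), list(present)))
    if short:
        logger.warning("aggregate_topics: %d (location, topic, year) cells aggregated "
                       "over a partial member set", short)
    frame = pd.DataFrame(rows, columns=TOPIC_COLUMNS)
    # guard referential sanity: every scored indicator belongs to a topic
    stray = set(sub["indicator_id"]) - set(ind_topic)
    if stray:
        logger.warning("scores contain indicators outside the registry topics: %s", sorted(stray))
    return frame
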