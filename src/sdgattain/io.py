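"""CSV readers/writers for panels, scores, topic indices, projections, reports.

All files are UTF-8 comma-separated with "." decimals.  The combined
report uses a ``table`` discriminator column so a single file can be
round-tripped back into its three constituent frames.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import ConsistencyError, DomainError, DuplicateKeyError, SchemaError
from .model import (
    IndicatorDefinition, PANEL_COLUMNS, PROJECTION_COLUMNS, REGIONS,
    SCORE_COLUMNS, SEXES, TOPIC_COLUMNS, YEAR_BOUNDS,
)
from .registry import registry_index

_KEY = ["location_id", "indicator_id", "sex", "year"]


def validate_panel(panel: pd.DataFrame, registry: Iterable[IndicatorDefinition]) -> pd.DataFrame:
    """Validate a long-format panel against the registry.

    Checks: schema, enum values, year bounds, duplicate keys,
    referential integrity, and transform domains (log values >= 0,
    logit values in [0, 1]).  Returns the panel with canonical column
    order and dtypes.
    """
    missing = [c for c in PANEL_COLUMNS if c not in panel.columns]
    if missing:
        raise SchemaError(f"panel missing columns: {missing}")
    panel = panel[PANEL_COLUMNS].copy()
    panel["year"] = panel["year"].astype(int)
    panel["value"] = panel["value"].astype(float)

    bad_sex = set(panel["sex"]) - set(SEXES)
    if bad_sex:
        raise SchemaError(f"unknown sex values: {sorted(bad_sex)}")
    bad_region = set(panel["region"]) - set(REGIONS)
    if bad_region:
        raise SchemaError(f"unknown region values: {sorted(bad_region)}")
    lo, hi = YEAR_BOUNDS
    if panel["year"].min() < lo or panel["year"].max() > hi:
        raise SchemaError(f"years must lie within [{lo}, {hi}]")

    dup = panel.duplicated(subset=_KEY)
    if dup.any():
        first = panel.loc[dup, _KEY].iloc[0].tolist()
        raise DuplicateKeyError(f"duplicate panel key {tuple(first)}")

    defs = registry_index(registry)
    unknown = set(panel["indicator_id"]) - set(defs)
    if unknown:
        raise SchemaError(f"panel references indicators not in registry: {sorted(unknown)}")

    for ind, sub in panel.groupby("indicator_id", sort=False):
        transform = defs[ind].transform
        vals = sub["value"].to_numpy()
        if not np.all(np.isfinite(vals)):
            key = sub.loc[~np.isfinite(sub["value"]), _KEY].iloc[0].tolist()
            raise DomainError(f"non-finite value at {tuple(key)}")
        if transform == "log" and np.any(vals < 0):
            key = sub.loc[sub["value"] < 0, _KEY].iloc[0].tolist()
            raise DomainError(f"negative value for log indicator at {tuple(key)}")
        if transform == "logit" and (np.any(vals < 0) or np.any(vals > 1)):
            bad = (sub["value"] < 0) | (sub["value"] > 1)
            key = sub.loc[bad, _KEY].iloc[0].tolist()
            raise DomainError(f"value outside [0, 1] for logit indicator at {tuple(key)}")
    return panel.reset_index(drop=True)


def read_panel(path: str | Path, registry: Iterable[IndicatorDefinition]) -> pd.DataFrame:
    """Read and validate a long-format indicator panel CSV."""
    frame = pd.read_csv(path, dtype={"indicator_id": str, "location_id": str})
    return validate_panel(frame, registry)


def write_panel(panel: pd.DataFrame, path: str | Path) -> None:
    panel[PANEL_COLUMNS].to_csv(path, index=False)


def write_scores(scores: pd.DataFrame, path: str | Path) -> None:
    scores[SCORE_COLUMNS].to_csv(path, index=False)


def read_scores(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"indicator_id": str, "location_id": str})


def write_topics(topics: pd.DataFrame, path: str | Path) -> None:
    topics[TOPIC_COLUMNS].to_csv(path, index=False)


def write_projections(projections: pd.DataFrame, path: str | Path) -> None:
    projections[PROJECTION_COLUMNS].to_csv(path, index=False)


_REPORT_COLUMNS = ["table"] + sorted(
    set(SCORE_COLUMNS) | set(TOPIC_COLUMNS) | set(PROJECTION_COLUMNS)
)


def write_report(
    scores: pd.DataFrame,
    topic_indices: pd.DataFrame,
    projections: pd.DataFrame,
    path: str | Path,
) -> None:
    """Write scores, topic indices, and projections into one report CSV.

    The three tables must agree on their location keys.  Member lists in
    topic rows are serialised ';'-joined.  Column order is fixed so
    identical inputs give byte-identical files.
    """
    frames = {"score": scores, "topic": topic_indices, "projection": projections}
    locsets = {
        name: set(frame["location_id"])
        for name, frame in frames.items()
        if len(frame)
    }
    if len(locsets) > 1:
        union = set.union(*locsets.values())
        for name, locs in locsets.items():
            if locs != union:
                raise ConsistencyError(
                    f"location keys of {name!r} table disagree with other tables"
                )

    parts = []
    for name, frame in frames.items():
        part = frame.copy()
        if name == "topic" and "members" in part.columns:
            part["members"] = part["members"].map(
                lambda m: ";".join(m) if isinstance(m, (list, tuple)) else m
            )
        part.insert(0, "table", name)
        parts.append(part)
    out = pd.concat(parts, ignore_index=True) if parts else pd.DataFrame()
    out = out.reindex(columns=_REPORT_COLUMNS)
    out.to_csv(path, index=False)


def read_report(path: str | Path) -> dict[str, pd.DataFrame]:
    """Read a combined report back into its three tables."""
    frame = pd.read_csv(path, dtype={"indicator_id": str, "location_id": str})
    tables: dict[str, pd.DataFrame] = {}
    for name, cols in (
        ("score", SCORE_COLUMNS),
        ("topic", TOPIC_COLUMNS),
        ("projection", PROJECTION_COLUMNS),
    ):
        sub = frame[frame["table"] == name][cols].reset_index(drop=True) if len(frame) else pd.DataFrame(columns=cols)
        if name == "topic" and len(sub):
            sub = sub.copy()
            sub["members"] = sub["members"].map(
                lambda m: m.split(";") if isinstance(m, str) else m
            )
            sub["n_members"] = sub["n_members"].astype(int)
            sub["year"] = sub["year"].astype(int)
        elif len(sub):
            sub = sub.copy()
            sub["year"] = sub["year"].astype(int)
        tables[name] = sub
    return tables
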