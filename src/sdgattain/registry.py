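"""Indicator registry: loading, validation, and the packaged 28-indicator set.

The packaged registry mirrors the published monitoring set: 28
indicators across nine thematic topics (three child-nutrition, six
MCHRH, five infectious-disease, two NCD-mortality, two NCD-risk, one
road-injury, three environmental-outcome, five environmental-exposure,
one UHC).  Targets without a numeric international value are encoded
with documented conventions and flagged in the ``assumed`` column.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path
from typing import Iterable

import pandas as pd

from .errors import DuplicateKeyError, SchemaError
from .model import IndicatorDefinition, TOPICS

N_INDICATORS = 28

_REQUIRED = [
    "indicator_id", "name", "topic", "direction", "transform",
    "target_type", "target_value", "baseline_year", "target_year",
]


def packaged_registry_path() -> Path:
    """Path to the registry CSV shipped with the package."""
    return Path(importlib.resources.files("sdgattain").joinpath("data/registry.csv"))


def load_registry(path: str | Path | None = None) -> list[IndicatorDefinition]:
    """Load and validate an indicator registry CSV.

    With no argument the packaged 28-indicator registry is used.
    Raises :class:`SchemaError` on missing fields, unknown enum values,
    or wrong cardinality, and :class:`DuplicateKeyError` on repeated
    indicator ids.
    """
    path = packaged_registry_path() if path is None else Path(path)
    frame = pd.read_csv(path, dtype={"indicator_id": str})
    missing_cols = [c for c in _REQUIRED if c not in frame.columns]
    if missing_cols:
        raise SchemaError(f"registry missing columns: {missing_cols}")

    dupes = frame["indicator_id"][frame["indicator_id"].duplicated()]
    if not dupes.empty:
        raise DuplicateKeyError(f"duplicate indicator_id: {sorted(dupes.unique())}")

    definitions: list[IndicatorDefinition] = []
    for row_no, row in enumerate(frame.itertuples(index=False), start=2):
        for col in ("indicator_id", "name", "topic", "direction", "transform", "target_type"):
            if pd.isna(getattr(row, col)):
                raise SchemaError(f"registry row {row_no}: missing field {col!r}")
        try:
            definitions.append(
                IndicatorDefinition(
                    indicator_id=str(row.indicator_id),
                    name=str(row.name),
                    topic=str(row.topic),
                    direction=str(row.direction),
                    transform=str(row.transform),
                    target_type=str(row.target_type),
                    target_value=None if pd.isna(row.target_value) else float(row.target_value),
                    baseline_year=None if pd.isna(row.baseline_year) else int(row.baseline_year),
                    target_year=int(row.target_year),
                    units="" if "units" not in frame.columns or pd.isna(row.units) else str(row.units),
                    assumed=bool(getattr(row, "assumed", 0)),
                )
            )
        except ValueError as exc:
            raise SchemaError(f"registry row {row_no}: {exc}") from exc

    if len(definitions) != N_INDICATORS:
        raise SchemaError(
            f"registry must define exactly {N_INDICATORS} indicators, got {len(definitions)}"
        )
    present = {d.topic for d in definitions}
    empty = [t for t in TOPICS if t not in present]
    if empty:
        raise SchemaError(f"registry leaves topics empty: {empty}")
    return definitions


def registry_index(registry: Iterable[IndicatorDefinition]) -> dict[str, IndicatorDefinition]:
    return {d.indicator_id: d for d in registry}


def topic_members(registry: Iterable[IndicatorDefinition]) -> dict[str, list[str]]:
    """Topic -> ordered member indicator ids."""
    members: dict[str, list[str]] = {t: [] for t in TOPICS}
    for d in registry:
        members[d.topic].append(d.indicator_id)
    return members


def write_registry(registry: Iterable[IndicatorDefinition], path: str | Path) -> None:
    rows = []
    for d in registry:
        rows.append({
            "indicator_id": d.indicator_id,
            "name": d.name,
            "topic": d.topic,
            "direction": d.direction,
            "transform": d.transform,
            "target_type": d.target_type,
            "target_value": d.target_value,
            "baseline_year": d.baseline_year,
            "target_year": d.target_year,
            "units": d.units,
            "assumed": int(d.assumed),
        })
    pd.DataFrame(rows).to_csv(path, index=False)
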