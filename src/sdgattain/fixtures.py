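"""Transcribed published values used as worked-example fixtures.

Three small lookup tables transcribed from the study's printed results
for China:

* ``NATIONAL_SCORES_2016`` — the national row of per-indicator
  attainment scores and topic subtotals (printed as integers);
* ``DISPARITY_INPUTS`` — national indicator values by stratum
  (sex, urban/rural) from the current-performance table;
* ``TOPIC_ENDPOINTS`` — topic index start/end values and the printed
  annual change rates.

These are inputs for disparity-ratio and aggregation worked examples;
they are not outputs of this package.  Known transcription notes: the
abstract's infectious-disease index (63.0) was computed from unrounded
member scores and differs in the last decimal from the geometric mean
of the printed integers (62.9); the HIV male/female incidence ratio is
printed as 3.6 in the table but cited as 3.5 in the running text.
"""

from __future__ import annotations

from types import MappingProxyType

# National per-indicator attainment scores, 2016 (printed integers).
NATIONAL_SCORES_2016 = MappingProxyType({
    "2.2.1": 86, "2.2.2a": 100, "2.2.2b": 94,
    "3.1.1": 100, "3.1.2": 92, "3.2.1": 100, "3.2.2": 100,
    "3.b.1": 98, "3.7.1": 66,
    "3.3.1": 40, "3.3.2": 63, "3.3.3": 100, "3.3.4": 49, "3.3.5": 80,
    "3.4.1": 72, "3.4.2": 89,
    "3.a.1": 74, "3.5.2": 50,
    "3.6.1": 64,
    "3.9.1": 58, "3.9.2": 95, "3.9.3": 79,
    "11.6.2": 31, "7.1.2": 76, "6.1.1": 56, "6.2.1a": 72, "6.2.1b": 66,
    "3.8.1": 54,
})

# National topic subtotals, 2016 (printed integers).
NATIONAL_SUBTOTALS_2016 = MappingProxyType({
    "child_nutrition": 91, "mchrh": 92, "infectious": 63,
    "ncd_mortality": 80, "ncd_risk": 60, "road_injury": 64,
    "env_outcome": 75, "env_exposure": 55, "uhc": 54,
})

# (indicator_id, stratum, year) -> value in indicator units.
DISPARITY_INPUTS = MappingProxyType({
    # child stunting prevalence (%), 2013 survey round
    ("2.2.1", "total", 2013): 8.1, ("2.2.1", "male", 2013): 8.7,
    ("2.2.1", "female", 2013): 7.4, ("2.2.1", "urban", 2013): 4.2,
    ("2.2.1", "rural", 2013): 11.3,
    # child wasting prevalence (%)
    ("2.2.2a", "total", 2013): 2.0, ("2.2.2a", "male", 2013): 2.0,
    ("2.2.2a", "female", 2013): 2.0, ("2.2.2a", "urban", 2013): 2.4,
    ("2.2.2a", "rural", 2013): 1.5,
    # child overweight prevalence (%)
    ("2.2.2b", "total", 2013): 8.4, ("2.2.2b", "male", 2013): 9.4,
    ("2.2.2b", "female", 2013): 7.2, ("2.2.2b", "urban", 2013): 8.4,
    ("2.2.2b", "rural", 2013): 8.4,
    # maternal mortality ratio (per 100,000), 2016
    ("3.1.1", "total", 2016): 19.9, ("3.1.1", "urban", 2016): 19.5,
    ("3.1.1", "rural", 2016): 20.0,
    # under-5 mortality (per 1,000), 2016
    ("3.2.1", "total", 2016): 10.2, ("3.2.1", "urban", 2016): 5.2,
    ("3.2.1", "rural", 2016): 12.4,
    # neonatal mortality (per 1,000), 2016
    ("3.2.2", "total", 2016): 4.9, ("3.2.2", "urban", 2016): 3.0,
    ("3.2.2", "rural", 2016): 5.7,
})

# Printed male/female incidence ratios for infectious diseases, 2013 column.
SEX_RATIOS_2013 = MappingProxyType({
    "3.3.1": 3.6,  # HIV (running text cites 3.5)
    "3.3.2": 1.8,  # TB
    "3.3.3": 1.0,  # malaria
    "3.3.4": 1.7,  # hepatitis B
})

# topic -> (year_start, index_start, year_end, index_end, printed_rate).
# Endpoint arithmetic reproduces the printed one-decimal rate only for
# road_injury, uhc, and env_exposure; the remaining printed rates were
# evidently computed on unrounded or differently-windowed series.
TOPIC_ENDPOINTS = MappingProxyType({
    "child_nutrition": (2016, 91.1, 2025, 80.5, -1.1),
    "mchrh": (2016, 91.8, 2030, 95.3, 1.0),
    "infectious": (2016, 63.0, 2030, 73.8, 0.7),
    "ncd_mortality": (2016, 79.7, 2030, 100.0, 1.6),
    "ncd_risk": (2016, 60.5, 2025, 38.8, -1.3),
    "road_injury": (2016, 63.6, 2020, 70.0, 1.6),
    "env_outcome": (2016, 75.5, 2030, 89.2, 0.9),
    "env_exposure": (2016, 54.9, 2030, 60.2, 0.4),
    "uhc": (2016, 54.4, 2030, 69.2, 1.1),
})

# Topics whose printed rate is consistent with endpoint arithmetic at
# one decimal; the others are documented, not asserted.
ENDPOINT_CONSISTENT_TOPICS = ("road_injury", "uhc", "env_exposure")

INFECTIOUS_MEMBER_SCORES_2016 = (40, 63, 100, 49, 80)  # HIV, TB, malaria, HBV, NTD


def make_fixture_tables() -> dict[str, dict]:
    """All fixture tables as plain dicts, for reporting or export."""
    return {
        "national_scores_2016": dict(NATIONAL_SCORES_2016),
        "national_subtotals_2016": dict(NATIONAL_SUBTOTALS_2016),
        "disparity_inputs": dict(DISPARITY_INPUTS),
        "sex_ratios_2013": dict(SEX_RATIOS_2013),
        "topic_endpoints": dict(TOPIC_ENDPOINTS),
    }


def fixture_lookup(indicator_id: str, stratum: str, year: int) -> float:
    """Value of one disparity-input cell, e.g. ("2.2.1", "male", 2013) -> 8.7."""
    return DISPARITY_INPUTS[(indicator_id, stratum, year)]
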