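"""Weighted annual-rate-of-change projection: rates, weights, omega selection."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sdgattain import (
    annual_log_changes, project_panel, project_series, recency_weights,
    select_omega, weighted_mean_aroc,
)
from sdgattain.errors import InsufficientDataError
from sdgattain.model import ProjectionConfig


def series(values, start=2000):
    return pd.Series(np.asarray(values, dtype=float),
                     index=range(start, start + len(values)))


def brute_force_aroc(values, years, omega):
    """Independent oracle: explicit loops over consecutive-year log ratios.

    Weights rank the change years (the later year of each pair) from
    their own first year.
    """
    raw = [(years[i] - years[1] + 1) ** omega for i in range(1, len(years))]
    total = math.fsum(raw)
    weights = [r / total for r in raw]
    changes = [math.log(values[i] / values[i - 1]) for i in range(1, len(values))]
    return math.fsum(w * c for w, c in zip(weights, changes))


class TestAnnualChanges:
    def test_constant_series_has_zero_changes(self):
        assert np.allclose(annual_log_changes(series([7, 7, 7, 7]), "log"), 0.0)

    def test_doubling_series_changes_are_ln2(self):
        values = [3 * 2 ** t for t in range(6)]
        np.testing.assert_allclose(
            annual_log_changes(series(values), "log"), math.log(2), rtol=1e-12)

    def test_hand_computed_log_changes(self):
        changes = annual_log_changes(series([100, 90, 81]), "log")
        np.testing.assert_allclose(changes, [math.log(0.9)] * 2, rtol=1e-12)
        assert changes[0] == pytest.approx(-0.10536, abs=1e-5)

    def test_interior_gap_interpolated_in_transform_space(self):
        s = pd.Series([100.0, 64.0], index=[2000, 2004])
        changes = annual_log_changes(s, "log")
        # geometric interpolation: equal log-steps across the gap
        np.testing.assert_allclose(changes, [math.log(0.64) / 4] * 4, rtol=1e-12)

    def test_gap_beyond_five_years_rejected(self):
        s = pd.Series([10.0, 5.0], index=[2000, 2007])
        with pytest.raises(InsufficientDataError):
            annual_log_changes(s, "log")


class TestWeights:
    def test_omega_zero_is_uniform(self):
        np.testing.assert_allclose(recency_weights(range(2001, 2006), 0.0), [0.2] * 5)

    def test_omega_one_is_proportional_to_rank(self):
        np.testing.assert_allclose(recency_weights([1, 2, 3], 1.0), [1/6, 2/6, 3/6])

    @given(st.integers(2, 40), st.floats(0.0, 3.0))
    @settings(max_examples=100, derandomize=True)
    def test_weights_sum_to_one_and_rise_with_recency(self, n, omega):
        w = recency_weights(range(2000, 2000 + n), omega)
        assert w.sum() == pytest.approx(1.0)
        assert (np.diff(w) >= -1e-15).all()


class TestWeightedAroc:
    def test_uniform_weights_give_arithmetic_mean(self):
        changes = [0.1, -0.2, 0.3]
        assert weighted_mean_aroc(changes, [1/3] * 3) == pytest.approx(np.mean(changes))

    def test_degenerate_weight_selects_single_change(self):
        assert weighted_mean_aroc([0.1, -0.2, 0.3], [0, 0, 1]) == pytest.approx(0.3)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            weighted_mean_aroc([0.1, 0.2], [1.0])

    def test_matches_brute_force_oracle_on_random_series(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            n = rng.integers(2, 41)
            years = np.arange(1990, 1990 + n)
            values = np.exp(rng.normal(2.0, 0.5, size=n))
            omega = rng.uniform(0.0, 3.0)
            changes = annual_log_changes(pd.Series(values, index=years), "log")
            weights = recency_weights(years[1:], omega)
            fast = weighted_mean_aroc(changes, weights)
            assert fast == pytest.approx(
                brute_force_aroc(values, years, omega), abs=1e-12)


class TestSelectOmega:
    def test_constant_rate_series_ties_to_smallest_omega(self):
        values = [100 * 0.95 ** t for t in range(12)]
        assert select_omega(series(values), "log") == 0.0

    def test_accelerating_decline_selects_positive_omega(self):
        # decline rate doubles over the window: recent years predict better
        t = np.arange(15)
        values = 100 * np.exp(-(0.02 * t + 0.004 * t ** 2))
        assert select_omega(series(values), "log") > 0.0

    def test_short_series_falls_back_to_omega_one(self, caplog):
        with caplog.at_level("WARNING"):
            omega = select_omega(series([10, 9, 8.5]), "log", holdout_years=3)
        assert omega == 1.0
        assert "fallback" in caplog.text


class TestProjectSeries:
    def test_constant_series_projects_flat(self):
        path, _ = project_series(
            series([4, 4, 4, 4, 4, 4], start=2011),
            ProjectionConfig(transform="log", horizon_year=2020))
        np.testing.assert_allclose(path.to_numpy(), 4.0, rtol=1e-12)

    def test_constant_rate_closed_form(self):
        path, _ = project_series(
            series([100, 90, 81], start=2014),
            ProjectionConfig(transform="log", horizon_year=2018, omega=0.5))
        assert path.loc[2018] == pytest.approx(65.61, rel=1e-12)

    def test_logit_projection_stays_in_unit_interval(self):
        values = [0.5, 0.6, 0.7, 0.78, 0.85, 0.9]
        path, _ = project_series(
            series(values, start=2011),
            ProjectionConfig(transform="logit", horizon_year=2035))
        assert ((path > 0) & (path < 1)).all()

    def test_log_projection_stays_positive(self):
        values = [100, 40, 16, 6.4, 2.56]
        path, _ = project_series(
            series(values, start=2012),
            ProjectionConfig(transform="log", horizon_year=2040))
        assert (path > 0).all()


class TestProjectPanel:
    def test_one_projection_per_series_and_closed_form(self, registry):
        # noiseless constant-rate panel: projections must match the
        # generator's closed-form extrapolation
        from sdgattain import default_scenario, generate_panel
        scenario = default_scenario(seed=11, sigma_scale=0.0)
        # restrict to a few provinces for speed
        scenario = type(scenario)(
            seed=11, indicators=scenario.indicators, n_provinces=3)
        panel = generate_panel(scenario, registry)
        projections, results = project_panel(panel, registry)
        n_series = panel.groupby(["location_id", "indicator_id", "sex"]).ngroups
        assert len(results) == n_series
        defs = {d.indicator_id: d for d in registry}
        from sdgattain.model import transform_forward, transform_inverse
        for (loc, ind, sex), sub in panel.groupby(
                ["location_id", "indicator_id", "sex"]):
            sc = scenario.indicators[ind]
            if sc.accel != 0.0:
                continue  # constant rate only
            transform = defs[ind].transform
            s = sub.set_index("year")["value"].sort_index()
            f2016 = float(transform_forward(transform, s.loc[2016]))
            expected = transform_inverse(transform, f2016 + sc.rate * (2030 - 2016))
            got = projections[(projections.location_id == loc)
                              & (projections.indicator_id == ind)
                              & (projections.sex == sex)
                              & (projections.year == 2030)]["value"].iloc[0]
            assert got == pytest.approx(float(expected), rel=1e-9, abs=1e-9)

    def test_noisy_rate_recovery_within_three_sigma(self):
        # constant-trend series with log-normal noise: the weighted AROC is
        # an unbiased rate estimator; every replicate stays within
        # 3*sigma/sqrt(n) of the truth for uniform and strongly
        # recency-weighted omega
        rng = np.random.default_rng(1)
        n, sigma = 27, 0.05
        bound = 3 * sigma / math.sqrt(n)
        years = np.arange(1990, 1990 + n)
        for _ in range(1000):
            r = rng.uniform(-0.1, 0.05)
            x = 100 * np.exp(r * (years - 1990) + rng.normal(0, sigma, n))
            s = pd.Series(x, index=years)
            changes = annual_log_changes(s, "log")
            for omega in (0.0, 1.0, 3.0):
                est = weighted_mean_aroc(changes, recency_weights(years[1:], omega))
                assert abs(est - r) <= bound

    def test_determinism_of_selection_and_projection(self, registry):
        from sdgattain import default_scenario, generate_panel
        scenario = default_scenario(seed=5)
        scenario = type(scenario)(seed=5, indicators=scenario.indicators, n_provinces=2)
        panel = generate_panel(scenario, registry)
        p1, r1 = project_panel(panel, registry)
        p2, r2 = project_panel(panel, registry)
        pd.testing.assert_frame_equal(p1, p2)
        assert r1 == r2
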