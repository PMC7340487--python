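"""Attainment scaling: Tukey trimming, anchor resolution, 0-100 scores."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sdgattain import (
    DegenerateAnchorError, InsufficientDataError, resolve_anchors,
    scale_panel, scale_series, scale_value, tukey_outlier_mask,
)
from sdgattain.model import AnchorPair, IndicatorDefinition
from sdgattain.scaling import fill_log_zeros


def make_def(**kw):
    base = dict(
        indicator_id="3.2.1", name="test", topic="mchrh",
        direction="lower_better", transform="log", target_type="absolute",
        target_value=25.0, baseline_year=None, target_year=2030,
    )
    base.update(kw)
    return IndicatorDefinition(**base)


class TestTukey:
    def test_constant_series_has_no_outliers(self):
        assert not tukey_outlier_mask([5, 5, 5, 5, 5]).any()

    def test_single_extreme_flagged(self):
        mask = tukey_outlier_mask([1, 2, 3, 4, 100])
        assert mask.tolist() == [False, False, False, False, True]

    def test_needs_four_values(self):
        with pytest.raises(InsufficientDataError):
            tukey_outlier_mask([1, 2, 3])

    @given(st.lists(st.floats(-1e6, 1e6), min_size=4, max_size=50))
    @settings(max_examples=200, derandomize=True)
    def test_mask_flags_exactly_fence_violations(self, values):
        arr = np.asarray(values)
        q1, q3 = np.percentile(arr, [25, 75])
        iqr = q3 - q1
        expected = (arr < q1 - 1.5 * iqr) | (arr > q3 + 1.5 * iqr)
        assert tukey_outlier_mask(values).tolist() == expected.tolist()


class TestAnchors:
    def test_worst_is_max_of_retained_for_lower_better(self):
        series = pd.Series([10, 8, 12, 9.0], index=[2010, 2011, 2012, 2013])
        anchors = resolve_anchors(series, make_def(target_value=2.0))
        assert anchors.worst_value == 12

    def test_outlier_excluded_from_worst(self):
        series = pd.Series([10, 8, 12, 9, 300.0], index=range(2010, 2015))
        anchors = resolve_anchors(series, make_def(target_value=2.0))
        assert anchors.worst_value == 12

    def test_no_increase_target_is_baseline_year_value(self):
        years = list(range(2010, 2016))
        series = pd.Series([9.0, 8.8, 8.9, 8.4, 8.5, 8.4], index=years)
        d = make_def(indicator_id="2.2.2b", topic="child_nutrition",
                     transform="linear", target_type="no_increase",
                     target_value=None, baseline_year=2015, target_year=2025)
        anchors = resolve_anchors(series, d)
        assert anchors.target_value_resolved == 8.4

    def test_flat_series_at_target_is_degenerate(self):
        series = pd.Series([25.0] * 6, index=range(2010, 2016))
        with pytest.raises(DegenerateAnchorError):
            resolve_anchors(series, make_def())

    def test_anchor_invariance_to_year_order(self):
        years = [2012, 2010, 2015, 2011, 2013]
        series = pd.Series([11, 10, 8, 12, 9.0], index=years)
        shuffled = series.sample(frac=1, random_state=0)
        d = make_def(target_value=2.0)
        assert resolve_anchors(series, d) == resolve_anchors(shuffled, d)


class TestScaleValue:
    def test_anchor_endpoints(self):
        d = make_def(target_value=1.0)
        anchors = AnchorPair(100.0, 1.0)
        assert scale_value(1.0, anchors, d) == 100.0
        assert scale_value(100.0, anchors, d) == 0.0

    def test_log_geometric_midpoint_is_50(self):
        d = make_def(target_value=1.0)
        assert scale_value(10.0, AnchorPair(100.0, 1.0), d) == pytest.approx(50.0)

    def test_linear_identity_with_0_100_anchors(self):
        d = make_def(direction="higher_better", transform="linear", target_value=100.0)
        anchors = AnchorPair(0.0, 100.0)
        for x in (0.0, 13.7, 55.0, 100.0):
            assert scale_value(x, anchors, d) == pytest.approx(x)

    def test_overachievement_and_deterioration_clip(self):
        d = make_def(target_value=1.0)
        anchors = AnchorPair(100.0, 1.0)
        assert scale_value(0.5, anchors, d) == 100.0
        assert scale_value(250.0, anchors, d) == 0.0

    def test_history_always_better_than_target_scores_by_attainment(self):
        # worst anchor on the good side of the target (wasting never above 5%)
        d = make_def(indicator_id="2.2.2a", transform="linear", target_value=5.0)
        anchors = AnchorPair(3.5, 5.0)
        assert scale_value(2.0, anchors, d) == 100.0
        assert scale_value(6.0, anchors, d) == 0.0

    @given(
        x=st.floats(0.5, 200.0),
        worst=st.floats(50.0, 200.0),
        target=st.floats(0.5, 10.0),
    )
    @settings(max_examples=300, derandomize=True)
    def test_scores_clipped_and_monotone(self, x, worst, target):
        d = make_def(target_value=target)
        anchors = AnchorPair(worst, target)
        s = scale_value(x, anchors, d)
        assert 0.0 <= s <= 100.0
        # moving toward the target (smaller x for lower_better) never lowers the score
        assert scale_value(max(x * 0.9, 1e-9), anchors, d) >= s - 1e-9


class TestScalePanel:
    def test_panel_at_targets_scores_100(self, registry):
        rows = []
        years = range(2010, 2017)
        for d in registry:
            if d.target_type != "absolute":
                continue
            for i, y in enumerate(years):
                # approach and hit the target by 2016
                if d.direction == "lower_better":
                    v = d.target_value * (2.0 - i / 6.0)
                else:
                    v = d.target_value * (0.6 + 0.4 * i / 6.0)
                    if d.transform == "logit":
                        v = min(v, 0.999)
                rows.append(("China", "national", d.indicator_id, "both", y, v))
        panel = pd.DataFrame(rows, columns=[
            "location_id", "region", "indicator_id", "sex", "year", "value"])
        scores = scale_panel(panel, registry)
        at_2016 = scores[scores.year == 2016]
        assert (at_2016["score"] >= 100.0 - 1e-9).all()

    def test_scores_match_hand_computed_formula(self):
        d = make_def(target_value=25.0)
        years = np.arange(2010, 2016)
        values = np.array([60, 55, 52, 47, 44, 40.0])
        series = pd.Series(values, index=years)
        scores, anchors = scale_series(series, d)
        worst = 60.0
        expected = 100 * (np.log(values) - np.log(worst)) / (np.log(25.0) - np.log(worst))
        assert anchors.worst_value == worst
        np.testing.assert_allclose(scores.to_numpy(), expected, rtol=1e-12)

    def test_zero_values_on_log_indicator_score_100_after_elimination(self):
        d = make_def(indicator_id="3.3.3", topic="infectious",
                     target_type="relative_reduction", target_value=0.9,
                     baseline_year=2014)
        series = pd.Series([2.0, 1.0, 0.5, 0.2, 0.1, 0.0],
                           index=range(2010, 2016))
        filled = fill_log_zeros(series)
        assert filled.iloc[-1] == pytest.approx(0.05)
        scores, _ = scale_series(series, d)
        assert scores.iloc[-1] == 100.0
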