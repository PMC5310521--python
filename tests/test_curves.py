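"""AUC comparison of dose-survival curves: interpolation, extension, verdicts."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import vehitox as vt
from vehitox.curves import IncomparableCurves, Strategy, Verdict

from conftest import make_curve


def dense_auc(points, lo, hi, n=4001):
    """Independent oracle: trapezoid over a dense grid that includes the knots."""
    xs = np.union1d(np.linspace(lo, hi, n), [d for d, _ in points if lo <= d <= hi])
    ys = np.interp(xs, [d for d, _ in points], [s for _, s in points])
    return float(np.trapezoid(ys, xs))


class TestInterpolateAt:
    @pytest.mark.parametrize(
        "points, dose, expected",
        [
            ([(100.0, 1.0), (200.0, 0.0)], 150.0, 0.5),
            ([(100.0, 1.0), (200.0, 0.0)], 200.0, 0.0),
            ([(1.0, 1.0), (2.0, 0.8), (4.0, 0.2)], 3.0, 0.5),
            ([(1.0, 1.0), (2.0, 0.8), (4.0, 0.2)], 2.0, 0.8),
        ],
    )
    def test_linear_interpolation_on_linear_dose_axis(self, points, dose, expected):
        assert vt.interpolate_at(make_curve(points), dose) == pytest.approx(expected)

    def test_dose_outside_range_is_an_error(self):
        with pytest.raises(ValueError, match="outside"):
            vt.interpolate_at(make_curve([(1.0, 1.0), (2.0, 0.0)]), 3.0)


class TestExtend:
    def test_high_extension_when_survival_reached_zero(self):
        saline = make_curve([(100.0, 1.0), (1000.0, 0.0)], vehicle="saline")
        cmc = make_curve([(100.0, 1.0), (5000.0, 0.2)], vehicle="CMC")
        extended = vt.extend(saline, cmc, Strategy.EXTRAPOLATE_HIGH)
        assert extended.points[-1] == (5000.0, 0.0)
        assert extended.points[:-1] == saline.points

    def test_no_extension_when_survival_positive_at_top_dose(self):
        curve = make_curve([(100.0, 1.0), (1000.0, 0.2)])
        other = make_curve([(100.0, 1.0), (5000.0, 0.0)], vehicle="CMC")
        assert vt.extend(curve, other, Strategy.EXTRAPOLATE_HIGH) is curve

    def test_low_extension_when_survival_is_complete_at_bottom_dose(self):
        curve = make_curve([(100.0, 1.0), (1000.0, 0.5)])
        other = make_curve([(10.0, 1.0), (1000.0, 0.5)], vehicle="CMC")
        extended = vt.extend(curve, other, Strategy.EXTRAPOLATE_HIGH_LOW)
        assert extended.points[0] == (10.0, 1.0)

    def test_interpolation_only_never_extends(self):
        curve = make_curve([(100.0, 1.0), (1000.0, 0.0)])
        other = make_curve([(10.0, 1.0), (5000.0, 0.0)], vehicle="CMC")
        assert vt.extend(curve, other, Strategy.INTERPOLATION_ONLY) is curve

    def test_extension_never_alters_interior_survival(self):
        curve = make_curve([(100.0, 1.0), (300.0, 0.4), (1000.0, 0.0)])
        other = make_curve([(10.0, 1.0), (5000.0, 0.0)], vehicle="CMC")
        extended = vt.extend(curve, other, Strategy.EXTRAPOLATE_HIGH_LOW)
        for dose in np.linspace(100.0, 1000.0, 17):
            assert vt.interpolate_at(extended, dose) == pytest.approx(
                vt.interpolate_at(curve, dose)
            )


class TestCommonWindow:
    def test_interval_intersection(self):
        a = make_curve([(1.0, 1.0), (10.0, 0.0)])
        b = make_curve([(2.0, 1.0), (8.0, 0.0)], vehicle="CMC")
        assert vt.common_window(a, b) == (2.0, 8.0)

    def test_identical_ranges(self):
        a = make_curve([(1.0, 1.0), (10.0, 0.0)])
        b = make_curve([(1.0, 1.0), (10.0, 0.0)], vehicle="CMC")
        assert vt.common_window(a, b) == (1.0, 10.0)

    def test_disjoint_ranges_are_incomparable(self):
        a = make_curve([(1.0, 1.0), (2.0, 0.0)])
        b = make_curve([(3.0, 1.0), (4.0, 0.0)], vehicle="CMC")
        with pytest.raises(IncomparableCurves):
            vt.common_window(a, b)


class TestAuc:
    @pytest.mark.parametrize(
        "points, window, expected",
        [
            ([(0.0 + 1e-12, 1.0), (100.0, 1.0)], (1e-12, 100.0), 100.0),
            ([(1e-12, 1.0), (100.0, 0.0)], (1e-12, 100.0), 50.0),
            ([(1.0, 1.0), (2.0, 0.8), (4.0, 0.2)], (1.0, 4.0), 1.9),
        ],
    )
    def test_known_areas(self, points, window, expected):
        assert vt.auc(make_curve(points), *window) == pytest.approx(expected)

    def test_window_outside_curve_span_is_an_error(self):
        with pytest.raises(ValueError, match="window"):
            vt.auc(make_curve([(1.0, 1.0), (2.0, 0.0)]), 0.5, 2.0)

    @given(
        st.lists(st.floats(0.0, 1.0), min_size=2, max_size=8),
        st.integers(0, 10_000),
    )
    def test_matches_dense_integration_oracle(self, survivals, dose_seed):
        rng = np.random.default_rng(dose_seed)
        doses = np.sort(rng.uniform(1.0, 1000.0, size=len(survivals)))
        if np.min(np.diff(doses)) <= 0:
            doses = np.cumsum(rng.uniform(1.0, 100.0, size=len(survivals)))
        points = list(zip(doses.tolist(), survivals))
        curve = make_curve(points)
        area = vt.auc(curve, doses[0], doses[-1])
        oracle = dense_auc(points, doses[0], doses[-1])
        assert area == pytest.approx(oracle, rel=1e-9, abs=1e-9)

    @given(st.integers(0, 10_000))
    def test_monotone_in_survival(self, seed):
        rng = np.random.default_rng(seed)
        doses = np.cumsum(rng.uniform(1.0, 100.0, size=5))
        lower = rng.uniform(0.0, 1.0, size=5)
        raised = np.minimum(1.0, lower + rng.uniform(0.0, 0.3, size=5))
        a1 = vt.auc(make_curve(list(zip(doses, lower))), doses[0], doses[-1])
        a2 = vt.auc(make_curve(list(zip(doses, raised))), doses[0], doses[-1])
        assert a2 >= a1 - 1e-12


class TestComparePair:
    def test_equal_areas_show_no_difference_at_every_threshold(self):
        a = make_curve([(1.0, 1.0), (2.0, 0.0)], vehicle="saline")
        b = make_curve([(1.0, 0.0), (2.0, 1.0)], vehicle="CMC")
        for threshold in (0, 30, 40, 60):
            verdict = vt.compare_pair(a, b, Strategy.INTERPOLATION_ONLY, threshold)
            assert verdict.verdict is Verdict.NO_DIFFERENCE

    def test_fifty_percent_difference_crosses_forty_threshold(self):
        a = make_curve([(0.5, 1.0), (100.5, 1.0)], vehicle="saline")
        b = make_curve([(0.5, 0.5), (100.5, 0.5)], vehicle="CMC")
        verdict = vt.compare_pair(a, b, Strategy.INTERPOLATION_ONLY, 40)
        assert verdict.verdict is Verdict.A_LESS_TOXIC
        assert verdict.rel_diff == pytest.approx(50.0)
        assert vt.compare_pair(a, b, Strategy.INTERPOLATION_ONLY, 60).verdict is Verdict.NO_DIFFERENCE

    def test_swapping_arguments_flips_the_verdict(self):
        a = make_curve([(1.0, 1.0), (4.0, 0.6)], vehicle="saline")
        b = make_curve([(1.0, 0.9), (4.0, 0.1)], vehicle="CMC")
        forward = vt.compare_pair(a, b, Strategy.EXTRAPOLATE_HIGH_LOW, 30)
        backward = vt.compare_pair(b, a, Strategy.EXTRAPOLATE_HIGH_LOW, 30)
        assert forward.verdict is Verdict.A_LESS_TOXIC
        assert backward.verdict is Verdict.B_LESS_TOXIC
        assert forward.rel_diff == pytest.approx(backward.rel_diff)

    def test_single_point_curve_is_incomparable(self):
        a = make_curve([(1.0, 1.0)], vehicle="saline")
        b = make_curve([(0.5, 1.0), (2.0, 0.0)], vehicle="CMC")
        with pytest.raises(IncomparableCurves):
            vt.compare_pair(a, b, Strategy.INTERPOLATION_ONLY, 30)

    def test_interpolation_only_never_finds_more_differences_than_extension(self):
        # wider windows can only add area where one curve sits at zero, so the
        # interpolation-only count of differing condition sets is the smallest
        for seed in (31, 32, 33):
            records, _, _ = vt.simulate(vt.SimulationConfig(n_compounds=100, seed=seed))
            curves = vt.aggregate(records)
            counts = {}
            for strategy in ("interp", "high", "highlow"):
                verdicts, _ = vt.compare_conditions(curves, "saline", "CMC", strategy, 40)
                counts[strategy] = sum(v.verdict is not Verdict.NO_DIFFERENCE for v in verdicts)
            assert counts["interp"] <= counts["high"]
            assert counts["interp"] <= counts["highlow"]

    def test_extension_changes_the_window_like_the_strategy_says(self):
        # survival at zero lets the shorter curve follow the longer one out
        saline = make_curve([(100.0, 1.0), (1000.0, 0.0)], vehicle="saline")
        cmc = make_curve([(100.0, 1.0), (6000.0, 0.0)], vehicle="CMC")
        interp = vt.compare_pair(saline, cmc, Strategy.INTERPOLATION_ONLY, 30)
        high = vt.compare_pair(saline, cmc, Strategy.EXTRAPOLATE_HIGH, 30)
        assert interp.window == (100.0, 1000.0)
        assert high.window == (100.0, 6000.0)
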