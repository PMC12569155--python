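"""Crossing times, windowed rates, ensembles, exposure plans and group stats."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from cryosonic import (
    TemperatureTrace,
    ThresholdNotReachedError,
    compare_rate_groups,
    compare_two_groups,
    ensemble_mean_curve,
    first_crossing_time,
    instantaneous_rate,
    normalized_curve,
    plan_exposure,
    summarise_kinetics,
    total_rewarm_time,
    window_rate,
)
from conftest import linear_trace


class TestFirstCrossing:
    def test_linear_trace_reaches_5c_at_70s(self):
        tr = linear_trace(rate_c_per_s=1.0)
        assert first_crossing_time(tr, 5.0) == pytest.approx(70.0)

    def test_midpoint_interpolation(self):
        tr = TemperatureTrace([0.0, 2.0], [-10.0, 0.0])
        assert first_crossing_time(tr, -5.0) == pytest.approx(1.0)

    def test_earliest_of_multiple_crossings_returned(self):
        # a noisy dip below -40 after the first crossing creates a second one
        t = np.arange(0.0, 60.0, 0.5)
        T = -65.0 + t
        T[(t > 26) & (t < 28)] -= 3.0  # dips back below -40 around t=26.5
        tr = TemperatureTrace(t, T)
        # brute-force oracle: scan consecutive sample pairs
        expected = None
        for i in range(t.size - 1):
            if T[i] < -40.0 <= T[i + 1]:
                frac = (-40.0 - T[i]) / (T[i + 1] - T[i])
                expected = t[i] + frac * (t[i + 1] - t[i])
                break
        assert first_crossing_time(tr, -40.0) == pytest.approx(expected)

    def test_unreached_threshold_raises(self):
        tr = TemperatureTrace([0.0, 1.0], [-65.0, -60.0])
        with pytest.raises(ThresholdNotReachedError):
            first_crossing_time(tr, 5.0)


class TestWindowedRates:
    def test_linear_trace_rate_is_60_c_per_min(self):
        tr = linear_trace(rate_c_per_s=1.0)
        assert window_rate(tr, -60.0, -40.0) == pytest.approx(60.0)

    def test_rate_time_identity_holds_by_construction(self):
        tr = linear_trace(rate_c_per_s=0.37)
        rate = window_rate(tr, -60.0, -40.0)
        dt = first_crossing_time(tr, -40.0) - first_crossing_time(tr, -60.0)
        assert rate * dt / 60.0 == pytest.approx(20.0, rel=1e-12)

    def test_transition_rate_below_frozen_rate_on_plateaued_trace(
        self, noiseless_trace_0w
    ):
        low = window_rate(noiseless_trace_0w, -60.0, -40.0)
        trans = window_rate(noiseless_trace_0w, -20.0, 5.0)
        assert trans < low

    def test_total_time_linear_trace(self):
        tr = linear_trace(rate_c_per_s=1.0)
        assert total_rewarm_time(tr) == pytest.approx(70.0)


class TestEnsemble:
    def test_identical_traces_have_zero_sd(self, noiseless_trace_0w):
        ens = ensemble_mean_curve([noiseless_trace_0w, noiseless_trace_0w])
        assert np.allclose(ens.sd_time_s, 0.0)
        # and the mean curve reproduces the trace's own crossing times
        for T in (-60.0, -30.0, 0.0, 5.0):
            j = np.argmin(np.abs(ens.temperature_grid_c - T))
            assert ens.mean_time_s[j] == pytest.approx(
                first_crossing_time(noiseless_trace_0w, ens.temperature_grid_c[j])
            )

    def test_mean_of_two_linear_traces(self):
        fast = linear_trace(rate_c_per_s=2.0)
        slow = linear_trace(rate_c_per_s=1.0)
        grid = np.array([-60.0, -40.0, 0.0])
        ens = ensemble_mean_curve([slow, fast], grid)
        for j, T in enumerate(grid):
            expected = ((T + 65.0) / 1.0 + (T + 65.0) / 2.0) / 2.0
            assert ens.mean_time_s[j] == pytest.approx(expected)

    def test_mean_time_non_decreasing_in_temperature(self, noiseless_trace_100w):
        ens = ensemble_mean_curve([noiseless_trace_100w, noiseless_trace_100w])
        assert np.all(np.diff(ens.mean_time_s) >= 0)

    def test_mixed_powers_rejected(self, noiseless_trace_0w, noiseless_trace_100w):
        with pytest.raises(ValueError, match="same power"):
            ensemble_mean_curve([noiseless_trace_0w, noiseless_trace_100w])


class TestNormalizedCurve:
    def test_endpoints_are_exactly_zero_and_one(self, noiseless_trace_0w):
        ens = ensemble_mean_curve([noiseless_trace_0w, noiseless_trace_0w])
        grid, norm = normalized_curve(ens)
        assert norm[0] == pytest.approx(0.0, abs=1e-12)
        assert norm[-1] == pytest.approx(1.0, abs=1e-12)

    def test_linear_trace_normalises_to_a_line(self):
        tr = linear_trace(rate_c_per_s=1.0)
        ens = ensemble_mean_curve([tr, tr])
        grid, norm = normalized_curve(ens)
        assert np.allclose(norm, (grid + 60.0) / 65.0, atol=1e-9)

    def test_plateaued_trace_is_convex_near_transition(self, noiseless_trace_0w):
        # the latent-heat plateau concentrates time near the liquidus, so the
        # normalised time curve bends upward approaching 0 °C
        ens = ensemble_mean_curve([noiseless_trace_0w, noiseless_trace_0w])
        grid, norm = normalized_curve(ens)
        mask = (grid >= -20.0) & (grid <= 0.0)
        second_diff = np.diff(norm[mask], 2)
        assert second_diff.mean() > 0


class TestInstantaneousRate:
    def test_linear_trace_constant_rate(self):
        tr = linear_trace(rate_c_per_s=1.0)
        ens = ensemble_mean_curve([tr, tr])
        _, rate = instantaneous_rate(ens)
        assert np.allclose(rate, 60.0, rtol=1e-6)

    def test_smoothing_preserves_constant_rate(self):
        tr = linear_trace(rate_c_per_s=1.0)
        ens = ensemble_mean_curve([tr, tr])
        _, rate = instantaneous_rate(ens, smooth_window=5)
        assert np.allclose(rate, 60.0, rtol=1e-6)


class TestExposurePlan:
    @staticmethod
    def _ensemble_with_total_times(times):
        traces = [linear_trace(rate_c_per_s=70.0 / x) for x in times]
        grid = np.arange(-65.0, 5.01, 0.5)
        return ensemble_mean_curve(traces, grid)

    @pytest.mark.parametrize(
        "times, expected",
        [((33.3, 33.5), 34), ((87.0, 89.0), 88), ((87.0, 87.4), 88)],
    )
    def test_ceiling_of_mean_time(self, times, expected):
        plan = plan_exposure(self._ensemble_with_total_times(times))
        assert plan.duration_s == expected

    @given(st.floats(min_value=1.0, max_value=3.0))
    def test_slower_ensemble_never_plans_shorter(self, factor):
        base = self._ensemble_with_total_times((40.0, 44.0))
        slow = self._ensemble_with_total_times((40.0 * factor, 44.0 * factor))
        assert plan_exposure(slow).duration_s >= plan_exposure(base).duration_s


class TestKineticsSummary:
    def test_both_overall_rate_conventions_reported(self, noiseless_trace_0w):
        s = summarise_kinetics([noiseless_trace_0w, noiseless_trace_0w])
        assert s.mean_overall_rate == pytest.approx(
            s.overall_rate_from_mean_time, rel=1e-9
        )
        assert s.mean_total_time_s == pytest.approx(189.0, abs=1.0)


class TestGroupComparisons:
    def test_identical_groups_give_f_zero_p_one(self):
        g = {"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0], "c": [1.0, 2.0, 3.0]}
        res = compare_rate_groups(g)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_two_group_anova_matches_t_test(self):
        a = [204.0, 198.0, 215.0, 199.0]
        b = [158.0, 162.0, 149.0, 170.0]
        res = compare_rate_groups({"fresh": a, "old": b})
        _, p_t = sps.ttest_ind(a, b, equal_var=True)
        assert res.p_value == pytest.approx(p_t, rel=1e-10)

    def test_pairwise_follow_up_covers_all_pairs(self):
        g = {
            "fresh": [204.0, 198.0, 215.0, 199.0],
            "r2": [158.0, 162.0, 149.0, 170.0],
            "r3": [153.0, 150.0, 160.0, 148.0],
        }
        res = compare_rate_groups(g)
        assert res.p_value < 0.05
        assert len(res.pairwise) == 3

    def test_degenerate_all_equal_flagged(self):
        res = compare_rate_groups({"a": [5.0, 5.0], "b": [5.0, 5.0]})
        assert res.degenerate
        assert res.p_value == 1.0

    def test_t_test_identical_groups(self):
        res = compare_two_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_t_test_zero_variance_shifted_groups(self):
        with pytest.warns(UserWarning, match="degenerate"):
            res = compare_two_groups([1.0, 1.0], [2.0, 2.0])
        assert res.degenerate
        assert res.p_value == 0.0
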