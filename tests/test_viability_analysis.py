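"""FDA/PI quantification and two-way ANOVA time-course statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cryosonic import (
    BeadImageConfig,
    TimecourseDataset,
    generate_bead_images,
    generate_viability_timecourse,
    quantify_pair,
    recovery_trajectory,
    sum_intensity,
    viability_ratio,
    viability_timecourse_stats,
)


class TestSumIntensity:
    def test_zero_and_uniform_images(self):
        assert sum_intensity(np.zeros((10, 10))) == 0.0
        assert sum_intensity(np.ones((10, 10))) == 100.0

    def test_constant_background_subtraction_clips_at_zero(self):
        img = np.array([[5.0, 1.0], [0.0, 10.0]])
        assert sum_intensity(img, "constant", background=2.0) == 3.0 + 8.0

    def test_negative_pixels_rejected(self):
        with pytest.raises(ValueError):
            sum_intensity(np.array([[-1.0, 2.0]]))

    def test_generated_bead_signal_recovered_within_2pct(self):
        cfg = BeadImageConfig(dead_fraction=0.25, seed=5)
        pair = generate_bead_images(cfg)
        measured = sum_intensity(pair.fda_image, "constant", cfg.background_level)
        assert measured == pytest.approx(pair.meta["fda_signal"], rel=0.02)


class TestViabilityRatio:
    def test_basic_values(self):
        assert viability_ratio(90.0, 10.0) == pytest.approx(0.90)
        assert viability_ratio(0.0, 5.0) == 0.0

    def test_both_zero_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            viability_ratio(0.0, 0.0)

    @given(
        st.floats(min_value=1.0, max_value=1e6),
        st.floats(min_value=1.0, max_value=1e6),
        st.floats(min_value=0.01, max_value=100.0),
    )
    def test_in_unit_interval_and_common_scaling_invariant(self, f, p, scale):
        v = viability_ratio(f, p)
        assert 0.0 <= v <= 1.0
        assert viability_ratio(scale * f, scale * p) == pytest.approx(v, rel=1e-9)

    @pytest.mark.parametrize("dead_fraction, seed", [(0.25, 0), (0.25, 1), (0.25, 2)])
    def test_generator_dead_fraction_recovered(self, dead_fraction, seed):
        cfg = BeadImageConfig(dead_fraction=dead_fraction, seed=seed)
        rec = quantify_pair(
            generate_bead_images(cfg), "constant", cfg.background_level
        )
        assert rec.viability == pytest.approx(1.0 - dead_fraction, abs=0.03)


def _balanced_dataset(values_by_condition, timepoints=(0.0, 24.0), n_reps=3):
    rows = []
    for cond, base in values_by_condition.items():
        for tp in timepoints:
            for rep in range(n_reps):
                rows.append(
                    {
                        "condition": cond,
                        "timepoint_h": tp,
                        "replicate": rep,
                        "value": base[rep],
                    }
                )
    return TimecourseDataset(pd.DataFrame(rows))


class TestTimecourseStats:
    def test_identical_conditions_show_no_condition_effect(self):
        ds = _balanced_dataset(
            {"a": [0.90, 0.92, 0.91], "b": [0.90, 0.92, 0.91], "c": [0.90, 0.92, 0.91]}
        )
        res = viability_timecourse_stats(ds)
        assert res.condition_p == pytest.approx(1.0)
        diffs = res.pairwise_conditions["meandiff"].astype(float)
        assert np.allclose(diffs, 0.0, atol=1e-12)

    def test_injected_condition_offset_detected(self):
        # +1.6 percentage points on one condition at the study's replicate
        # count and noise level must be detectable
        ds = generate_viability_timecourse(
            condition_offsets_pct={"bath": 0.0, "us20": 1.6},
            noise_sd_pct=1.2,
            n_replicates=5,
            seed=202,
        )
        res = viability_timecourse_stats(ds)
        assert res.condition_p < 0.05

    def test_sum_of_squares_decomposition_on_balanced_layout(self):
        ds = generate_viability_timecourse(seed=9)
        res = viability_timecourse_stats(ds)
        values = ds.frame["value"].to_numpy()
        ss_total = float(((values - values.mean()) ** 2).sum())
        assert res.anova_table["sum_sq"].sum() == pytest.approx(ss_total, rel=1e-9)

    def test_two_condition_reduction_consistent_with_t_test(self):
        from scipy import stats as sps

        ds = generate_viability_timecourse(
            condition_offsets_pct={"a": 0.0, "b": 1.0}, seed=77
        )
        res = viability_timecourse_stats(ds, include_interaction=False)
        df = ds.frame
        # t-test on per-timepoint-aggregated condition means
        agg = df.groupby(["condition", "timepoint_h"])["value"].mean().unstack()
        _, p_t = sps.ttest_rel(agg.loc["a"], agg.loc["b"])
        # both must agree on the presence/absence of a condition effect
        assert (res.condition_p < 0.05) == (p_t < 0.05)

    def test_unbalanced_layout_rejected_without_permission(self):
        ds = generate_viability_timecourse(seed=1)
        frame = ds.frame.drop(index=[0]).reset_index(drop=True)
        with pytest.raises(ValueError, match="unbalanced"):
            viability_timecourse_stats(TimecourseDataset(frame))
        res = viability_timecourse_stats(
            TimecourseDataset(frame), allow_unbalanced=True
        )
        assert 0.0 <= res.condition_p <= 1.0

    def test_insufficient_replication_rejected(self):
        rows = [
            {"condition": c, "timepoint_h": t, "replicate": 0, "value": 0.9}
            for c in "ab"
            for t in (0.0, 24.0)
        ]
        with pytest.raises(ValueError, match="replicates"):
            viability_timecourse_stats(TimecourseDataset(pd.DataFrame(rows)))

    def test_type_one_error_rate_is_calibrated(self):
        # no condition effect: the condition p-value should be ~uniform
        hits = 0
        n_runs = 200
        for seed in range(n_runs):
            ds = generate_viability_timecourse(
                condition_offsets_pct={"a": 0.0, "b": 0.0, "c": 0.0},
                n_replicates=3,
                seed=seed,
            )
            res = viability_timecourse_stats(ds)
            hits += res.condition_p < 0.05
        assert 0.02 <= hits / n_runs <= 0.09


class TestRecoveryTrajectory:
    def test_single_record_per_cell_reproduced_exactly(self):
        rows = [
            {"condition": "a", "timepoint_h": t, "replicate": 0, "value": v}
            for t, v in [(0.0, 0.9), (24.0, 0.8)]
        ]
        out = recovery_trajectory(TimecourseDataset(pd.DataFrame(rows)))
        assert out["mean"].tolist() == [0.9, 0.8]
        assert out["sd"].tolist() == [0.0, 0.0]

    def test_dip_located_at_24h(self):
        ds = generate_viability_timecourse(seed=4)
        out = recovery_trajectory(ds)
        for cond, grp in out.groupby("condition"):
            dip_tp = grp.loc[grp["mean"].idxmin(), "timepoint_h"]
            assert dip_tp == 24.0

    def test_empty_condition_excluded_with_warning(self):
        rows = [
            {"condition": "a", "timepoint_h": 0.0, "replicate": r, "value": 0.9}
            for r in range(2)
        ] + [
            {"condition": "ghost", "timepoint_h": 0.0, "replicate": 0, "value": np.nan}
        ]
        with pytest.warns(UserWarning, match="ghost"):
            out = recovery_trajectory(TimecourseDataset(pd.DataFrame(rows)))
        assert set(out["condition"]) == {"a"}
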