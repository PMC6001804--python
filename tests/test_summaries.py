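"""Unit and property tests for the rewarming summary measures."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rewarm.simulate import rewarming_curve
from rewarm.summaries import (add_log_transforms, average_fingers,
                              compute_auc, compute_ddd, compute_grad,
                              compute_max, mobile_auc_approx,
                              summarize_dataset)

THERMO_GRID = np.arange(0.0, 901.0, 15.0)


class TestAuc:
    def test_constant_curve_is_rectangle(self):
        assert compute_auc(THERMO_GRID, np.full(61, 3.0)) == pytest.approx(
            900.0 * 3.0)

    def test_linear_curve_closed_form(self):
        m = 0.01
        auc = compute_auc(THERMO_GRID, m * THERMO_GRID)
        assert auc == pytest.approx(m * 900.0 ** 2 / 2.0, rel=1e-12)

    def test_two_samples_single_trapezoid(self):
        assert compute_auc([0.0, 900.0], [2.0, 4.0]) == pytest.approx(
            900.0 * 3.0)

    def test_frames_beyond_window_excluded(self):
        t = np.r_[THERMO_GRID, 915.0]
        v = np.r_[np.full(61, 1.0), 1000.0]
        assert compute_auc(t, v) == pytest.approx(900.0)

    def test_linear_matches_fine_riemann_sum(self):
        # quadrature oracle: midpoint Riemann sum of the linear interpolant
        m, b = 0.004, 25.0
        t = THERMO_GRID
        v = m * t + b
        fine = np.linspace(0, 900, 2_000_001)
        riemann = np.sum(np.interp((fine[:-1] + fine[1:]) / 2, t, v)
                         * np.diff(fine))
        assert compute_auc(t, v) == pytest.approx(riemann, rel=1e-9)

    def test_rejects_too_few_samples(self):
        with pytest.raises(ValueError):
            compute_auc([10.0], [1.0])

    def test_rejects_non_increasing_times(self):
        with pytest.raises(ValueError):
            compute_auc([0.0, 10.0, 10.0], [1.0, 2.0, 3.0])

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(a=st.floats(-5, 5), b=st.floats(-10, 10))
    def test_linearity_in_values(self, a, b):
        """AUC(a*v + b) == a*AUC(v) + 900*b."""
        v = np.sin(THERMO_GRID / 150.0) + 2.0
        lhs = compute_auc(THERMO_GRID, a * v + b)
        rhs = a * compute_auc(THERMO_GRID, v) + 900.0 * b
        assert lhs == pytest.approx(rhs, rel=1e-9, abs=1e-7)

    @pytest.mark.parametrize("rate", [0.1, 0.35, 1.0, 2.0])
    def test_monoexponential_closed_form(self, rate):
        """Trapezoid at 4 frames/min within 0.1% of the analytic area."""
        plateau, drop = 31.0, 7.0
        v = rewarming_curve(THERMO_GRID, plateau, drop, rate)
        exact = 900.0 * plateau - (drop * 60.0 / rate) * (
            1.0 - math.exp(-rate * 900.0 / 60.0))
        assert compute_auc(THERMO_GRID, v) == pytest.approx(exact, rel=1e-3)


class TestMax:
    def test_monotone_curve_max_at_right_endpoint(self):
        v = rewarming_curve(THERMO_GRID, 31.0, 7.0, 0.5)
        assert compute_max(THERMO_GRID, v) == pytest.approx(v[-1])

    def test_constant(self):
        assert compute_max(THERMO_GRID, np.full(61, 5.5)) == 5.5

    def test_excludes_extra_frame(self):
        t = np.r_[THERMO_GRID, 915.0]
        v = np.r_[np.full(61, 1.0), 99.0]
        assert compute_max(t, v) == 1.0

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_matches_bruteforce_scan(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.normal(size=61)
        best = -np.inf
        for ti, vi in zip(THERMO_GRID, v):     # exhaustive oracle
            if 0 <= ti <= 900 and vi > best:
                best = vi
        assert compute_max(THERMO_GRID, v) == pytest.approx(best)


class TestGrad:
    def test_recovers_line(self):
        m, b = 0.05, 24.0
        assert compute_grad(THERMO_GRID, m * THERMO_GRID + b) == \
            pytest.approx(m, rel=1e-12)

    def test_constant_series_zero(self):
        assert compute_grad(THERMO_GRID, np.full(61, 3.0)) == \
            pytest.approx(0.0, abs=1e-15)

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(5)
        v = 0.03 * THERMO_GRID + rng.normal(0, 0.5, 61)
        keep = THERMO_GRID <= 120.0
        t, y = THERMO_GRID[keep], v[keep]
        n = len(t)
        slope = (n * np.sum(t * y) - t.sum() * y.sum()) / (
            n * np.sum(t * t) - t.sum() ** 2)
        assert compute_grad(THERMO_GRID, v) == pytest.approx(slope, abs=1e-10)

    def test_shift_invariance(self):
        v = np.sin(THERMO_GRID / 100.0)
        assert compute_grad(THERMO_GRID, v + 7.0) == pytest.approx(
            compute_grad(THERMO_GRID, v), abs=1e-12)

    def test_two_point_method(self):
        v = 0.02 * THERMO_GRID
        assert compute_grad(THERMO_GRID, v, method="two_point") == \
            pytest.approx(0.02)

    def test_rejects_single_sample(self):
        with pytest.raises(ValueError):
            compute_grad([0.0, 500.0], [1.0, 2.0], window_s=120.0)


class TestDddAndAveraging:
    def test_ddd_arithmetic(self):
        assert compute_ddd(28.0, 30.0) == pytest.approx(2.0)
        assert compute_ddd(30.0, 30.0) == 0.0

    def test_ddd_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            compute_ddd(float("nan"), 30.0)

    def test_average_fingers(self):
        assert average_fingers([4.0] * 8) == (4.0, 8)
        assert average_fingers(list(range(1, 9))) == (4.5, 8)

    def test_average_fingers_missing_aware(self):
        vals = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, np.nan, np.nan]
        mean, n = average_fingers(vals)
        assert mean == pytest.approx(3.5)
        assert n == 6

    def test_average_all_missing_flagged(self):
        mean, n = average_fingers([np.nan] * 8)
        assert math.isnan(mean) and n == 0


class TestMobileAuc:
    def test_definition(self):
        assert mobile_auc_approx(2.0, 4.0) == pytest.approx(900.0 * 3.0)

    def test_constant_matches_full_auc(self):
        c = 27.3
        assert mobile_auc_approx(c, c) == pytest.approx(
            compute_auc(THERMO_GRID, np.full(61, c)))

    def test_linear_matches_full_auc(self):
        # the trapezoid through two points is exact for a line
        m, b = 0.005, 24.0
        full = compute_auc(THERMO_GRID, m * THERMO_GRID + b)
        assert mobile_auc_approx(b, m * 900.0 + b) == pytest.approx(full)

    def test_missing_frame_flagged(self):
        assert math.isnan(mobile_auc_approx(float("nan"), 3.0))

    @pytest.mark.parametrize("rates", [(0.2, 0.5), (0.5, 1.0), (1.0, 2.0)])
    def test_discrepancy_grows_with_curvature(self, rates):
        discrepancies = []
        for rate in rates:
            v = rewarming_curve(THERMO_GRID, 31.0, 7.0, rate)
            approx = mobile_auc_approx(v[0], v[-1])
            discrepancies.append(abs(approx - compute_auc(THERMO_GRID, v)))
        assert discrepancies[1] > discrepancies[0]


class TestLogTransform:
    def test_log_values(self):
        df = pd.DataFrame({"auc": [math.e ** 9, 1.0],
                           "max_value": [math.e, 1.0]})
        out = add_log_transforms(df)
        assert out["auc_log"].tolist() == pytest.approx([9.0, 0.0])
        assert out["max_log"].tolist() == pytest.approx([1.0, 0.0])

    def test_round_trip(self):
        xs = np.geomspace(1e-3, 1e6, 25)
        df = add_log_transforms(pd.DataFrame({"auc": xs, "max_value": xs}))
        assert np.exp(df["auc_log"].to_numpy()) == pytest.approx(xs, rel=1e-12)

    def test_nonpositive_flagged_not_zero_filled(self):
        df = pd.DataFrame({"auc": [-1.0, 5.0], "max_value": [2.0, 0.0]})
        with pytest.warns(UserWarning):
            out = add_log_transforms(df)
        assert math.isnan(out["auc_log"].iloc[0])
        assert math.isnan(out["max_log"].iloc[1])


class TestSummarizeDataset:
    def test_handcrafted_group(self):
        """One patient/visit/modality, constant curves: every measure known."""
        rows = []
        for roi, val in [("finger_1", 20.0), ("dorsum_left", 23.0)]:
            rows.append(dict(patient_id="P1", center_id="C1",
                             observer_id="o", visit=1, modality="thermo",
                             roi=roi, phase="baseline", time_s=-60.0,
                             value=val, room_temp_c=23.0, rcs_on_day=4))
        for roi in ["finger_1", "dorsum_left"]:
            for t in THERMO_GRID:
                rows.append(dict(patient_id="P1", center_id="C1",
                                 observer_id="o", visit=1, modality="thermo",
                                 roi=roi, phase="post_challenge", time_s=t,
                                 value=30.0, room_temp_c=23.0, rcs_on_day=4))
        out = summarize_dataset(pd.DataFrame(rows))
        assert len(out) == 1
        rec = out.iloc[0]
        assert rec["ddd"] == pytest.approx(3.0)        # 23 - 20
        assert rec["auc"] == pytest.approx(900.0 * 30.0)
        assert rec["max_value"] == pytest.approx(30.0)
        assert rec["grad"] == pytest.approx(0.0, abs=1e-12)
        assert rec["n_fingers"] == 1
        assert rec["auc_log"] == pytest.approx(math.log(27000.0))

    def test_mobile_max_grad_not_applicable(self, small_study):
        frames, _ = small_study
        out = summarize_dataset(frames)
        mob = out[out["modality"] == "mobile"]
        assert len(mob) > 0
        assert mob["max_value"].isna().all()
        assert mob["grad"].isna().all()
        assert np.isfinite(mob["auc"]).all()

    def test_full_finger_count(self, small_study):
        frames, _ = small_study
        out = summarize_dataset(frames)
        assert (out["n_fingers"] == 8).all()
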