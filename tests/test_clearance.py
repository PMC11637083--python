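import math
import warnings

import numpy as np
import pytest

import footclear as fc
from footclear.clearance import ForwardSwingWindow
from footclear.errors import InsufficientDataError
from footclear.pdr import ZuptMask

from conftest import random_rotation


class TestLowestPointTrace:
    def test_picks_minimum_and_first_on_ties(self):
        clouds = np.zeros((1, 3, 3))
        clouds[0, :, 2] = [0.003, 0.001, 0.002]
        lp, idx = fc.lowest_point_trace(clouds, np.array([0, 1, 2]))
        assert lp[0] == pytest.approx(0.001)
        assert idx[0] == 1
        clouds[0, :, 2] = [0.002, 0.001, 0.001]
        _lp, idx = fc.lowest_point_trace(clouds, np.array([0, 1, 2]))
        assert idx[0] == 1  # earliest index wins the tie

    def test_identity_pose_equals_scan_minimum_plus_height(self, shoe_cloud):
        z_shift = 0.42
        clouds = shoe_cloud.points[None].copy()
        clouds[..., 2] += z_shift
        lp, _ = fc.lowest_point_trace(clouds, shoe_cloud.sole_indices)
        want = shoe_cloud.points[shoe_cloud.sole_indices, 2].min() + z_shift
        assert lp[0] == pytest.approx(want, abs=1e-12)

    def test_random_rotations_match_exhaustive_minimum(self, shoe_cloud):
        rng = np.random.default_rng(7)
        n = 100
        rot = np.stack([random_rotation(rng) for _ in range(n)])
        pos = rng.normal(size=(n, 3))
        clouds = np.einsum("kij,nj->kni", rot, shoe_cloud.points) + pos[:, None]
        lp, idx = fc.lowest_point_trace(clouds, shoe_cloud.sole_indices)
        for k in range(n):
            zs = [clouds[k, i, 2] for i in shoe_cloud.sole_indices]
            assert lp[k] == pytest.approx(min(zs), abs=0)
            assert idx[k] == shoe_cloud.sole_indices[int(np.argmin(zs))]


def _mask(n, runs):
    flags = np.zeros(n, bool)
    for s, e in runs:
        flags[s:e] = True
    return ZuptMask(flags)


class TestForwardSwingWindow:
    def test_heel_then_toe_is_valid(self):
        n = 60
        heel = np.zeros(n)
        toe = np.zeros(n)
        heel[10] = 1.0
        toe[30] = 1.0
        win = fc.forward_swing_window((0, 5, 50), heel, toe, _mask(n, [(0, 5)]))
        assert (win.k_max_heel, win.k_max_toe, win.valid) == (10, 30, True)

    def test_toe_peak_first_is_invalid(self):
        n = 60
        heel = np.zeros(n)
        toe = np.zeros(n)
        heel[10] = 1.0
        toe[8] = 1.0
        win = fc.forward_swing_window((0, 5, 50), heel, toe, _mask(n, [(0, 5)]))
        assert not win.valid

    def test_peak_inside_stance_is_invalid(self):
        n = 60
        heel = np.zeros(n)
        toe = np.zeros(n)
        heel[3] = 1.0  # inside the stance run
        toe[30] = 1.0
        win = fc.forward_swing_window((0, 5, 50), heel, toe, _mask(n, [(0, 5)]))
        assert not win.valid

    def test_synthetic_window_brackets_oracle_mfc_instant(self, analyzed_typical):
        bout, oracle = analyzed_typical
        for win, o in zip(bout.windows, oracle):
            assert win.valid and o.valid
            assert win.k_max_heel <= o.k_mfc <= win.k_max_toe


class TestStrideMfc:
    def test_constant_lp_takes_window_start(self):
        lp = np.full(50, 0.005)
        idx = np.zeros(50, int)
        sc = fc.stride_mfc(lp, idx, ForwardSwingWindow(10, 30, True))
        assert sc.mfc == pytest.approx(0.005)
        assert sc.k_mfc == 10

    def test_negative_clearance_preserved(self):
        lp = np.full(50, 0.005)
        lp[20] = -0.002
        sc = fc.stride_mfc(lp, np.zeros(50, int), ForwardSwingWindow(10, 30, True))
        assert sc.mfc == pytest.approx(-0.002)

    def test_invalid_window_gives_invalid_stride(self):
        sc = fc.stride_mfc(np.zeros(10), np.zeros(10, int), ForwardSwingWindow(5, 3, False))
        assert not sc.valid and sc.mfc is None

    def test_pipeline_mfc_within_1mm_of_oracle(self, analyzed_typical):
        bout, oracle = analyzed_typical
        for s in bout.strides:
            o = oracle[s.stride_id]
            assert abs(s.mfc - o.mfc) < 1e-3

    def test_mfc_is_window_minimum(self, analyzed_typical):
        bout, _ = analyzed_typical
        for s in bout.valid_strides:
            seg = bout.lp[s.k_max_heel : s.k_max_toe + 1]
            assert s.mfc <= seg.max() and s.mfc == pytest.approx(seg.min())


class TestLateSwing:
    def test_final_third_sample_arithmetic(self, shoe_cloud):
        idx = np.zeros(40, int)
        locs = fc.late_swing_lowest_locations(
            ForwardSwingWindow(0, 30, True), idx, shoe_cloud
        )
        assert locs.shape == (11, 2)  # samples 20..30 inclusive

    def test_all_toe_lowest_gives_toe_coordinates(self, shoe_cloud):
        idx = np.full(40, shoe_cloud.toe_index, int)
        locs = fc.late_swing_lowest_locations(ForwardSwingWindow(0, 30, True), idx, shoe_cloud)
        assert np.allclose(locs, shoe_cloud.points[shoe_cloud.toe_index, :2])

    def test_short_window_warns_and_is_empty(self, shoe_cloud):
        with pytest.warns(UserWarning):
            locs = fc.late_swing_lowest_locations(
                ForwardSwingWindow(5, 6, True), np.zeros(10, int), shoe_cloud
            )
        assert locs.size == 0

    def test_window_length_always_final_third(self):
        for w in range(3, 200, 7):
            start = math.ceil(2 * w / 3)
            length = w - start + 1
            assert math.floor(w / 3) <= length <= math.ceil(w / 3) + 1

    def test_foot_drop_concentrates_in_forefoot(self, shoe_cloud):
        """With no late-swing dorsiflexion the analytic lowest point sits in
        the anterior third of the sole over the final third of swing (the
        forward-swing window itself is undefined for this gait, so the true
        swing schedule delimits late swing here)."""
        params = fc.scenario_params("foot_drop", seed=13, n_strides=5)
        truth = fc.simulate_foot_poses(params, shoe_cloud)
        xs = []
        starts = [s for s, _e in truth.zupt_schedule]
        for (s0, e0), s1 in zip(truth.zupt_schedule[:-1], starts[1:]):
            start = e0 + math.ceil(2 * (s1 - e0) / 3)
            world = np.einsum(
                "kij,nj->kni",
                truth.rotation[start:s1],
                shoe_cloud.points[shoe_cloud.sole_indices],
            ) + truth.position[start:s1, None, :]
            idx = world[..., 2].argmin(axis=1)
            xs.extend(shoe_cloud.points[shoe_cloud.sole_indices[idx], 0])
        xs = np.array(xs)
        x_sole = shoe_cloud.points[shoe_cloud.sole_indices, 0]
        forefoot = x_sole.min() + 2 * (x_sole.max() - x_sole.min()) / 3
        assert np.mean(xs > forefoot) > 0.9


class TestHeatmap:
    def test_single_location_closed_form(self, shoe_cloud):
        spacing, sigma = 2e-3, 10e-3
        probe = fc.sole_density_heatmap(np.empty((0, 2)), shoe_cloud, spacing, sigma)
        i, j = 8, 10
        loc = np.array([probe.grid_x[j], probe.grid_y[i]])  # exactly on a node
        heat = fc.sole_density_heatmap(loc[None], shoe_cloud, spacing, sigma)
        assert heat.density[i, j] == pytest.approx(1.0, abs=1e-12)
        assert heat.density[i, j + 1] == pytest.approx(
            np.exp(-(spacing**2) / (2 * sigma**2)), rel=1e-9
        )
        # radially decreasing along the row through the peak
        row = heat.density[i]
        assert np.all(np.diff(row[: j + 1]) >= -1e-12)
        assert np.all(np.diff(row[j:]) <= 1e-12)

    def test_empty_locations_all_zero(self, shoe_cloud):
        heat = fc.sole_density_heatmap(np.empty((0, 2)), shoe_cloud)
        assert not heat.density.any()
        assert heat.marginal_x.sum() == 0

    def test_matches_direct_summation(self, shoe_cloud):
        rng = np.random.default_rng(2)
        locs = np.vstack(
            [rng.normal([0.05, 0.01], 0.004, (15, 2)), rng.normal([-0.05, -0.02], 0.004, (15, 2))]
        )
        spacing, sigma = 4e-3, 8e-3
        heat = fc.sole_density_heatmap(locs, shoe_cloud, spacing, sigma)
        direct = np.zeros_like(heat.density)
        for i, gy in enumerate(heat.grid_y):
            for j, gx in enumerate(heat.grid_x):
                direct[i, j] = np.sum(
                    np.exp(-((gx - locs[:, 0]) ** 2 + (gy - locs[:, 1]) ** 2) / (2 * sigma**2))
                )
        direct /= direct.max()
        assert np.max(np.abs(direct - heat.density)) < 1e-9

    def test_duplicating_locations_leaves_density_unchanged(self, shoe_cloud):
        rng = np.random.default_rng(3)
        locs = rng.normal(0.0, 0.01, (20, 2))
        a = fc.sole_density_heatmap(locs, shoe_cloud)
        b = fc.sole_density_heatmap(np.vstack([locs, locs]), shoe_cloud)
        assert np.allclose(a.density, b.density, atol=1e-12)
        assert b.marginal_x.sum() == 2 * a.marginal_x.sum()

    def test_marginals_count_contributing_samples(self, shoe_cloud):
        rng = np.random.default_rng(4)
        locs = rng.uniform(-0.03, 0.03, (37, 2))
        heat = fc.sole_density_heatmap(locs, shoe_cloud)
        assert heat.marginal_x.sum() == 37
        assert heat.marginal_y.sum() == 37


class TestClearanceTrend:
    @staticmethod
    def _strides(times, mfc_mm):
        return [
            fc.StrideClearance(stride_id=i, t_start=t, valid=True, mfc=m * 1e-3,
                               k_mfc=0, i_mfc=0, k_max_heel=0, k_max_toe=1)
            for i, (t, m) in enumerate(zip(times, mfc_mm))
        ]

    def test_constant_mfc_has_zero_slope(self):
        slope, _icpt, p = fc.clearance_trend(self._strides([0, 30, 60, 90], [20, 20, 20, 20]))
        assert slope == 0.0
        assert p == pytest.approx(1.0)

    def test_exact_linear_recovery(self):
        t = np.array([0.0, 60.0, 120.0, 180.0])
        mfc = 25.0 - 2.5 * t / 60.0
        slope, icpt, p = fc.clearance_trend(self._strides(t, mfc))
        assert slope == pytest.approx(-2.5, abs=1e-9)
        assert icpt == pytest.approx(25.0, abs=1e-9)
        assert p < 1e-9

    def test_too_few_strides(self):
        with pytest.raises(InsufficientDataError):
            fc.clearance_trend(self._strides([0, 30], [20, 19]))

    def test_simulated_fatigue_slope_within_2_se(self):
        rng = np.random.default_rng(0)
        t = np.arange(120) * 1.1
        decline = -1.2  # mm/min
        mfc = 22.0 + decline * t / 60.0 + rng.normal(0, 2.0, t.size)
        slope, _icpt, p = fc.clearance_trend(self._strides(t, mfc))
        from scipy import stats

        res = stats.linregress(t / 60.0, mfc)
        assert abs(slope - decline) < 2 * res.stderr
        assert p < 0.001
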