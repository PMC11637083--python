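import numpy as np
import pytest

import footclear as fc
from footclear.errors import AlignmentError, DataError, ExtractionError
from footclear.io import MarkerTrajectory
from footclear.pdr import StrideSegmentation
from footclear.synthetic import simulate_agreement_differences
from footclear.validation import _balanced_reml, limits_of_agreement


def _traj(time, z, gaps=None):
    n = len(time)
    pos = np.column_stack([np.zeros(n), np.zeros(n), np.asarray(z, float)])
    g = np.zeros(n, bool) if gaps is None else np.asarray(gaps, bool)
    return MarkerTrajectory(time=np.asarray(time, float), position=pos, gap_mask=g)


class TestResample:
    def test_identity_on_source_times(self):
        t = np.linspace(0, 1, 201)
        traj = _traj(t, np.sin(t))
        out = fc.resample_trajectory(traj, t)
        assert np.allclose(out.position, traj.position, atol=1e-12)

    def test_midpoint_is_linear_interpolation(self):
        traj = _traj([0.0, 0.01], [0.0, 0.002])
        out = fc.resample_trajectory(traj, np.array([0.005]))
        assert out.position[0, 2] == pytest.approx(0.001, abs=1e-15)

    def test_sinusoid_downsampling_error_bound(self):
        """Linear interpolation of a sinusoid sampled at 200 Hz is accurate
        to the standard second-derivative bound."""
        f, amp = 4.0, 0.05
        t200 = np.arange(0, 2.0, 1 / 200.0)
        traj = _traj(t200, amp * np.sin(2 * np.pi * f * t200))
        t128 = np.arange(0.0, 1.9, 1 / 128.0)
        out = fc.resample_trajectory(traj, t128)
        analytic = amp * np.sin(2 * np.pi * f * t128)
        bound = (2 * np.pi * f) ** 2 / (2 * 200.0**2) * amp
        assert np.max(np.abs(out.position[:, 2] - analytic)) < bound

    def test_gap_propagates_to_bracketing_targets(self):
        t = np.arange(5) * 0.01
        traj = _traj(t, np.zeros(5), gaps=[False, False, True, False, False])
        out = fc.resample_trajectory(traj, np.array([0.005, 0.015, 0.025, 0.035]))
        assert list(out.gap_mask) == [False, True, True, False]

    def test_out_of_span_raises(self):
        traj = _traj([0.0, 1.0], [0.0, 1.0])
        with pytest.raises(DataError):
            fc.resample_trajectory(traj, np.array([1.5]))


class TestMatchStrides:
    def _seg(self, n_strides, stride_len=100, stance=20):
        strides = [
            (i * stride_len, i * stride_len + stance, (i + 1) * stride_len)
            for i in range(n_strides)
        ]
        return StrideSegmentation(strides=strides)

    def _signal(self, n_strides, stride_len=100, rng=None):
        t = np.arange(n_strides * stride_len + stride_len)
        z = np.sin(2 * np.pi * t / stride_len) ** 2 * 0.1
        if rng is not None:
            z = z + rng.normal(0, 0.002, z.size)
        return z

    def test_identical_signals_zero_lag(self):
        z = self._signal(5)
        pairs, lag, peak = fc.match_strides(z, self._seg(5), z.copy())
        assert lag == 0 and peak > 0.99
        assert [p[0] for p in pairs] == list(range(5))

    def test_constructed_shift_recovered(self):
        z = self._signal(6)
        ref = np.concatenate([np.zeros(64), z])
        pairs, lag, _peak = fc.match_strides(z, self._seg(6), ref)
        assert lag == 64
        assert all(a == s + 64 for sid, (a, b) in pairs for s in [self._seg(6).strides[sid][0]])

    def test_gapped_reference_drops_pairs(self):
        z = self._signal(5)
        gaps = np.zeros(z.size, bool)
        gaps[250:260] = True  # inside stride 2
        pairs, _lag, _peak = fc.match_strides(z, self._seg(5), z.copy(), ref_gap_mask=gaps)
        assert 2 not in [p[0] for p in pairs]
        assert len(pairs) == 4

    def test_noisy_pair_matches_95_percent(self):
        rng = np.random.default_rng(10)
        z = self._signal(20, rng=rng)
        ref = self._signal(20, rng=rng)  # independent noise, zero true lag
        pairs, lag, _peak = fc.match_strides(z, self._seg(20), ref)
        assert lag == 0
        assert len(pairs) >= 19

    def test_uncorrelated_signals_raise(self):
        rng = np.random.default_rng(1)
        with pytest.raises(AlignmentError):
            fc.match_strides(
                rng.normal(size=500), self._seg(4), rng.normal(size=500)
            )


def _m_trace(p1=0.08, valley=0.04, p2=0.12, n=60):
    t = np.linspace(0, 1, n)
    return (
        p1 * np.exp(-((t - 0.25) ** 2) / 0.01)
        + p2 * np.exp(-((t - 0.75) ** 2) / 0.01)
        + valley * np.exp(-((t - 0.5) ** 2) / 0.02)
    )


class TestExtractKeyPoints:
    def test_m_shaped_trace(self):
        trace = _m_trace()
        kp = fc.extract_key_points(trace, prominence_min=5e-3)
        assert kp.shape_class == "M"
        # oracle: direct extrema of the constructed curve
        k1 = np.argmax(trace[:30])
        k2 = 30 + np.argmax(trace[30:])
        assert kp.max_p1 == pytest.approx(trace[k1], abs=1e-12)
        assert kp.max_p2 == pytest.approx(trace[k2], abs=1e-12)
        assert kp.min_p == pytest.approx(trace[k1:k2].min(), abs=1e-12)

    def test_single_peak_trace(self):
        t = np.linspace(0, 1, 50)
        kp = fc.extract_key_points(0.1 * np.sin(np.pi * t), prominence_min=5e-3)
        assert kp.shape_class == "single"
        assert kp.max_p1 is None and kp.min_p is None
        assert kp.max_p2 == pytest.approx(0.1, abs=2e-3)

    def test_no_peak_raises(self):
        with pytest.raises(ExtractionError):
            fc.extract_key_points(np.linspace(0, 1, 30))

    @pytest.mark.parametrize("shift", [-0.3, 0.0, 1.7])
    def test_invariant_to_constant_offset(self, shift):
        base = fc.extract_key_points(_m_trace())
        moved = fc.extract_key_points(_m_trace() + shift)
        assert moved.max_p1 == pytest.approx(base.max_p1 + shift, abs=1e-12)
        assert moved.min_p == pytest.approx(base.min_p + shift, abs=1e-12)
        assert moved.max_p2 == pytest.approx(base.max_p2 + shift, abs=1e-12)

    def test_noisy_m_strides_recovered_within_3_sigma(self):
        rng = np.random.default_rng(17)
        sigma = 1e-3
        hits = 0
        n = 100
        for _ in range(n):
            kp = fc.extract_key_points(
                _m_trace() + rng.normal(0, sigma, 60), prominence_min=5e-3
            )
            if (
                kp.shape_class == "M"
                and abs(kp.max_p1 - 0.08) < 3 * sigma + 5e-3
                and abs(kp.max_p2 - 0.12) < 3 * sigma + 5e-3
            ):
                hits += 1
        assert hits >= 95

    def test_pairing_requires_same_shape_class(self):
        m = fc.extract_key_points(_m_trace())
        t = np.linspace(0, 1, 50)
        single = fc.extract_key_points(0.1 * np.sin(np.pi * t))
        assert fc.pair_key_points(m, single) is None
        pairs = fc.pair_key_points(m, m)
        assert [p[0] for p in pairs] == ["max_p1", "min_p", "max_p2"]


class TestLimitsOfAgreement:
    def test_all_zero_differences(self):
        r = limits_of_agreement(np.zeros(12), ["P"] * 12, [f"s{i//3}" for i in range(12)])
        assert (r.bias, r.lower, r.upper) == (0.0, 0.0, 0.0)

    def test_constant_differences_collapse(self):
        r = limits_of_agreement(np.full(9, -1.7), ["P"] * 9, [f"s{i//3}" for i in range(9)])
        assert (r.bias, r.lower, r.upper) == (-1.7, -1.7, -1.7)
        assert r.var_participant == r.var_stride == r.var_residual == 0.0

    def test_balanced_recovery_of_simulated_components(self):
        d, pid, sid = simulate_agreement_differences(seed=42)
        r = limits_of_agreement(d, pid, sid)
        se_bias = np.sqrt(4 / 3 + 4 / 150 + 9 / 450)
        assert abs(r.bias - (-0.05)) < 3 * se_bias
        lo = -0.05 - 1.96 * np.sqrt(17)
        hi = -0.05 + 1.96 * np.sqrt(17)
        assert abs(r.lower - lo) < 0.10 * abs(lo)
        assert abs(r.upper - hi) < 0.10 * abs(hi)

    def test_balanced_closed_form_agrees_with_mixedlm(self):
        """The balanced-design closed form must match the general REML
        fitter (statsmodels MixedLM) — dual-route check."""
        import warnings

        import pandas as pd
        from statsmodels.regression.mixed_linear_model import MixedLM

        d, pid, sid = simulate_agreement_differences(
            seed=3, n_participants=4, n_strides=6, n_keypoints=3, exact_moments=False
        )
        vp, vs, ve = _balanced_reml(d, pid, sid, 4, 6, 3)
        df = pd.DataFrame({"d": d, "participant": pid, "stride": sid})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = MixedLM.from_formula(
                "d ~ 1",
                groups="participant",
                re_formula="1",
                vc_formula={"stride": "0 + C(stride)"},
                data=df,
            ).fit(reml=True)
        assert vp == pytest.approx(float(fit.cov_re.iloc[0, 0]), abs=2e-2)
        assert vs == pytest.approx(float(fit.vcomp[0]), abs=2e-2)
        assert ve == pytest.approx(float(fit.scale), abs=2e-2)

    def test_unbalanced_design_goes_through_mixedlm(self):
        rng = np.random.default_rng(8)
        d, pid, sid = simulate_agreement_differences(seed=8, n_participants=3, n_strides=8)
        keep = rng.random(d.size) > 0.2  # knock out random observations
        r = limits_of_agreement(d[keep], pid[keep], sid[keep])
        assert np.isfinite(r.bias) and r.lower < r.bias < r.upper

    def test_single_participant_converges_to_classic_bland_altman(self):
        rng = np.random.default_rng(0)
        d = rng.normal(1.0, 5.0, 10_000)
        r = limits_of_agreement(d, ["P"] * d.size, [f"s{i}" for i in range(d.size)])
        lo = d.mean() - 1.96 * d.std(ddof=1)
        hi = d.mean() + 1.96 * d.std(ddof=1)
        assert r.lower == pytest.approx(lo, rel=0.02)
        assert r.upper == pytest.approx(hi, rel=0.02)

    def test_sign_symmetry(self):
        d, pid, sid = simulate_agreement_differences(seed=5)
        a = limits_of_agreement(d, pid, sid)
        b = limits_of_agreement(-d, pid, sid)
        assert b.bias == pytest.approx(-a.bias, abs=1e-9)
        assert b.lower == pytest.approx(-a.upper, abs=1e-9)
        assert b.upper == pytest.approx(-a.lower, abs=1e-9)

    def test_stride_under_two_participants_rejected(self):
        with pytest.raises(DataError):
            limits_of_agreement(np.zeros(4) + [0, 1, 2, 3], ["A", "A", "B", "B"],
                                ["s1", "s2", "s2", "s3"])

    def test_r_squared_of_paired_heights(self):
        d, pid, sid = simulate_agreement_differences(seed=6)
        ref = np.random.default_rng(6).normal(100.0, 30.0, d.size)
        r = limits_of_agreement(d, pid, sid, recon=ref + d, ref=ref)
        assert 0.9 < r.r_squared <= 1.0


class TestValidationPipeline:
    def test_self_comparison_collapses_to_zero(self, shoe_cloud, typical_bout):
        """Feeding the reconstruction's own marker heights back as the
        reference gives zero bias and collapsed limits."""
        _p, _t, rec = typical_bout
        bout = fc.analyze_bout(rec, shoe_cloud)
        ref = MarkerTrajectory(
            time=rec.time,
            position=np.column_stack(
                [np.zeros(len(rec.time)), np.zeros(len(rec.time)), bout.marker_z]
            ),
            gap_mask=np.zeros(len(rec.time), bool),
        )
        rep = fc.validate_bout(bout, ref, rec.time)
        assert rep.agreement.bias == pytest.approx(0.0, abs=1e-9)
        assert rep.agreement.upper - rep.agreement.lower < 1e-6

    def test_constant_reference_offset_appears_as_negative_bias(
        self, shoe_cloud, typical_bout
    ):
        """difference = reconstruction - reference, so a reference shifted
        +2 mm up yields a bias of -2 mm."""
        _p, truth, rec = typical_bout
        bout = fc.analyze_bout(rec, shoe_cloud)
        ref = fc.reference_marker_trajectory(
            truth, shoe_cloud, rate=200.0, height_offset=2e-3
        )
        rep = fc.validate_bout(bout, ref, rec.time)
        assert rep.agreement.bias == pytest.approx(-2.0, abs=0.3)

    def test_noisy_reference_recovers_bias(self, shoe_cloud):
        params = fc.scenario_params("typical", seed=7, n_strides=20,
                                    accel_noise_sd=0.02, gyro_noise_sd=0.002)
        truth = fc.simulate_foot_poses(params, shoe_cloud)
        rec = fc.synthesize_imu(truth, params)
        bout = fc.analyze_bout(rec, shoe_cloud)
        ref = fc.reference_marker_trajectory(
            truth, shoe_cloud, rate=200.0, noise_sd=0.5e-3, seed=11
        )
        rep = fc.validate_bout(bout, ref, rec.time, participant_id="A")
        ag = rep.agreement
        assert ag.n >= 50
        se = ag.total_sd / np.sqrt(ag.n)
        assert abs(ag.bias) < 3 * se + 0.5
        assert ag.r_squared > 0.99
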