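"""Per-segment metric definitions against analytic and quadrature oracles."""

import numpy as np
import pytest
from scipy import integrate

import rehabpredict as rp
from rehabpredict.errors import DegenerateSegmentError, ParameterError
from rehabpredict.metrics import (
    force_rate_num_peaks,
    force_rate_sparc,
    rms_jerk,
    speed_profile,
)


def min_jerk_1d(L, T, n):
    t = np.linspace(0.0, T, n)
    tau = t / T
    return t, L * (10 * tau**3 - 15 * tau**4 + 6 * tau**5)


class TestPreprocess:
    def test_constant_trial_unchanged(self):
        n = 500
        trial = rp.TrialRecording(
            time=np.arange(n) / 100.0,
            position=np.full((n, 3), 10.0),
            grip_force=np.full(n, 3.0),
            board=rp.default_board())
        out = rp.preprocess(trial)
        assert np.allclose(out.position, trial.position, atol=1e-8)
        assert np.allclose(out.grip_force, trial.grip_force, atol=1e-8)

    def test_passband_sinusoid_amplitude_preserved(self):
        t = np.arange(2000) / 100.0
        wave = 10.0 * np.sin(2 * np.pi * 2.0 * t)   # 2 Hz, well below 10 Hz
        trial = rp.TrialRecording(
            time=t, position=np.column_stack([wave, wave, wave]),
            grip_force=np.zeros_like(t),
            board=rp.default_board())
        out = rp.preprocess(trial, kinematic_cutoff=10.0)
        mid = slice(200, -200)  # avoid filter edge transients
        assert np.max(np.abs(out.position[mid, 0])) == pytest.approx(10.0, rel=0.01)

    def test_noise_variance_reduced(self):
        rng = np.random.default_rng(0)
        t = np.arange(4000) / 100.0
        noise = rng.normal(0, 1.0, size=len(t)) + 5.0
        trial = rp.TrialRecording(
            time=t, position=np.zeros((len(t), 3)),
            grip_force=np.clip(noise, 0, None),
            board=rp.default_board())
        out = rp.preprocess(trial, force_cutoff=20.0)
        assert out.grip_force.var() < trial.grip_force.var()

    def test_cutoff_at_nyquist_rejected(self):
        t = np.arange(100) / 100.0
        trial = rp.TrialRecording(
            time=t, position=np.zeros((100, 3)), grip_force=np.zeros(100),
            board=rp.default_board())
        with pytest.raises(ParameterError):
            rp.preprocess(trial, kinematic_cutoff=50.0)


class TestLogDimensionlessJerk:
    def test_matches_quadrature_oracle_on_minimum_jerk(self):
        L, T, n = 120.0, 1.2, 20001
        t, x = min_jerk_1d(L, T, n)
        value = rp.log_dimensionless_jerk(x, t[1] - t[0])
        jerk = lambda s: L / T**3 * (60 - 360 * (s / T) + 360 * (s / T) ** 2)
        integral, _ = integrate.quad(lambda s: jerk(s) ** 2, 0, T)
        oracle = np.log(T**5 / L**2 * integral)
        assert value == pytest.approx(oracle, abs=1e-3)

    def test_invariant_to_spatial_and_temporal_scaling(self):
        t, x = min_jerk_1d(100.0, 1.0, 3000)
        base = rp.log_dimensionless_jerk(x, t[1] - t[0])
        assert abs(rp.log_dimensionless_jerk(2 * x, t[1] - t[0]) - base) < 1e-9
        t2, x2 = min_jerk_1d(100.0, 2.0, 3000)
        assert abs(rp.log_dimensionless_jerk(x2, t2[1] - t2[0]) - base) < 1e-9

    def test_tremor_strictly_degrades_smoothness(self):
        t, x = min_jerk_1d(100.0, 1.0, 2000)
        values = [rp.log_dimensionless_jerk(
            x + a * np.sin(2 * np.pi * 4.0 * t), t[1] - t[0])
            for a in (0.0, 0.5, 1.0, 2.0, 4.0)]
        assert np.all(np.diff(values) > 0)

    def test_zero_movement_is_degenerate(self):
        with pytest.raises(DegenerateSegmentError):
            rp.log_dimensionless_jerk(np.zeros(100), 0.01)


class TestSpectralArcLength:
    def test_sampling_rate_invariance(self):
        t, x = min_jerk_1d(100.0, 1.2, 6000)
        dense = rp.spectral_arc_length(speed_profile(x, t[1] - t[0]), t[1] - t[0])
        t2, x2 = min_jerk_1d(100.0, 1.2, 600)
        coarse = rp.spectral_arc_length(
            speed_profile(x2, t2[1] - t2[0]), t2[1] - t2[0])
        assert dense == pytest.approx(coarse, abs=1e-2)

    def test_amplitude_invariance(self):
        t, x = min_jerk_1d(100.0, 1.0, 1000)
        s = speed_profile(x, t[1] - t[0])
        assert (rp.spectral_arc_length(s, 0.001)
                == rp.spectral_arc_length(10 * s, 0.001))

    def test_tremor_makes_value_strictly_more_negative(self):
        t, x = min_jerk_1d(100.0, 1.0, 2000)
        dt = t[1] - t[0]
        clean = rp.spectral_arc_length(speed_profile(x, dt), dt)
        shaky = rp.spectral_arc_length(
            speed_profile(x + 2.0 * np.sin(2 * np.pi * 4.0 * t), dt), dt)
        assert shaky < clean

    def test_constant_speed_gives_finite_value(self):
        v = rp.spectral_arc_length(np.full(500, 3.0), 0.01)
        assert np.isfinite(v) and v <= 0

    def test_all_zero_profile_is_degenerate(self):
        with pytest.raises(DegenerateSegmentError):
            rp.spectral_arc_length(np.zeros(100), 0.01)


class TestPathLengthRatio:
    def test_straight_segment_is_one(self):
        pos = np.column_stack([np.linspace(0, 100, 50),
                               np.linspace(0, 50, 50),
                               np.zeros(50)])
        assert rp.path_length_ratio(pos) == pytest.approx(1.0, abs=1e-12)

    def test_semicircle_is_pi_over_two(self):
        th = np.linspace(0, np.pi, 4000)
        pos = np.column_stack([np.cos(th), np.sin(th), np.zeros_like(th)])
        assert rp.path_length_ratio(pos) == pytest.approx(np.pi / 2, abs=1e-3)

    def test_monotone_in_curvature_gain(self):
        tau = np.linspace(0, 1, 500)
        values = []
        for gain in (0.0, 0.1, 0.2, 0.4, 0.8):
            pos = np.column_stack([100 * tau, gain * 100 * np.sin(np.pi * tau),
                                   np.zeros_like(tau)])
            values.append(rp.path_length_ratio(pos))
        assert np.all(np.diff(values) > 0)
        assert all(v >= 1.0 for v in values)

    def test_closed_loop_is_degenerate(self):
        th = np.linspace(0, 2 * np.pi, 100)
        pos = np.column_stack([np.cos(th), np.sin(th), np.zeros_like(th)])
        with pytest.raises(DegenerateSegmentError):
            rp.path_length_ratio(pos)


class TestVelocityMax:
    def test_constant_velocity(self):
        pos = np.column_stack([np.linspace(0, 100, 101),
                               np.zeros(101), np.zeros(101)])
        assert rp.velocity_max(pos, 0.01) == pytest.approx(100.0)

    def test_minimum_jerk_peak_speed(self):
        L, T = 150.0, 1.2
        t, x = min_jerk_1d(L, T, 5000)
        assert rp.velocity_max(x, t[1] - t[0]) == pytest.approx(
            1.875 * L / T, rel=0.01)

    def test_zero_movement_gives_zero(self):
        assert rp.velocity_max(np.zeros((10, 3)), 0.01) == 0.0


class TestRmsJerk:
    def test_straight_constant_velocity_is_zero(self):
        pos = np.column_stack([np.linspace(0, 100, 200),
                               np.zeros(200), np.zeros(200)])
        assert rms_jerk(pos, 0.01) == pytest.approx(0.0, abs=1e-6)

    def test_increases_with_tremor_amplitude(self):
        t, x = min_jerk_1d(50.0, 0.8, 1000)
        values = [rms_jerk(x + a * np.sin(2 * np.pi * 4.0 * t), t[1] - t[0])
                  for a in (0.0, 0.5, 1.0, 2.0)]
        assert np.all(np.diff(values) > 0)

    def test_sampling_convergence_within_five_percent(self):
        t, x = min_jerk_1d(50.0, 0.8, 4000)
        dense = rms_jerk(x, t[1] - t[0])
        t2, x2 = min_jerk_1d(50.0, 0.8, 2000)
        half = rms_jerk(x2, t2[1] - t2[0])
        assert half == pytest.approx(dense, rel=0.05)


class TestForceRateMetrics:
    def test_monotone_ramp_has_no_peaks(self):
        tt = np.arange(0, 2, 0.01)
        assert force_rate_num_peaks(2 + 2 * tt, 0.01) == 0

    @pytest.mark.parametrize("k", [2, 3, 5])
    def test_k_full_cycles_give_k_peaks(self, k):
        tt = np.arange(0, 2, 0.01)
        force = 2 + 2 * tt - 1.5 * np.cos(2 * np.pi * (k / 2) * tt)
        assert force_rate_num_peaks(force, 0.01) == k

    def test_sub_prominence_ripples_not_counted(self):
        tt = np.arange(0, 2, 0.01)
        force = 0.5 * tt**2 + 1e-4 * np.sin(2 * np.pi * 3 * tt)
        assert force_rate_num_peaks(force, 0.01) == 0

    def test_oscillatory_force_rate_less_smooth_than_bell(self):
        tt = np.arange(0, 2, 0.01)
        bell = 2 + 4 * np.sin(np.pi * tt / 2) ** 2
        wobble = bell + 0.3 * np.sin(2 * np.pi * 6 * tt)
        assert force_rate_sparc(wobble, 0.01) < force_rate_sparc(bell, 0.01)

    def test_amplitude_scaling_invariance(self):
        tt = np.arange(0, 2, 0.01)
        bell = 2 + 4 * np.sin(np.pi * tt / 2) ** 2
        assert force_rate_sparc(bell, 0.01) == force_rate_sparc(10 * bell, 0.01)

    def test_constant_force_is_degenerate(self):
        with pytest.raises(DegenerateSegmentError):
            force_rate_sparc(np.full(200, 5.0), 0.01)


class TestConfoundsAndNormalization:
    def test_identity_at_reference_means(self, reference):
        ref, _ = reference
        raw = ref.healthy_median + 1.0
        cov = {c: float(ref.covariate_means[c]) for c in ref.covariate_means.index}
        out = rp.adjust_confounds(raw, cov, ref)
        assert np.allclose(out, raw)

    def test_null_coefficients_are_identity(self, reference):
        ref, _ = reference
        import dataclasses
        null = dataclasses.replace(ref, confound_coefs=ref.confound_coefs * 0.0)
        raw = ref.healthy_median
        cov = {"age": 77.0, "sex": 1, "dominant_hand_tested": 0,
               "stereo_vision_deficit": 1}
        assert np.allclose(rp.adjust_confounds(raw, cov, null), raw)

    def test_planted_age_slope_recovered_within_ten_percent(self, reference):
        ref, table = reference
        planted = table.attrs["planted_age_slopes"]
        for m in rp.METRIC_NAMES:
            fitted = ref.confound_coefs.loc[m, "age"]
            assert abs(fitted - planted[m]) <= 0.1 * abs(planted[m])

    def test_age_adjustment_equalizes_twin_subjects(self, reference):
        ref, _ = reference
        base_cov = {c: float(ref.covariate_means[c])
                    for c in ref.covariate_means.index}
        young, old = dict(base_cov, age=40.0), dict(base_cov, age=70.0)
        raw_young = ref.healthy_median.copy()
        raw_old = raw_young + ref.confound_coefs["age"] * 30.0
        a = rp.adjust_confounds(raw_young, young, ref)
        b = rp.adjust_confounds(raw_old, old, ref)
        assert np.allclose(a, b, atol=1e-9)

    def test_out_of_support_age_warns(self, reference):
        ref, _ = reference
        cov = {"age": 99.0, "sex": 0, "dominant_hand_tested": 1,
               "stereo_vision_deficit": 0}
        with pytest.warns(UserWarning, match="extrapolat"):
            rp.adjust_confounds(ref.healthy_median, cov, ref)

    def test_normalization_anchors(self, reference):
        ref, _ = reference
        at_median = rp.normalize_metrics(ref.healthy_median, ref)
        assert np.allclose(at_median, 0.0)
        at_worst = rp.normalize_metrics(ref.worst_impaired, ref)
        assert np.allclose(at_worst, 100.0)

    def test_better_than_healthy_is_negative(self, reference):
        ref, _ = reference
        better = ref.healthy_median - 0.5 * ref.worse_direction * (
            ref.worst_impaired - ref.healthy_median).abs()
        pct = rp.normalize_metrics(better, ref)
        assert (pct < 0).all()

    def test_normalization_is_affine_and_order_preserving(self, reference):
        ref, _ = reference
        rng = np.random.default_rng(4)
        a = ref.healthy_median + rng.normal(size=10)
        b = ref.healthy_median + rng.normal(size=10)
        na, nb = rp.normalize_metrics(a, ref), rp.normalize_metrics(b, ref)
        mid = rp.normalize_metrics((a + b) / 2, ref)
        assert np.allclose(mid, (na + nb) / 2)          # affine
        worse = ref.healthy_median + ref.worse_direction * 1.0
        assert (rp.normalize_metrics(worse, ref)
                > rp.normalize_metrics(ref.healthy_median, ref)).all()
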