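"""Detrended fluctuation analysis: profile, F(t), exponent, calibration."""

import numpy as np
import pytest

from neurofei.bands import FrequencyBin
from neurofei.dfa import (
    EstimationError,
    FittingRange,
    FluctuationCurve,
    calibrate_lower_bound,
    compute_fluctuations,
    default_window_sizes,
    fit_exponent,
    signal_profile,
)
from neurofei.validation import fractional_gaussian_noise

FS = 250.0


def brute_force_fluctuations(profile, fs, window_sizes, overlap=0.5):
    """Naive per-window double-loop oracle for F(t)."""
    out_sizes, out_f = [], []
    seen = set()
    for t_sec in window_sizes:
        n = int(round(t_sec * fs))
        if n < 4 or n > len(profile) or n in seen:
            continue
        seen.add(n)
        step = max(1, int(round(n * (1 - overlap))))
        rms_values = []
        for start in range(0, len(profile) - n + 1, step):
            w = np.asarray(profile[start: start + n], dtype=float)
            x = np.arange(n, dtype=float)
            slope, intercept = np.polyfit(x, w, 1)
            resid = w - (slope * x + intercept)
            rms_values.append(np.sqrt(np.mean(resid**2)))
        out_sizes.append(n / fs)
        out_f.append(np.mean(rms_values))
    return np.array(out_sizes), np.array(out_f)


class TestSignalProfile:
    def test_hand_computed_example(self):
        np.testing.assert_allclose(signal_profile(np.array([1.0, 2, 3])), [-1, -1, 0])

    def test_constant_envelope_gives_zero_profile(self):
        np.testing.assert_allclose(signal_profile(np.full(100, 7.3)), 0, atol=1e-9)

    def test_linearity_in_amplitude(self):
        rng = np.random.default_rng(0)
        x = rng.random(500)
        np.testing.assert_allclose(
            signal_profile(4.0 * x), 4.0 * signal_profile(x), rtol=1e-12
        )

    def test_profile_ends_at_zero(self):
        x = np.random.default_rng(1).random(1000)
        assert abs(signal_profile(x)[-1]) < 1e-7


class TestComputeFluctuations:
    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        profile = signal_profile(np.abs(rng.standard_normal(10_000)))
        sizes = default_window_sizes(t_max=8.0)
        fast = compute_fluctuations(profile, FS, sizes)
        slow_sizes, slow_f = brute_force_fluctuations(profile, FS, sizes)
        np.testing.assert_allclose(fast.window_sizes, slow_sizes)
        np.testing.assert_allclose(fast.fluctuations, slow_f, rtol=1e-9)

    def test_white_noise_profile_slope_near_half(self):
        rng = np.random.default_rng(11)
        profile = signal_profile(rng.standard_normal(200_000))
        curve = compute_fluctuations(profile, 100.0, default_window_sizes(t_max=100))
        fit = fit_exponent(curve, FittingRange(1.0, 100.0))
        assert abs(fit.exponent - 0.5) < 0.03

    def test_fluctuations_monotone_nondecreasing(self, white_noise_envelope):
        profile = signal_profile(white_noise_envelope)
        curve = compute_fluctuations(profile, FS, default_window_sizes(t_max=30))
        assert np.all(np.diff(curve.fluctuations) > 0)

    def test_amplitude_scaling_scales_f_not_slope(self):
        rng = np.random.default_rng(3)
        x = np.abs(rng.standard_normal(50_000))
        c1 = compute_fluctuations(signal_profile(x), FS)
        c2 = compute_fluctuations(signal_profile(5.0 * x), FS)
        np.testing.assert_allclose(c2.fluctuations, 5.0 * c1.fluctuations, rtol=1e-9)
        f1 = fit_exponent(c1, FittingRange(0.5, 30))
        f2 = fit_exponent(c2, FittingRange(0.5, 30))
        assert abs(f1.exponent - f2.exponent) < 1e-12

    def test_additive_offset_leaves_everything_unchanged(self):
        rng = np.random.default_rng(4)
        x = np.abs(rng.standard_normal(20_000))
        c1 = compute_fluctuations(signal_profile(x), FS)
        c2 = compute_fluctuations(signal_profile(x + 123.0), FS)
        np.testing.assert_allclose(c2.fluctuations, c1.fluctuations, rtol=1e-9)

    def test_oversized_windows_skipped_with_warning(self):
        profile = signal_profile(np.random.default_rng(5).random(1000))
        with pytest.warns(UserWarning, match="skipped"):
            curve = compute_fluctuations(profile, FS, np.array([1.0, 2.0, 60.0]))
        assert curve.window_sizes.max() <= 1000 / FS

    def test_invalid_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            compute_fluctuations(np.arange(100.0), FS, overlap=1.0)


class TestFitExponent:
    def test_exact_power_law_recovered(self):
        sizes = default_window_sizes(t_max=30)
        curve = FluctuationCurve(
            window_sizes=sizes,
            fluctuations=sizes**0.8,
            n_windows=np.ones(sizes.size, dtype=int),
        )
        fit = fit_exponent(curve, FittingRange(0.1, 30))
        assert fit.exponent == pytest.approx(0.8, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("hurst", [0.55, 0.7, 0.85])
    def test_fgn_hurst_recovery(self, hurst):
        exps = []
        for seed in range(4):
            x = fractional_gaussian_noise(int(1000 * 100), hurst, seed)
            curve = compute_fluctuations(signal_profile(x), 100.0)
            exps.append(fit_exponent(curve, FittingRange(0.5, 30)).exponent)
        assert abs(np.mean(exps) - hurst) < 0.05

    def test_too_few_points_in_range(self):
        sizes = np.array([0.5, 1.0, 20.0])
        curve = FluctuationCurve(sizes, sizes**0.5, np.ones(3, dtype=int))
        with pytest.raises(EstimationError, match="window sizes"):
            fit_exponent(curve, FittingRange(5.0, 30.0))


class TestCalibration:
    def test_lower_bound_decreases_with_frequency(self):
        # the filter transient shrinks with f_low, so the trustworthy
        # scale must not grow along the scheme
        bins = [
            FrequencyBin(1, 4, 0),
            FrequencyBin(8, 10.5, 4),
            FrequencyBin(22, 28, 8),
            FrequencyBin(73, 93, 13),
        ]
        t_mins = [calibrate_lower_bound(b, FS, n_sims=10) for b in bins]
        assert all(a >= b for a, b in zip(t_mins, t_mins[1:]))
        assert t_mins[0] > 3 * t_mins[-1]

    def test_alpha_bound_leaves_room_for_the_fit(self):
        t_min = calibrate_lower_bound(FrequencyBin(8, 10.5, 4), FS)
        assert 1.0 <= t_min <= 15.0
        sizes = default_window_sizes(t_max=30)
        assert ((sizes >= t_min) & (sizes <= 30)).sum() >= 3

    def test_infinite_tolerance_gives_smallest_window(self):
        t_min = calibrate_lower_bound(
            FrequencyBin(8, 10.5, 4), FS, tolerance=np.inf, use_cache=False,
            n_sims=10, sim_duration=160.0,
        )
        assert t_min == pytest.approx(0.1)

    def test_calibration_is_cached_and_deterministic(self):
        b = FrequencyBin(22, 28, 8)
        t1 = calibrate_lower_bound(b, FS, n_sims=10)
        t2 = calibrate_lower_bound(b, FS, n_sims=10)
        assert t1 == t2
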