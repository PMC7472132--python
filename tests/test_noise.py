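import numpy as np
import pytest
from scipy import signal as sps

from ecgdenoise import (
    COLOR_ALPHA,
    DegenerateInputError,
    MotionArtifactSpec,
    NoiseSpec,
    ParameterError,
    generate_colored_noise,
    generate_motion_artifact,
    measure_snr,
    scale_noise_to_snr,
)

FS = 256.0


def fitted_psd_slope(x: np.ndarray, fs: float) -> float:
    """Averaged-periodogram log-log slope over [1 Hz, 0.45 fs]."""
    freqs, psd = sps.welch(x, fs=fs, nperseg=512)
    sel = (freqs >= 1.0) & (freqs <= 0.45 * fs)
    coef = np.polyfit(np.log10(freqs[sel]), np.log10(psd[sel]), 1)
    return float(coef[0])


class TestColoredNoise:
    @pytest.mark.parametrize("color,alpha", sorted(COLOR_ALPHA.items()))
    def test_psd_slope_matches_color(self, color, alpha):
        slopes = [
            fitted_psd_slope(generate_colored_noise(color, 2560, FS, seed), FS)
            for seed in range(10)
        ]
        assert all(abs(s - alpha) < 0.15 for s in slopes)

    def test_white_noise_is_flat(self):
        x = generate_colored_noise("white", 2560, FS, seed=0)
        assert abs(fitted_psd_slope(x, FS)) < 0.15

    def test_zero_mean_unit_variance(self):
        x = generate_colored_noise("pink", 2560, FS, seed=1)
        assert abs(x.mean()) < 1e-10
        assert abs(x.std() - 1.0) < 1e-12

    def test_deterministic_per_seed(self):
        a = generate_colored_noise("brown", 1000, FS, seed=4)
        b = generate_colored_noise("brown", 1000, FS, seed=4)
        assert np.array_equal(a, b)

    def test_unknown_color_rejected(self):
        with pytest.raises(ParameterError):
            generate_colored_noise("green", 100, FS, seed=0)
        with pytest.raises(ParameterError):
            NoiseSpec("green", -5.0)


class TestSnrCalibration:
    def test_achieved_snr_exact(self, clean_filtered):
        noise = generate_colored_noise("white", len(clean_filtered), FS, seed=0)
        res = scale_noise_to_snr(clean_filtered, noise, -5.0)
        assert abs(res.achieved_snr_db + 5.0) < 1e-6
        assert abs(measure_snr(res.clean, res.noisy) + 5.0) < 1e-6

    def test_zero_db_equalizes_power(self, rng):
        clean = rng.standard_normal(1000)
        noise = rng.standard_normal(1000)
        res = scale_noise_to_snr(clean, noise, 0.0)
        assert np.mean(res.noise**2) == pytest.approx(np.mean(clean**2), rel=1e-12)

    def test_scale_agrees_with_grid_search_oracle(self):
        clean = np.array([1.0, 1.0, 1.0, 1.0])
        noise = np.array([1.0, -1.0, 1.0, -1.0])
        res = scale_noise_to_snr(clean, noise, -15.0)
        # brute-force: scan scales, keep the one whose measured SNR is closest
        scales = np.linspace(0.1, 20.0, 2_000_001)
        snrs = 10 * np.log10(1.0 / scales**2)  # both series have unit power
        best = scales[np.argmin(np.abs(snrs + 15.0))]
        implied = np.abs(res.noise[0] / noise[0])
        assert implied == pytest.approx(best, abs=1e-5)

    def test_additive_decomposition_is_exact(self, clean_filtered):
        noise = generate_colored_noise("purple", len(clean_filtered), FS, seed=3)
        res = scale_noise_to_snr(clean_filtered, noise, -7.0)
        assert np.array_equal(res.noisy - res.clean, res.noise)

    def test_round_trip_all_colors_and_levels(self, clean_filtered):
        for color in COLOR_ALPHA:
            for target in (-5.0, -7.0, -15.0, -17.0):
                noise = generate_colored_noise(color, len(clean_filtered), FS, seed=8)
                res = scale_noise_to_snr(clean_filtered, noise, target)
                assert abs(measure_snr(res.clean, res.noisy) - target) < 1e-6

    def test_degenerate_inputs_rejected(self):
        zeros = np.zeros(10)
        ones = np.ones(10)
        with pytest.raises(DegenerateInputError):
            scale_noise_to_snr(zeros, ones, -5.0)
        with pytest.raises(DegenerateInputError):
            scale_noise_to_snr(ones, zeros, -5.0)


class TestMeasureSnr:
    def test_identical_pair_returns_infinity_sentinel(self):
        x = np.array([1.0, 2.0, 3.0])
        assert measure_snr(x, x) == np.inf

    def test_equal_residual_power_is_zero_db(self):
        ref = np.array([1.0, -1.0, 1.0, -1.0])
        assert measure_snr(ref, ref + np.array([1.0, 1.0, -1.0, -1.0])) == pytest.approx(0.0)

    def test_hand_arithmetic_example(self):
        # P_ref = (4+0+4+0)/4 = 2; residual [1,1,1,1], P_res = 1
        ref = np.array([2.0, 0.0, -2.0, 0.0])
        cor = np.array([3.0, 1.0, -1.0, 1.0])
        assert measure_snr(ref, cor) == pytest.approx(10 * np.log10(2.0), abs=1e-12)


class TestMotionArtifact:
    def test_zero_amplitudes_give_silence(self):
        spec = MotionArtifactSpec(wander_amp_mv=0, burst_amp_mv=0, pop_amp_mv=0)
        assert not np.any(generate_motion_artifact(spec, 2560, FS, seed=0))

    def test_wander_only_is_subhertz(self):
        spec = MotionArtifactSpec(wander_freq_hz=0.3, burst_amp_mv=0, pop_amp_mv=0)
        x = generate_motion_artifact(spec, 2560, FS, seed=1)
        freqs, psd = sps.periodogram(x, fs=FS)
        assert freqs[np.argmax(psd)] < 1.0

    def test_deterministic_per_seed(self):
        spec = MotionArtifactSpec()
        a = generate_motion_artifact(spec, 2560, FS, seed=2)
        b = generate_motion_artifact(spec, 2560, FS, seed=2)
        assert np.array_equal(a, b)

    def test_burst_band_validation(self):
        with pytest.raises(ParameterError):
            generate_motion_artifact(
                MotionArtifactSpec(burst_band_hz=(20.0, 200.0)), 100, FS, seed=0
            )
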