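import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecgdenoise import (
    ParameterError,
    STFTConfig,
    apply_norm,
    fit_normalizer,
    invert_norm,
    istft,
    stack_context,
    stft,
)
from ecgdenoise.spectral import reconstruction_interior


def rel_rms(a, b):
    return float(np.sqrt(np.mean((a - b) ** 2)) / np.sqrt(np.mean(b**2)))


class TestStft:
    def test_ten_second_sequence_shape(self, rng):
        spec = stft(rng.standard_normal(2560))
        assert spec.frames.shape == (37, 129)
        assert spec.config.hop == 64

    def test_zero_input_zero_magnitudes(self):
        spec = stft(np.zeros(512))
        assert not np.any(spec.magnitudes)

    def test_impulse_energy_confined_to_covering_frames(self):
        x = np.zeros(1024)
        x[0] = 1.0
        spec = stft(x)
        energy = np.sum(spec.magnitudes**2, axis=1)
        # only frame 0 covers sample 0 (frame m starts at 64*m)
        assert energy[0] > 0
        assert not np.any(energy[1:])

    def test_too_short_rejected(self):
        with pytest.raises(ParameterError):
            stft(np.zeros(255))

    @given(st.integers(min_value=256, max_value=10_000))
    @settings(max_examples=60, deadline=None)
    def test_frame_count_formula_vs_enumeration(self, n):
        cfg = STFTConfig()
        count = 0
        start = 0
        while start + cfg.n_fft <= n:  # brute-force frame enumeration
            count += 1
            start += cfg.hop
        assert cfg.n_frames(n) == count

    def test_agrees_with_scipy_stft(self, rng):
        """Independent cross-check against scipy's STFT (no padding, same window)."""
        from scipy import signal as sps

        x = rng.standard_normal(2560)
        cfg = STFTConfig()
        spec = stft(x, cfg)
        w = cfg.window
        _, _, Z = sps.stft(
            x, fs=cfg.fs, window=w, nperseg=256, noverlap=192, boundary=None, padded=False
        )
        assert np.max(np.abs(Z.T * w.sum() - spec.frames)) < 1e-12

    def test_parseval_per_frame(self, rng):
        x = rng.standard_normal(2560)
        cfg = STFTConfig()
        spec = stft(x, cfg)
        w = cfg.window
        for m in (0, 17, 36):
            frame = x[m * cfg.hop : m * cfg.hop + cfg.n_fft] * w
            spectrum = spec.frames[m]
            # one-sided spectrum: double all bins except DC and Nyquist
            weights = np.full(cfg.n_bins, 2.0)
            weights[0] = weights[-1] = 1.0
            freq_energy = np.sum(weights * np.abs(spectrum) ** 2) / cfg.n_fft
            assert freq_energy == pytest.approx(np.sum(frame**2), rel=1e-8)


class TestIstft:
    def test_round_trip_twenty_random_signals(self, rng):
        cfg = STFTConfig()
        for _ in range(20):
            x = rng.standard_normal(2560)
            back = istft(stft(x, cfg))
            sl = reconstruction_interior(2560, cfg)
            assert rel_rms(back[sl], x[sl]) < 1e-10

    def test_magnitude_with_own_phase_recombines_to_input(self, rng):
        from ecgdenoise import Spectrogram

        x = rng.standard_normal(2560)
        spec = stft(x)
        rebuilt = Spectrogram(
            frames=spec.magnitudes * np.exp(1j * spec.phases),
            config=spec.config,
            origin_length=spec.origin_length,
        )
        sl = reconstruction_interior(2560, spec.config)
        assert rel_rms(istft(rebuilt)[sl], x[sl]) < 1e-10

    def test_single_frame_against_hand_overlap_add(self, rng):
        cfg = STFTConfig()
        x = rng.standard_normal(256)
        spec = stft(x, cfg)
        assert spec.frames.shape[0] == 1
        out = istft(spec)
        w = cfg.window
        expected = w * (w * x) / np.maximum(w * w, 1e-8)  # single-term WOLA
        assert np.allclose(out, expected, atol=1e-12)

    def test_config_mismatch_rejected(self, rng):
        spec = stft(rng.standard_normal(512))
        with pytest.raises(ParameterError):
            istft(spec, STFTConfig(overlap=128))


class TestStackContext:
    def test_thirty_stacks_from_thirtyseven_frames(self, rng):
        mags = rng.standard_normal((37, 129))
        fs_ = stack_context(mags, k=8)
        assert fs_.stacks.shape == (30, 8, 129)
        assert fs_.target_index == 7
        assert np.array_equal(fs_.stacks[3], mags[3:11])

    def test_k_equal_one_is_identity(self, rng):
        mags = rng.standard_normal((10, 129))
        fs_ = stack_context(mags, k=1)
        assert np.array_equal(fs_.stacks[:, 0, :], mags)

    def test_too_few_frames_rejected(self, rng):
        with pytest.raises(ParameterError):
            stack_context(rng.standard_normal((7, 129)), k=8)


class TestNormalizer:
    def test_fit_apply_zero_mean_unit_variance(self, rng):
        x = np.abs(rng.standard_normal((200, 129))) * np.logspace(0, 3, 129)
        stats = fit_normalizer(x)
        z = apply_norm(x, stats)
        assert np.max(np.abs(z.mean(axis=0))) < 1e-9
        assert np.max(np.abs(z.var(axis=0) - 1.0)) < 1e-6

    def test_invert_round_trip(self, rng):
        x = np.abs(rng.standard_normal((50, 129)))
        stats = fit_normalizer(x)
        back = invert_norm(apply_norm(x, stats), stats)
        assert rel_rms(back, x) < 1e-12

    def test_training_stats_differ_on_shifted_data(self, rng):
        a = rng.standard_normal((100, 129))
        b = a + 5.0
        stats_a = fit_normalizer(a)
        z = apply_norm(b, stats_a)
        # b normalized with a's stats is NOT zero mean: training stats travel
        assert np.min(np.abs(z.mean(axis=0))) > 1.0
        stats_b = fit_normalizer(b)
        assert not np.allclose(stats_a.mean, stats_b.mean)

    def test_constant_bin_floored_not_raised(self):
        x = np.ones((10, 3))
        stats = fit_normalizer(x)
        assert np.all(stats.sd == 1e-8)

    def test_unfitted_stats_rejected(self, rng):
        from ecgdenoise import NormStats

        with pytest.raises(ParameterError):
            apply_norm(rng.standard_normal((4, 4)), NormStats())
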