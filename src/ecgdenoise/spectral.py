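"""Short-time Fourier analysis/synthesis and network feature construction.

Analysis uses a 256-point Hamming window with 192-point overlap (hop 64) at
256 Hz; the one-sided non-redundant spectrum of a real transform gives 129
magnitude bins per frame.  No padding is applied, so a signal of length N
yields floor((N - 256)/64) + 1 frames and reconstruction is exact wherever
the synthesis normalizer is positive.

Synthesis is weighted overlap-add with the least-squares normalizer
sum_m w(n - m*hop)^2: a plain Hamming window at 75% overlap does not satisfy
the constant-overlap-add condition, so the normalizer is required for the
round-trip contract.

Feature stacks merge 8 consecutive magnitude spectra (stride 1) as network
input; normalization to zero mean and unit variance is per frequency bin,
fitted on training frames only, because magnitudes span orders of magnitude
across bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import get_window

from .errors import ParameterError

SD_FLOOR = 1e-8


@dataclass(frozen=True)
class STFTConfig:
    n_fft: int = 256
    overlap: int = 192
    fs: float = 256.0
    window_name: str = "hamming"

    def __post_init__(self) -> None:
        if not 0 <= self.overlap < self.n_fft:
            raise ParameterError("overlap must satisfy 0 <= overlap < n_fft")

    @property
    def hop(self) -> int:
        return self.n_fft - self.overlap

    @property
    def n_bins(self) -> int:
        return self.n_fft // 2 + 1

    @property
    def window(self) -> np.ndarray:
        return get_window(self.window_name, self.n_fft, fftbins=True)

    def n_frames(self, n_samples: int) -> int:
        if n_samples < self.n_fft:
            return 0
        return (n_samples - self.n_fft) // self.hop + 1


@dataclass(frozen=True)
class Spectrogram:
    """Complex STFT frames (n_frames x n_bins) plus provenance."""

    frames: np.ndarray
    config: STFTConfig
    origin_length: int

    @property
    def magnitudes(self) -> np.ndarray:
        return np.abs(self.frames)

    @property
    def phases(self) -> np.ndarray:
        return np.angle(self.frames)


@dataclass(frozen=True)
class FeatureStack:
    """Sliding context of k consecutive magnitude frames, stride 1.

    ``stacks`` has shape (n_stacks, k, n_bins); ``target_index`` marks the
    frame within the context that the network predicts (k-1 = causal).
    """

    stacks: np.ndarray
    context_k: int
    target_index: int

    def __post_init__(self) -> None:
        if not 0 <= self.target_index < self.context_k:
            raise ParameterError("target_index must lie within the context")


def stft(seq: np.ndarray, cfg: STFTConfig | None = None) -> Spectrogram:
    """Analysis transform; requires at least one full window of samples."""
    cfg = cfg or STFTConfig()
    seq = np.asarray(seq, dtype=float)
    if len(seq) < cfg.n_fft:
        raise ParameterError(
            f"sequence of {len(seq)} samples shorter than n_fft={cfg.n_fft}"
        )
    n_frames = cfg.n_frames(len(seq))
    idx = np.arange(n_frames)[:, None] * cfg.hop + np.arange(cfg.n_fft)[None, :]
    frames = np.fft.rfft(seq[idx] * cfg.window[None, :], axis=1)
    return Spectrogram(frames=frames, config=cfg, origin_length=len(seq))


def istft(spec: Spectrogram, cfg: STFTConfig | None = None) -> np.ndarray:
    """Weighted overlap-add synthesis with least-squares normalization.

    Returns a series of ``origin_length`` samples; positions not covered by
    any window (possible tail remainder) come out as zero.
    """
    cfg = cfg or spec.config
    if cfg != spec.config:
        raise ParameterError("STFT config mismatch between spectrogram and request")
    n_frames, n_bins = spec.frames.shape
    if n_bins != cfg.n_bins:
        raise ParameterError(f"expected {cfg.n_bins} bins, got {n_bins}")
    w = cfg.window
    out = np.zeros(spec.origin_length)
    norm = np.zeros(spec.origin_length)
    time_frames = np.fft.irfft(spec.frames, n=cfg.n_fft, axis=1)
    for m in range(n_frames):
        start = m * cfg.hop
        out[start : start + cfg.n_fft] += w * time_frames[m]
        norm[start : start + cfg.n_fft] += w * w
    covered = norm > SD_FLOOR
    out[covered] /= norm[covered]
    return out


def reconstruction_interior(origin_length: int, cfg: STFTConfig) -> slice:
    """Sample range fully covered by overlapping analysis windows."""
    n_frames = cfg.n_frames(origin_length)
    covered = (n_frames - 1) * cfg.hop + cfg.n_fft if n_frames else 0
    return slice(cfg.n_fft, max(cfg.n_fft, covered - cfg.n_fft))


def stack_context(magnitudes: np.ndarray, k: int = 8, target_index: int | None = None) -> FeatureStack:
    """Merge ``k`` consecutive frames into network input stacks (stride 1)."""
    magnitudes = np.asarray(magnitudes, dtype=float)
    n_frames = magnitudes.shape[0]
    if n_frames < k:
        raise ParameterError(f"need at least k={k} frames, got {n_frames}")
    if target_index is None:
        target_index = k - 1
    idx = np.arange(n_frames - k + 1)[:, None] + np.arange(k)[None, :]
    return FeatureStack(stacks=magnitudes[idx], context_k=k, target_index=target_index)


@dataclass
class NormStats:
    """Per-bin zero-mean/unit-variance statistics, fitted on training frames."""

    mean: np.ndarray = field(default_factory=lambda: np.zeros(0))
    sd: np.ndarray = field(default_factory=lambda: np.zeros(0))
    fitted: bool = False


def fit_normalizer(training_magnitudes: np.ndarray) -> NormStats:
    """Fit per-bin mean and standard deviation over all training frames.

    A constant bin gets its sd floored at 1e-8 rather than raising.
    """
    x = np.asarray(training_magnitudes, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ParameterError("fit_normalizer needs a (n_frames >= 2, n_bins) matrix")
    mean = x.mean(axis=0)
    sd = np.maximum(x.std(axis=0), SD_FLOOR)
    return NormStats(mean=mean, sd=sd, fitted=True)


def apply_norm(x: np.ndarray, stats: NormStats) -> np.ndarray:
    if not stats.fitted:
        raise ParameterError("normalizer has not been fitted")
    return (np.asarray(x, dtype=float) - stats.mean) / stats.sd


def invert_norm(x: np.ndarray, stats: NormStats) -> np.ndarray:
    if not stats.fitted:
        raise ParameterError("normalizer has not been fitted")
    return np.asarray(x, dtype=float) * stats.sd + stats.mean
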