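"""Synthetic single-channel ECG with known R-peak ground truth.

Each beat is a sum of five Gaussian bumps (P, Q, R, S, T) placed on a beat
grid whose RR intervals carry i.i.d. Gaussian jitter (truncated at three
standard deviations).  The model is deliberately simple: downstream
evaluation only relies on R-peak timing and on the QRS energy lying inside
the 3-25 Hz band, both of which the template guarantees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError

#: (center offset from R in seconds, amplitude in mV, Gaussian width in seconds)
DEFAULT_WAVES: dict[str, tuple[float, float, float]] = {
    "P": (-0.2, 0.15, 0.025),
    "Q": (-0.03, -0.1, 0.01),
    "R": (0.0, 1.0, 0.012),
    "S": (0.03, -0.15, 0.01),
    "T": (0.25, 0.3, 0.05),
}

#: hard physiological floor on the RR interval (240 bpm)
MIN_RR_S = 0.25


@dataclass(frozen=True)
class ECGModelParams:
    """Parameters of the sum-of-Gaussians beat model.

    Parameters
    ----------
    fs : float
        Sampling rate in Hz.  256 Hz matches the conditioned input of the
        denoising pipeline; 1000 Hz exercises the resampling stage.
    heart_rate_bpm : float
        Mean heart rate in beats per minute, within [30, 220].
    rr_jitter_s : float
        Standard deviation of the beat-to-beat interval in seconds.
    waves : dict
        Mapping wave name -> (offset_s, amplitude_mv, width_s).  The R wave
        must have the strictly largest absolute amplitude.
    """

    fs: float = 256.0
    heart_rate_bpm: float = 60.0
    rr_jitter_s: float = 0.03
    waves: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_WAVES)
    )

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ParameterError(f"fs must be positive, got {self.fs}")
        if not 30.0 <= self.heart_rate_bpm <= 220.0:
            raise ParameterError(
                f"heart_rate_bpm must lie in [30, 220], got {self.heart_rate_bpm}"
            )
        if self.rr_jitter_s < 0:
            raise ParameterError("rr_jitter_s must be non-negative")
        if "R" not in self.waves:
            raise ParameterError("waves must include an R component")
        r_amp = abs(self.waves["R"][1])
        for name, (_, amp, width) in self.waves.items():
            if width <= 0:
                raise ParameterError(f"wave {name} width must be positive")
            if name != "R" and abs(amp) >= r_amp:
                raise ParameterError(
                    f"R amplitude must strictly dominate; wave {name} violates this"
                )

    @property
    def mean_rr_s(self) -> float:
        return 60.0 / self.heart_rate_bpm


@dataclass(frozen=True)
class SyntheticRecord:
    """A generated ECG trace with ground-truth annotations."""

    samples: np.ndarray  # mV
    fs: float
    r_peaks: np.ndarray  # sample indices, strictly increasing
    seed: int

    def __post_init__(self) -> None:
        peaks = np.asarray(self.r_peaks)
        if peaks.size:
            if np.any(np.diff(peaks) <= 0):
                raise ParameterError("r_peaks must be strictly increasing")
            if peaks[0] < 0 or peaks[-1] >= len(self.samples):
                raise ParameterError("r_peaks out of record bounds")
            if np.any(np.diff(peaks) < MIN_RR_S * self.fs):
                raise ParameterError("r_peaks violate the minimum RR interval")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs


def _beat_times(params: ECGModelParams, duration_s: float, rng: np.random.Generator) -> np.ndarray:
    """Jittered beat grid: first beat at half the mean RR, then jittered steps."""
    rr = params.mean_rr_s
    times = []
    t = 0.5 * rr
    while t < duration_s:
        times.append(t)
        jitter = rng.normal(0.0, params.rr_jitter_s) if params.rr_jitter_s > 0 else 0.0
        jitter = float(np.clip(jitter, -3 * params.rr_jitter_s, 3 * params.rr_jitter_s))
        step = max(rr + jitter, MIN_RR_S + 1.0 / params.fs)
        t += step
    return np.asarray(times)


def generate_ecg(
    params: ECGModelParams, duration_s: float, seed: int
) -> SyntheticRecord:
    """Generate a synthetic ECG record of ``duration_s`` seconds.

    The record has ``round(duration_s * fs)`` samples and roughly
    ``heart_rate_bpm * duration_s / 60`` R-peaks.  Output is deterministic
    for a fixed seed.
    """
    if duration_s < 0:
        raise ParameterError("duration_s must be non-negative")
    n = int(round(duration_s * params.fs))
    if n == 0:
        return SyntheticRecord(
            samples=np.zeros(0), fs=params.fs, r_peaks=np.zeros(0, dtype=int), seed=seed
        )
    rng = np.random.default_rng(seed)
    t = np.arange(n) / params.fs
    beat_times = _beat_times(params, duration_s, rng)

    samples = np.zeros(n)
    for bt in beat_times:
        for offset, amp, width in params.waves.values():
            center = bt + offset
            # Gaussians are negligible beyond 5 widths; restrict the support
            lo = max(0, int((center - 5 * width) * params.fs))
            hi = min(n, int((center + 5 * width) * params.fs) + 1)
            if lo >= hi:
                continue
            tt = t[lo:hi]
            samples[lo:hi] += amp * np.exp(-0.5 * ((tt - center) / width) ** 2)

    r_idx = np.round(beat_times * params.fs).astype(int)
    r_idx = r_idx[(r_idx >= 0) & (r_idx < n)]
    return SyntheticRecord(samples=samples, fs=params.fs, r_peaks=r_idx, seed=seed)
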