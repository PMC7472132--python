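"""Signal conditioning chain: resample to 256 Hz, band-pass 3-25 Hz,
cut into 10-s sequences, trim 1-s evaluation edges.

The band-pass is a 4th-order Butterworth applied forward-backward
(zero-phase), so R-peak ground-truth indices stay valid after filtering.
Resampling is rational-factor polyphase with built-in anti-aliasing.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .errors import ParameterError


@dataclass(frozen=True)
class PreprocessConfig:
    """Conditioning parameters (all frequencies in Hz, durations in seconds)."""

    fs_target: float = 256.0
    bp_low: float = 3.0
    bp_high: float = 25.0
    segment_s: float = 10.0
    edge_trim_s: float = 1.0
    order: int = 4  # Butterworth order per pass

    def __post_init__(self) -> None:
        if not 0 < self.bp_low < self.bp_high < self.fs_target / 2:
            raise ParameterError(
                "band edges must satisfy 0 < bp_low < bp_high < fs_target/2"
            )
        if self.edge_trim_s * 2 >= self.segment_s:
            raise ParameterError("edge_trim_s too large for segment_s")


def resample(seq: np.ndarray, fs_from: float, fs_to: float) -> np.ndarray:
    """Rational-factor polyphase resampling (e.g. 1000 -> 256 Hz is x32/125)."""
    if fs_from <= 0 or fs_to <= 0:
        raise ParameterError("sampling rates must be positive")
    seq = np.asarray(seq, dtype=float)
    if seq.size == 0 or fs_from == fs_to:
        return seq.copy()
    frac = Fraction(fs_to / fs_from).limit_denominator(10_000)
    return sps.resample_poly(seq, frac.numerator, frac.denominator)


def bandpass(seq: np.ndarray, fs: float, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Zero-phase Butterworth band-pass; same length as the input."""
    cfg = cfg or PreprocessConfig()
    if fs <= 2 * cfg.bp_high:
        raise ParameterError(
            f"fs={fs} too low for band edge {cfg.bp_high} Hz (need fs > {2 * cfg.bp_high})"
        )
    seq = np.asarray(seq, dtype=float)
    if seq.size == 0:
        return seq.copy()
    sos = sps.butter(cfg.order, [cfg.bp_low, cfg.bp_high], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, seq)


def segment(seq: np.ndarray, fs: float, segment_s: float = 10.0) -> list[np.ndarray]:
    """Non-overlapping consecutive windows; a trailing remainder is dropped."""
    seq = np.asarray(seq, dtype=float)
    n = int(round(segment_s * fs))
    if n <= 0:
        raise ParameterError("segment_s must be positive")
    return [seq[i : i + n].copy() for i in range(0, len(seq) - n + 1, n)]


def trim_edges(seq: np.ndarray, fs: float, edge_trim_s: float = 1.0) -> np.ndarray:
    """Drop the first and last ``edge_trim_s`` seconds (edge-effect guard)."""
    seq = np.asarray(seq, dtype=float)
    k = int(round(edge_trim_s * fs))
    if k == 0:
        return seq.copy()
    if len(seq) < 2 * k:
        raise ParameterError(
            f"sequence of {len(seq)} samples too short to trim {k} samples per edge"
        )
    return seq[k : len(seq) - k].copy()
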