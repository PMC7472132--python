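"""Pan-Tompkins R-peak detection and tolerance-window peak matching.

The detector follows the classic chain: 5-15 Hz band-pass, five-point
derivative, squaring, moving-window integration (150 ms), then adaptive
dual thresholds on integrated-signal peaks with running signal/noise level
estimates, a refractory period (200 ms), T-wave discrimination inside the
360 ms window (slope comparison), and search-back at the lower threshold
when an expected beat is missed.

The band-pass and the moving-window integrator are applied in zero-phase /
centered form, so integrated-signal peaks align with the QRS rather than
lagging it; detections are then snapped to the band-passed waveform's
local maximum.  Thresholds are initialized from the first two seconds of
the integrated signal (the learning phase).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import ParameterError


@dataclass(frozen=True)
class PeakDetectionConfig:
    pt_band_hz: tuple[float, float] = (5.0, 15.0)
    integration_window_ms: float = 150.0
    refractory_ms: float = 200.0
    twave_window_ms: float = 360.0
    init_window_s: float = 2.0
    # running-estimate update coefficients
    signal_update: float = 0.125
    noise_update: float = 0.125
    searchback_update: float = 0.25
    threshold_fraction: float = 0.25  # THR1 = noise + frac*(signal - noise)
    lower_threshold_fraction: float = 0.5  # THR2 = frac * THR1
    searchback_rr_factor: float = 1.66
    refine_window_ms: float = 75.0

    def __post_init__(self) -> None:
        if self.refractory_ms >= self.twave_window_ms:
            raise ParameterError("refractory must be shorter than the T-wave window")
        if self.integration_window_ms <= 0:
            raise ParameterError("integration window must be positive")


@dataclass(frozen=True)
class PeakMatchResult:
    """Counts and rates from one-to-one peak matching within a tolerance."""

    tp: int
    fp: int
    fn: int
    tolerance_ms: float
    ppv_defined: bool = True

    @property
    def sensitivity_pct(self) -> float:
        denom = self.tp + self.fn
        return 100.0 * self.tp / denom if denom else 100.0

    @property
    def ppv_pct(self) -> float:
        denom = self.tp + self.fp
        return 100.0 * self.tp / denom if denom else 0.0


def _preprocess_stages(seq: np.ndarray, fs: float, cfg: PeakDetectionConfig):
    sos = sps.butter(2, cfg.pt_band_hz, btype="bandpass", fs=fs, output="sos")
    bp = sps.sosfiltfilt(sos, seq)
    # centered five-point derivative (zero group delay)
    kernel = np.array([2.0, 1.0, 0.0, -1.0, -2.0]) * fs / 8.0
    deriv = np.convolve(bp, kernel, mode="same")
    squared = deriv * deriv
    n_int = max(1, int(round(cfg.integration_window_ms / 1000.0 * fs)))
    mwi = np.convolve(squared, np.ones(n_int) / n_int, mode="same")
    return bp, deriv, mwi


def detect_rpeaks(
    seq: np.ndarray, fs: float, cfg: PeakDetectionConfig | None = None
) -> np.ndarray:
    """Detected R-peak sample indices, strictly increasing.

    Requires fs >= 100 Hz and at least two seconds of signal (the threshold
    learning phase).
    """
    cfg = cfg or PeakDetectionConfig()
    seq = np.asarray(seq, dtype=float)
    if fs < 100:
        raise ParameterError(f"fs={fs} too low; need >= 100 Hz")
    n_init = int(cfg.init_window_s * fs)
    if len(seq) < n_init:
        raise ParameterError(
            f"sequence of {len(seq)} samples shorter than the "
            f"{cfg.init_window_s}-s threshold initialization window"
        )
    if not np.any(seq):
        return np.zeros(0, dtype=int)

    bp, deriv, mwi = _preprocess_stages(seq, fs, cfg)
    refractory = int(round(cfg.refractory_ms / 1000.0 * fs))
    twave_win = int(round(cfg.twave_window_ms / 1000.0 * fs))
    candidates, _ = sps.find_peaks(mwi, distance=max(1, refractory))
    if candidates.size == 0:
        return np.zeros(0, dtype=int)

    spki = np.max(mwi[:n_init]) / 3.0
    npki = np.mean(mwi[:n_init]) / 2.0

    def thr1() -> float:
        return npki + cfg.threshold_fraction * (spki - npki)

    def max_slope_around(idx: int) -> float:
        lo = max(0, idx - refractory // 2)
        hi = min(len(deriv), idx + refractory // 2 + 1)
        return float(np.max(np.abs(deriv[lo:hi])))

    accepted: list[int] = []
    rr_intervals: list[float] = []
    rejected: list[int] = []

    for peak in candidates:
        height = mwi[peak]
        is_signal = height > thr1()
        if is_signal and accepted and (peak - accepted[-1]) < twave_win:
            # possible T wave: reject if its maximal slope is under half
            # the slope of the preceding QRS
            if max_slope_around(peak) < 0.5 * max_slope_around(accepted[-1]):
                is_signal = False
        if is_signal:
            if accepted:
                rr_intervals.append(peak - accepted[-1])
            accepted.append(int(peak))
            spki = cfg.signal_update * height + (1 - cfg.signal_update) * spki
        else:
            rejected.append(int(peak))
            npki = cfg.noise_update * height + (1 - cfg.noise_update) * npki

        # search-back: if the expected beat did not arrive, revisit skipped
        # candidates at the lower threshold
        if len(rr_intervals) >= 1:
            rr_avg = float(np.mean(rr_intervals[-8:]))
            if accepted and (peak - accepted[-1]) > cfg.searchback_rr_factor * rr_avg:
                window = [
                    r
                    for r in rejected
                    if accepted[-1] + refractory < r < peak - refractory
                    and mwi[r] > cfg.lower_threshold_fraction * thr1()
                ]
                if window:
                    back = max(window, key=lambda r: mwi[r])
                    accepted.append(int(back))
                    accepted.sort()
                    rejected.remove(back)
                    spki = (
                        cfg.searchback_update * mwi[back]
                        + (1 - cfg.searchback_update) * spki
                    )

    # snap integrated-signal peaks to the band-passed waveform maximum
    refine = int(round(cfg.refine_window_ms / 1000.0 * fs))
    refined = []
    for peak in sorted(accepted):
        lo, hi = max(0, peak - refine), min(len(bp), peak + refine + 1)
        refined.append(lo + int(np.argmax(bp[lo:hi])))

    # deduplicate refined positions that collapsed within the refractory
    result: list[int] = []
    for r in sorted(refined):
        if result and r - result[-1] < refractory:
            if bp[r] > bp[result[-1]]:
                result[-1] = r
        else:
            result.append(r)
    return np.asarray(result, dtype=int)


def match_peaks(
    reference: np.ndarray,
    detected: np.ndarray,
    fs: float,
    tolerance_ms: float = 50.0,
) -> PeakMatchResult:
    """Greedy one-to-one nearest matching within ``tolerance_ms``.

    Candidate pairs are considered in order of increasing time difference;
    each reference and each detected peak is used at most once.  With no
    detections PPV is undefined and reported as 0 with ``ppv_defined``
    cleared.
    """
    reference = np.asarray(reference, dtype=int)
    detected = np.asarray(detected, dtype=int)
    tol = tolerance_ms / 1000.0 * fs
    pairs = [
        (abs(int(r) - int(d)), i, j)
        for i, r in enumerate(reference)
        for j, d in enumerate(detected)
        if abs(int(r) - int(d)) <= tol
    ]
    pairs.sort()
    used_ref: set[int] = set()
    used_det: set[int] = set()
    tp = 0
    for _, i, j in pairs:
        if i in used_ref or j in used_det:
            continue
        used_ref.add(i)
        used_det.add(j)
        tp += 1
    return PeakMatchResult(
        tp=tp,
        fp=len(detected) - tp,
        fn=len(reference) - tp,
        tolerance_ms=tolerance_ms,
        ppv_defined=len(detected) > 0,
    )
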