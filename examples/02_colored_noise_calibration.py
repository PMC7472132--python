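"""Corrupt a clean sequence with each of the five colored noises.

Each noise has power spectral density proportional to f^alpha and is
scaled so the corrupted signal sits exactly at the requested SNR; the
printout verifies the calibration and the fitted spectral slope.
"""

import numpy as np
from scipy import signal as sps

from ecgdenoise import (
    COLOR_ALPHA,
    DEFAULT_SNR_LEVELS,
    ECGModelParams,
    bandpass,
    generate_colored_noise,
    generate_ecg,
    measure_snr,
    scale_noise_to_snr,
)

record = generate_ecg(ECGModelParams(), 10.0, seed=7)
clean = bandpass(record.samples, 256.0)

print(f"{'color':8s} {'alpha':>5s} {'fitted slope':>12s} {'target dB':>9s} {'achieved dB':>11s}")
for color, alpha in COLOR_ALPHA.items():
    noise = generate_colored_noise(color, len(clean), 256.0, seed=1)
    freqs, psd = sps.welch(noise, fs=256.0, nperseg=512)
    sel = (freqs >= 1.0) & (freqs <= 0.45 * 256.0)
    slope = np.polyfit(np.log10(freqs[sel]), np.log10(psd[sel]), 1)[0]
    target = DEFAULT_SNR_LEVELS[color][0]
    corrupted = scale_noise_to_snr(clean, noise, target)
    achieved = measure_snr(corrupted.clean, corrupted.noisy)
    print(f"{color:8s} {alpha:+5.0f} {slope:12.3f} {target:9.1f} {achieved:11.6f}")
# the slope should match alpha within ~0.15 and the SNR be exact to 1e-6 dB
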