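# ecgdenoise

Spectral-domain neural denoising for single-channel ECG, with the full
evaluation loop needed to measure it: synthetic ECG with ground-truth
R-peaks, calibrated colored-noise and motion-artifact corruption,
Pan–Tompkins QRS detection, signal quality indices, and the statistical
protocol.

## The problem

Ambulatory ECG — especially from arm-worn dry-electrode devices — is
routinely corrupted by motion artifacts, muscle noise and baseline wander
that bury the QRS complexes and break heart-rate estimation. Classical
linear filtering struggles because the contamination overlaps the signal
band. This package implements a learned alternative: a **redundant
convolutional encoder–decoder (R-CED)** that regresses clean short-time
Fourier transform (STFT) magnitude spectra from noisy ones.

## The method

A sequence x[n] sampled at 256 Hz (band-passed 3–25 Hz) is analyzed with a
256-point Hamming STFT at 192-point (75%) overlap, keeping the 129-bin
one-sided magnitude spectrum |X(m, f)|. The network input is a context of
8 consecutive noisy magnitude frames, normalized per frequency bin to zero
mean and unit variance with statistics fitted on the training set; the
target is the corresponding clean frame, likewise normalized:

    |X̂_clean(m, ·)| = RCED( |X_noisy(m−7, ·)|, …, |X_noisy(m, ·)| )

The R-CED is fully convolutional along frequency: 16 convolution blocks,
the first 15 each followed by batch normalization and ReLU, the last a bare
convolution; filter counts rise and fall symmetrically with no pooling, so
the 129-bin dimension is preserved throughout. Training is SGD with
momentum (mini-batch 128, 12 epochs, learning rate ×0.95 per epoch) on a
mean-squared-error loss. At inference the predicted magnitudes are
denormalized, clamped non-negative, recombined with the **noisy phase**,
and inverted by weighted overlap-add.

Performance is measured against the clean reference by

* **SNR improvement**: SNR_imp = SNR_denoised − SNR_noisy, with
  SNR = 10·log10(P_signal / P_residual);
* **ratio of power**: fraction of total power in 5–20 Hz (high for clean
  ECG because QRS energy concentrates there);
* **cross-correlation**: zero-lag Pearson correlation with the clean
  sequence;
* **Pan–Tompkins detection**: sensitivity and positive predictivity of
  R-peak detection against ground truth (±50 ms tolerance, middle 8 s of
  each 10-s sequence).

Condition-level differences are tested with repeated-measures ANOVA plus
Bonferroni post-hoc (ratio of power) and an independent t-test
(cross-correlation).

## Worked example

`examples/03_denoise_white_noise.py` trains the denoiser on 10 synthetic
sequences corrupted with white noise at −5 dB and scores 6 held-out
sequences (a couple of minutes on one CPU):

```
condition: white -5 dB
SNR improvement      : +6.55 +/- 0.25 dB
ratio of power       : clean 0.74  noisy 0.27  denoised 0.56
cross-correlation    : noisy 0.49  denoised 0.68
detection sensitivity: clean 100.0%  noisy 100.0%  denoised 100.0%
ratio-of-power ANOVA p = 7.60e-12, noisy-vs-denoised Bonferroni p = 2.24e-05
```

The network recovers 6.5 dB of SNR from a signal whose power was three
times smaller than the noise; the ratio of power and cross-correlation move
most of the way back toward the clean values, and the differences are
statistically significant at these sample sizes. The other examples cover
simulation and detection, noise calibration, the motion-artifact
experiment, and the statistics. A command-line interface mirrors the
library (`ecgdenoise simulate | corrupt | preprocess | train | denoise |
detect | score | evaluate`).

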