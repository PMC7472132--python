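# Methods

This note documents the models, parameters and numerical choices behind
`ecgdenoise`, and what the synthetic experiments do and do not demonstrate.

## Synthetic ECG model

Each beat is a sum of five Gaussians (P, Q, R, S, T) placed on a beat grid
with i.i.d. Gaussian RR jitter truncated at ±3 sd and floored at a 0.25-s
RR interval. Default morphology (offset from R in s, amplitude in mV,
width in s): P(−0.2, 0.15, 0.025), Q(−0.03, −0.1, 0.01), R(0, 1.0, 0.012),
S(0.03, −0.15, 0.01), T(0.25, 0.3, 0.05) — a textbook-shaped adult ECG
whose QRS energy lies inside 3–25 Hz. Default rate 60 bpm with 30-ms RR
jitter; default sampling 256 Hz (a 1000-Hz mode exercises the resampler).
The first beat sits at half the mean RR so a 10-s record carries the
expected beat count ±1.

This surrogate was chosen over a limit-cycle dynamical model because only
two properties matter downstream: exact R-peak timing (known by
construction) and QRS-band spectral energy. It deliberately omits
pathological morphologies, respiration modulation and multi-lead structure,
so passing tests say nothing about arrhythmic or multi-channel data.

## Corruption models

**Colored noise.** White Gaussian noise is shaped in the FFT domain with
|H(f)| = f^(α/2) (DC forced to zero), then inverse-transformed and scaled
to unit variance; α = 0, −1, −2, +1, +2 for white, pink, brown, blue,
purple. This yields the exact asymptotic slope with no filter transients;
the fitted log–log Welch-PSD slope over [1 Hz, 0.45·fs] lands within ±0.15
of α. Noise is scaled to a target SNR with
scale = sqrt(P_clean / (P_noise·10^(SNR/10))), where power is the mean of
squared samples over the full sequence; the stored noise is the exact
residual noisy − clean so the additive decomposition is bitwise. Default
corruption levels: −5/−7 dB for white, pink, blue, purple and −15/−17 dB
for brown — deep enough that the QRS complexes are buried.

**Motion-artifact surrogate.** Additive sum of (a) baseline wander: a
0.33-Hz sinusoid plus a normalized random walk at 0.8 mV, (b) EMG-like
bursts: 20–60 Hz band-limited noise, Hann-windowed, 2 bursts/s at 1.5 mV,
and (c) electrode pops: decaying steps (τ = 0.3 s) at 0.2/s and 2 mV. With
this package's zero-phase detector the surrogate degrades detection only
moderately (sensitivity in the low-to-mid 90s, PPV near 80 on test runs)
rather than to the severe degradation seen with real armband artifacts —
the burst band overlaps the detector's 5–15 Hz passband only marginally.
The directional orderings (denoised better than noisy on every index) are
what the experiments assert; absolute degradation levels are not claims
about real recordings.

## Conditioning chain

Resampling is rational-factor polyphase (e.g. 1000→256 Hz = ×32/125) with
built-in anti-aliasing. The band-pass is a 4th-order Butterworth applied
forward–backward; zero phase keeps ground-truth R-peak indices valid after
filtering. Gain is within ±1 dB at 10 Hz with ≥20 dB attenuation at 0.2 Hz
and 50 Hz. Sequences are cut into non-overlapping 10-s windows from sample
0 (remainder dropped); all metrics are computed on the middle 8 s (1 s
trimmed per edge against filter and STFT edge effects).

## STFT and features

256-point Hamming window, hop 64 (75% overlap), one-sided 129-bin spectra,
no padding: N samples give floor((N−256)/64)+1 frames. Synthesis is
weighted overlap-add with the least-squares normalizer Σ w², required
because a Hamming window at this overlap is not constant-overlap-add;
reconstruction is exact (≪1e−10 relative) wherever windows overlap fully.
Normalization is per frequency bin (129 means and sds, floored at 1e−8 for
constant bins) because magnitudes span orders of magnitude across bins;
test data always reuses training statistics.

## Network and training

The R-CED default schedule is filter counts
(12, 16, 20, 24, 32, 24, 20, 16, 12, 16, 20, 24, 32, 24, 20, 1) with kernel
widths (13, 11, 9, 7, 7, 7, 9, 11, 13, 11, 9, 7, 7, 9, 11, 129), "same"
padding along frequency, totalling 60,125 parameters — an engineering
choice following the encoder–decoder family's symmetric
increase-then-decrease redundancy principle; both schedules are fully
configurable. The context is causal (the stack's last frame is predicted),
which permits streaming use; a centered alignment is configurable.

Training: SGD with momentum 0.9, lr₀ = 0.01 decayed ×0.95 per epoch,
mini-batch 128, 12 epochs, MSE on normalized magnitudes. Loss and
learning-rate schedule follow the standard recipe; lr₀ and momentum are
conventional values validated by the identity-task learnability check
(loss below 5% of its starting value within 12 epochs; larger rates
diverge). Initialization is seeded uniform fan-in; batch-norm uses frozen
running statistics at inference, so prediction is deterministic. Everything
is plain NumPy with im2col convolutions; single-threaded determinism holds
to the reproducibility contract (identical seeds give identical histories).

At inference, predicted magnitudes are denormalized with the training
statistics, negatives clamped to zero (counted and logged), and frames not
covered by a prediction — the first 7 under the causal alignment — fall
back to the noisy magnitudes so output length always equals input length;
the 1-s edge trim removes them from every metric anyway.

## QRS detection

Pan–Tompkins with a 5–15 Hz band-pass, five-point derivative, squaring and
150-ms moving-window integration. The band-pass is zero-phase and the
derivative/integrator centered, so integrated-signal peaks align with the
QRS instead of lagging it; detections are snapped to the band-passed
waveform's maximum within ±75 ms. Adaptive dual thresholds with 0.125
running updates, 200-ms refractory, T-wave rejection inside 360 ms when
the candidate's maximal slope is under half the preceding QRS's, and
search-back at half threshold when a beat is overdue (1.66× the running RR
mean). Thresholds initialize from the first 2 s. All constants are exposed
in the configuration. Matching against reference peaks is greedy
one-to-one nearest within ±50 ms — a standard benchmarking tolerance,
within half the integration window. Both sensitivity and positive
predictivity are reported since either denominator is defensible for a
"percent detected" figure; sensitivity is the headline number.

## Experiments and scale

The colored-noise protocol uses 10 training and 6 held-out test sequences
per condition, 5 colors × 2 levels; by default one model is trained on the
pooled 100-sequence corpus, with a per-condition mode available (tables
are reported per condition either way). The motion experiment defaults to
20 pairs (configurable up to larger cohorts) split 60/40. Heart rates are
drawn uniformly from 55–95 bpm per record. These sizes keep a full
condition grid within minutes on a single CPU while leaving enough test
sequences (6–8) for the within-subject ANOVA. Statistics: RM-ANOVA F from
explicit sums of squares with Bonferroni-corrected paired t post-hocs
(α/3), and a pooled-variance independent t-test (Welch optional);
distribution tails come from scipy.

## Degenerate inputs and sentinels

Zero-power clean or noise signals raise a degenerate-input error; a
corrupted sequence identical to its reference yields an SNR of +inf (a
documented sentinel, not an exception); constant spectral bins are floored,
not fatal; an empty detection list reports 0% PPV with a flag rather than
dividing by zero.

## Known limitations

* The surrogate data cannot reproduce absolute figures measured on real
  armband or arrhythmia-database recordings; only directional behavior
  (denoised better than noisy, clean detection at 100%) is asserted.
* The filter schedule of the original 16-block network is not public; the
  default here is an explicit stand-in with the same structure.
* The WFDB reader is minimal (header + formats 16/212, single-channel
  extraction) and intended for optional real-data experiments.
* Training is CPU-bound NumPy: adequate at desk scale, not for large
  corpora.
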