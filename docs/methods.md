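# Methods

This note documents the models behind `pcgscreen`, the parameters that
matter, the choices made where the design was genuinely open, and what the
synthetic data does and does not establish.

## Preprocessing

Every recording passes through bandpass → resample → segment → z-score.

* **Bandpass 20 Hz–1 kHz, 4th-order Butterworth, applied
  forward-backward.** Heart sounds and murmurs live below ~1 kHz; the
  zero-phase (filtfilt) realization preserves the timing of transients
  (S1/S2, murmur onsets), which matters because several features are
  envelope-sensitive. The double application gives ≥ 40 dB attenuation one
  octave beyond each edge. For inputs already sampled at 2 kHz the upper
  edge is clipped to 0.99 × Nyquist so the same chain applies.
* **Polyphase resampling to 2 kHz.** The bandpass has already made the
  signal Nyquist-safe at 2 kHz. Output length is exactly
  `round(n · 2000 / rate)`.
* **Single 30-s window from offset 0.** The window position within longer
  recordings is not otherwise determined, so the first 30 s is used:
  deterministic and reproducible. An `offset` parameter exists for
  sensitivity studies. Recordings shorter than 30 s are rejected — the
  same inclusion rule applied to open-dataset records.
* **Z-score.** Removes the unknown absolute gain of stethoscope hardware.
  A second corrective pass keeps mean/std within 1e-8 even for inputs with
  extreme offsets. Constant signals are rejected as degenerate.

## Time and frequency features

Computed on the z-scored 60 000-sample record.

* Quantiles use **linear interpolation** between order statistics (the
  most widespread convention, stated here so ports can match).
* Mean absolute deviation is taken **about the mean**; kurtosis is
  **non-excess** (Gaussian → 3).
* Shannon energy is −(1/N) Σ x² ln x² with 0·ln 0 := 0 — the standard
  envelope-emphasizing energy of heart-sound analysis.
* Zero-crossing rate counts strict sign products x_i·x_{i+1} < 0 over the
  N−1 pairs; exact zeros never count (a measure-zero event on real data,
  decided for determinism).
* The PSD is a **Welch estimate** (1024-sample Hamming windows, 50%
  overlap, one-sided, ~1.95 Hz resolution). The DC bin is excluded from
  all features; after z-scoring it carries no information.
* The **dominant-frequency ratio** is the normalized power within ±5% of
  the dominant frequency (at least ±1 bin); **bandwidth** is the
  power-weighted spectral spread around the centroid. These two
  definitions are this package's own, since the named features admit
  several readings; both are deterministic and scale-free. Dominant-bin
  ties resolve to the lowest frequency.

## MFCC (perceptual) features

13 mel-frequency cepstral coefficients per record, parameters chosen for a
2-kHz, 0–1-kHz-band signal:

| parameter | default | why |
|---|---|---|
| frame length | 256 samples (128 ms) | resolves low-frequency murmur bands |
| hop | 128 samples | 50% overlap, standard |
| mel filters | 26 triangles over 0–1000 Hz | ≥ 2 FFT bins under every filter |
| coefficients | DCT-II (orthonormal) indices 1..13 | c0 excluded |
| aggregation | arithmetic mean over frames | one scalar per coefficient |

The **0th coefficient is excluded**: it is a loudness proxy already
covered by the acoustic loudness feature, so "MFCC1" is the first
non-energy coefficient. **No pre-emphasis** is applied — that is a
speech-specific high-frequency boost inappropriate for cardiac audio.
Mean aggregation makes the result invariant to frame order, and the log
turns any overall amplitude scaling into a pure c0 shift, so the 13 kept
coefficients are level-free.

## Psychoacoustic (acoustic) features

Four scalar metrics describing perceived sound quality: loudness (sone),
sharpness (acum), roughness (asper), fluctuation strength (vacil). They
are computed from first principles following the published model family:
Zwicker's stationary specific loudness, the DIN 45692 sharpness weighting,
and envelope-modulation analysis in overlapping critical-band channels in
the spirit of Daniel–Weber (roughness) and Fastl (fluctuation strength).

* **Calibration.** Digital stethoscope data has no sound-pressure
  reference, so a fixed convention maps the unit-RMS z-scored record to
  60 dB SPL re 20 µPa. The convention is arbitrary but consistent;
  sharpness, roughness and fluctuation strength are level-normalized by
  construction, and loudness becomes a comparable relative measure.
* **Model rate 8 kHz.** The preprocessed phonocardiogram is bandlimited to
  1 kHz, so every Bark band it can excite is represented at 8 kHz; running
  the models at a higher rate only adds empty bands. Unit tests drive the
  same code with full-band audio test tones.
* **Loudness.** Per 2048-sample frame: third-octave band levels →
  excitation on a 0.1-Bark grid (Traunmüller Hz↔Bark mapping) with a
  27 dB/Bark lower skirt and a level- and frequency-dependent upper skirt
  (24 + 230/f − 0.2L dB/Bark, clamped to [5, 40]) → Zwicker's compressive
  law N′ = 0.08·E_TQ^0.23·[(0.5 + 0.5E/E_TQ)^0.23 − 1] against the
  Terhardt threshold-in-quiet. The scale is anchored so a 1-kHz tone at
  40 dB SPL is exactly 1 sone (the sone's definition), with the anchor
  tone run through the identical code path. Total loudness is the
  time-mean of ∫N′dz.
* **Sharpness.** 0.11·∫N′(z)g(z)z dz / ∫N′(z)dz with g = 1 below
  15.8 Bark and growing exponentially above — a weighted centroid, hence
  level-insensitive to first order (verified within 10% over 50–70 dB).
* **Roughness / fluctuation strength.** The signal is split into 1-Bark
  wide channels spaced 0.5 Bark (FFT masking; Hilbert envelopes).
  Channels carrying < 1e-6 of total power are skipped. Per channel the
  normalized envelope-modulation amplitude spectrum is weighted by a
  bandpass peaking near 70 Hz for roughness (shifting down for
  low-frequency carriers) or by Fastl's 2/(f/4 + 4/f) curve peaking at
  4 Hz for fluctuation strength; weighted modulation depths are capped at
  1, and roughness additionally multiplies in the cross-correlation of
  envelope fluctuations between channels two steps apart, suppressing
  uncorrelated noise. Both metrics sum squared per-channel contributions
  and are anchored to their defining references: a 60-dB 1-kHz tone, 100%
  AM at 70 Hz → 1 asper; the same tone AM at 4 Hz → 1 vacil.

These are re-implementations of the model *family*, not of any specific
commercial toolbox; the tests pin the models' defining behavior (anchor
values, AM-frequency peaks, level monotonicity, silence limits) rather
than third-party output.

## Classifier

Soft-margin SVM with Gaussian RBF kernel, solved by an established SMO
procedure (libsvm, as wrapped by scikit-learn); the decision function
g(x) = Σ αᵢyᵢK(x,xᵢ) + b is evaluated directly from the stored dual
solution, and the box (|αᵢ| ≤ C) and equality (Σαᵢyᵢ ≈ 0) constraints are
checked on every fit. Inside the grid search, kernels are precomputed per
fold and the raw SMO entry point is used for speed (with the standard
estimator as a fallback); both paths run the same solver and the tests
assert they select identical hyperparameters.

Design choices:

* **Per-partition feature standardization.** The 31 features mix units
  (Hz, sone, dimensionless moments); an isotropic RBF needs comparable
  scales. Statistics are estimated on training subjects only — this is an
  assumption that materially affects results and is therefore surfaced
  prominently. Constant features get std 1 and a flag.
* Solver tolerance 1e-3, iteration cap 1e6.
* Grid-search ties resolve to smallest C then smallest gamma — the
  smoother decision boundary.
* Decision threshold fixed at 0; the tie g = 0 predicts HC, conservative
  for precision. No probability calibration, class weighting, or
  alternative kernels: imbalance is handled by the evaluation protocol,
  not the loss.

## Evaluation protocols

RHD is the positive class everywhere (recall = sensitivity to disease).

* **Stratified nested 10-fold.** Outer stratified 10-fold over subjects;
  each outer training set is again split stratified 10-fold for the inner
  grid search (the inner fold count mirrors the outer loop, a choice made
  here).
* **Imbalanced (prevalence-controlled).** The HC pool is split once per
  repeat into an inner and an outer pool sized by the (n−1) : n ratio of
  inner to outer folds — effectively 50/50, which keeps both pools large
  enough for every prevalence in the 2.5–20% sweep. One outer fold per
  RHD subject; each evaluation fold is that subject plus round(1/p) HCs
  drawn without replacement from the matching pool (HCs may recur across
  folds, never within one). Inner folds are leave-one-RHD-out over the
  remaining n−1 RHD subjects. The final per-fold model trains on all
  outer-training RHD subjects plus the entire inner HC pool — every
  non-test subject contributes while the pools stay disjoint.
* **Aggregation.** Within a repeat, all outer-fold predictions are pooled
  into one confusion matrix (per-fold metrics would be degenerate with a
  single positive per fold); experiments run 5 repeats by default and
  report mean ± sample standard deviation (ddof = 1) in percent. Metrics
  with zero denominators are reported as 0 and flagged.
* **Leakage audit.** Every plan is checked — before any model sees data —
  for subject-level train/test disjointness and for inner folds escaping
  their outer training set; standardization and hyperparameter selection
  only ever receive training rows by construction.
* Repeat r of an experiment uses seed `base + 1000·r`; all seeds are
  recorded in the report and the CLI provenance block.

## Synthetic data

The generator emulates the *structure* of a screening dataset, not the
physiology of any patient: Gaussian-enveloped tone bursts for S1 (~60 Hz,
22 ms) and S2 (~90 Hz, 16 ms) at 5% and 42% of the cycle, cycle length
from a 60–100 bpm heart rate with 4% jitter, murmurs as 150–400 Hz
band-limited noise confined to the systolic and/or diastolic interval with
a configurable murmur-to-S1 energy ratio, and additive babble-like
(80–600 Hz, syllabically modulated) or white noise at a configurable SNR.
Band and burst parameters follow standard auscultation descriptions.

Two presets define the study conditions: **separable** (murmur ratio
−3 to +3 dB, SNR 12–18 dB — a clearly audible murmur) and **hard**
(−15 to −6 dB, SNR −3 to +3 dB) for robustness checks without pass/fail
thresholds. The default cohort is 124 RHD-like and 127 HC-like subjects,
one 35-s record each.

What passing tests show — and what they do not: perfect scores on the
separable preset demonstrate that the pipeline is plumbed correctly
(features carry the murmur signal, the CV protocols measure it without
leakage); they say nothing about performance on clinical recordings,
which contain borderline disease, pediatric heart rates, sensor
variability and noise structure the generator does not model.

## Numerical choices and degenerate inputs

* Tie-breaks: dominant PSD bin → lowest frequency; grid search → smallest
  C then gamma; decision g = 0 → HC.
* Degenerate inputs raise typed errors: constant signals, all-zero
  spectra, single-class training partitions, sub-30-s recordings.
* Non-finite features abort vector assembly naming the offending feature.
* Model serialization round-trips decision values to 1e-12 (plain .npz,
  no pickling).
* Scaled-down problem sizes used by the end-to-end checks and the
  acceptance script: 3×3 hyperparameter grid (C ∈ {0.1, 1, 10},
  γ ∈ {0.1, 0.01, 0.001}) and 2 repeats, chosen as the smallest
  configuration that still exercises model selection in both protocols at
  the full cohort size.

## Known limitations

* The psychoacoustic models are re-derived from the literature, and their
  absolute values depend on the fixed 60-dB calibration convention;
  relative comparisons across records are meaningful, absolute sones are
  conventional.
* The MFCC and spectral features assume stationarity over 30 s; transient
  artifacts (stethoscope repositioning) are not excised.
* The imbalanced protocol reuses HC subjects across folds, reducing HC
  variety — an inherent property of evaluating low prevalence from a
  near-balanced pool.
* No borderline-RHD phenotype exists in the generator, and no claim is
  made about detecting it.
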