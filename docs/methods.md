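# Methods

## Scope and model

The package quantifies the irregularity of cortical hemoglobin
oscillations measured by continuous-wave fNIRS during three clinical
tests (Clock Drawing, CDT; Digit Span, DST; Corsi Block Tapping, CBTT),
administered consecutively with 1-minute rests, and asks whether that
irregularity separates early-AD patients from controls. Because the
tests are unpaced, no task regressor exists; the unit of analysis is
the Sample Entropy (SampEn) of each channel's corrected O₂Hb series,
integrated over each task phase, optionally at coarse-grained scales
(Multiscale Entropy, MSE).

## Sample Entropy conventions

- Embedding `m = 2`, tolerance `r = 0.2 · SD` (population SD, ddof = 0),
  delay `T = 1`; Chebyshev (max-coordinate) template distance;
  self-matches excluded.
- Both the m- and (m+1)-dimensional match totals are taken over the
  **common** template index range `i ≤ N − mT`. A literal reading of the
  per-dimension ranges in some formulations normalizes the two counts
  over different index sets, which breaks the defining property that
  SampEn is `−ln` of a conditional probability (a constant series would
  not yield 0). The common-range (Richman–Moorman) counting restores
  `A ≤ B`, hence `SampEn ≥ 0`, and gives exactly 0 for constant input.
- `A = 0` (no extended matches) leaves the conditional probability
  undefined: the value is reported as missing (NaN) with a warning,
  never clamped to a large number. Zero-SD input returns 0 with a
  warning.
- MSE coarse-grains by non-overlapping block means (`τ = 2, 3` by
  default; longer scales are not trustworthy on ~400-sample phases) and
  reuses the tolerance computed from the original (`τ = 1`) series, the
  standard MSE practice, so scale profiles reflect structure rather than
  per-scale renormalization.
- The SD entering `r` is computed per phase window (entropy is
  phase-integrated, so the tolerance should be, too).
- The pair-counting kernel is O(N²); a numba-compiled loop is used when
  available, with an exactly equivalent vectorized numpy fallback. Both
  produce integer counts, so results are bit-identical across paths.

## Preprocessing chain

Fixed order, each stage appended to an audit log on the container:

1. **Optical density**: `od = −log10(I / mean_t I)`. The whole-recording
   mean is the reference (robust to an artifactual first sample); the
   choice only shifts OD by a constant, which the band-pass removes.
2. **Wavelet motion correction**: db5, up to 4 decomposition levels,
   `mode="periodization"` (orthonormal at any length, so zeroing
   coefficients can only remove energy). Detail coefficients outside the
   interquartile fence `[q1 − 1.5·IQR, q3 + 1.5·IQR]` are zeroed; spikes
   and step changes concentrate in the details, in-band hemodynamics in
   the approximation. Measured on a 0.1 Hz probe sinusoid, a 10·SD spike
   is attenuated ≥ 90% while passband amplitude changes < 0.1%.
3. **Band-pass**: 3rd-order Butterworth, 0.01–0.4 Hz, applied
   forward–backward (`sosfiltfilt`). Zero-phase filtering was chosen
   because phase distortion would alter the temporal patterns entropy
   measures; the effective response is the squared magnitude (≈ 56 dB at
   the 1.1 Hz cardiac line).
4. **Modified Beer–Lambert inversion** per channel: solve the 2×2 system
   `ΔOD(λ) = ε(λ,·)·[ΔO₂Hb, ΔHHb]·d·DPF(λ)`. Extinction coefficients
   (OD·µM⁻¹·cm⁻¹, base-10): 690 nm (O₂Hb 0.000350, HHb 0.002051),
   830 nm (O₂Hb 0.000974, HHb 0.000693); DPF 6.0 / 5.2 at 690 / 830 nm.
   These are conventional tabulated values, exposed in
   `PreprocessParams` since they are instrument- and subject-dependent
   in reality.
5. **CBSI**: `α = SD(O₂Hb)/SD(HHb)`, corrected
   `O₂Hb′ = (O₂Hb − α·HHb)/2`, `HHb′ = −O₂Hb′/α`. The corrected pair is
   exactly anticorrelated, so all downstream analysis uses O₂Hb′ only.

Filtering happens on OD, before the Beer–Lambert inversion, matching
the stated stage order; because both operations are linear the
alternative order is numerically equivalent.

## Phase handling

Entropy estimates depend on series length, so for each phase every
subject's window is truncated (from the end) to the cohort-minimum
length before any entropy is computed. With the default generator the
homogenized task lengths land near 370 (CDT), 380 (DST) and 530 (CBTT)
samples at 10 Hz. The headline metric map is CDT → SampEn, DST →
SampEn, CBTT → MSE(τ = 3), configurable per run.

## Group inference

- **Channel-wise**: pooled-variance unpaired t (df = n₁ + n₂ − 2 = 20
  for 11 vs 11), two-sided p, Benjamini–Hochberg step-up across the 21
  channels at q = 0.05. Missing entropies are dropped pairwise.
- **Multivariate**: linear regression of the label (patient = 1) on all
  channels' entropies with leave-one-out cross-validation; each
  subject's prediction comes from a model never trained on it. With 21
  features and 21 training subjects per fold, ordinary least squares
  interpolates the training labels, and its held-out predictions are
  *optimistically* biased under the null (measured mean held-out AUC
  ≈ 0.56–0.58 over hundreds of simulated null cohorts, for both
  raw-intercept and centered minimum-norm variants). The default solver
  is therefore ridge regression, λ = 2 on fold-standardized features,
  which measured null-calibrated (mean held-out AUC 0.50 ± 0.01) and
  more powerful at the effect sizes studied; minimum-norm least squares
  remains available (`solver="min-norm"`) for comparison.
- **ROC**: AUC as pairwise concordance (ties ½), operating point by
  Youden's J with the higher-threshold point kept on ties.

## Synthetic cohorts

The generator emulates the acquisition geometry (11 + 11 subjects, 21
channels at 3 or 4 cm source–detector separation, two wavelengths,
10 Hz, rest/task phase structure with per-subject task-duration jitter)
and the signal statistics that matter to the method:

- Latent O₂Hb per channel: variance-preserving blend of white noise and
  a strongly autocorrelated AR(2) process (double pole at 0.9), SD
  0.5 µM. The blend weight `noise_mix` (default 0.5, between-subject SD
  0.08) is the single complexity knob; SampEn responds monotonically to
  it. Patients' weight is shifted by `complexity_effect` on
  `affected_channels`.
- HHb = −0.4 · latent O₂Hb + scaled physiology + independent noise,
  honoring the anticorrelation CBSI exploits.
- Additive physiology (cardiac ≈ 1.1 Hz, respiration ≈ 0.25 Hz, Mayer
  ≈ 0.1 Hz; 0.2/0.1/0.15 µM), linear drift (0.3 µM/min, random sign),
  and motion artifacts (0.5/min; spikes 5–20 SD of 1–5 samples and
  baseline steps 1–5 SD) with positions and amplitudes kept as ground
  truth. Intensities follow from the forward Beer–Lambert model.
- All randomness flows from one seed via spawned per-subject
  substreams; cohorts are bit-reproducible.

What it does **not** emulate: hemodynamic response functions or any
biophysical AD mechanism, scalp/systemic layers, spatial correlation
between channels, heavy-tailed artifact statistics of real probes.
Passing tests therefore demonstrate that the *pipeline* is correct and
calibrated — not that the synthetic effect size transfers to clinical
recordings.

`COMPLEXITY_EFFECT_D15 = 0.42` is the blend shift that realizes a
post-pipeline per-channel Cohen's d ≈ 1.5 on affected channels
(measured 1.48–1.53 across Monte-Carlo batches); it was fixed once with
`calibrate_complexity_effect` and is the "effect" condition throughout.

## Monte-Carlo evaluation sizes

Calibration and power are measured on full simulate→preprocess→entropy→
inference replicates: 200 null cohorts (type-I error, null AUC, FDR
false positives) and 60 effect cohorts in the test suite; 120 and 50 in
the acceptance script. One cohort costs ≈ 0.9 s on one CPU. Because all
channels of a subject share that subject's latent blend weight,
channel-wise test outcomes are positively correlated within a cohort;
aggregate rejection rates are therefore judged against per-cohort
(cluster-level) dispersion rather than a pooled binomial, which would
overstate the effective sample size.

## Known limitations

- SNIRF support is a minimal standard-layout writer/reader (one
  source–detector pair per channel, stim groups for phases), not a full
  implementation of the format's optional features.
- The literal per-dimension normalization variant of the entropy count
  is intentionally not used (see conventions above); users comparing
  against implementations that use it will see small systematic
  differences at short N.
- Undefined entropies are rare at the default tolerance but possible on
  very regular channels; they propagate as missing values and are
  imputed (training-fold mean) only inside the classifier.
- With 11 + 11 subjects the held-out AUC of a single cohort has an SD
  of ≈ 0.17 under the null; single-cohort AUCs should be read
  accordingly.
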