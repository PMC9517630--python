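# Methods

This note documents the models and procedures `preictal` implements, the
defaults it ships, what the synthetic benchmark does and does not emulate,
and the numerical choices made where the design was genuinely open.

## Problem setting

Given a long-term multichannel scalp EEG recording with annotated seizure
onsets, the package builds a patient-specific classifier that distinguishes
two kinds of 10-minute epochs:

* **Category A (label 1)** — epochs followed by a seizure after a fixed
  alarm horizon, the *interval time* InT (30 or 40 minutes by default).
  The epoch is `[onset − (InT + 10) min, onset − InT min)`, so an alarm
  raised from it leaves the patient InT minutes to intervene.
* **Category B (label 0)** — epochs far from any seizure, drawn from
  4-hour seizure-free spans.

Class balance holds by construction: for every patient, one B epoch is
drawn per selected seizure.

## Epoch selection rules

A seizure is *eligible* when (a) no other seizure — onset **or** offset —
falls in the 2 hours before its onset, and (b) its category-A interval is
fully recorded, i.e. crosses no inter-file gap. Rule (a) deliberately
counts the previous seizure's ictal activity, not just its onset: any
ictal contamination of the isolation window disqualifies the seizure. This
is the stricter of the two possible readings and costs a small number of
borderline seizures.

B epochs are placed uniformly at random (seeded, integer-second grid)
within the first 3 hours of disjoint 4-hour seizure-free spans, one epoch
per span, so a seizure can never occur within InT + 10 min after a B epoch
and no two B epochs overlap. B epochs may come from any qualifying span,
including other days than the A epochs. Epochs may cross file boundaries
only when no recording gap intervenes; samples are then concatenated.

Each 10-min epoch is partitioned into 60 consecutive non-overlapping 10-s
windows (2560 samples at 256 Hz); the windows, not the epochs, are the
classifier's samples.

## Denoising

Each window/channel is cleaned independently:

1. **CEEMD** with 50 complementary noise pairs, added-noise std 0.2 x the
   window std, at most 10 IMFs. The ensemble size and noise amplitude are
   conventional values for complementary-ensemble decompositions; because
   every single EMD is exactly additive and the ± noise pairs cancel in the
   ensemble sum, reconstruction is exact to floating point regardless of
   these settings (the tests bound the relative RMS error at 1%, observed
   ~1e-16). Sifting stops at the standard normalized squared-difference
   criterion SD < 0.2 (cap 100 sifts); envelopes are cubic splines through
   local extrema with two mirrored extrema at each end.
2. **Noise-IMF identification.** IMFs are ordered high-to-low frequency;
   the flagged set is the maximal *prefix* whose spectral centroid exceeds
   30 Hz (scalp EEG content of interest lies below 30 Hz). The centroid
   rule automates what is otherwise a visual judgement on IMF spectra; a
   `strict_first_two` switch hard-codes IMF1+IMF2 instead for users who
   want the fixed convention. Note one consequence of the automatic rule:
   a CEEMD of a noise-free narrowband signal retains a tiny high-frequency
   auxiliary-noise residue in IMF1, whose centroid (an amplitude-free
   statistic) is high, so IMF1 may be flagged even when nearly empty. This
   is harmless — shrinking a near-zero IMF changes the reconstruction by
   well under the 2% bound the tests enforce.
3. **Wavelet shrinkage** of each flagged IMF: db4, 4 decomposition levels,
   symmetric extension, one global universal threshold
   λ = σ̂ √(2 ln N) with σ̂ = median(|finest detail|)/0.6745, soft
   thresholding of all detail levels (approximation untouched). A single
   global λ mirrors the classic single-level universal-threshold recipe;
   per-level rescaling is a documented non-goal.
4. Denoised and untouched IMFs plus the residual are summed; output length
   equals input length.

Per-window CEEMD seeds derive from (global seed, segment, window, channel)
via `numpy.random.SeedSequence` spawn keys, so runs are bit-reproducible.

## Entropy features

Five features per channel per window; the feature matrix has
`channels x 5 + 1` columns (116 for the 23-channel montage), windows as
rows, label last.

* **ApEn(m=2, r=0.2·σ_window)** — self-matches included, Chebyshev
  distance, comparator `d ≤ r`. σ is the *window's* std, recomputed per
  window per channel (computing r per epoch or per recording would leak
  slow amplitude drifts into the feature).
* **SampEn(m=2, same r)** — standard self-match-excluded estimator
  −ln(A/B) over the first N−m templates at both dimensions. When no
  template pair matches, SampEn is undefined; the estimator returns +inf,
  the row is flagged, and matrix assembly imputes the column's maximum
  finite value (an "at least this irregular" reading of the sentinel).
  ApEn's small negative bias on short series is clamped at zero during
  assembly only; the estimator itself returns the raw value so oracle
  equivalence is exact.
* **PEn(m=3, τ=1)** — ordinal-pattern Shannon entropy normalized by
  ln(m!); ties broken by temporal order (stable sort). Order 3 keeps the
  pattern alphabet (6) far below the per-window vector count (2558).
* **SpEn** — Shannon entropy (natural log) of the rectangular-window
  periodogram normalized to total power 1. A rectangular window keeps a
  bin-aligned sinusoid a one-bin spectrum (entropy 0), which is the
  defining degenerate case; tapering would smear it across bins.
* **WEn** — Shannon entropy of the per-scale wavelet energy shares, db4 at
  4 levels, including the approximation band so the shares sum to one.

Natural logarithms throughout (PEn's normalization makes its base moot).
Both ApEn and SampEn run through one compiled O(N²) pair scan with early
exit; the tests pin them to plain brute-force implementations at 1e-12.

## Classifier

A logistic-loss gradient-boosting machine whose initial score comes from a
random forest:

* RF: 100 trees. On training data the class-1 probability is taken
  out-of-bag where available (in-fit RF probabilities are near-degenerate);
  on test data, `predict_proba`.
* The probability is mapped to score space as H₀ = logit(clip(p, 1e-6,
  1−1e-6)). Boosting updates and the final sigmoid live on the logit
  scale, so feeding a probability in directly would pass it through a
  second sigmoid and compress it into (0.5, 0.73); `init_mode="raw"`
  preserves that literal variant for comparison.
* Boosting: T = 100 rounds, shrinkage φ = 0.1, depth-3 regression trees
  fitted to the negative gradient r = y − sigmoid(H); each leaf gets one
  Newton step Σr / Σp(1−p) (the gradient alone fixes the tree's shape but
  not the leaf constant). T = 0 reproduces the bare RF exactly.
* Prediction: p = sigmoid(H_T), label 1 iff p ≥ 0.5 (ties favor the
  alarm).

Hyperparameters are deliberately unremarkable defaults — none were tuned —
and all are exposed in the run configuration.

Evaluation is stratified 10-fold cross-validation over pooled windows,
with accuracy, sensitivity, FPR and F1 per fold and macro-averaged, and
out-of-fold predictions retained in row order. Pooling windows means two
windows of one epoch can land in train and test folds respectively; a
`group_by_segment` option assigns whole epochs to folds for users who want
leakage-free estimates (expect lower numbers with it).

## Alarm post-processing

Out-of-fold window predictions are reassembled per epoch (each window is
predicted exactly once across folds). Stage 1 maps the 60-window sequence
through non-overlapping groups of 6 with a ≥3 threshold; stage 2 alarms
iff ≥5 of the 10 group outputs fire. Non-overlapping groups are the only
reading under which 60 inputs produce the 10 stage-2 inputs. Both stages
are monotone, and both are pinned to exhaustive popcount oracles (2^6 and
2^10 inputs) in the tests. An alarmed A epoch counts as a predicted
seizure, a silent A epoch as a miss, an alarmed B epoch as a false alarm.

## Synthetic benchmark

The generator emulates the statistical structure the pipeline assumes, not
seizure physiology:

* baseline: per-channel pink noise (power ∝ 1/f, the standard EEG-like
  background) plus a shared pink component (weight 0.3) for inter-channel
  correlation, scaled to 50 µV std and quantized to 16 bits;
* pre-seizure shift: inside `[onset − (InT+10) min, onset)` an
  amplitude-modulated 3–7 Hz oscillation is mixed in with weight
  `class_effect` (variance-preserving blend). The shift is a continuous
  mixture weight rather than a regime switch so statistical power can be
  studied along `class_effect ∈ [0, 1]`; at 0 the two classes are
  distributionally identical, at the default 1.0 the rhythmic component
  carries half the variance — a large, unambiguous complexity drop;
* artifacts: Poisson-scheduled 0.5 s bursts at 35–60 Hz (0.5/min default)
  on a third of the channels;
* recording structure: 1-hour EDF files separated by 10 s gaps, a
  CHB-MIT-dialect summary file, and a JSON ground-truth manifest.

The default benchmark patient (`benchmark_spec`, 4 seizures) places onsets
in every other file, staggered so both the 30- and 40-minute alarm
horizons leave the pre-seizure interval inside one file and the 2-hour
isolation holds against onsets *and* offsets, followed by ~17 h of
seizure-free recording for the interictal span search; segmentation then
yields exactly 4 A + 4 B epochs → a 480 × 116 feature matrix.

What the generator does **not** emulate: spike-wave seizure morphology,
patient-to-patient variability, electrode artifacts other than broadband
bursts, non-stationary background drifts, or any physiologic pre-ictal
dynamics beyond "complexity decreases". Passing the benchmark therefore
demonstrates that the pipeline's plumbing, estimators and classifier
behave as specified and can detect a genuine complexity shift at
realistic sampling parameters — it says nothing about clinical
performance on real EEG, which requires the real corpus.

## Problem sizes and run costs

The shipped tests and the acceptance script size their computations for a
single CPU: the full-scale benchmark (23 channels, ~27 h, 480 windows)
runs feature extraction without the CEEMD pass — the synthetic pink-noise
background carries no >30 Hz artifact for it to remove, and a 50-pair
ensemble decomposition of all 11,040 window-channels is a multi-hour
computation that would add nothing to the check — while the CEEMD +
shrinkage path is exercised end-to-end on a smaller patient (2 channels,
ensemble 2) and at full ensemble size on single-window fixtures. The
class-effect-zero control uses a 4-channel patient; chance-level accuracy
does not depend on the channel count.

## Known limitations

* EMD has no unique definition; envelope boundary handling and stopping
  criteria differ across implementations, so IMF-level outputs are not
  expected to match other EMD codes sample-for-sample (reconstruction
  identities and spectral ordering are the stable contract).
* The summary-time parser assumes whole-second file clock times and
  monotone recording order (midnight rollovers are unwrapped).
* `+inf` SampEn imputation uses the per-run column maximum, so feature
  values are not comparable across runs when sentinels occur.
* Metrics with zero denominators return NaN sentinels; macro-averaging
  skips them.
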