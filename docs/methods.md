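# Methods

## Scientific setting

Resting-state EEG in Alzheimer's disease shows two robust effects:
*spectral slowing* (power shifts from the alpha/beta bands into delta/theta)
and *reduced complexity* (lower entropy and fractal-dimension values).
`eegtf` operationalizes both as a feature-engineering pipeline feeding a
bank of standard classifiers, for balanced pairwise comparisons between
healthy controls (C), mild cognitive impairment (MCI) and AD, seven
subjects per group, 19 channels in the 10–20 montage.

## Preprocessing

Stages, in order, applied per channel:

1. **Resampling** to 256 Hz (polyphase, anti-aliased, via
   `scipy.signal.resample_poly`; the 200→256 Hz case uses the exact 32/25
   rational ratio). Control-like recordings are generated at 200 Hz
   precisely to exercise this path. A fidelity diagnostic interpolates the
   magnitude spectra of original and resampled signals onto a common
   1–40 Hz grid (512 points) and reports their Pearson correlation; the
   first and last 0.5 s are excluded to avoid boundary transients, and
   values below 0.99 log a warning.
2. **RMS normalization**: each channel divided by its own RMS over the full
   recording, making amplitudes comparable across subjects and recording
   lengths. A flat channel is an error naming the channel.
3. **Mean removal.** Applied after RMS scaling (that order is a deliberate
   contract of the pipeline, although centering first is more common);
   for near-zero-mean signals the post-centering RMS deviates from 1 only
   to second order in the removed mean.
4. **Band-pass** 1–40 Hz, 5th-order Butterworth, applied forward–backward
   (`sosfiltfilt`). Zero-phase filtering is chosen because downstream
   time-domain features (Hjorth, fractal dimensions) are sensitive to phase
   distortion; the effective attenuation order doubles.

## The 43-metric feature bank

Computed on non-overlapping 1-s windows (256 samples at 256 Hz; overlap is
configurable but defaults to none). Families and conventions:

**Entropies (6).** Amplitude-histogram Shannon entropy (16 bins, natural
log); permutation entropy (order 3, delay 1, normalized by log 3! to
[0, 1], stable tie-break by time index); spectral entropy (normalized
Shannon entropy of the one-sided periodogram, DC excluded); SVD entropy
(order-3, delay-1 embedding, singular values normalized to sum 1, entropy
normalized by log 3); approximate entropy ApEn(m=2, r=0.2·SD) with
self-matches included; sample entropy SampEn(m=2, r=0.2·SD) = −ln(A/B)
with self-matches excluded and N−m templates at both lengths. Both use the
Chebyshev distance. m and r are the literature-standard defaults. The bank
deliberately carries *both* the histogram amplitude entropy and SampEn as
separate metrics.

**Basic statistics (12).** min, max, mean, RMS, population variance and SD,
crest factor (max |x| / RMS), population skewness and non-excess kurtosis
(Gaussian → 3), and the 25th/50th/75th percentiles with linear
interpolation. Zero-variance windows define crest/skewness/kurtosis as 0.

**PSD metrics (11).** One-sided rectangular-window periodogram
|X(f)|²/(fs·N) on the DFT grid (1 Hz resolution at N = 256). Band powers
integrate PSD·Δf over δ [1,4), θ [4,8), α [8,13), β [13,30), γ [30,40]
(half-open, gamma closed) so the five bands exactly partition the total
1–40 Hz power — an identity the tests assert to 1e−9. The total 1–40 Hz
power is itself the family's first metric, completing the bank's count of
43. Peak and peak-to-peak PSD are taken over the same 1–40 Hz range. The
slowing ratios are r1 = δ/(α+β), r2 = θ/(α+β), r3 = (δ+θ)/(α+β), the
standard formulations consistent with the slowing effect; their band sets
are configurable. A zero denominator maps a ratio to 0 with a diagnostic.

**Frequency-domain metrics (7).** Power weights w(f) = |X(f)|² restricted
to 1–40 Hz: maximum frequency (largest f with w > 1e−6 · max w — a
numerical reading of "highest nonzero component"), summed power, mean
frequency (power-weighted), median frequency (smallest f where cumulative
power reaches half the total), peak frequency (smallest argmax on ties),
and power-weighted standardized spectral skewness and kurtosis.

**Fractal/complexity metrics (7).** Zero crossings (strict sign changes,
zeros skipped); Katz FD with n = N−1, L = Σ|Δx|, d = max|x_i − x_1|
(a straight line gives exactly 1; L = 0 maps to 0; the measure-zero case
d/L = 1/n, where the estimator diverges, also maps to 0); Higuchi FD
(kmax = 10, standard curve-length normalization, −slope of the log–log
least-squares fit); DFA exponent (cumulative-sum profile, 10 log-spaced
box sizes from 4 to N/4, non-overlapping boxes, linear detrending; white
noise → α ≈ 0.5); Petrosian FD from sign changes of the first difference;
Hjorth mobility √(var Δx / var x) and complexity mobility(Δx)/mobility(x).
First differences are *not* scaled by fs — values are comparable across
runs at the common 256 Hz rate but not across sampling rates.

Degenerate (constant) windows map every undefined metric to 0 with a
logged diagnostic instead of raising, so a single flat window cannot abort
a subject. All 43 outputs are finite by construction.

## Temporal compression and dataset assembly

Each per-channel feature series over windows collapses to 10 statistics:
mean, median, min, max, SD, variance, q25, q50, q75, q95 (linear
interpolation, population variance). Median and q50 are duplicates and
both are kept so the flat vector preserves its channels × features × 10
factorization: 19 × 43 × 10 = 8170 columns. Ordering is channel-major,
then feature, then statistic, and the columns are named
`channel|feature|statistic`.

Pairwise matrices stack the two groups' subjects (first group labelled 0,
second — the more-affected one by convention — labelled 1) and min-max
normalize each column over the *entire* pair matrix. That convention leaks
fold statistics into training folds; it is kept as the pipeline's default
contract, and `CVConfig(normalize_within_folds=True)` re-normalizes from
training folds only for honest evaluation. Constant columns map to 0 and
are kept, preserving the 8170-column contract; the per-column (min, max)
pairs are stored for audit.

## Classification

Fifteen scikit-learn classifiers at library defaults (the SVC uses
`gamma="auto"`), pinned by canonical name; stochastic learners receive a
fixed seed from `CVConfig`. Stratified 7-fold cross-validation (7 matches
the per-class subject count, so each test fold holds exactly one subject
per class). Predictions are **pooled** across folds into a single confusion
matrix per classifier — per-fold metrics on two test subjects are
degenerate, and pooling keeps accuracies on the k/14 grid (13/14 ≈ 92.86%
is representable). Accuracy, recall, precision, F1 and specificity derive
from the pooled counts; AUC comes from pooled continuous scores
(`predict_proba`, else `decision_function`, else 0.5 with a diagnostic).
A classifier failure on any fold is recorded on its report entry rather
than raised.

## Synthetic cohort generator

Each channel is an independent sum of five band-limited Gaussian noise
components (the same 5th-order Butterworth band definitions as the
preprocessing filter, so generator and analysis agree on band edges), each
rescaled so its power equals the profile's band weight, plus a 1/f^a
background whose power is the total band power divided by the profile SNR
(default a = 1, SNR = 4 — a plausible structured-to-background ratio for
filtered resting EEG). Default band-weight profiles:

| band  | control | MCI  | AD  |
|-------|---------|------|-----|
| delta | 0.5     | 1.0  | 1.5 |
| theta | 0.7     | 1.05 | 1.4 |
| alpha | 1.5     | 1.05 | 0.6 |
| beta  | 1.0     | 0.7  | 0.4 |
| gamma | 0.3     | 0.25 | 0.2 |

Control-like recordings are produced at 200 Hz and patient-like ones at
256 Hz to exercise the resampling path. MCI is the elementwise midpoint of
the other two profiles. Weight magnitudes are free parameters chosen to
encode the slowing direction with an intermediate MCI; recording duration
is a parameter (60 s in the study-scale tests and the acceptance script —
long enough for 60 windows per channel while keeping a full 14-subject run
around a minute).

Determinism: one cohort seed drives per-subject and per-channel substreams
through `numpy.random.SeedSequence` spawn keys, so identical specs give
bit-identical cohorts and enlarging a cohort never perturbs existing
subjects.

**What the generator does not emulate:** eye-blink/EMG artifacts, volume
conduction and cross-channel covariance (channels are independent, which
is acceptable because no cross-channel feature exists in the bank),
nonstationarity beyond stochastic noise, and realistic inter-subject
variability structure. Passing discrimination tests on this cohort
demonstrates that the pipeline detects controlled spectral/complexity
differences — not that it attains any particular accuracy on clinical
recordings.

## Verification strategy

Entropy, fractal-dimension and percentile estimators are checked for
agreement to 1e−12 (1e−10 for Higuchi, whose oracle uses an independent
least-squares formulation) against loop-based brute-force oracles on 50
random short windows, plus closed forms: sine crest factor √2, Katz FD of
a line = 1, Hjorth mobility of a sinusoid = 2 sin(πf/fs), the band-power
partition identity, and DFA ≈ 0.5 on white noise. Property tests cover
amplitude-scale invariance of the shape/complexity features, monotone
invariance of permutation entropy, quantile ordering, and
window-permutation invariance of the compression stage.

## Known limitations

- The feature bank's conventions (population moments, rectangular-window
  periodogram, unscaled differences) are internally consistent but not
  interchangeable with implementations using other conventions.
- Whole-matrix min-max normalization before cross-validation inflates
  small-sample performance estimates; use the fold-wise option when the
  estimate itself matters.
- With 7 subjects per class, pooled metrics have a granularity of 1/14 and
  wide confidence intervals; the pipeline reports discrimination, not a
  clinically calibrated effect size.
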