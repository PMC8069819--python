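# Methods

## Overview

`kernelfc` implements a single-trial functional-connectivity (FC) feature
pipeline for binary motor-related EEG decoding, built around a
Gaussian-kernel connectivity measure (GFC), and validates it end to end on
synthetic coupled-oscillator EEG with planted class-dependent coupling.
The stages are:

1. **Filter bank + sliding windows.** Each epoched trial (R trials,
   C channels, T samples) is band-pass filtered into a bank of Butterworth
   sub-bands and cut into overlapping sliding windows, producing a tensor
   `x[r, n, t, c, l]` over trials, bands, windows, channels and samples.
2. **Pairwise connectivity.** For every (trial, band, window) split, a
   C x C symmetric dependency matrix is estimated; only the strict upper
   triangle (P = C(C-1)/2 pairs) is stored.
3. **Sparse relevance selection.** The band-major vectorized features
   (D = |bands| x |windows| x P columns per trial) are matched to the 0/1
   labels by an elastic net; the absolute coefficients are the relevance
   weights used for feature selection and interpretation.
4. **Classification.** A shrinkage linear discriminant on the selected
   columns, scored by seeded stratified 10-fold cross-validation.
5. **Interpretation.** Per-subject relevance vectors are embedded with
   t-SNE, concatenated with accuracy and clustered with k-means into
   groups ranked I (best) to III; pair relevance is accumulated onto
   channels for topographies, and links above a percentile threshold
   (default 99) are reported.

## Connectivity measures

For windowed channel series `x_c, x_c' in R^L`:

- **GFC** (the method's core): `exp(-||x_c - x_c'||^2 / (2 sigma^2))`,
  a Gaussian-kernel similarity in (0, 1].  It is sensitive to joint
  amplitude-profile differences and, unlike a correlation, is a bounded
  positive-definite kernel evaluation.  The bandwidth `sigma` follows the
  median heuristic: the median of the P pairwise Euclidean distances
  within each (trial, band, window) split, averaged over all splits of
  the trials being pooled.  One `sigma` is used per fitted model; inside
  cross-validation it is re-estimated from the training trials of each
  fold so no test statistics leak into the features.  Whether the
  bandwidth should instead be per band or per window is genuinely open;
  the global choice is the simplest defensible one and is cheap to
  revisit because the distance tensor is cached independently of `sigma`.
- **CCF**: the Pearson correlation of the two windowed series, in
  [-1, 1].  The raw inner product would not be scale-invariant across
  subjects and amplifiers, so the normalized form is used.
- **PLV**: the modulus of the window-averaged complex phase difference,
  `|mean_t exp(j(phi_c(t) - phi_c'(t)))|`, in [0, 1], with instantaneous
  phase from the analytic (Hilbert) signal of each windowed channel.
  Note that the *pointwise* modulus of a unit phasor is identically 1;
  only the time average carries locking information, which is why the
  time-averaged definition is the established one and the one
  implemented.  Filtering is zero-phase (forward-backward, second-order
  sections) precisely so that these phases are undistorted; the full
  window enters the phase average, with no edge-sample exclusion.

## Filter banks and windows

Two presets mirror common motor-decoding practice: a motor-imagery bank
of 17 overlapped 5th-order Butterworth band-passes covering 4-40 Hz
(4 Hz wide, 2 Hz step) and a motor-execution bank of four rhythm bands
8-12, 12-30, 30-50 and 50-125 Hz (the last requires fs > 250 Hz; any
band reaching the Nyquist frequency is rejected by name).  Window
lengths tau of 0.5-2 s with 75% overlap are the intended operating
range; window starts are multiples of `round(L(1 - overlap))` samples
and trailing partial windows are dropped, so the window count is
`floor((T - L)/step) + 1` deterministically.  Filters are designed in
second-order sections because a 5th-order narrow band-pass is
numerically fragile in polynomial form.  Edge effects of zero-phase
filtering are handled by scipy's default reflect padding.

## Sparse relevance (elastic net)

The 0/1 labels are regressed on the standardized feature columns under
`MSE + alpha1 ||v||_1 + alpha2 ||v||_2^2`.  The penalty pair is chosen on
a grid of l2/l1 ratios {0.1, 0.5, 0.9} crossed with 10 log-spaced overall
strengths by seeded 5-fold inner cross-validation (sklearn's coordinate
descent with warm-started paths).  Constant feature columns are dropped
with a warning; standardization statistics come from the training rows
only.  Feature selection keeps the nonzero-coefficient columns, falling
back to the 10 largest-|v| columns (ties: larger |v|, then lower column
index) if the support is empty — that fallback exists so downstream
classifiers always receive features, e.g. under permutation controls.
Pair-level relevance sums |v| over each pair's (band, window) block and
is min-max normalized; an all-equal nonzero vector is reported as
uniform ones rather than zeros, with a warning, so "equally relevant"
and "irrelevant" remain distinguishable.

## CSP on FC matrices

As an alternative feature representation, classic common-spatial-pattern
eigenvectors are computed per (band, window) split with the class-mean
FC matrix standing in for the covariance: solve
`S1 w = lambda (S1 + S2) w`, keep the K = 3 largest-eigenvalue filters
(eigenvalues in [0, 1]; swapping class labels maps them to their
complements), and use the upper triangle of the projected matrix
`W' M W` (K(K+1)/2 values) per trial, concatenated across splits.  Raw
projections are used rather than log-variance because the inputs are
already normalized dependency matrices, not covariances.  A ridge of
`1e-6 trace(S)/C` (by default) keeps the composite matrix positive
definite — PLV matrices need not be.  Filter signs are fixed by making
each filter's largest-magnitude entry positive, for determinism.

## Evaluation

Accuracy is `(TP + TN) / (TP + TN + FP + FN)`.  Folds come from seeded
stratified k-fold (k = 10 by default; per-fold class proportions within
one trial of exact).  Everything fitted — bandwidth, standardization,
penalties, CSP filters, discriminant — is computed inside the training
folds.  Reported means and standard deviations are over fold accuracies
(population std), and the per-fold values are retained so any other
summary can be recomputed.  The final classifier is a shrinkage ("lsqr",
Ledoit-Wolf) linear discriminant; the decoding contribution lives in the
features, so a simple, stable linear classifier is preferred, with a
thresholded elastic-net prediction available as a configuration
alternative.

## Synthetic coupled-oscillator EEG

The generator emulates band-limited oscillatory EEG with planted
class-dependent pairwise coupling:

- each channel is a sum of unit-variance background rhythms (Butterworth
  band-limited Gaussian noise, order 4) in configured bands, plus
  1/f-shaped (spectral exponent 1, flattened below 1 Hz) and white noise
  mixed 60/40 by power and scaled so rhythm power over noise power
  matches the configured SNR in dB;
- in class-1 trials, each planted effect replaces the effect-band
  component of its two channels by
  `sqrt(1 - g(t)^2) * own + g(t) * shared`, where `shared` is one common
  band-limited source per trial and `g(t)` ramps over 50 ms raised
  cosines inside the effect window.  Mixing preserves per-channel
  marginal variance, so the two classes differ only in pairwise
  dependence — amplitude-profile similarity, correlation and phase
  locking rise together, keeping the comparison across all three FC
  measures meaningful.

The **strong-coupling preset** used for validation: C = 8 channels,
100 trials per class, fs = 128 Hz, 1.5 s trials, background rhythms at
8-12 and 16-24 Hz, one effect (band 8-12 Hz, whole-trial window, pair
(0, 1), gain g = 0.9), SNR 5 dB; analysis with five contiguous 4 Hz
bands spanning 4-24 Hz, tau = 1 s, 75% overlap.  Contiguous (rather than
overlapped) analysis bands are used here deliberately: with overlapped
bands every planted effect is duplicated across several near-identical
sub-bands, and a cross-validated elastic net — correctly — keeps only
one copy of redundant predictors, which makes "recover every
ground-truth column" an ill-posed target.  With contiguous bands the
ground-truth column set is non-redundant across bands and support
recovery is a meaningful score.  Problem sizes throughout (R = 200
trials, D = 420 features, 10 validation seeds, 20 permutation runs) are
chosen so the full validation study runs in minutes on one CPU.

What passing synthetic tests does *not* show: robustness to volume
conduction, artifacts (EOG/EMG), nonstationarity across sessions,
montage-dependent spatial correlation of real EEG noise, or multi-class
tasks.  The generator's couplings are stationary within their window and
identical across trials of a class, which is cleaner than real
sensorimotor dynamics.

## Numerical and design notes

- Pairwise distances are computed once per dataset through per-window
  Gram matrices; the Gaussian kernel is an elementwise `exp` on top, so
  per-fold bandwidth refits are cheap.
- Percentile thresholds for top links use linear interpolation with a
  strict inequality, so an all-equal relevance vector yields no links
  instead of all of them.
- t-SNE runs on l2-normalized relevance rows (exact method, PCA
  initialization, perplexity 5 for small cohorts) and is deterministic
  given its seed; k-means uses 20 restarts with a seeded generator.
  Accuracy is standardized before being concatenated with the embedding
  so neither dominates the k-means metric.
- k = 3 subject groups reflects the best/regular/worst reading of
  decoder performance cohorts; k is configurable, and the cluster count
  question (as well as per-tau versus pooled-tau clustering, implemented
  per tau) is documented rather than hidden.
- Degenerate inputs fail loudly and specifically: all-zero signals make
  the median bandwidth zero (error), zero-variance channels name the
  channel, bands at or beyond the Nyquist frequency name the band.
- EEG units are never interpreted; no re-referencing or Laplacian
  filtering is applied anywhere, and the only scale-aware quantity, the
  kernel bandwidth, is data-driven.

## Known limitations

- The elastic-net support is prediction-optimal, not
  identification-optimal: under heavy feature redundancy (overlapped
  banks, long trials with many overlapping windows) it deliberately
  under-selects duplicated truth columns.
- PLV on short windows (tau = 0.5 s at low sampling rates) carries
  analytic-signal edge bias; no edge-sample exclusion is applied.
- Real-data adapters (EDF/GDF import) are out of scope; the HDF5
  subject container and the synthetic generator are the supported input
  paths.
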