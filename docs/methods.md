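# Methods

`speechtrf` implements the forward ("encoding") modelling chain used to
study how EEG tracks continuous speech, together with a generative
simulator that makes every stage checkable by parameter recovery. This
note documents the models, the defaults and why they were chosen, the
numerical decisions, and what the simulator does and does not emulate.

## The encoding model

The core object is the temporal response function (TRF): a linear kernel
`w[l, f, c]` mapping stimulus features to each EEG channel across time
lags,

    y_c(t) = Σ_f Σ_l  w[l, f, c] · x_f(t − l) + b_c .

Estimation is Tikhonov-regularized least squares on the lagged design
matrix, `β = (XᵀX + λI)⁻¹ Xᵀy`, computed per channel by a symmetric
positive-definite solve (Cholesky via LAPACK), never by explicit matrix
inversion. The intercept is handled by column-centering and is excluded
from the penalty. The penalty is the identity on all lagged columns; no
derivative (smoothness) penalty is applied, matching the closed form
above.

Column ordering of the lagged design is feature-major with lags
ascending; out-of-range samples at fold and recording edges are
zero-padded rather than trimmed, which keeps folds equal length at the
cost of a small edge bias that shrinks with data length.

**Regularization search.** λ is selected by leave-one-fold-out
cross-validation on a logarithmic grid, by default 11 values spanning
10⁻²–10⁸ (one per decade; the endpoints are the documented search range,
the density is this package's choice). The recording is split into five
contiguous folds; for each held-out fold the model fit on the rest
predicts the fold and the Pearson correlation with the recorded EEG is
computed per channel. The λ maximizing the fold- and channel-averaged r
wins (one shared λ across channels and features), and the final model is
refit on all data at that value. Fold-wise sufficient statistics
(per-fold Gram and cross-product matrices) are cached so the grid search
costs one factorization per fold and grid value.

**Feature scaling.** Each regressor column is divided by its standard
deviation before fitting — for sparse onset columns, the SD of the
nonzero entries, keeping zeros exact. This stabilizes a single shared λ
across heterogeneous features (a dense envelope and sparse surprisal
spikes differ in scale by orders of magnitude). It is on by default and
switchable (`scale=False`); the divisors are stored in the model so
prediction is consistent. Whether the original analyses scaled
regressors is not documented; this is the package's own choice.

**Degenerate correlations.** A zero-variance predicted or recorded
segment would make Pearson r undefined; it is reported as 0 with a
warning.

**Model registry.** Three named models reproduce the standard hierarchy:
`Env` (envelope, lags −200…600 ms), `PhFSgram` (19 phonetic features +
8-band spectrogram, −200…600 ms, univariate baseline `Sgram`), `SemEnv`
(surprisal + envelope, −200…700 ms, baseline `Env`). The *residual-r*
statistic is the per-channel prediction gain of the multivariate model
over its baseline, averaged over channels per participant, tested
against zero with a one-tailed one-sample t-test across participants.
Because the models are nested and regularized, the null gain is slightly
negative on held-out data, which makes the test conservative under the
null — the calibration experiment below measures this.

## Preprocessing

Polyphase FIR resampling (to 100 Hz by default) precedes filtering; the
band-pass is a Butterworth of order 2 applied forward and backward
(`sosfiltfilt`), i.e. zero phase with a 4th-order magnitude response,
passing 1–8 Hz. Channels whose variance exceeds 3× the median channel
variance are flagged and rebuilt by spherical-spline interpolation
(Perrin-style Legendre expansion, stiffness m = 4, regularization 1e-5,
50 series terms) from the clean channels. A participant-level QC gate
warns above 4 interpolated electrodes or 30% rejected data. Re-reference
defaults to `none`: whether any offline re-reference beyond the
recording reference should precede TRF fitting is not documented, and
the TRF is reference-invariant up to a common component.

## Component metrics

The N1-P2 metric is the peak-to-peak amplitude of the envelope TRF in a
search window (default 30–180 ms): per electrode, most negative minus
most positive weight, with no ordering constraint between the two
extrema and window-edge extrema accepted but flagged (`at_edge`). The
N400-like metric is the signed mean surprisal weight in a late window
(default 440–640 ms). Both operate on TRF weights, not epoched averages.
Group statistics beyond tidy tables (e.g. mixed models over electrodes)
are deliberately left to external statistics packages.

## Phoneme distance maps

Phonetic-feature weights are rotated to the phoneme domain through the
inventory's binary indicator matrix M (`W_p = M W_f`). The raw indicator
is the default; a row-normalized variant (averaging rather than summing
features) is behind a flag. Pairwise Euclidean distances between the
phonemes' weight vectors (flattened over the full lag window and all
channels by default; both selectable) form the distance map. Classical
(Torgerson) MDS embeds the map — default dimensionality k = 2, the
smallest space that can be visualized and aligned; negative eigenvalues
are clipped with a warning. Each embedding is aligned to a reference map
(the map of the cohort-average weights of the reference condition) by
similarity Procrustes — translation, orthogonal transform with
reflections permitted, isotropic scale — and residuals are per-phoneme
Euclidean distances in the embedding space after alignment. Computing
residuals in the embedding (rather than the full weight space) follows
the reading that the alignment operates on MDS results; both the
embedding dimensionality and this choice are configurable at the API
level.

The shipped inventory covers 39 ARPAbet phonemes on the 19 binary
articulatory features. Because the place axis is collapsed to five
categories, a few assignments are pragmatic (documented in
`speechtrf.inventory`) so that all 39 feature rows are unique — a
requirement for the rotation to distinguish phonemes.

## Cluster-based permutation test

Paired two-condition contrasts of (channel × lag) weight maps across
participants: per-sample paired t; samples with |t| above the two-tailed
critical value at the cluster-forming α (default 0.05, not documented in
the original analyses and configurable) are grouped into connected
clusters of one sign, with connectivity the union of channel adjacency
(sensor pairs closer than 0.6 unit-sphere distance — the smallest round
threshold leaving no channel isolated on the shipped montage) and
consecutive-lag adjacency. The cluster statistic is the signed t-sum;
the null is the distribution of the maximum absolute cluster statistic
under random within-participant condition sign flips (default 5000
permutations, consistent with the Monte-Carlo precision of reported
p-values; 1000 in the calibration studies below). The observed labelling
is included in the null — p = (b+1)/(m+1) — so the smallest attainable p
is 1/(m+1), and the Monte-Carlo SD of p is √(p(1−p)/m). Sign-flip t
statistics are computed vectorized: flips leave per-sample sums of
squares unchanged, so each permutation's t-map follows from its flipped
mean alone.

## The forward simulator

`generate_stimulus` draws Poisson phoneme onsets (default 8/s) labelled
uniformly from the inventory and Poisson word onsets (default 2/s) with
log-normal surprisal (μ=1.0, σ=0.5 on the log scale — positive and
right-skewed like −log p). The envelope is the phoneme-onset pulse train
convolved with a 50 ms raised cosine; each spectrogram band applies a
per-phoneme band-gain profile to the same pulses, so acoustics co-vary
with the phoneme stream. `make_kernels` builds response kernels as sums
of Gaussian bumps (width given as FWHM, truncated at 4σ so stated
latencies carry exactly the stated amplitudes) with smooth positive
scalp topographies (von-Mises–Fisher bumps around a random upper-
hemisphere direction on the sensor sphere). Defaults place −2 at 70 ms
and +3 at 140 ms on the envelope (an N1-P2-like complex) and −1.5 at
500 ms on surprisal (an N400-like late negativity).

`simulate_eeg` convolves each feature with its kernel, spreads it by the
topography and adds noise: 1/f¹-colored and white noise mixed 80/20 in
power, band-limited to the 1–8 Hz analysis band, scaled so the realized
signal-to-noise power ratio equals the requested dB value exactly. The
1/f choice is a generic EEG-spectrum stand-in, not an inference about
any particular dataset.

`make_cohort` replicates participants (kernel amplitude jittered by
LogNormal(0, 0.1), latencies by N(0, 5 ms)) and conditions (amplitude
scaling, latency shifts, and per-phoneme kernel perturbation when
simulating at the phoneme level). Each condition draws its own stimulus,
shared across participants — as when a cohort hears the same recordings.
`shared_stimulus=True` makes all conditions share one stimulus; this
matters for null calibration, because regularization bias is
stimulus-specific and common to all participants hearing the same
stimulus, so two *different* stimuli under identical kernels produce a
systematic (non-null) weight difference. Calibration studies therefore
use a shared stimulus, where condition labels are exactly exchangeable.

**What the simulator does not emulate:** realistic acoustics (the
"audio" exists only as regressors), phonotactics and prosody (phoneme
sequences are iid), non-linear or adaptive neural responses, attention
and arousal dynamics, artifacts (blinks, muscle), and volume-conduction
realism beyond smooth topographies. Passing recovery tests therefore
demonstrates the correctness and calibration of the estimation and
inference machinery under the linear-convolutional generative model they
assume — not robustness to everything real EEG contains.

## Recovery battery and problem sizes

`speechtrf.recovery` packages the validation studies; `tests/` and
`scripts/acceptance.py` run them at these sizes, chosen as desk-scale
defaults for a single CPU core:

- solver exactness: 50 random instances up to 200×50 against a direct
  normal-equations solve (agreement ≤ 1e-10 relative);
- kernel recovery: 64 channels, 3 min, +20 dB; best-channel correlation
  with the true envelope kernel and the distance (in grid steps) between
  the CV-chosen λ and the λ maximizing prediction of an independent
  noise realization;
- N1-P2 effect recovery: 15 participants × 2 conditions, 90 s, 32
  channels, programmed 1.5× amplitude scaling;
- residual-r power/false positives: 20 cohorts of 15, 60 s, 16 channels,
  with and without a true surprisal kernel;
- phoneme maps: 20 cohorts of 6, 40 s, 16 channels, phoneme-level
  simulation with perturbation SD 0.05 (A) vs 0.5 (B), phonetic-feature
  TRFs at fixed λ = 50 over lags 0–250 ms;
- CBPT: 200 null repetitions and 20 injected-effect seeds, 15
  participants, 30 s recordings, 64 channels, envelope TRFs at fixed
  λ = 10 over lags 0–400 ms, 1000 permutations. Fixed-λ fits are used in
  the calibration loops because the quantity under test is the
  permutation machinery, not the λ search.

## Known limitations

- The ridge solve materializes the full lagged Gram matrix; very wide
  feature sets at high sampling rates will want banded or iterative
  solvers, which are out of scope.
- Only forward (encoding) models are implemented — no backward decoders,
  no banded per-feature λ, no boosting.
- The TextGrid reader handles the common long text format's interval
  tiers only.
- The QC gate warns rather than excludes; participant exclusion is left
  to the caller.
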