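# speechtrf

Forward (encoding) models of continuous-speech EEG, for auditory and
cognitive neuroscientists who study how the brain tracks naturalistic
speech. The package implements the full analysis chain used in
speech-tracking experiments — EEG conditioning, stimulus regressor
construction, temporal response function (TRF) estimation, ERP-like
component metrics, phoneme distance maps, and cluster-based permutation
statistics — together with a ground-truth forward simulator, so that
every stage can be validated by parameter recovery without any real
recordings.

## The model

A TRF is a lagged linear kernel mapping stimulus features to each EEG
channel,

    y_c(t) = Σ_f Σ_l  w[l, f, c] · x_f(t − l) + b_c ,

estimated in closed form with Tikhonov (ridge) regularization,
β = (XᵀX + λI)⁻¹Xᵀy, on the time-lagged design matrix X. λ is chosen by
leave-one-fold-out cross-validation (5 contiguous folds) over a log grid
10⁻²–10⁸, maximizing the Pearson prediction correlation averaged over
channels and folds. Supported regressors: the Hilbert speech envelope,
an 8-band spectrogram with edges spaced along the Greenwood cochlear map
(250–8000 Hz), sparse phoneme onsets coded on 19 binary articulatory
features, and word onsets weighted by surprisal (−log word probability).
On top of the fitted kernels the package measures the envelope N1-P2
peak-to-peak complex (30–180 ms), the late surprisal (N400-like)
amplitude, nested-model prediction gains (residual-r, one-tailed cohort
t-test), phoneme distance maps (feature-to-phoneme rotation, classical
MDS, Procrustes alignment, per-phoneme residuals), and paired
spatiotemporal cluster-based permutation tests with sign-flip nulls.

See `docs/methods.md` for the full model description, defaults, and
numerical choices.

## Worked example

`examples/` holds one short script per capability. The first simulates
two minutes of speech-like stimulation, generates 64-channel EEG from a
known envelope kernel at +15 dB SNR, and fits a TRF:

```bash
$ python examples/01_simulate_and_recover_trf.py
chosen lambda           : 1000
mean prediction r       : 0.522
kernel recovery r (best): 0.9999
```

The prediction r is the held-out correlation between predicted and
simulated EEG (bounded well below 1 by sensor noise, as in real data);
the recovery r compares the estimated kernel's lag profile against the
generating one at its best channel and approaches 1 at this SNR — the
estimator is recovering the ground truth, not just predicting.

The other examples walk through the preprocessing chain
(`02_preprocessing_chain.py`), regressor construction from audio and
alignments (`03_stimulus_features.py`), component metrics and the
residual-r test (`04_component_metrics.py`), phoneme maps
(`05_phoneme_maps.py`), and the cluster permutation test
(`06_cluster_permutation.py`).

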