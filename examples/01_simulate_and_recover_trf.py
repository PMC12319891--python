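"""Simulate speech-evoked EEG and recover the generating kernel with a TRF.

Builds a 2-minute speech-like stimulus, convolves its envelope with a
known N1-P2-shaped kernel spread over 64 channels, adds 1/f noise at
+15 dB, then fits a lagged ridge model with cross-validated
regularization and compares the estimated kernel with the truth.
"""

import numpy as np

import speechtrf as st

stim = st.generate_stimulus(duration=120.0, seed=1)
kernels = st.make_kernels(st.default_kernel_specs(), n_channels=64, seed=2)
rec = st.simulate_eeg(stim.features, kernels, snr_db=15.0, seed=3)

cv = st.cv_lambda_search(stim.features.select(["env"]), rec,
                         lag_window=(-200.0, 600.0))

true = kernels[0]
est = cv.model.kernel("env")
ref = np.interp(cv.model.lags_ms, true.lags_ms, true.amplitude_profile,
                left=0.0, right=0.0)
r_best = max(
    np.corrcoef(est[:, c], ref)[0, 1] for c in range(est.shape[1])
)

print(f"chosen lambda           : {cv.best_lambda:g}")
print(f"mean prediction r       : {cv.prediction.mean_r:.3f}")
print(f"kernel recovery r (best): {r_best:.4f}")
print()
print("The prediction r is the Pearson correlation between model-predicted")
print("and held-out EEG (modest even for a perfect model, because most EEG")
print("variance is noise); the recovery r compares the estimated lag")
print("profile with the generating kernel and should approach 1 at this SNR.")
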