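"""Spatiotemporal cluster test on a programmed condition contrast.

Simulates 15 participants hearing the same stimulus under two conditions,
with condition B's envelope kernel amplitude-scaled; fits envelope TRFs
and asks the paired cluster-based permutation test where the conditions
differ across channels and lags.
"""

import numpy as np

import speechtrf as st
from speechtrf.recovery import _fit_env_weights

base = st.CohortSpec(duration=30.0, n_channels=64, snr_db=10.0,
                     shared_stimulus=True)
ds = st.make_cohort(15, ["A", "B"], {"B": {"kernel_scale": {"env": 1.5}}},
                    base, seed=10)
weights = _fit_env_weights(ds, lam=10.0, lag_window=(0.0, 400.0))
A = np.stack([weights[(p, "A")] for p in ds.participants])
B = np.stack([weights[(p, "B")] for p in ds.participants])

labels, pos = st.default_montage()
adj = st.adjacency_from_positions(pos, 0.6)
res = st.paired_cluster_permutation(A, B, adj, n_permutations=1000, seed=11)

print(f"clusters found: {len(res.clusters)}")
for i in range(min(3, len(res.clusters))):
    members = res.clusters[i]
    lags_ms = members[:, 1] * 10.0
    chans = sorted({labels[c] for c in members[:, 0]})
    print(f"  cluster t = {res.cluster_stats[i]:9.1f}, "
          f"p = {res.p_values[i]:.4f} (MC SD {res.mc_sd[i]:.4f}), "
          f"{lags_ms.min():.0f}-{lags_ms.max():.0f} ms, "
          f"{len(chans)} channels")
print()
print("The significant cluster's signed t-sum, its permutation p-value and")
print("the Monte-Carlo SD of that p are reported; the cluster should span")
print("the lags where the envelope kernel lives (~30-200 ms) on the")
print("channels its topography drives.")
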