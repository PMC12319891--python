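"""Measure N1-P2 and N400-like components on a simulated cohort.

Simulates eight participants hearing two speech registers whose envelope
kernel differs in amplitude by 1.5x, fits envelope and surprisal models,
and reads the ERP-like components off the TRF weights, including the
residual-r check that surprisal adds predictive power over the envelope
and the component-vs-behavior correlation.
"""

import numpy as np

import speechtrf as st

base = st.CohortSpec(duration=60.0, n_channels=32, snr_db=20.0)
ds = st.make_cohort(8, ["plain", "clear"],
                    {"clear": {"kernel_scale": {"env": 1.5}}},
                    base, seed=8)
cfg = st.RunConfig()

env_run = st.run_model(cfg, "Env", ds)
tab = st.component_table({k: v.model for k, v in env_run.fits.items()})
means = tab.groupby("condition")["value"].mean()
print("mean N1-P2 peak-to-peak:")
print(f"  plain : {means['plain']:.3f}")
print(f"  clear : {means['clear']:.3f}  "
      f"(ratio {means['clear'] / means['plain']:.2f}, programmed 1.50)")

sem_run = st.run_model(cfg, "SemEnv", ds)
pooled = sem_run.residual_test_pooled
print(f"surprisal prediction gain: t({pooled.df}) = {pooled.t:.2f}, "
      f"one-tailed p = {pooled.p:.2g}")

n400 = st.component_table({k: v.model for k, v in sem_run.fits.items()},
                          component="N400", feature="surprisal",
                          window=(440.0, 640.0))
values = n400.groupby(["participant", "condition"])["value"].mean()
rng = np.random.default_rng(0)
scores = -0.3 * values.to_numpy() + 0.05 * rng.standard_normal(len(values))
r, p = st.behavior_correlation(values.to_numpy(), scores)
print(f"N400 vs synthetic comprehension score: r = {r:.2f}, p = {p:.2g}")
print()
print("A more negative N400-like amplitude indicates stronger semantic")
print("surprisal encoding; the synthetic scores were built to anticorrelate")
print("with it, and the correlation recovers that construction.")
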