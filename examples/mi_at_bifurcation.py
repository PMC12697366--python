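"""Stimulus-response mutual information peaks at the critical bifurcation.

Sweeps the control parameter of the supercritical pitchfork toward mu = 0,
runs 300 pulse trials per value (six pulse amplitudes, round-robin), and
estimates I(X_tau; delta_X) at a 10 s readout lag.  Away from the
bifurcation the stimulus is forgotten exponentially at rate |mu|; at mu = 0
critical slowing down turns forgetting into a slow power law, so the
longer the readout lag the more decisively the critical point wins.
"""

import critbif as cb

cfg = cb.SimConfig(duration=10.0, dt=1e-3, D=5e-5, settle_time=100.0,
                   seed=50, record_stride=10)
df = cb.mi_sweep("pitchfork_super", [-1.0, -0.3, -0.1, 0.0], cfg,
                 lags=[10.0], n_trials=300)
print(df[["mu", "lag", "mi_bits", "h_bits", "hcond_bits"]]
      .to_string(index=False, float_format=lambda v: f"{v:.3f}"))
best = df.loc[df["mi_bits"].idxmax(), "mu"]
print(f"\nMI at lag 10 s is maximal at mu = {best:g}: the critical "
      "bifurcation is the informational optimum of the sweep "
      "(upper bound log2(6) ~ 2.585 bits for 6 stimuli).")
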