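"""Which canonical bifurcations are critical AND biologically plausible?

Prints the seven-form taxonomy: how each normal form can be scale
invariant (deterministic power-law relaxation, noise-driven Brownian
fluctuations, both, or neither) and whether it survives noise in the order
and control parameters without flying away.  Only the supercritical
pitchfork, supercritical Hopf, and the x>0-confined transcritical pass
every requirement.
"""

from critbif.experiments import verdict_table

df = verdict_table()
print(df.to_string(index=False))
plausible = ", ".join(df[df["biologically_plausible"]]["form"])
print(f"\nBiologically plausible critical bifurcations: {plausible}.")
print("The linear form is Brownian-critical but unbounded; subcritical "
      "forms repel; the saddle node flies away on its unstable side.")
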