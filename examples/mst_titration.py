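"""Estimate a dissociation constant from a simulated MST titration.

Simulates a 19-point two-fold dilution (200 uM down to 0.763 nM) of ligand
against 50 nM labeled target with 2% response noise, then fits the 1:1
binding isotherm with ligand depletion.
"""

import polku as pk

K_D_TRUE = 35.6e-6  # 35.6 uM
TARGET = 50e-9      # 50 nM labeled species

curve = pk.simulate_titration(K_D_TRUE, TARGET, noise=0.02, seed=3)
fit = pk.fit_isotherm(curve)

print(f"titration: {curve.concentrations.size} points spanning "
      f"{curve.span_orders:.1f} orders of magnitude")
print(f"fitted K_D = {1e6 * fit.param('k_d'):.1f} "
      f"+/- {1e6 * fit.stderr['k_d']:.1f} uM (truth "
      f"{1e6 * K_D_TRUE:.1f} uM)")
print("K_D is the ligand concentration at which half the target is bound "
      "in the depletion-corrected 1:1 model.")
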