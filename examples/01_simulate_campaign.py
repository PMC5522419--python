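"""Simulate a binary SERS measurement campaign.

Builds a 4-MBA / 4-MPY dilution series (the two molecules have very
different adsorption capacities: k_true 0.56 vs 1.44), simulates 8 replicate
spots per sample with spot-to-spot enhancement scatter and detector noise,
and prints the ground-truth ledger.
"""

import sersmix as sx

lib = {c.name: c for c in sx.default_component_library()}
names = ["4-MBA", "4-MPY"]
samples = [
    ("A3", sx.Composition(names, [0.25, 0.75])),
    ("A5", sx.Composition(names, [0.50, 0.50])),
    ("A7", sx.Composition(names, [0.75, 0.25])),
]
design = sx.SimulationDesign([lib[n] for n in names], samples, spots_per_sample=8)
noise = sx.NoiseModel(spot_factor_sigma=0.2, additive_sigma=0.01)

study = sx.simulate_study(design, noise, seed=42)
print(f"pure reference spectra : {len(study.pure)} (8 spots x 2 components)")
print(f"mixture spectra        : {len(study.mixtures)} (8 spots x 3 samples)")
print("\nGround-truth ledger (solution vs adsorbed surface fractions):")
print(study.ledger.to_string(index=False))
print(
    "\nNote how the surface fractions are pulled toward 4-MPY (k_true 1.44):"
    "\nthe substrate over-represents the strongly adsorbing molecule, which is"
    "\nexactly the bias the kinetics correction later removes."
)
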