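"""Estimate adsorbed-phase (surface) compositions from PC scores.

The mixture's mean score vector is converted to mole fractions by solving
the constrained linear system: the score must be the composition-weighted
barycentre of the pure-component score anchors, and the fractions must sum
to one.  With all kinetics factors k = 1 this yields the composition of
molecules actually sitting on the substrate.
"""

import numpy as np

import sersmix as sx
from sersmix.pipeline import predict_surface_compositions

lib = {c.name: c for c in sx.default_component_library()}
names = ["1,4-BDT", "4-MBA", "4-MPY"]
samples = [("mix", sx.Composition(names, [0.2, 0.3, 0.5]))]
design = sx.SimulationDesign([lib[n] for n in names], samples)
study = sx.simulate_study(design, sx.NoiseModel(0.0, 0.0), seed=3)  # noiseless

model = sx.fit_pure_references(study.pure)
surface, _, _ = predict_surface_compositions(study.mixtures, model)

truth = sx.ledger_composition(study.ledger, "mix", "surface_fraction")
print("estimated surface composition:", {k: round(v, 4) for k, v in surface["mix"].as_percent().items()})
print("simulator ground truth       :", {k: round(float(v) * 100, 4) for k, v in zip(truth.component_names, truth.fractions)})
gap = np.abs(surface["mix"].reorder(truth.component_names).fractions - truth.fractions).max()
print(f"largest gap: {gap:.2e} (noiseless spectra -> recovery to numerical precision)")
print(
    "\nThese are the fractions ON the substrate, not in the liquid: the"
    "\nsolution held 20/30/50 but the adsorbed mixture is biased toward the"
    "\nmore strongly adsorbing molecules."
)
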