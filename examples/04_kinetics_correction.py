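"""Calibrate adsorption-kinetics factors and recover solution compositions.

One mixture of known makeup (the reference) gives each component's k =
predicted/true ratio; dividing any other sample's prediction by k and
renormalizing removes the adsorption bias.  The whole pipeline is one call.
"""

import numpy as np

import sersmix as sx

lib = {c.name: c for c in sx.default_component_library()}
names = ["4-MBA", "4-MPY"]
samples = [
    ("A3", sx.Composition(names, [0.25, 0.75])),
    ("A5", sx.Composition(names, [0.50, 0.50])),   # the reference
    ("A7", sx.Composition(names, [0.75, 0.25])),
]
design = sx.SimulationDesign([lib[n] for n in names], samples)
study = sx.simulate_study(design, sx.NoiseModel(0.2, 0.01), seed=11)

analysis = sx.analyze_simulated(study, reference_sample_id="A5")
print("calibrated k (display rounding):", analysis.factors.rounded())
print()
for sid in ("A3", "A5", "A7"):
    surf = analysis.surface[sid].as_percent()
    sol = analysis.solution[sid].as_percent()
    truth = sx.ledger_composition(study.ledger, sid, "solution_fraction")
    err = np.abs(
        analysis.solution[sid].reorder(truth.component_names).fractions - truth.fractions
    ).max() * 100
    print(f"{sid}: surface {surf['4-MPY']:.1f}% 4-MPY -> corrected "
          f"{sol['4-MPY']:.2f}% (true {truth['4-MPY'] * 100:.2f}%, "
          f"max error {err:.2f} pp)")
print(
    "\nUncorrected surface values overshoot 4-MPY by 10-20 points; after the"
    "\nsingle-reference k correction the solution compositions come back"
    "\nwithin a fraction of a percentage point under this noise level."
)
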