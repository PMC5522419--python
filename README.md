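# sersmix

Semi-quantitative composition analysis of trace-level molecular mixtures from
surface-enhanced Raman scattering (SERS) spectra.

## The problem

SERS detects molecules adsorbed on a nanostructured metal substrate at
micromolar concentrations and below, but the spectra report the **adsorbed**
mixture, not the **solution**: molecules compete for adsorption sites, and a
strongly adsorbing species is systematically over-represented on the surface.
For a 1:2 mixture the surface can easily look like 3:2 — an error of 20+
percentage points if the bias is ignored.

`sersmix` implements a two-stage estimator for users of SERS substrates
(chemical sensing, food safety, environmental monitoring) who need mixture
compositions, not just detection:

1. **PCA score unmixing.** A loading model is fitted by mean-centered PCA on
   replicate spectra of the pure components; c pure components need c − 1
   retained PCs. A mixture's replicate-spot spectra are projected onto the
   loading matrix and their scores averaged. The surface composition
   a = (a₁, …, a_{n+1}) solves the constrained linear system

   ```
   Σᵢ aᵢ kᵢ (x_{i,j} − x_{m,j}) = 0   for each retained PC j,
   Σᵢ aᵢ = 1,
   ```

   where x_{i,j} is pure component i's mean score on PC j and x_{m,j} the
   mixture's mean score (kᵢ = 1 at this stage). For a binary mixture this is
   linear interpolation between the two pure PC1 scores.

2. **Adsorption-kinetics correction.** Each component's adsorption capacity
   is summarized by a factor kᵢ = (PCA-predicted fraction) / (true solution
   fraction), calibrated once from a single reference mixture of known
   makeup. Treating k as constant across trace-level mixtures, any sample's
   solution composition is recovered as aᵢ ∝ (predictedᵢ / kᵢ), renormalized
   — equivalently by solving the system above with the calibrated kᵢ.

A synthetic-campaign generator (Lorentzian band spectra of the four standard
thiol probes 1,4-BDT, 2-NaT, 4-MBA, 4-MPY; constant-k adsorption competition;
log-normal spot-to-spot enhancement scatter; additive detector noise)
provides fully controlled end-to-end validation.

## Worked example

```python
import sersmix as sx

lib = {c.name: c for c in sx.default_component_library()}
names = ["4-MBA", "4-MPY"]
samples = [("A3", sx.Composition(names, [0.25, 0.75])),
           ("A5", sx.Composition(names, [0.50, 0.50])),   # reference
           ("A7", sx.Composition(names, [0.75, 0.25]))]
design = sx.SimulationDesign([lib[n] for n in names], samples)
study = sx.simulate_study(design, sx.NoiseModel(0.2, 0.01), seed=11)

analysis = sx.analyze_simulated(study, reference_sample_id="A5")
print(analysis.factors.rounded())
print({sid: round(c.as_percent()["4-MPY"], 2) for sid, c in analysis.solution.items()})
```

prints

```
{'4-MBA': 0.56, '4-MPY': 1.44}
{'A3': 75.02, 'A5': 50.0, 'A7': 24.81}
```

The calibrated factors recover the simulator's adsorption capacities (4-MPY
adsorbs ~2.6× more readily than 4-MBA), and the corrected 4-MPY fractions
match the true 75 / 50 / 25% within 0.2 percentage points despite 20%
spot-to-spot enhancement scatter — whereas the uncorrected surface values
read 88.6 / 72.2 / 46.2%. The scripts in `examples/` walk through each stage
(simulation, model fitting, surface composition, kinetics correction,
benchmark tables) with commentary.

A `sersmix` command-line tool wraps the same pipeline
(`simulate | fit | predict | calibrate | correct | reproduce-tables`); see
`sersmix --help`.

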