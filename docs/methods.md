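# Methods

## Model

A SERS spectrum of a mixture at trace level is modelled as a linear
superposition of the pure-component spectra of whatever is adsorbed on the
substrate. Two distinct compositions matter:

* the **surface composition** s — mole fractions of molecules on the
  substrate, which the spectra directly encode;
* the **solution composition** a — mole fractions in the liquid, the quantity
  of interest.

Adsorption competition links them. At trace level, where molecules are
assumed not to interact, each component's propensity to adsorb is summarized
by one positive constant, the adsorption-kinetics factor kᵢ, and

  sᵢ = aᵢ kᵢ / Σⱼ aⱼ kⱼ.

This constant-k model is both the forward model of the simulator and the
assumption behind the correction; it is exact when relative adsorption rates
are concentration-independent over the working range.

### Score unmixing

Mean-centered PCA is fitted on pure-component replicate spectra only; mixture
spectra are projected onto the fixed loading matrix. Because a noiseless
mixture spectrum is a convex combination of pure spectra, its score vector is
the same convex combination of the pure-component score anchors. The surface
composition therefore solves

  Σᵢ aᵢ kᵢ (x_{i,j} − x_{m,j}) = 0 (j = 1..n),  Σᵢ aᵢ = 1,

with kᵢ = 1: a square (n+1)×(n+1) system when c = n+1 components meet n
retained PCs. For a binary mixture this reduces to interpolation on PC1,
a₁ = (x_m − x₂)/(x₁ − x₂).

### Kinetics calibration and correction

One reference mixture of known composition gives kᵢ = predictedᵢ / trueᵢ at
full precision (reports round to 2 decimals for display only). Any other
prediction is corrected by aᵢ = (pᵢ/kᵢ)/Σⱼ(pⱼ/kⱼ). Solving the general
system with k directly is algebraically identical to correcting the k = 1
solution; both routes are implemented and property-tested equal to 1e-9,
and correction is invariant to rescaling all k by a common constant (only
ratios of k matter). Correcting the reference with its own k returns its
true composition exactly, which the pipeline uses as a self-check.

## Preprocessing choices

* **Closure normalization (default on).** Each spectrum is scaled to unit
  total intensity. The score-interpolation model needs mixture scores to be
  convex combinations of pure scores; closure guarantees this regardless of
  the spot's absolute enhancement factor, which in SERS varies strongly from
  spot to spot. A raw mode is retained for workflows that rely on scores
  being linear in absolute intensity; the flag is recorded in the model's
  provenance and reused automatically at projection time.
* **No baseline correction by default.** An iterative polynomial
  (min-clipped refit) hook exists for spectra with broad backgrounds but is
  off everywhere.
* **Working grid 600–1800 cm⁻¹, step 2 cm⁻¹** (601 channels), covering all
  bands of the four thiol probes; spectra on other grids are linearly
  interpolated, and extrapolation outside the measured range is an error.
* **Duplicate shifts are an error, never averaged** — silent averaging hides
  acquisition faults.

## Numerical choices

* PCA is computed by SVD of the centered training matrix; loadings are
  sign-fixed (largest-magnitude entry positive) so scores are comparable
  across runs, and the same input gives bit-identical models.
* Retained PCs default to c − 1 for c components — the centered pure spectra
  span at most c − 1 dimensions, so noiseless training data put 100% of
  variance there. A warning is raised when the retained PCs explain < 99% of
  training variance.
* The composition system is solved exactly in the square case and by
  ordinary least squares with the sum-to-one constraint eliminated exactly
  when more PCs than c − 1 are retained. A condition number above 1e10
  raises an error naming the closest pair of component score anchors
  (near-duplicate spectra, e.g. two thiols sharing their dominant band,
  make the system meaningless rather than merely noisy).
* Out-of-simplex fractions (possible under noise or extrapolation) are
  returned raw with a warning; an opt-in step clips at zero and
  renormalizes. Raw output is the default because clipping hides model
  mismatch and because reproducing published tables requires the plain
  arithmetic.
* Spot scores are averaged before solving by default; a per-spot mode
  (solve/correct each spot, then average fractions) exists for spot-level
  parity plots. The two agree exactly on noiseless data and differ only at
  second order under noise.

## Synthetic campaigns

The generator emulates what the method assumes about real measurements:

* pure-component spectra as sums of Lorentzian bands (Gaussian by flag) at
  the probes' characteristic Raman shifts, FWHM 14 cm⁻¹;
* equal total intensity across pure components by default, so mole fractions
  and intensity shares coincide; with unequal budgets the simulator warns and
  records the effective intensity-share weights in the ledger;
* surface fractions from the constant-k competition model (default k_true
  1.4, 1.0, 0.56, 1.44 for 1,4-BDT, 2-NaT, 4-MBA, 4-MPY — an arbitrary but
  realistic spread of adsorption capacities); a Langmuir-type option differs
  only in total coverage, which closure removes, and so probes exactly the
  robustness the constant-k assumption claims;
* 8 replicate spots per sample, each scaled by a log-normal enhancement
  factor (σ = 0.2) plus additive Gaussian noise (σ = 1% of the tallest pure
  peak) and an optional polynomial baseline; all draws come from one seeded
  generator, so studies are byte-reproducible.

The noise magnitudes are synthetic choices, set so that a calibrated
20-sample ternary campaign shows mean absolute solution-composition errors
in the low tenths of a percentage point — comfortably inside the ~5-point
scale of errors the method is expected to tolerate — while leaving PC1 of a
binary campaign just above the 99%-variance retention threshold. What
passing synthetic tests shows is that the estimator chain is correct and
stable under the model's own assumptions; it does not validate those
assumptions against real spectra, where band-shape changes on adsorption,
concentration-dependent k, or interacting analytes would violate them.

## Benchmark tables

The published binary (4-MPY/4-MBA, samples A3–A7, reference A5) and ternary
(1,4-BDT/4-MBA/4-MPY, samples A4–A7, reference A4) validation tables are
reproduced from their measured inputs only: stored true and PCA-predicted
compositions with the digits as printed, everything downstream recomputed.
Tolerance is 0.02 percentage points because the printed cells are 2-decimal
roundings of arithmetic on already-rounded inputs; recomputation lands
within 0.006 points of every printed corrected cell. Recomputed k rows agree
with the printed ones at 2-decimal rounding except one ternary cell printed
a final digit low (1.56 where the ratio of printed values rounds to 1.57),
and the printed binary error rows repeat the first component's row for the
second component (the two differ by 0.01 in two cells when recomputed
exactly). The quaternary series and the original studies' exact
explained-variance percentages depend on unreleased measured spectra and are
exercised via simulation only.

## Limitations

* k is calibrated from a single reference and assumed constant; pH,
  concentration and co-adsorption effects are out of scope (a spread
  diagnostic across multiple known samples is provided, but no pooling).
* No cosmic-ray despiking, smoothing, or vendor binary formats; inputs are
  delimited text in the two supported dialects.
* The solver is unregularized by design: heavily collinear component spectra
  fail loudly instead of returning a stabilized guess.
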