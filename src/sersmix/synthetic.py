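"""Synthetic SERS measurement campaigns with the statistical structure the
unmixing method assumes.

A pure component is a sum of Lorentzian bands at its characteristic Raman
shifts.  Adsorption competition follows the constant-k linear model: for a
solution composition a and per-component adsorption-kinetics factors k_true,
the adsorbed (surface) fractions are

    s_i = a_i * k_true_i / sum_j a_j * k_true_j.

Each measured spot sees the surface mixture scaled by a log-normal
spot-to-spot enhancement factor (SERS hot-spot variability), plus optional
polynomial baseline and additive Gaussian noise.  A study consists of
pure-component replicate sets (8 spots each by default, mirroring the
acquisition design of 8 randomly chosen points per substrate), mixture
samples, and a ground-truth ledger for test harnesses.

An optional Langmuir-type adsorption model (s_i proportional to
K_i a_i / (1 + sum_j K_j a_j)) probes robustness of the constant-k
assumption; in the trace limit it reduces to the linear model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import DesignError, IntensityBudgetWarning
from .solver import Composition
from .spectra import DEFAULT_GRID, RamanSpectrum, SpectraCollection


@dataclass
class ComponentSpec:
    """One simulated molecule: band positions/heights/widths and its true k."""

    name: str
    peak_centers: np.ndarray  # cm^-1
    peak_amplitudes: np.ndarray  # relative heights
    peak_fwhm: np.ndarray  # cm^-1
    k_true: float = 1.0

    def __post_init__(self) -> None:
        self.peak_centers = np.atleast_1d(np.asarray(self.peak_centers, dtype=float))
        self.peak_amplitudes = np.broadcast_to(
            np.asarray(self.peak_amplitudes, dtype=float), self.peak_centers.shape
        ).copy()
        self.peak_fwhm = np.broadcast_to(
            np.asarray(self.peak_fwhm, dtype=float), self.peak_centers.shape
        ).copy()
        if np.any(self.peak_amplitudes <= 0) or np.any(self.peak_fwhm <= 0):
            raise DesignError(f"component {self.name!r}: amplitudes and FWHM must be > 0")
        if self.k_true <= 0:
            raise DesignError(f"component {self.name!r}: k_true must be > 0")


@dataclass
class NoiseModel:
    """Noise structure of one campaign.

    ``spot_factor_sigma`` is the log-scale sigma of the multiplicative
    log-normal spot enhancement factor; ``additive_sigma`` is the additive
    Gaussian noise scale expressed relative to the tallest pure-spectrum peak.
    """

    spot_factor_sigma: float = 0.2
    additive_sigma: float = 0.01
    baseline_coeffs: Optional[Sequence[float]] = None

    def __post_init__(self) -> None:
        if self.spot_factor_sigma < 0 or self.additive_sigma < 0:
            raise DesignError("noise sigmas must be >= 0")


@dataclass
class SimulationDesign:
    """Components, sample compositions, spots per sample, and the shift grid."""

    components: list[ComponentSpec]
    samples: list[tuple[str, Composition]]
    spots_per_sample: int = 8
    grid: np.ndarray = field(default_factory=lambda: DEFAULT_GRID.copy())
    adsorption_model: str = "linear"  # or "langmuir"
    lineshape: str = "lorentzian"  # or "gaussian"
    equal_intensity_budget: bool = True

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.spots_per_sample < 1:
            raise DesignError("spots_per_sample must be >= 1")
        names = self.component_names
        for spec in self.components:
            if np.any(spec.peak_centers < self.grid[0]) or np.any(
                spec.peak_centers > self.grid[-1]
            ):
                raise DesignError(
                    f"component {spec.name!r} has peak centers outside the grid"
                )
        for sid, comp in self.samples:
            unknown = set(comp.component_names) - set(names)
            if unknown:
                raise DesignError(f"sample {sid!r} references unknown components {unknown}")
        if self.adsorption_model not in ("linear", "langmuir"):
            raise DesignError(f"unknown adsorption model {self.adsorption_model!r}")
        if self.lineshape not in ("lorentzian", "gaussian"):
            raise DesignError(f"unknown lineshape {self.lineshape!r}")

    @property
    def component_names(self) -> list[str]:
        return [c.name for c in self.components]


@dataclass
class StudyResult:
    """Everything a test harness needs: data plus ground truth."""

    pure: SpectraCollection
    mixtures: SpectraCollection
    ledger: pd.DataFrame  # per (sample, component): solution/surface fractions, k_true
    design: SimulationDesign
    noise: NoiseModel


def default_component_library() -> list[ComponentSpec]:
    """The four thiol probe molecules with their characteristic band positions.

    Band centers (cm^-1) follow the standard assignments for these molecules
    on silver substrates: 1,4-benzenedithiol (C-S stretch 1063, C-H bend 1178,
    C-C stretch 1563), 2-naphthalenethiol (1062, 1378, 1567, 1620),
    4-mercaptobenzoic acid (C-C 1073/1580, C-H 1135/1178, COO- 1369), and
    4-mercaptopyridine (ring breathing 1007/1094, C-H bend 1060, C=C 1577).
    Default FWHM 14 cm^-1 and unit amplitudes are generic choices; the
    default k_true spread (1.4, 1.0, 0.56, 1.44) is an arbitrary but
    realistic range of adsorption capacities.
    """
    fwhm = 14.0
    return [
        ComponentSpec("1,4-BDT", [1063, 1178, 1563], 1.0, fwhm, k_true=1.4),
        ComponentSpec("2-NaT", [1062, 1378, 1567, 1620], 1.0, fwhm, k_true=1.0),
        ComponentSpec("4-MBA", [1073, 1135, 1178, 1369, 1580], 1.0, fwhm, k_true=0.56),
        ComponentSpec("4-MPY", [1007, 1060, 1094, 1577], 1.0, fwhm, k_true=1.44),
    ]


def render_pure_spectrum(
    spec: ComponentSpec,
    grid: Optional[np.ndarray] = None,
    lineshape: str = "lorentzian",
) -> RamanSpectrum:
    """Noiseless unit-scale pure spectrum: a sum of Lorentzian (or Gaussian) bands.

    Lorentzian: I(v) = sum_p A_p (w_p/2)^2 / ((v - c_p)^2 + (w_p/2)^2), so the
    value at a band center is exactly A_p (for isolated bands) and A_p/2 at
    center +/- FWHM/2.
    """
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    v = grid[:, None]
    c = spec.peak_centers[None, :]
    a = spec.peak_amplitudes[None, :]
    hw = spec.peak_fwhm[None, :] / 2.0
    if lineshape == "lorentzian":
        profile = a * hw**2 / ((v - c) ** 2 + hw**2)
    elif lineshape == "gaussian":
        sigma = spec.peak_fwhm[None, :] / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        profile = a * np.exp(-0.5 * ((v - c) / sigma) ** 2)
    else:
        raise DesignError(f"unknown lineshape {lineshape!r}")
    return RamanSpectrum(grid, profile.sum(axis=1), sample_id=spec.name,
                         spot_index=1, component_label=spec.name)


def surface_fractions(
    solution: Composition, design: SimulationDesign
) -> np.ndarray:
    """Adsorbed fractions for the design's components (zeros where absent)."""
    names = design.component_names
    a = np.array(
        [solution[n] if n in solution.component_names else 0.0 for n in names]
    )
    k = np.array([c.k_true for c in design.components])
    # langmuir occupancy K_i a_i / (1 + sum K_j a_j) shares its denominator
    # across components, so the *fractions* match the linear model; the models
    # differ only in total coverage (see total_coverage), which closure
    # normalization removes downstream.
    w = a * k
    total = w.sum()
    if total <= 0:
        raise DesignError("sample adsorbs nothing: all surface weights are zero")
    return w / total


def total_coverage(solution: Composition, design: SimulationDesign) -> float:
    """Overall surface occupancy scaling: 1 for the linear model, the
    Langmuir saturation factor sum(K a)/(1 + sum(K a)) otherwise."""
    if design.adsorption_model == "linear":
        return 1.0
    names = design.component_names
    a = np.array(
        [solution[n] if n in solution.component_names else 0.0 for n in names]
    )
    k = np.array([c.k_true for c in design.components])
    w = float((a * k).sum())
    return w / (1.0 + w)


def _pure_profiles(design: SimulationDesign) -> np.ndarray:
    """(n_components, n_channels) pure intensity profiles on the design grid."""
    profiles = np.vstack(
        [
            render_pure_spectrum(c, design.grid, design.lineshape).intensity
            for c in design.components
        ]
    )
    totals = profiles.sum(axis=1)
    if design.equal_intensity_budget:
        # equal total intensity across components: mole fractions == intensity shares
        profiles = profiles / totals[:, None] * totals.mean()
    elif np.ptp(totals) / totals.mean() > 1e-6:
        warnings.warn(
            "pure components have unequal total intensity; intensity-share "
            "fractions will differ from mole-fraction weights (effective "
            "weights recorded in the ledger)",
            IntensityBudgetWarning,
            stacklevel=3,
        )
    return profiles


def _effective_weights(s: np.ndarray, totals: np.ndarray) -> np.ndarray:
    """Intensity-share weights actually realized when budgets are unequal."""
    w = s * totals
    return w / w.sum() if w.sum() > 0 else w


def simulate_sample(
    sample: tuple[str, Composition],
    design: SimulationDesign,
    noise: NoiseModel,
    rng: np.random.Generator,
    profiles: Optional[np.ndarray] = None,
) -> SpectraCollection:
    """Simulate one sample's replicate spots.

    Each spot's spectrum is gamma * sum_i s_i P_i(v) + baseline(v) + eps(v),
    with gamma log-normal, eps Gaussian, and spots drawn independently.
    """
    sid, solution = sample
    if profiles is None:
        profiles = _pure_profiles(design)
    s = surface_fractions(solution, design)
    clean = total_coverage(solution, design) * (s @ profiles)
    max_peak = profiles.max()
    baseline = np.zeros_like(design.grid)
    if noise.baseline_coeffs is not None:
        x = (design.grid - design.grid.mean()) / (np.ptp(design.grid) / 2)
        baseline = np.polynomial.polynomial.polyval(x, np.asarray(noise.baseline_coeffs))
    spectra = []
    for spot in range(1, design.spots_per_sample + 1):
        gamma = float(np.exp(rng.normal(0.0, noise.spot_factor_sigma))) if noise.spot_factor_sigma > 0 else 1.0
        eps = (
            rng.normal(0.0, noise.additive_sigma * max_peak, size=design.grid.size)
            if noise.additive_sigma > 0
            else 0.0
        )
        spectra.append(
            RamanSpectrum(design.grid, gamma * clean + baseline + eps, sid, spot)
        )
    return SpectraCollection(spectra, design.grid)


def simulate_study(
    design: SimulationDesign,
    noise: NoiseModel,
    seed: int = 0,
    pure_spots: Optional[int] = None,
) -> StudyResult:
    """Simulate a full campaign: pure references, mixtures, ground-truth ledger.

    Fully reproducible: the same seed yields byte-identical output.  Pure
    references are measured with the same noise model and spot count as
    mixtures unless ``pure_spots`` overrides it.
    """
    rng = np.random.default_rng(seed)
    profiles = _pure_profiles(design)
    totals = profiles.sum(axis=1)
    names = design.component_names
    n_pure = design.spots_per_sample if pure_spots is None else pure_spots

    pure_list: list[RamanSpectrum] = []
    for i, spec in enumerate(design.components):
        pure_solution = Composition(
            names, np.eye(len(names))[i], {"pure": spec.name}
        )
        coll = simulate_sample(
            (f"pure-{spec.name}", pure_solution),
            SimulationDesign(
                design.components, [], n_pure, design.grid,
                design.adsorption_model, design.lineshape,
                design.equal_intensity_budget,
            ),
            noise,
            rng,
            profiles=profiles,
        )
        for s in coll:
            pure_list.append(
                RamanSpectrum(s.shift, s.intensity, s.sample_id, s.spot_index,
                              component_label=spec.name)
            )

    mixture_list: list[RamanSpectrum] = []
    ledger_rows = []
    for sid, solution in design.samples:
        coll = simulate_sample((sid, solution), design, noise, rng, profiles=profiles)
        mixture_list.extend(coll)
        s = surface_fractions(solution, design)
        eff = _effective_weights(s, totals)
        for j, name in enumerate(names):
            ledger_rows.append(
                {
                    "sample_id": sid,
                    "component": name,
                    "solution_fraction": solution[name]
                    if name in solution.component_names
                    else 0.0,
                    "surface_fraction": s[j],
                    "effective_weight": eff[j],
                    "k_true": design.components[j].k_true,
                }
            )

    ledger = pd.DataFrame(ledger_rows)
    return StudyResult(
        pure=SpectraCollection(pure_list, design.grid),
        mixtures=SpectraCollection(mixture_list, design.grid),
        ledger=ledger,
        design=design,
        noise=noise,
    )


def ledger_composition(ledger: pd.DataFrame, sample_id: str, column: str) -> Composition:
    """Extract one sample's ground-truth composition from the ledger."""
    sub = ledger[ledger["sample_id"] == sample_id]
    if sub.empty:
        raise DesignError(f"sample {sample_id!r} not in ledger")
    return Composition(sub["component"].tolist(), sub[column].to_numpy())
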