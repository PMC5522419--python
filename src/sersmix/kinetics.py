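"""Adsorption-kinetics calibration and composition correction.

Molecules compete for adsorption sites on the substrate, so the adsorbed
(surface) composition the spectra report differs systematically from the
solution composition.  The per-component adsorption-kinetics factor

    k_i = (surface fraction predicted from PC scores) / (true solution fraction)

quantifies each molecule's adsorption capacity.  At trace level the factors
are treated as constant across mixtures, so a single reference sample of
known composition calibrates them all; dividing any predicted composition by
k and renormalizing then recovers the solution composition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .exceptions import ParameterError
from .pca import LoadingModel
from .solver import Composition, solve_general


@dataclass
class KineticsFactors:
    """Per-component positive adsorption-capacity ratios k, with provenance."""

    component_names: list[str]
    k: np.ndarray
    reference_sample_id: str = ""
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.k = np.asarray(self.k, dtype=float)
        if len(self.component_names) != self.k.size:
            raise ParameterError("one k per component name required")
        if np.any(self.k <= 0):
            raise ParameterError(f"kinetics factors must be positive, got {self.k}")

    def __getitem__(self, name: str) -> float:
        return float(self.k[self.component_names.index(name)])

    def aligned_to(self, names: list[str]) -> np.ndarray:
        if set(names) != set(self.component_names):
            raise ParameterError(
                f"component mismatch: factors for {self.component_names}, "
                f"requested {names}"
            )
        return np.asarray([self[n] for n in names], dtype=float)

    def rounded(self, decimals: int = 2) -> dict[str, float]:
        """Display-rounded factors for human reports; computation keeps full precision."""
        return {n: round(float(v), decimals) for n, v in zip(self.component_names, self.k)}

    def save(self, path: str | Path) -> None:
        doc = {
            "component_names": self.component_names,
            "k": self.k.tolist(),
            "reference_sample_id": self.reference_sample_id,
            "provenance": self.provenance,
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "KineticsFactors":
        doc = json.loads(Path(path).read_text())
        return cls(
            component_names=list(doc["component_names"]),
            k=np.asarray(doc["k"], dtype=float),
            reference_sample_id=doc.get("reference_sample_id", ""),
            provenance=doc.get("provenance", {}),
        )


def estimate_k(
    predicted: Composition,
    true_solution: Composition,
    reference_sample_id: str = "",
) -> KineticsFactors:
    """Calibrate k from one reference sample: k_i = predicted_i / true_i.

    The reference must contain every component with nonzero true fraction,
    otherwise its factor is undefined.
    """
    names = predicted.component_names
    true_aligned = true_solution.reorder(names)
    t = true_aligned.fractions
    if np.any(t <= 0):
        zero = [n for n, v in zip(names, t) if v <= 0]
        raise ParameterError(
            f"true fraction of {zero} is zero in the reference; use a reference "
            "sample containing every component"
        )
    k = predicted.fractions / t
    return KineticsFactors(
        list(names),
        k,
        reference_sample_id=reference_sample_id,
        provenance={"predicted": predicted.fractions.tolist(), "true": t.tolist()},
    )


def correct_composition(predicted: Composition, factors: KineticsFactors) -> Composition:
    """Ratio-renormalize correction: a_i = (p_i / k_i) / sum_j (p_j / k_j)."""
    names = predicted.component_names
    k = factors.aligned_to(list(names))
    w = predicted.fractions / k
    total = w.sum()
    if total == 0:
        raise ParameterError("corrected fractions sum to zero; cannot renormalize")
    prov = dict(predicted.provenance)
    prov["k_reference"] = factors.reference_sample_id
    return Composition(list(names), w / total, prov)


def predict_solution_composition(
    x_m: np.ndarray,
    model: LoadingModel,
    factors: KineticsFactors,
    clip: bool = False,
    warn: bool = True,
) -> Composition:
    """Solution composition straight from scores via the general k-system.

    Algebraically identical to ``correct_composition(surface_composition(x_m,
    model), factors)``; both routes are exposed and property-tested equal.
    """
    k = factors.aligned_to(model.component_names)
    comp = solve_general(x_m, model, k=k, clip=clip, warn=warn)
    comp.provenance["k_reference"] = factors.reference_sample_id
    return comp


def error_report(estimated: Composition, true_solution: Composition) -> pd.Series:
    """Per-component absolute error in percentage points: |est_i - true_i| * 100."""
    names = estimated.component_names
    t = true_solution.reorder(list(names)).fractions
    err = np.abs(estimated.fractions - t) * 100.0
    return pd.Series(err, index=list(names), name="abs_error_pp")


def k_spread_report(
    predictions: dict[str, Composition],
    true_solutions: dict[str, Composition],
) -> pd.DataFrame:
    """Diagnostic: per-sample k for every sample of known composition.

    Rows are samples, columns components; a final ``spread`` row gives
    (max - min) per component.  Large spread means the constant-k assumption
    is strained for these mixtures.  No pooling is performed — calibration
    still uses a single designated reference.
    """
    rows = {}
    for sid, pred in predictions.items():
        if sid not in true_solutions:
            continue
        rows[sid] = estimate_k(pred, true_solutions[sid], sid).rounded(decimals=6)
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.loc["spread"] = frame.max() - frame.min()
    return frame
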