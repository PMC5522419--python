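"""End-to-end analysis: fit on pure references, project mixtures, estimate
surface compositions, calibrate k on one reference, correct to solution
compositions.

Two averaging orders are supported.  The default averages replicate-spot
scores per sample and then solves once per sample ("average-then-solve",
matching score-averaging practice for replicate SERS spots).  The per-spot
mode solves and corrects every spot individually and averages the resulting
fractions — useful for parity plots of spot-level scatter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .kinetics import (
    KineticsFactors,
    correct_composition,
    error_report,
    estimate_k,
    predict_solution_composition,
)
from .pca import LoadingModel, fit_loading_model, mean_scores, project
from .solver import Composition, surface_composition
from .spectra import SpectraCollection, preprocess
from .synthetic import StudyResult, ledger_composition


@dataclass
class StudyAnalysis:
    """All intermediate and final products of one campaign analysis."""

    model: LoadingModel
    scores: pd.DataFrame
    sample_scores: pd.DataFrame
    surface: dict[str, Composition]
    factors: Optional[KineticsFactors] = None
    solution: dict[str, Composition] = field(default_factory=dict)

    def error_table(self, truths: dict[str, Composition], which: str = "solution") -> pd.DataFrame:
        """Per-sample, per-component absolute errors (pp) against known truths."""
        source = self.solution if which == "solution" else self.surface
        rows = []
        for sid, comp in source.items():
            if sid not in truths:
                continue
            err = error_report(comp, truths[sid])
            for name, e in err.items():
                rows.append({"sample_id": sid, "component": name, "abs_error_pp": e})
        return pd.DataFrame(rows)


def fit_pure_references(
    pure: SpectraCollection,
    n_components: Optional[int] = None,
    grid: Optional[np.ndarray] = None,
    closure: bool = True,
    baseline_degree: Optional[int] = None,
) -> LoadingModel:
    """Preprocess pure-component replicates and fit the loading model."""
    grid = pure.common_grid if grid is None else grid
    prepped = preprocess(pure, grid=grid, closure=closure, baseline_degree=baseline_degree)
    return fit_loading_model(
        prepped,
        n_components,
        preprocessing={
            "closure": closure,
            "baseline_degree": baseline_degree,
            "grid": [float(prepped.common_grid[0]), float(prepped.common_grid[-1]),
                     float(prepped.common_grid[1] - prepped.common_grid[0])],
        },
    )


def predict_surface_compositions(
    mixtures: SpectraCollection,
    model: LoadingModel,
    per_spot: bool = False,
    warn: bool = True,
) -> tuple[dict[str, Composition], pd.DataFrame, pd.DataFrame]:
    """Project mixtures and estimate each sample's surface composition.

    Returns (compositions, spot score table, per-sample mean-score table).
    """
    closure = bool(model.preprocessing.get("closure", True))
    baseline = model.preprocessing.get("baseline_degree")
    prepped = preprocess(mixtures, grid=model.grid, closure=closure, baseline_degree=baseline)
    scores = project(prepped, model)
    sample_scores = mean_scores(scores)
    pc_cols = [f"PC{i+1}" for i in range(model.n_pc)]
    out: dict[str, Composition] = {}
    for sid in sample_scores.index:
        if per_spot:
            spot_fracs = [
                surface_composition(row.to_numpy(), model, warn=warn).fractions
                for _, row in scores.loc[sid][pc_cols].iterrows()
            ]
            mean_frac = np.mean(spot_fracs, axis=0)
            out[sid] = Composition(list(model.component_names), mean_frac / mean_frac.sum())
        else:
            x_m = sample_scores.loc[sid, pc_cols].to_numpy(dtype=float)
            out[sid] = surface_composition(x_m, model, warn=warn)
    return out, scores, sample_scores


def analyze_study(
    pure: SpectraCollection,
    mixtures: SpectraCollection,
    reference_sample_id: Optional[str] = None,
    reference_true: Optional[Composition] = None,
    n_components: Optional[int] = None,
    closure: bool = True,
    per_spot: bool = False,
    warn: bool = True,
) -> StudyAnalysis:
    """Full pipeline on spectra collections.

    When a reference sample (id + known solution composition) is given, k is
    calibrated on it and solution compositions are produced for every sample;
    otherwise the analysis stops at surface compositions.
    """
    model = fit_pure_references(pure, n_components, closure=closure)
    surface, scores, sample_scores = predict_surface_compositions(
        mixtures, model, per_spot=per_spot, warn=warn
    )
    analysis = StudyAnalysis(model, scores, sample_scores, surface)
    if reference_sample_id is not None:
        if reference_true is None:
            raise ValueError("reference_true composition required to calibrate k")
        if reference_sample_id not in surface:
            raise ValueError(f"reference sample {reference_sample_id!r} not among mixtures")
        factors = estimate_k(
            surface[reference_sample_id], reference_true, reference_sample_id
        )
        analysis.factors = factors
        pc_cols = [f"PC{i+1}" for i in range(model.n_pc)]
        for sid, comp in surface.items():
            if per_spot:
                spot_fracs = [
                    predict_solution_composition(
                        row.to_numpy(), model, factors, warn=warn
                    ).fractions
                    for _, row in scores.loc[sid][pc_cols].iterrows()
                ]
                mean_frac = np.mean(spot_fracs, axis=0)
                analysis.solution[sid] = Composition(
                    list(model.component_names), mean_frac / mean_frac.sum()
                )
            else:
                analysis.solution[sid] = correct_composition(comp, factors)
    return analysis


def analyze_simulated(
    study: StudyResult,
    reference_sample_id: str,
    n_components: Optional[int] = None,
    closure: bool = True,
    per_spot: bool = False,
    warn: bool = True,
) -> StudyAnalysis:
    """Run the full pipeline on a simulated study, calibrating on one of its
    samples using the ledger's true solution composition."""
    reference_true = ledger_composition(study.ledger, reference_sample_id, "solution_fraction")
    return analyze_study(
        study.pure,
        study.mixtures,
        reference_sample_id=reference_sample_id,
        reference_true=reference_true,
        n_components=n_components,
        closure=closure,
        per_spot=per_spot,
        warn=warn,
    )
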