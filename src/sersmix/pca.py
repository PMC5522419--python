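"""Loading-model fitting, projection, and score summaries.

The model is ordinary mean-centered PCA of the pure-component replicate
spectra: the loading matrix holds the top right-singular directions of the
centered training matrix.  Mixture spectra are then projected onto that fixed
loading matrix, and per-sample mean scores feed the composition solver.

The solver path is fully deterministic (numpy SVD with a fixed sign
convention: each loading is oriented so its largest-magnitude entry is
positive), so the same input yields bit-identical loadings across runs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .exceptions import (
    GridMismatchError,
    LowVarianceWarning,
    RankError,
    SampleLookupError,
)
from .spectra import SpectraCollection

#: Cumulative-variance fraction below which a retention warning is emitted.
VARIANCE_WARN_THRESHOLD = 0.99


@dataclass
class LoadingModel:
    """Fitted PCA loading model over pure-component training spectra.

    ``component_scores[i]`` is the mean score vector of pure component
    ``component_names[i]`` — the anchor points between which mixture scores
    interpolate.
    """

    grid: np.ndarray
    mean_spectrum: np.ndarray
    loadings: np.ndarray  # (n_pc, n_channels), rows orthonormal
    explained_variance_fraction: np.ndarray  # (n_pc,)
    component_names: list[str]
    component_scores: np.ndarray  # (n_components, n_pc)
    preprocessing: dict = field(default_factory=dict)
    training_scores: Optional[pd.DataFrame] = None  # per-spectrum, diagnostics

    @property
    def n_pc(self) -> int:
        return self.loadings.shape[0]

    def __post_init__(self) -> None:
        gram = self.loadings @ self.loadings.T
        if not np.allclose(gram, np.eye(self.n_pc), atol=1e-8):
            raise ValueError("loadings are not orthonormal within 1e-8")
        ev = self.explained_variance_fraction
        if np.any(ev < -1e-12) or np.any(ev > 1 + 1e-12) or np.any(np.diff(ev) > 1e-12):
            raise ValueError("explained variance fractions must be non-increasing in [0,1]")
        if self.component_scores.shape != (len(self.component_names), self.n_pc):
            raise ValueError("component_scores must have one row per component name")

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        doc = {
            "grid": self.grid.tolist(),
            "mean_spectrum": self.mean_spectrum.tolist(),
            "loadings": self.loadings.tolist(),
            "explained_variance_fraction": self.explained_variance_fraction.tolist(),
            "component_names": self.component_names,
            "component_scores": self.component_scores.tolist(),
            "preprocessing": self.preprocessing,
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "LoadingModel":
        doc = json.loads(Path(path).read_text())
        return cls(
            grid=np.asarray(doc["grid"], dtype=float),
            mean_spectrum=np.asarray(doc["mean_spectrum"], dtype=float),
            loadings=np.asarray(doc["loadings"], dtype=float),
            explained_variance_fraction=np.asarray(
                doc["explained_variance_fraction"], dtype=float
            ),
            component_names=list(doc["component_names"]),
            component_scores=np.asarray(doc["component_scores"], dtype=float),
            preprocessing=doc.get("preprocessing", {}),
        )


def fit_loading_model(
    pure: SpectraCollection,
    n_components: Optional[int] = None,
    preprocessing: Optional[dict] = None,
) -> LoadingModel:
    """Fit the loading model on pure-component replicate spectra.

    Training spectra must all carry a ``component_label`` and share one grid.
    ``n_components`` defaults to (number of distinct components) - 1, the
    minimum that spans the simplex of c anchor points: 1 PC for binary, 2 for
    ternary, 3 for quaternary mixtures.
    """
    spectra = list(pure)
    if pure.common_grid is None:
        raise GridMismatchError("training spectra must share a common grid")
    unlabeled = [s for s in spectra if not s.component_label]
    if unlabeled:
        s = unlabeled[0]
        raise ValueError(
            f"training spectrum {s.sample_id}:{s.spot_index} lacks a component_label"
        )
    names: list[str] = []
    for s in spectra:
        if s.component_label not in names:
            names.append(s.component_label)
    counts = {n: sum(1 for s in spectra if s.component_label == n) for n in names}
    if len(names) < 2:
        raise ValueError("need >= 2 pure components to fit a loading model")
    if min(counts.values()) < 2:
        few = min(counts, key=counts.get)
        raise ValueError(f"component {few!r} has < 2 replicate spectra")

    if n_components is None:
        n_components = len(names) - 1
    if n_components < 1:
        raise RankError("n_components must be >= 1")
    if n_components >= len(spectra):
        raise RankError(
            f"n_components={n_components} >= number of training spectra ({len(spectra)})"
        )

    X = pure.to_matrix()
    mean = X.mean(axis=0)
    Xc = X - mean
    # deterministic: LAPACK gesdd on a fixed matrix, then a fixed sign rule
    _, svals, vt = np.linalg.svd(Xc, full_matrices=False)
    total_var = float((svals**2).sum())
    if total_var == 0:
        raise ValueError("training spectra are all identical; no variance to model")
    loadings = vt[:n_components].copy()
    for row in loadings:
        j = int(np.argmax(np.abs(row)))
        if row[j] < 0:
            row *= -1
    ev = (svals[:n_components] ** 2) / total_var

    scores = Xc @ loadings.T
    training = pd.DataFrame(
        scores,
        index=pd.MultiIndex.from_tuples(
            [s.key for s in spectra], names=["sample_id", "spot_index"]
        ),
        columns=[f"PC{i+1}" for i in range(n_components)],
    )
    comp_scores = np.vstack(
        [
            scores[[s.component_label == n for s in spectra]].mean(axis=0)
            for n in names
        ]
    )
    return LoadingModel(
        grid=np.asarray(pure.common_grid, dtype=float),
        mean_spectrum=mean,
        loadings=loadings,
        explained_variance_fraction=ev,
        component_names=names,
        component_scores=comp_scores,
        preprocessing=dict(preprocessing or {}),
        training_scores=training,
    )


def project(spectra: SpectraCollection, model: LoadingModel) -> pd.DataFrame:
    """Project spectra onto the loading model; returns a score table.

    The score of spectrum ``S`` is the vector of inner products of
    ``S - mean_spectrum`` with each loading.  Rows are keyed by
    ``(sample_id, spot_index)``; columns are ``PC1..PCn``.
    """
    if spectra.common_grid is None or not np.array_equal(spectra.common_grid, model.grid):
        raise GridMismatchError("spectra are not on the model's grid")
    X = spectra.to_matrix() - model.mean_spectrum
    scores = X @ model.loadings.T
    return pd.DataFrame(
        scores,
        index=pd.MultiIndex.from_tuples(
            [s.key for s in spectra], names=["sample_id", "spot_index"]
        ),
        columns=[f"PC{i+1}" for i in range(model.n_pc)],
    )


def mean_scores(scores: pd.DataFrame, sample_ids: Optional[list[str]] = None) -> pd.DataFrame:
    """Per-sample arithmetic mean (and std, for diagnostics) of spot scores.

    Returns a frame indexed by sample_id with columns ``PCi`` (means) and
    ``PCi_std``.  Averaging replicate spots suppresses hot-spot enhancement
    variability before composition estimation.
    """
    grouped = scores.groupby(level="sample_id", sort=False)
    means = grouped.mean()
    stds = grouped.std(ddof=0).add_suffix("_std")
    out = pd.concat([means, stds], axis=1)
    if sample_ids is not None:
        missing = [s for s in sample_ids if s not in out.index]
        if missing:
            raise SampleLookupError(f"unknown sample_id(s): {missing}")
        out = out.loc[sample_ids]
    return out


def explained_variance_report(model: LoadingModel) -> pd.DataFrame:
    """Per-PC and cumulative explained-variance fractions.

    Warns when the retained PCs explain < 99% of training variance — the
    retention rationale for keeping c-1 components.
    """
    ev = model.explained_variance_fraction
    report = pd.DataFrame(
        {
            "explained_variance_fraction": ev,
            "cumulative": np.cumsum(ev),
        },
        index=[f"PC{i+1}" for i in range(model.n_pc)],
    )
    if report["cumulative"].iloc[-1] < VARIANCE_WARN_THRESHOLD:
        warnings.warn(
            f"retained {model.n_pc} PC(s) explain only "
            f"{report['cumulative'].iloc[-1]:.4f} of variance (< "
            f"{VARIANCE_WARN_THRESHOLD})",
            LowVarianceWarning,
            stacklevel=2,
        )
    return report
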