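"""Composition estimation from PC scores via the n+1-component linear system.

For a mixture with mean score vector x_m and c = n+1 components whose pure
mean scores are x_1 .. x_{n+1}, the composition a solves

    sum_i a_i * k_i * (x_{i,j} - x_{m,j}) = 0   for each retained PC j,
    sum_i a_i = 1,

i.e. the mixture's score is the k-weighted barycentre of the pure-component
scores.  With every k_i = 1 the solution is the *surface* (adsorbed)
composition the spectra directly report; with calibrated adsorption-kinetics
factors k it is the solution-phase composition (see :mod:`sersmix.kinetics`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .exceptions import DegenerateComponentsError, OutOfSimplexWarning, ParameterError
from .pca import LoadingModel

#: Condition number above which the system is declared degenerate.
CONDITION_LIMIT = 1e10


@dataclass
class Composition:
    """Named mole fractions.

    Fractions sum to 1 (enforced to 1e-9 at construction).  Individual
    fractions may fall outside [0, 1] when noise or extrapolation pushes the
    solution off the simplex; such compositions are flagged, not clipped,
    unless clipping is requested explicitly.
    """

    component_names: list[str]
    fractions: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        if len(self.component_names) != self.fractions.size:
            raise ValueError("one fraction per component name required")
        if abs(self.fractions.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"fractions sum to {self.fractions.sum():.12g}, not 1 within 1e-9"
            )

    def __getitem__(self, name: str) -> float:
        return float(self.fractions[self.component_names.index(name)])

    @property
    def in_simplex(self) -> bool:
        return bool(np.all(self.fractions >= -1e-12) and np.all(self.fractions <= 1 + 1e-12))

    def as_percent(self) -> dict[str, float]:
        return {n: float(f) * 100 for n, f in zip(self.component_names, self.fractions)}

    def reorder(self, names: Sequence[str]) -> "Composition":
        idx = [self.component_names.index(n) for n in names]
        return Composition(list(names), self.fractions[idx], dict(self.provenance))

    def clipped(self) -> "Composition":
        """Clip negative fractions at 0 and renormalize (opt-in post-step)."""
        f = np.clip(self.fractions, 0.0, None)
        if f.sum() == 0:
            raise ParameterError("all fractions clipped to zero; cannot renormalize")
        out = Composition(
            list(self.component_names), f / f.sum(), dict(self.provenance)
        )
        out.provenance["clipped"] = True
        return out

    @classmethod
    def from_dict(cls, fractions: dict[str, float], **prov) -> "Composition":
        names = list(fractions)
        vals = np.asarray([fractions[n] for n in names], dtype=float)
        total = vals.sum()
        if not np.isclose(total, 1.0, atol=1e-9):
            vals = vals / total  # accept percent or unnormalized input
        return cls(names, vals, dict(prov))


def solve_general(
    x_m: np.ndarray,
    model: LoadingModel,
    k: Optional[np.ndarray] = None,
    clip: bool = False,
    warn: bool = True,
) -> Composition:
    """Solve the general composition system for one mixture score vector.

    ``x_m`` is the mixture's (usually spot-averaged) score vector with one
    entry per retained PC.  ``k`` holds per-component adsorption-kinetics
    factors; ``None`` means all ones, giving the surface composition.  When
    the model retains more than c-1 PCs the system is solved in the
    least-squares sense with the sum-to-one constraint enforced exactly by
    eliminating the last fraction.
    """
    names = model.component_names
    c = len(names)
    x_m = np.atleast_1d(np.asarray(x_m, dtype=float))
    n_pc = model.n_pc
    if x_m.size != n_pc:
        raise ValueError(f"score vector has {x_m.size} entries; model retains {n_pc} PCs")
    if k is None:
        k = np.ones(c)
    else:
        k = np.asarray(k, dtype=float)
        if k.size != c:
            raise ParameterError(f"need one k per component ({c}), got {k.size}")
        if np.any(k <= 0):
            raise ParameterError(f"kinetics factors must be positive, got {k}")

    # rows j: (x_{i,j} - x_{m,j}) * k_i ; final row: ones
    diff = (model.component_scores - x_m).T  # (n_pc, c)
    A = np.vstack([diff * k, np.ones(c)])
    b = np.zeros(n_pc + 1)
    b[-1] = 1.0

    if n_pc == c - 1:
        cond = np.linalg.cond(A)
        if not np.isfinite(cond) or cond > CONDITION_LIMIT:
            raise DegenerateComponentsError(
                f"composition system is ill-conditioned (cond={cond:.3g} > "
                f"{CONDITION_LIMIT:g}); components {_collinear_pair(model)} have "
                "near-collinear score signatures"
            )
        a = np.linalg.solve(A, b)
    elif n_pc > c - 1:
        # eliminate a_c = 1 - sum(a_1..a_{c-1}); OLS on the PC rows only
        M = diff * k  # (n_pc, c)
        rhs = -M[:, -1]
        Mred = M[:, :-1] - M[:, [-1]]
        if np.linalg.matrix_rank(Mred) < c - 1:
            raise DegenerateComponentsError(
                "overdetermined composition system is rank-deficient; components "
                f"{_collinear_pair(model)} have near-collinear score signatures"
            )
        sol, *_ = np.linalg.lstsq(Mred, rhs, rcond=None)
        a = np.append(sol, 1.0 - sol.sum())
    else:
        raise DegenerateComponentsError(
            f"{n_pc} retained PC(s) cannot determine {c} fractions; retain >= {c - 1}"
        )

    # enforce the sum row exactly against accumulated round-off
    a = a / a.sum()
    comp = Composition(
        list(names),
        a,
        {"k": k.tolist(), "n_pc": n_pc, "preprocessing": dict(model.preprocessing)},
    )
    if warn and not comp.in_simplex:
        warnings.warn(
            f"composition off the simplex: {dict(zip(names, np.round(a, 4)))}",
            OutOfSimplexWarning,
            stacklevel=2,
        )
    if clip:
        comp = comp.clipped()
    return comp


def surface_composition(
    x_m: np.ndarray, model: LoadingModel, clip: bool = False, warn: bool = True
) -> Composition:
    """Adsorbed-phase composition: the general solve with every k_i = 1.

    For a binary model with one retained PC this reduces to linear
    interpolation on PC1: a_1 = (x_m - x_2) / (x_1 - x_2).
    """
    return solve_general(x_m, model, k=None, clip=clip, warn=warn)


def _collinear_pair(model: LoadingModel) -> str:
    """Name the closest pair of component score vectors (for error messages)."""
    S = model.component_scores
    names = model.component_names
    best, pair = np.inf, (names[0], names[-1])
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            d = float(np.linalg.norm(S[i] - S[j]))
            if d < best:
                best, pair = d, (names[i], names[j])
    return f"{pair[0]!r} and {pair[1]!r}"
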