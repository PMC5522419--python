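"""Reading, writing and preprocessing of Raman spectra.

All downstream computation (model fitting, projection, unmixing) assumes
spectra are aligned on a common Raman-shift grid and, by default,
closure-normalized so each spectrum's intensities sum to one.  Closure makes
mixture spectra convex combinations of pure-component spectra regardless of
absolute SERS enhancement, which is the premise of score interpolation.

Two delimited-text dialects are supported:

* **long** — columns ``sample_id, spot_index, shift, intensity`` (optionally
  ``component_label``), one row per measured point;
* **wide** — first column ``shift``, every other column one spectrum with a
  header ``sample_id:spot_index`` or ``sample_id:spot_index:component_label``.

Comma or tab delimiters are auto-detected and ``#`` comment lines ignored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    DegenerateSpectrumError,
    DuplicateRecordError,
    ExtrapolationError,
    FormatError,
    GridMismatchError,
)

logger = logging.getLogger(__name__)

#: Default working grid, 600-1800 cm^-1 in 2 cm^-1 steps (601 points).
#: Covers every band of the four thiol probes used as the reference library.
DEFAULT_GRID = np.arange(600.0, 1800.0 + 1e-9, 2.0)


@dataclass(frozen=True)
class RamanSpectrum:
    """One spot's spectrum: intensity (detector counts, a.u.) on a shift grid (cm^-1).

    ``spot_index`` enumerates replicate acquisition points on one substrate
    sample (typically 8 randomly chosen spots).  ``component_label`` is set
    for pure-component reference spectra and absent for mixtures.
    """

    shift: np.ndarray
    intensity: np.ndarray
    sample_id: str
    spot_index: int = 1
    component_label: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "shift", np.asarray(self.shift, dtype=float))
        object.__setattr__(self, "intensity", np.asarray(self.intensity, dtype=float))
        if self.shift.ndim != 1 or self.intensity.ndim != 1:
            raise FormatError("shift and intensity must be 1-D arrays")
        if self.shift.size != self.intensity.size:
            raise FormatError(
                f"spectrum {self.sample_id}:{self.spot_index}: shift length "
                f"{self.shift.size} != intensity length {self.intensity.size}"
            )
        if self.shift.size < 2:
            raise FormatError(
                f"spectrum {self.sample_id}:{self.spot_index}: needs >= 2 points"
            )
        diffs = np.diff(self.shift)
        if np.any(diffs == 0):
            dup = self.shift[:-1][diffs == 0][0]
            raise DuplicateRecordError(
                f"spectrum {self.sample_id}:{self.spot_index}: duplicate shift {dup:g}"
            )
        if np.any(diffs < 0):
            raise FormatError(
                f"spectrum {self.sample_id}:{self.spot_index}: shift axis not "
                "strictly increasing (sort before constructing)"
            )
        if self.spot_index < 1:
            raise FormatError("spot_index must be >= 1")

    @property
    def key(self) -> tuple[str, int]:
        return (self.sample_id, self.spot_index)

    def with_intensity(self, intensity: np.ndarray) -> "RamanSpectrum":
        return replace(self, intensity=np.asarray(intensity, dtype=float))


@dataclass
class SpectraCollection:
    """An ordered set of spectra, optionally sharing one common shift grid."""

    spectra: list[RamanSpectrum] = field(default_factory=list)
    common_grid: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.common_grid is not None:
            self.common_grid = np.asarray(self.common_grid, dtype=float)
            for s in self.spectra:
                if not np.array_equal(s.shift, self.common_grid):
                    raise GridMismatchError(
                        f"spectrum {s.sample_id}:{s.spot_index} is not on the "
                        "collection's common grid"
                    )

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)

    def sample_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.spectra:
            seen.setdefault(s.sample_id, None)
        return list(seen)

    def select(self, sample_id: str) -> "SpectraCollection":
        sub = [s for s in self.spectra if s.sample_id == sample_id]
        return SpectraCollection(sub, self.common_grid)

    def to_matrix(self) -> np.ndarray:
        """Stack intensities into (n_spectra, n_channels); requires a common grid."""
        if self.common_grid is None:
            raise GridMismatchError("collection has no common grid; resample first")
        return np.vstack([s.intensity for s in self.spectra])

    def map(self, fn) -> "SpectraCollection":
        out = [fn(s) for s in self.spectra]
        grid = self.common_grid
        if grid is not None and out and not np.array_equal(out[0].shift, grid):
            grid = out[0].shift
        return SpectraCollection(out, grid)


# ---------------------------------------------------------------------------
# file I/O


def _read_table(path: Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep=None, engine="python", comment="#")
    except Exception as exc:  # pandas raises several parser error types
        raise FormatError(f"{path}: cannot parse delimited text: {exc}") from exc


def _require_numeric(df: pd.DataFrame, col: str, path: Path) -> np.ndarray:
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = vals.isna() & df[col].notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise FormatError(
            f"{path}: non-numeric value {df[col].iloc[row]!r} in column "
            f"'{col}', data row {row + 1}"
        )
    if vals.isna().any():
        row = int(np.flatnonzero(vals.isna().to_numpy())[0])
        raise FormatError(f"{path}: missing value in column '{col}', data row {row + 1}")
    return vals.to_numpy(dtype=float)


def _sorted_spectrum(
    shift: np.ndarray,
    intensity: np.ndarray,
    sample_id: str,
    spot_index: int,
    component_label: Optional[str],
    origin: str,
) -> RamanSpectrum:
    if np.unique(shift).size != shift.size:
        raise DuplicateRecordError(
            f"{origin}: duplicate shift value for spectrum {sample_id}:{spot_index}"
        )
    if np.any(np.diff(shift) < 0):
        logger.info(
            "%s: spectrum %s:%s has a non-monotone shift column; sorting ascending",
            origin, sample_id, spot_index,
        )
        order = np.argsort(shift, kind="stable")
        shift, intensity = shift[order], intensity[order]
    return RamanSpectrum(shift, intensity, sample_id, spot_index, component_label)


def read_spectra(path: str | Path, dialect: str = "long") -> SpectraCollection:
    """Read a delimited spectra file in the *long* or *wide* dialect.

    Shifts are returned sorted ascending per spectrum (a non-monotone shift
    column is sorted with a logged note).  Malformed numeric fields and
    duplicate ``(sample, spot, shift)`` records raise, never drop silently.
    """
    path = Path(path)
    if dialect not in ("long", "wide"):
        raise ValueError(f"unknown dialect {dialect!r}; use 'long' or 'wide'")
    df = _read_table(path)
    spectra: list[RamanSpectrum] = []

    if dialect == "long":
        required = {"sample_id", "spot_index", "shift", "intensity"}
        missing = required - set(df.columns)
        if missing:
            raise FormatError(f"{path}: long dialect missing columns {sorted(missing)}")
        shift = _require_numeric(df, "shift", path)
        inten = _require_numeric(df, "intensity", path)
        spot = _require_numeric(df, "spot_index", path).astype(int)
        comp = df["component_label"] if "component_label" in df.columns else None
        work = pd.DataFrame(
            {
                "sample_id": df["sample_id"].astype(str),
                "spot_index": spot,
                "shift": shift,
                "intensity": inten,
            }
        )
        dup = work.duplicated(subset=["sample_id", "spot_index", "shift"])
        if dup.any():
            r = work[dup].iloc[0]
            raise DuplicateRecordError(
                f"{path}: duplicate record (sample {r['sample_id']!r}, spot "
                f"{r['spot_index']}, shift {r['shift']:g})"
            )
        if comp is not None:
            work["component_label"] = comp.where(comp.notna(), None)
        for (sid, sp), grp in work.groupby(["sample_id", "spot_index"], sort=False):
            label = None
            if "component_label" in work.columns:
                labels = grp["component_label"].dropna().unique()
                label = str(labels[0]) if len(labels) else None
            spectra.append(
                _sorted_spectrum(
                    grp["shift"].to_numpy(),
                    grp["intensity"].to_numpy(),
                    str(sid),
                    int(sp),
                    label,
                    str(path),
                )
            )
    else:  # wide
        if df.shape[1] < 2:
            raise FormatError(f"{path}: wide dialect needs a shift column plus >= 1 spectrum")
        shift_col = df.columns[0]
        shift = _require_numeric(df, shift_col, path)
        for col in df.columns[1:]:
            parts = str(col).split(":")
            if len(parts) == 2:
                sid, sp = parts
                label = None
            elif len(parts) == 3:
                sid, sp, label = parts
            else:
                raise FormatError(
                    f"{path}: wide header {col!r} is not "
                    "'sample_id:spot_index[:component_label]'"
                )
            try:
                spot = int(sp)
            except ValueError as exc:
                raise FormatError(f"{path}: spot index {sp!r} in header {col!r}") from exc
            inten = _require_numeric(df, col, path)
            spectra.append(
                _sorted_spectrum(shift.copy(), inten, sid, spot, label, str(path))
            )

    grid = None
    if spectra and all(np.array_equal(s.shift, spectra[0].shift) for s in spectra):
        grid = spectra[0].shift
    return SpectraCollection(spectra, grid)


def write_spectra(
    collection: SpectraCollection | Iterable[RamanSpectrum],
    path: str | Path,
    dialect: str = "long",
    delimiter: str = ",",
) -> None:
    """Write spectra as delimited text; numbers carry 12 significant digits."""
    path = Path(path)
    spectra = list(collection)
    fmt = "{:.12g}".format
    if dialect == "long":
        rows = []
        for s in spectra:
            for v, i in zip(s.shift, s.intensity):
                rows.append(
                    (s.sample_id, s.spot_index, fmt(v), fmt(i), s.component_label or "")
                )
        out = pd.DataFrame(
            rows, columns=["sample_id", "spot_index", "shift", "intensity", "component_label"]
        )
        out.to_csv(path, sep=delimiter, index=False)
    elif dialect == "wide":
        if not spectra:
            raise ValueError("nothing to write")
        grid = spectra[0].shift
        for s in spectra:
            if not np.array_equal(s.shift, grid):
                raise GridMismatchError("wide dialect requires a common grid")
        data = {"shift": [fmt(v) for v in grid]}
        for s in spectra:
            head = f"{s.sample_id}:{s.spot_index}"
            if s.component_label:
                head += f":{s.component_label}"
            data[head] = [fmt(v) for v in s.intensity]
        pd.DataFrame(data).to_csv(path, sep=delimiter, index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# preprocessing


def resample_to_grid(s: RamanSpectrum, grid: Sequence[float]) -> RamanSpectrum:
    """Linearly interpolate a spectrum onto ``grid`` (must lie inside its range)."""
    grid = np.asarray(grid, dtype=float)
    if grid.min() < s.shift[0] - 1e-9 or grid.max() > s.shift[-1] + 1e-9:
        raise ExtrapolationError(
            f"grid [{grid.min():g}, {grid.max():g}] extends outside measured "
            f"range [{s.shift[0]:g}, {s.shift[-1]:g}] for {s.sample_id}:{s.spot_index}"
        )
    new_int = np.interp(grid, s.shift, s.intensity)
    return replace(s, shift=grid, intensity=new_int)


def normalize_closure(s: RamanSpectrum) -> RamanSpectrum:
    """Scale intensities to unit total (closure normalization).

    After closure a noiseless mixture spectrum is an exact convex combination
    of the closure-normalized pure spectra, independent of the spot's absolute
    enhancement factor.
    """
    total = float(s.intensity.sum())
    if total <= 0:
        raise DegenerateSpectrumError(
            f"spectrum {s.sample_id}:{s.spot_index}: total intensity {total:g} <= 0"
        )
    return s.with_intensity(s.intensity / total)


def subtract_polynomial_baseline(
    s: RamanSpectrum, degree: int = 2, n_iter: int = 20
) -> RamanSpectrum:
    """Optional baseline hook: iterative polynomial baseline subtraction.

    Fits a degree-``degree`` polynomial, clips the spectrum to the fit, and
    refits, so peaks do not drag the baseline up.  Off by default everywhere;
    provided for spectra with a broad background.
    """
    x = (s.shift - s.shift.mean()) / (np.ptp(s.shift) / 2 or 1.0)
    y = s.intensity.copy()
    base = np.zeros_like(y)
    for _ in range(n_iter):
        coeffs = np.polynomial.polynomial.polyfit(x, y, degree)
        base = np.polynomial.polynomial.polyval(x, coeffs)
        y = np.minimum(y, base)
    return s.with_intensity(s.intensity - base)


def preprocess(
    collection: SpectraCollection,
    grid: Optional[np.ndarray] = None,
    closure: bool = True,
    baseline_degree: Optional[int] = None,
) -> SpectraCollection:
    """Standard pipeline: resample to a common grid, optional baseline, closure."""
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)

    def _one(s: RamanSpectrum) -> RamanSpectrum:
        out = resample_to_grid(s, grid)
        if baseline_degree is not None:
            out = subtract_polynomial_baseline(out, baseline_degree)
        if closure:
            out = normalize_closure(out)
        return out

    return SpectraCollection([_one(s) for s in collection], grid)
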