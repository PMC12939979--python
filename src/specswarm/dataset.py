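"""Data model and CSV I/O for Vis-NIR reflectance spectra and reference targets.

The in-memory currency of the whole package is :class:`SpectralDataset`: a
uniform wavelength grid, an ``n_samples x n_wavelengths`` reflectance matrix,
and a table of per-sample reference values (TVB-N in mg/100 g and CIELAB
L*, a*, b*).  Wavelengths are addressed 0-based internally; every user-facing
artefact reports physical nanometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Reference indicators the package knows about.  TVB-N is a spoilage marker
#: (mg per 100 g); L*, a*, b* are CIELAB colour coordinates (unitless).
INDICATORS = ("tvbn", "L", "a", "b")


# ---------------------------------------------------------------------------
# wavelength grid
# ---------------------------------------------------------------------------

@dataclass(frozen=True, eq=False)
class WavelengthGrid:
    """Inclusive, uniformly spaced wavelength axis in nanometres."""

    start_nm: float
    stop_nm: float
    step_nm: float
    values: np.ndarray = field(repr=False)

    def __len__(self) -> int:
        return self.values.size

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavelengthGrid):
            return NotImplemented
        return (
            self.step_nm == other.step_nm
            and len(self) == len(other)
            and bool(np.array_equal(self.values, other.values))
        )

    def index_of(self, wavelength_nm: float) -> int:
        """Index of the grid point nearest ``wavelength_nm``."""
        return int(np.argmin(np.abs(self.values - wavelength_nm)))


def make_grid(start_nm: float, stop_nm: float, step_nm: float) -> WavelengthGrid:
    """Build the inclusive uniform grid ``start, start+step, ..., stop``.

    The default instrument axis used throughout the package is
    ``make_grid(400, 1800, 4)`` — 351 points.

    Raises
    ------
    ValueError
        If ``stop <= start``, ``step <= 0``, or the range is not divisible by
        the step (the message names the remainder).
    """
    if step_nm <= 0:
        raise ValueError(f"step_nm must be positive, got {step_nm}")
    if stop_nm <= start_nm:
        raise ValueError(f"stop_nm ({stop_nm}) must exceed start_nm ({start_nm})")
    span = stop_nm - start_nm
    n_steps = span / step_nm
    remainder = span - round(n_steps) * step_nm
    if abs(remainder) > 1e-9:
        raise ValueError(
            f"grid range {start_nm}-{stop_nm} nm is not divisible by step "
            f"{step_nm} nm (remainder {remainder:g} nm)"
        )
    n = int(round(n_steps)) + 1
    values = start_nm + step_nm * np.arange(n, dtype=float)
    values[-1] = stop_nm  # exact endpoint, no accumulation error
    return WavelengthGrid(float(start_nm), float(stop_nm), float(step_nm), values)


def grid_from_values(values: Sequence[float]) -> WavelengthGrid:
    """Validate an explicit wavelength axis and wrap it as a grid.

    The axis must be strictly increasing and uniformly spaced.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ValueError("a wavelength grid needs at least two points")
    diffs = np.diff(arr)
    if np.any(diffs <= 0):
        raise ValueError("wavelengths must be strictly increasing")
    step = diffs[0]
    if not np.allclose(diffs, step, rtol=0, atol=1e-6):
        raise ValueError(
            f"non-uniform wavelength spacing: steps range "
            f"{diffs.min():g}-{diffs.max():g} nm"
        )
    return WavelengthGrid(float(arr[0]), float(arr[-1]), float(step), arr)


# ---------------------------------------------------------------------------
# dataset
# ---------------------------------------------------------------------------

@dataclass
class SpectralDataset:
    """Reflectance spectra plus reference targets for one sample collection.

    ``targets`` is a DataFrame indexed by sample id; a sample may lack a value
    for an individual indicator (NaN) — modelling operations drop such rows
    for their own indicator only.
    """

    grid: WavelengthGrid
    reflectance: np.ndarray
    targets: pd.DataFrame
    sample_ids: np.ndarray

    def __post_init__(self) -> None:
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        if self.reflectance.ndim != 2:
            raise ValueError("reflectance must be a 2-D matrix")
        if self.reflectance.shape[1] != len(self.grid):
            raise ValueError(
                f"reflectance has {self.reflectance.shape[1]} columns but the "
                f"grid has {len(self.grid)} wavelengths"
            )
        if np.isnan(self.reflectance).any():
            raise ValueError("reflectance contains missing values")
        if len(self.sample_ids) != self.reflectance.shape[0]:
            raise ValueError("sample_ids length does not match reflectance rows")
        ids, counts = np.unique(self.sample_ids.astype(str), return_counts=True)
        if (counts > 1).any():
            dup = ids[counts > 1][0]
            raise ValueError(f"duplicate sample id {dup!r}")
        if len(self.targets) != self.reflectance.shape[0]:
            raise ValueError("targets row count does not match n_samples")
        if "tvbn" in self.targets.columns:
            tvbn = self.targets["tvbn"].to_numpy(dtype=float)
            if np.any(tvbn[~np.isnan(tvbn)] <= 0):
                raise ValueError("TVB-N values must be positive where present")

    @property
    def n_samples(self) -> int:
        return self.reflectance.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return len(self.grid)

    def rows_with(self, indicator: str) -> np.ndarray:
        """Row indices carrying a finite value for ``indicator``."""
        if indicator not in self.targets.columns:
            raise KeyError(
                f"indicator {indicator!r} absent from targets "
                f"(have {list(self.targets.columns)})"
            )
        y = self.targets[indicator].to_numpy(dtype=float)
        return np.flatnonzero(np.isfinite(y))

    def indicator_values(self, indicator: str) -> np.ndarray:
        """Target vector for ``indicator`` (may contain NaN)."""
        if indicator not in self.targets.columns:
            raise KeyError(f"indicator {indicator!r} absent from targets")
        return self.targets[indicator].to_numpy(dtype=float)

    def subset(self, rows: Iterable[int]) -> "SpectralDataset":
        rows = np.asarray(list(rows), dtype=int)
        return SpectralDataset(
            grid=self.grid,
            reflectance=self.reflectance[rows],
            targets=self.targets.iloc[rows],
            sample_ids=self.sample_ids[rows],
        )


# ---------------------------------------------------------------------------
# selection mask
# ---------------------------------------------------------------------------

@dataclass
class SelectionMask:
    """Boolean wavelength-inclusion vector over a grid."""

    flags: np.ndarray

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags, dtype=bool)
        if self.flags.ndim != 1:
            raise ValueError("mask flags must be a 1-D boolean vector")

    @property
    def n_selected(self) -> int:
        return int(self.flags.sum())

    def indices(self) -> np.ndarray:
        return np.flatnonzero(self.flags)

    def wavelengths(self, grid: WavelengthGrid) -> np.ndarray:
        if len(self.flags) != len(grid):
            raise ValueError("mask length does not match grid length")
        return grid.values[self.flags]

    @classmethod
    def from_indices(cls, indices: Iterable[int], length: int) -> "SelectionMask":
        flags = np.zeros(length, dtype=bool)
        flags[np.asarray(list(indices), dtype=int)] = True
        return cls(flags)

    @classmethod
    def full(cls, length: int) -> "SelectionMask":
        return cls(np.ones(length, dtype=bool))


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def read_spectra_csv(
    spectra_path: str | Path,
    references_path: str | Path | None = None,
    grid: WavelengthGrid | None = None,
) -> SpectralDataset:
    """Read a wide-format spectra CSV (and optional reference CSV).

    The spectra file holds one row per sample: first column the sample id,
    remaining column headers numeric wavelengths in nm
    (``sample_id,400,404,...,1800``).  The reference file shares the sample-id
    column and carries indicator columns (``sample_id,tvbn,L,a,b``); the two
    are joined on id and any id present in only one file is an error naming
    the offenders.

    ``grid`` may be passed to enforce an expected axis; by default the grid is
    inferred from the header and validated for uniform spacing.
    """
    spectra_path = Path(spectra_path)
    if not spectra_path.exists():
        raise FileNotFoundError(f"spectra file not found: {spectra_path}")
    df = pd.read_csv(spectra_path)
    if df.shape[1] < 3:
        raise ValueError("spectra CSV needs a sample-id column and >=2 wavelengths")
    header = list(df.columns[1:])
    try:
        wavelengths = [float(h) for h in header]
    except ValueError as exc:
        bad = next(h for h in header if not _is_number(h))
        raise ValueError(f"non-numeric wavelength header cell {bad!r}") from exc
    inferred = grid_from_values(wavelengths)
    if grid is not None and inferred != grid:
        raise ValueError("spectra header wavelengths do not match the given grid")
    sample_ids = df.iloc[:, 0].astype(str).to_numpy(dtype=object)
    dup_ids, counts = np.unique(sample_ids, return_counts=True)
    if (counts > 1).any():
        raise ValueError(f"duplicate sample id {dup_ids[counts > 1][0]!r}")
    reflectance = df.iloc[:, 1:].to_numpy(dtype=float)

    if references_path is not None:
        references_path = Path(references_path)
        if not references_path.exists():
            raise FileNotFoundError(f"references file not found: {references_path}")
        refs = pd.read_csv(references_path)
        refs = refs.set_index(refs.columns[0])
        refs.index = refs.index.astype(str)
        if refs.index.has_duplicates:
            dup = refs.index[refs.index.duplicated()][0]
            raise ValueError(f"duplicate sample id {dup!r} in references")
        spec_only = sorted(set(sample_ids) - set(refs.index))
        ref_only = sorted(set(refs.index) - set(sample_ids))
        if spec_only or ref_only:
            raise ValueError(
                "sample-id mismatch between spectra and references: "
                f"spectra-only={spec_only}, references-only={ref_only}"
            )
        targets = refs.loc[sample_ids].astype(float)
    else:
        targets = pd.DataFrame(index=pd.Index(sample_ids, name="sample_id"))

    targets.index = pd.Index(sample_ids, name="sample_id")
    return SpectralDataset(
        grid=inferred, reflectance=reflectance, targets=targets,
        sample_ids=sample_ids,
    )


def write_spectra_csv(
    ds: SpectralDataset,
    spectra_path: str | Path,
    references_path: str | Path | None = None,
) -> None:
    """Write a dataset back to the wide spectra CSV (and reference CSV)."""
    cols = [_format_nm(v) for v in ds.grid.values]
    out = pd.DataFrame(ds.reflectance, columns=cols)
    out.insert(0, "sample_id", ds.sample_ids)
    out.to_csv(spectra_path, index=False)
    if references_path is not None:
        ds.targets.to_csv(references_path, index=True, index_label="sample_id")


def write_mask(mask: SelectionMask, grid: WavelengthGrid, path: str | Path) -> None:
    """Write a mask as a two-column CSV ``wavelength_nm,selected``."""
    if len(mask.flags) != len(grid):
        raise ValueError(
            f"mask length {len(mask.flags)} does not match grid length {len(grid)}"
        )
    out = pd.DataFrame(
        {"wavelength_nm": grid.values, "selected": mask.flags.astype(int)}
    )
    out.to_csv(path, index=False)


def read_mask(path: str | Path) -> tuple[SelectionMask, WavelengthGrid]:
    """Inverse of :func:`write_mask`; round-trips losslessly."""
    df = pd.read_csv(path)
    if list(df.columns) != ["wavelength_nm", "selected"]:
        raise ValueError("mask CSV must have columns wavelength_nm,selected")
    grid = grid_from_values(df["wavelength_nm"].to_numpy(dtype=float))
    flags = df["selected"].to_numpy(dtype=int)
    if not np.isin(flags, (0, 1)).all():
        raise ValueError("mask CSV 'selected' column must be 0/1")
    return SelectionMask(flags.astype(bool)), grid


def _format_nm(v: float) -> str:
    return f"{v:g}"


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False
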