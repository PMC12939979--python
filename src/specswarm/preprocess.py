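"""Spectral preprocessing: scatter correction and Savitzky-Golay filtering.

Five single-step transforms are supported next to the raw spectra: SNV and
MSC for additive/multiplicative scatter, SG smoothing, and SG first/second
derivatives.  Only MSC carries fitted state (the calibration-mean reference
spectrum); the reference is frozen on the calibration set and applied to
prediction spectra so no information leaks across the split.

``bake_off`` runs the data-driven method comparison: one full-spectrum
boosted-tree model per method on a shared calibration/prediction split,
ranked by ascending RMSEP.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .dataset import SpectralDataset

#: Canonical method order; doubles as the final tie-break in the bake-off.
METHOD_ORDER = ("RAW", "SG", "SNV", "MSC", "SG1D", "SG2D")

_DERIV = {"RAW": 0, "SG": 0, "SNV": 0, "MSC": 0, "SG1D": 1, "SG2D": 2}


@dataclass(frozen=True)
class PreprocessMethod:
    """One named preprocessing transform with its SG parameters.

    ``window``/``polyorder`` only matter for the SG family; defaults (11, 2)
    are common chemometric practice.
    """

    name: str = "RAW"
    window: int = 11
    polyorder: int = 2

    def __post_init__(self) -> None:
        if self.name not in METHOD_ORDER:
            raise ValueError(
                f"unknown preprocessing method {self.name!r}; "
                f"choose from {METHOD_ORDER}"
            )
        if self.window % 2 == 0:
            raise ValueError(f"SG window must be odd, got {self.window}")
        if self.window <= self.polyorder:
            raise ValueError("SG window must exceed polyorder")
        if self.polyorder < self.deriv:
            raise ValueError("SG polyorder must be >= derivative order")

    @property
    def deriv(self) -> int:
        return _DERIV[self.name]


@dataclass
class FittedPreprocessor:
    """A method plus any state estimated on the calibration set."""

    method: PreprocessMethod
    reference_spectrum: np.ndarray | None = None

    def __post_init__(self) -> None:
        has_ref = self.reference_spectrum is not None
        if (self.method.name == "MSC") != has_ref:
            raise ValueError("reference spectrum present iff method is MSC")


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def snv(spectra: np.ndarray) -> np.ndarray:
    """Standard normal variate: centre and scale each spectrum (ddof=1).

    Output rows have mean 0 and sample standard deviation 1.  A constant row
    has no defined SNV transform and raises, naming the sample.
    """
    X = np.asarray(spectra, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("snv expects a matrix with >=2 points per row")
    sd = X.std(axis=1, ddof=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(f"constant spectrum (zero variance) at row {bad[0]}")
    return (X - X.mean(axis=1, keepdims=True)) / sd[:, None]


def msc_fit(calibration: np.ndarray) -> FittedPreprocessor:
    """Fit MSC: the reference is the columnwise mean calibration spectrum."""
    X = np.asarray(calibration, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("MSC needs >=2 calibration spectra to form a reference")
    return FittedPreprocessor(
        method=PreprocessMethod("MSC"), reference_spectrum=X.mean(axis=0)
    )


def msc_apply(fp: FittedPreprocessor, spectra: np.ndarray) -> np.ndarray:
    """Apply MSC: regress each row on the reference, return (row - a) / b."""
    if fp.method.name != "MSC" or fp.reference_spectrum is None:
        raise ValueError("msc_apply requires a preprocessor fitted by msc_fit")
    X = np.asarray(spectra, dtype=float)
    ref = fp.reference_spectrum
    if X.shape[1] != ref.size:
        raise ValueError("spectrum length does not match MSC reference")
    ref_c = ref - ref.mean()
    denom = float(ref_c @ ref_c)
    slope = (X - X.mean(axis=1, keepdims=True)) @ ref_c / denom
    tiny = np.flatnonzero(np.abs(slope) < 1e-12)
    if tiny.size:
        raise ValueError(
            f"degenerate MSC regression (|slope| < 1e-12) at row {tiny[0]}"
        )
    intercept = X.mean(axis=1) - slope * ref.mean()
    return (X - intercept[:, None]) / slope[:, None]


def savitzky_golay(
    spectra: np.ndarray,
    window: int = 11,
    polyorder: int = 2,
    deriv: int = 0,
    step_nm: float = 1.0,
) -> np.ndarray:
    """Rowwise Savitzky-Golay filtering; output length equals input length.

    Derivatives are reported per physical nm (scaled by ``step_nm**deriv``),
    matching how band positions are interpreted.  Edges are handled by
    fitting the local polynomial to the terminal windows, which keeps the
    filter exact on polynomial rows of degree <= ``polyorder`` everywhere.
    """
    X = np.asarray(spectra, dtype=float)
    if window % 2 == 0:
        raise ValueError(f"SG window must be odd, got {window}")
    if not (window > polyorder >= deriv):
        raise ValueError("require window > polyorder >= deriv")
    if X.shape[-1] < window:
        raise ValueError(
            f"SG window {window} exceeds spectrum length {X.shape[-1]}"
        )
    return savgol_filter(
        X, window_length=window, polyorder=polyorder, deriv=deriv,
        delta=step_nm, axis=-1, mode="interp",
    )


def fit_preprocessor(
    method: PreprocessMethod, calibration: np.ndarray
) -> FittedPreprocessor:
    """Estimate any fitted state for ``method`` on calibration spectra."""
    if method.name == "MSC":
        fp = msc_fit(calibration)
        return FittedPreprocessor(method=method, reference_spectrum=fp.reference_spectrum)
    return FittedPreprocessor(method=method)


def apply_preprocessor(
    fp: FittedPreprocessor, spectra: np.ndarray, step_nm: float = 1.0
) -> np.ndarray:
    """Apply a fitted preprocessor to a spectra matrix."""
    name = fp.method.name
    if name == "RAW":
        return np.asarray(spectra, dtype=float).copy()
    if name == "SNV":
        return snv(spectra)
    if name == "MSC":
        return msc_apply(fp, spectra)
    return savitzky_golay(
        spectra, fp.method.window, fp.method.polyorder, fp.method.deriv, step_nm
    )


# ---------------------------------------------------------------------------
# method bake-off
# ---------------------------------------------------------------------------

def bake_off(
    ds: SpectralDataset,
    indicator: str,
    methods: Sequence[PreprocessMethod],
    split,
    model_cfg: dict | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Rank preprocessing methods by full-spectrum prediction error.

    For each method one boosted-tree model is fitted on the (preprocessed)
    calibration spectra and evaluated on the prediction spectra; the split is
    computed once on raw spectra and reused so the comparison isolates the
    transform.  Returns a DataFrame sorted by ascending RMSEP, ties broken by
    higher R2p and finally by :data:`METHOD_ORDER`.
    """
    from .modeling import fit_fixed_model, evaluate  # local import, avoids cycle

    if indicator not in ds.targets.columns:
        raise KeyError(f"indicator {indicator!r} absent from targets")
    y = ds.indicator_values(indicator)
    cal, pred = np.asarray(split.calibration_idx), np.asarray(split.prediction_idx)
    cal = cal[np.isfinite(y[cal])]
    pred = pred[np.isfinite(y[pred])]

    rows = []
    for method in methods:
        fp = fit_preprocessor(method, ds.reflectance[cal])
        Xc = apply_preprocessor(fp, ds.reflectance[cal], ds.grid.step_nm)
        Xp = apply_preprocessor(fp, ds.reflectance[pred], ds.grid.step_nm)
        model = fit_fixed_model(Xc, y[cal], model_cfg, seed=seed)
        report = evaluate(model, Xc, y[cal], Xp, y[pred])
        rows.append(
            {
                "method": method.name,
                "r2_pred": report.r2_pred,
                "rmse_pred": report.rmse_pred,
            }
        )
    table = pd.DataFrame(rows)
    order = {name: i for i, name in enumerate(METHOD_ORDER)}
    table["_ord"] = table["method"].map(order)
    table = table.sort_values(
        by=["rmse_pred", "r2_pred", "_ord"], ascending=[True, False, True],
        kind="stable",
    ).drop(columns="_ord")
    return table.reset_index(drop=True)
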