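"""Synthetic Vis-NIR spectra with planted informative absorption bands.

The generator emulates the structure of reflectance spectra of stored meat:
a gentle linear baseline minus Gaussian absorption bands whose per-sample
amplitudes vary, with per-spectrum multiplicative/additive scatter and
instrument noise.  The response (a TVB-N-like spoilage indicator by default)
is driven by the summed amplitudes of a *known* subset of bands, rescaled to
a realistic reference range — so selectors and explainers can be scored
against planted ground truth that real spectra never reveal.

Default conditions: 420 samples on a 400-1800 nm grid at 4 nm (351 points);
five informative bands at 576, 728, 1020, 1236 and 1450 nm (myoglobin and
C-H/O-H/N-H overtone regions); TVB-N range 6.65-66.05 mg/100 g.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .dataset import SpectralDataset, WavelengthGrid, make_grid

#: (center nm, width nm, base amplitude) of the default absorption bands.
DEFAULT_BANDS: tuple[tuple[float, float, float], ...] = (
    (440.0, 18.0, 0.10),
    (576.0, 12.0, 0.16),
    (728.0, 14.0, 0.14),
    (912.0, 22.0, 0.08),
    (1020.0, 16.0, 0.12),
    (1236.0, 12.0, 0.18),
    (1450.0, 20.0, 0.20),
    (1592.0, 30.0, 0.07),
)

#: Indices into DEFAULT_BANDS that drive the response.
DEFAULT_INFORMATIVE = (1, 2, 4, 5, 6)


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of one synthetic data draw."""

    n_samples: int = 420
    grid: WavelengthGrid = field(default_factory=lambda: make_grid(400, 1800, 4))
    bands: tuple[tuple[float, float, float], ...] = DEFAULT_BANDS
    informative_idx: tuple[int, ...] = DEFAULT_INFORMATIVE
    response: str = "linear"            # or "saturating"
    noise_sd: float = 0.005             # reflectance units
    scatter_slope_sd: float = 0.05
    scatter_offset_sd: float = 0.02
    target_range: tuple[float, float] = (6.65, 66.05)   # TVB-N mg/100 g
    target_noise_frac: float = 0.02     # response noise SD as share of range
    indicator: str = "tvbn"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.informative_idx:
            raise ValueError("informative_idx must be non-empty")
        for idx in self.informative_idx:
            if not (0 <= idx < len(self.bands)):
                raise ValueError(f"informative band index {idx} out of range")
        for center, width, amp in self.bands:
            if not (self.grid.start_nm <= center <= self.grid.stop_nm):
                raise ValueError(
                    f"band center {center} nm outside grid "
                    f"{self.grid.start_nm}-{self.grid.stop_nm} nm"
                )
            if width <= 0 or amp <= 0:
                raise ValueError("band widths and amplitudes must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        lo, hi = self.target_range
        if not hi > lo:
            raise ValueError("target_range must be non-degenerate (min < max)")
        if self.response not in ("linear", "saturating"):
            raise ValueError("response must be 'linear' or 'saturating'")


@dataclass
class GroundTruth:
    """The evaluation key: which wavelengths actually drive the response."""

    informative_wavelengths: np.ndarray
    latent_amplitudes: np.ndarray       # (n_samples, n_bands)
    band_centers: np.ndarray
    informative_idx: np.ndarray


def _baseline(grid: WavelengthGrid) -> np.ndarray:
    """Gentle linear reflectance ramp, 0.90 down to 0.65 across the grid."""
    frac = (grid.values - grid.start_nm) / (grid.stop_nm - grid.start_nm)
    return 0.90 - 0.25 * frac


def _band_profiles(spec: SyntheticSpec) -> np.ndarray:
    """(n_bands, n_wavelengths) unit-amplitude Gaussian absorption shapes."""
    lam = spec.grid.values[None, :]
    centers = np.array([b[0] for b in spec.bands])[:, None]
    widths = np.array([b[1] for b in spec.bands])[:, None]
    return np.exp(-((lam - centers) ** 2) / (2.0 * widths**2))


def _response_from_amplitudes(
    spec: SyntheticSpec, amplitudes: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Map summed informative amplitudes to the target range (+ noise).

    The affine map uses the *theoretical* amplitude bounds (0.5x to 1.5x the
    base amplitudes), so its image is exactly ``target_range`` regardless of
    the particular draw.  Drifted amplitudes (storage series) extrapolate
    the same monotone map beyond the range.
    """
    info = list(spec.informative_idx)
    base = np.array([spec.bands[i][2] for i in info])
    s = amplitudes[:, info].sum(axis=1)
    s_min, s_max = 0.5 * base.sum(), 1.5 * base.sum()
    u = (s - s_min) / (s_max - s_min)
    if spec.response == "saturating":
        u = (1.0 - np.exp(-3.0 * u)) / (1.0 - np.exp(-3.0))
    lo, hi = spec.target_range
    y = lo + (hi - lo) * u
    if spec.target_noise_frac > 0:
        y = y + rng.normal(0.0, spec.target_noise_frac * (hi - lo), size=y.size)
    return y


def generate(spec: SyntheticSpec) -> tuple[SpectralDataset, GroundTruth]:
    """Draw one dataset.  Deterministic under ``spec.seed``."""
    rng = np.random.default_rng([7, int(spec.seed)])
    n = spec.n_samples
    n_bands = len(spec.bands)
    base_amp = np.array([b[2] for b in spec.bands])
    amplitudes = rng.uniform(0.5, 1.5, size=(n, n_bands)) * base_amp

    profiles = _band_profiles(spec)
    reflectance = _baseline(spec.grid)[None, :] - amplitudes @ profiles
    y = _response_from_amplitudes(spec, amplitudes, rng)

    if spec.scatter_slope_sd > 0 or spec.scatter_offset_sd > 0:
        slope = rng.normal(1.0, spec.scatter_slope_sd, size=(n, 1))
        offset = rng.normal(0.0, spec.scatter_offset_sd, size=(n, 1))
        reflectance = slope * reflectance + offset
    if spec.noise_sd > 0:
        reflectance = reflectance + rng.normal(0.0, spec.noise_sd, reflectance.shape)

    sample_ids = np.array([f"S{i + 1:04d}" for i in range(n)], dtype=object)
    targets = pd.DataFrame(
        {spec.indicator: y}, index=pd.Index(sample_ids, name="sample_id")
    )
    ds = SpectralDataset(
        grid=spec.grid, reflectance=reflectance, targets=targets,
        sample_ids=sample_ids,
    )
    centers = np.array([b[0] for b in spec.bands])
    truth = GroundTruth(
        informative_wavelengths=centers[list(spec.informative_idx)],
        latent_amplitudes=amplitudes,
        band_centers=centers,
        informative_idx=np.asarray(spec.informative_idx, dtype=int),
    )
    return ds, truth


def storage_series(
    spec: SyntheticSpec,
    days: Sequence[float],
    drift_per_day: float,
) -> tuple[SpectralDataset, GroundTruth]:
    """Storage-time series: informative amplitudes drift with storage day.

    Samples are distributed as evenly as possible across ``days`` (earlier
    days take the remainder); the amplitude of every informative band scales
    by ``1 + drift_per_day * day``, so the TVB-N-like response increases with
    storage under positive drift.  Day labels are attached as a ``day``
    column in the targets.
    """
    days = list(days)
    if any(b < a for a, b in zip(days, days[1:])):
        raise ValueError("days must be non-decreasing")
    scale_min = min(1.0 + drift_per_day * d for d in days)
    if scale_min <= 0:
        raise ValueError(
            "drift would drive informative amplitudes non-positive "
            f"(1 + drift*day = {scale_min:g})"
        )
    rng = np.random.default_rng([11, int(spec.seed)])
    n = spec.n_samples
    counts = np.full(len(days), n // len(days))
    counts[: n % len(days)] += 1
    day_of_sample = np.repeat(days, counts)

    n_bands = len(spec.bands)
    base_amp = np.array([b[2] for b in spec.bands])
    amplitudes = rng.uniform(0.5, 1.5, size=(n, n_bands)) * base_amp
    drift = 1.0 + drift_per_day * day_of_sample
    for idx in spec.informative_idx:
        amplitudes[:, idx] *= drift

    profiles = _band_profiles(spec)
    reflectance = _baseline(spec.grid)[None, :] - amplitudes @ profiles
    # the affine response map keeps the theoretical 0.5-1.5 bounds; drifted
    # amplitudes can exceed them, in which case the target saturates at the
    # range edge exactly as a bounded chemical indicator would
    y = _response_from_amplitudes(spec, amplitudes, rng)

    if spec.scatter_slope_sd > 0 or spec.scatter_offset_sd > 0:
        slope = rng.normal(1.0, spec.scatter_slope_sd, size=(n, 1))
        offset = rng.normal(0.0, spec.scatter_offset_sd, size=(n, 1))
        reflectance = slope * reflectance + offset
    if spec.noise_sd > 0:
        reflectance = reflectance + rng.normal(0.0, spec.noise_sd, reflectance.shape)

    sample_ids = np.array([f"S{i + 1:04d}" for i in range(n)], dtype=object)
    targets = pd.DataFrame(
        {spec.indicator: y, "day": day_of_sample},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    ds = SpectralDataset(
        grid=spec.grid, reflectance=reflectance, targets=targets,
        sample_ids=sample_ids,
    )
    centers = np.array([b[0] for b in spec.bands])
    truth = GroundTruth(
        informative_wavelengths=centers[list(spec.informative_idx)],
        latent_amplitudes=amplitudes,
        band_centers=centers,
        informative_idx=np.asarray(spec.informative_idx, dtype=int),
    )
    return ds, truth


def small_planted_problem(
    n_samples: int = 60,
    n_wavelengths: int = 12,
    n_informative: int = 3,
    seed: int = 0,
    noise_sd: float = 0.01,
    target_noise_frac: float = 0.02,
) -> tuple[SpectralDataset, GroundTruth]:
    """A compact planted problem for selector benchmarking and enumeration.

    Narrow (one-grid-step) bands on a short grid, with reflectance noise
    above the cross-band leakage, keep the off-band columns genuinely
    uninformative at small p.
    """
    grid = make_grid(400, 400 + 4 * (n_wavelengths - 1), 4)
    step = max(1, n_wavelengths // n_informative)
    centers = [float(grid.values[(i * step + 1) % n_wavelengths])
               for i in range(n_informative)]
    # sub-grid-step band width: adjacent columns carry <1% of a band's
    # signal, so the planted columns are not substitutable by neighbours
    bands = tuple((c, 1.2, 0.2) for c in sorted(centers))
    spec = SyntheticSpec(
        n_samples=n_samples,
        grid=grid,
        bands=bands,
        informative_idx=tuple(range(n_informative)),
        noise_sd=noise_sd,
        scatter_slope_sd=0.0,
        scatter_offset_sd=0.0,
        target_noise_frac=target_noise_frac,
        seed=seed,
    )
    return generate(spec)
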