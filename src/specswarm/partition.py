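"""SPXY calibration/prediction sample-set partitioning.

SPXY extends Kennard-Stone max-min selection to a joint metric over spectra
and the response: pairwise Euclidean distances on X and on y are each
normalised by their maximum and summed, so both spaces contribute equally.
Selection is fully deterministic: the seed pair is the globally most distant
pair, then the sample farthest (in min-distance) from the chosen set is added
until the calibration quota is met.  Ties break toward the lowest index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform


@dataclass
class PartitionResult:
    """Calibration indices (in selection order) and the remaining prediction set."""

    calibration_idx: np.ndarray
    prediction_idx: np.ndarray
    ratio: float

    def __post_init__(self) -> None:
        self.calibration_idx = np.asarray(self.calibration_idx, dtype=int)
        self.prediction_idx = np.asarray(self.prediction_idx, dtype=int)
        overlap = np.intersect1d(self.calibration_idx, self.prediction_idx)
        if overlap.size:
            raise ValueError("calibration and prediction sets overlap")


def spxy_split(X: np.ndarray, y: np.ndarray, ratio: float = 0.75) -> PartitionResult:
    """Split samples into calibration/prediction sets by the SPXY rule.

    Parameters
    ----------
    X : (n, p) spectra matrix (raw spectra by convention — the split is made
        before preprocessing so every method comparison shares it).
    y : (n,) response for the indicator being modelled.
    ratio : calibration share; 0.75 reproduces a 3:1 split
        (420 samples -> 315 calibration / 105 prediction).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 samples to split, got {n}")
    if y.size != n:
        raise ValueError("X and y disagree on sample count")
    if not np.isfinite(y).all():
        raise ValueError("y must be finite")
    if not (0.0 < ratio < 1.0):
        raise ValueError(f"ratio must be in (0, 1), got {ratio}")
    n_cal = int(round(n * ratio))
    if n_cal < 2:
        raise ValueError(f"calibration share {ratio} yields fewer than 2 samples")
    if n_cal >= n:
        raise ValueError(f"calibration share {ratio} leaves an empty prediction set")

    dx = squareform(pdist(X, metric="euclidean"))
    dy = np.abs(y[:, None] - y[None, :])
    dx_max, dy_max = dx.max(), dy.max()
    if dx_max == 0.0 and dy_max == 0.0:
        raise ValueError("all samples identical in X and y; SPXY is undefined")
    d = np.zeros_like(dx)
    if dx_max > 0:
        d += dx / dx_max
    if dy_max > 0:
        d += dy / dy_max

    # seed with the global max-distance pair (lowest-index pair on ties)
    flat = np.argmax(d)  # argmax scans row-major -> lowest (i, j) wins ties
    i, j = divmod(int(flat), n)
    selected = [min(i, j), max(i, j)]
    chosen = np.zeros(n, dtype=bool)
    chosen[selected] = True
    # min distance from each unchosen sample to the chosen set
    min_d = np.minimum(d[selected[0]], d[selected[1]])

    while len(selected) < n_cal:
        min_d_masked = np.where(chosen, -np.inf, min_d)
        nxt = int(np.argmax(min_d_masked))  # argmax -> lowest index on ties
        selected.append(nxt)
        chosen[nxt] = True
        min_d = np.minimum(min_d, d[nxt])

    prediction = np.flatnonzero(~chosen)
    return PartitionResult(
        calibration_idx=np.asarray(selected), prediction_idx=prediction, ratio=ratio
    )
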