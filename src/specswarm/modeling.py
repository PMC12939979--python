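"""Final boosted-tree regression with grid search, and evaluation metrics.

The reported model is an XGBoost regressor whose main hyperparameters
(number of trees, learning rate, tree depth) are grid-searched by 3-fold CV
RMSE inside fixed boundary ranges (n_estimators 100-500, learning_rate
0.01-0.3, max_depth 3-8; gamma = 0, reg_lambda = 0, reg_alpha = 1 held
fixed).  Metrics follow the standard chemometric report: R2 and RMSE on the
calibration ("correction") and prediction sets, plus the relative prediction
deviation RPD = SD(prediction-set reference values) / RMSEP.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
import numpy as np
import xgboost as xgb

# immutable regularisation settings of the reported model
FIXED_PARAMS = {"gamma": 0.0, "reg_lambda": 0.0, "reg_alpha": 1.0}

_BOUNDS = {
    "n_estimators": (100, 500),
    "learning_rate": (0.01, 0.3),
    "max_depth": (3, 8),
}


@dataclass(frozen=True)
class HyperGrid:
    """Grid-search candidate sets, validated against the boundary ranges."""

    n_estimators: tuple[int, ...] = (100, 200, 300, 400, 500)
    learning_rate: tuple[float, ...] = (0.01, 0.05, 0.1, 0.2, 0.3)
    max_depth: tuple[int, ...] = (3, 4, 5, 6, 7, 8)

    def __post_init__(self) -> None:
        for name in ("n_estimators", "learning_rate", "max_depth"):
            values = getattr(self, name)
            object.__setattr__(self, name, tuple(values))
            lo, hi = _BOUNDS[name]
            for v in getattr(self, name):
                if not (lo <= v <= hi):
                    raise ValueError(
                        f"{name}={v} outside the allowed range [{lo}, {hi}]"
                    )
            if not getattr(self, name):
                raise ValueError(f"{name} candidate set is empty")

    def points(self):
        """Candidate combinations in deterministic tie-break order."""
        for n_est, depth, lr in itertools.product(
            sorted(self.n_estimators), sorted(self.max_depth),
            sorted(self.learning_rate),
        ):
            yield {"n_estimators": n_est, "max_depth": depth, "learning_rate": lr}


@dataclass
class ModelReport:
    """Calibration/prediction metrics for one fitted model."""

    r2_cal: float
    rmse_cal: float
    r2_pred: float
    rmse_pred: float
    rpd: float
    best_params: dict = field(default_factory=dict)
    n_features: int = 0

    def __post_init__(self) -> None:
        if self.rmse_cal < 0 or self.rmse_pred < 0:
            raise ValueError("RMSE must be non-negative")
        if self.rpd <= 0:
            raise ValueError("RPD must be positive")
        if self.r2_cal > 1 or self.r2_pred > 1:
            raise ValueError("R2 cannot exceed 1")

    def to_dict(self) -> dict:
        return {
            "R2c": self.r2_cal,
            "RMSEC": self.rmse_cal,
            "R2p": self.r2_pred,
            "RMSEP": self.rmse_pred,
            "RPD": self.rpd,
            "best_params": dict(self.best_params),
            "n_features": self.n_features,
        }


class BoostedTreeModel:
    """Thin deterministic wrapper over a trained XGBoost booster."""

    def __init__(self, booster: xgb.Booster, params: dict) -> None:
        self.booster = booster
        self.params = dict(params)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.ascontiguousarray(np.asarray(X, dtype=np.float32))
        return np.asarray(self.booster.inplace_predict(X), dtype=float)

    def get_booster(self) -> xgb.Booster:
        return self.booster


def _train_params(point: dict, seed: int, max_bin: int) -> dict:
    return {
        "max_depth": int(point["max_depth"]),
        "eta": float(point["learning_rate"]),
        "objective": "reg:squarederror",
        "tree_method": "hist",
        "max_bin": int(max_bin),
        "nthread": 1,
        "seed": int(seed) % (2**31),
        "verbosity": 0,
        **FIXED_PARAMS,
    }


def fit_fixed_model(
    X: np.ndarray, y: np.ndarray, model_cfg: dict | None = None, seed: int = 0
) -> BoostedTreeModel:
    """Train one boosted-tree model at a single (non-searched) grid point."""
    cfg = {"n_estimators": 300, "learning_rate": 0.1, "max_depth": 3,
           "max_bin": 256}
    if model_cfg:
        cfg.update(model_cfg)
    params = _train_params(cfg, seed, cfg["max_bin"])
    dtrain = xgb.DMatrix(np.asarray(X, dtype=np.float32), label=np.asarray(y, float),
                         nthread=1)
    booster = xgb.train(params, dtrain, num_boost_round=int(cfg["n_estimators"]))
    return BoostedTreeModel(booster, cfg)


def grid_search_fit(
    X_cal: np.ndarray,
    y_cal: np.ndarray,
    grid: HyperGrid | None = None,
    cv_folds: int = 3,
    seed: int = 0,
    max_bin: int = 256,
) -> tuple[BoostedTreeModel, dict]:
    """Exhaustive grid search by k-fold CV RMSE, then refit on all of X_cal.

    Ties between grid points resolve toward smaller ``n_estimators``, then
    smaller ``max_depth``, then smaller ``learning_rate`` (the enumeration
    order of :meth:`HyperGrid.points` with strict improvement makes this
    automatic).  The refitted model carries the fixed regularisation
    settings (gamma 0, reg_lambda 0, reg_alpha 1).
    """
    grid = grid or HyperGrid()
    X_cal = np.asarray(X_cal, dtype=np.float32)
    y_cal = np.asarray(y_cal, dtype=float).ravel()
    n = X_cal.shape[0]
    rng = np.random.default_rng([23, int(seed)])
    perm = rng.permutation(n)
    folds = np.array_split(perm, cv_folds)
    train_sets = [
        np.concatenate([f for j, f in enumerate(folds) if j != i])
        for i in range(cv_folds)
    ]

    best_rmse, best_point = math.inf, None
    for point in grid.points():
        params = _train_params(point, seed, max_bin)
        sq = 0.0
        for test, train in zip(folds, train_sets):
            dtrain = xgb.DMatrix(X_cal[train], label=y_cal[train], nthread=1)
            booster = xgb.train(params, dtrain,
                                num_boost_round=int(point["n_estimators"]))
            pred = booster.inplace_predict(X_cal[test])
            sq += float(np.sum((y_cal[test] - pred) ** 2))
        rmse = math.sqrt(sq / n)
        if rmse < best_rmse:
            best_rmse, best_point = rmse, point

    params = _train_params(best_point, seed, max_bin)
    dtrain = xgb.DMatrix(X_cal, label=y_cal, nthread=1)
    booster = xgb.train(params, dtrain,
                        num_boost_round=int(best_point["n_estimators"]))
    model = BoostedTreeModel(booster, {**best_point, "cv_rmse": best_rmse})
    return model, dict(best_point)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def _r2(y: np.ndarray, pred: np.ndarray) -> float:
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("constant reference values: R2 undefined (SS_tot = 0)")
    return 1.0 - float(np.sum((y - pred) ** 2)) / ss_tot


def _rmse(y: np.ndarray, pred: np.ndarray) -> float:
    return float(np.sqrt(np.mean((y - pred) ** 2)))


def evaluate(
    model,
    X_cal: np.ndarray,
    y_cal: np.ndarray,
    X_pred: np.ndarray,
    y_pred: np.ndarray,
    n_features: int | None = None,
    best_params: dict | None = None,
) -> ModelReport:
    """Score a fitted model on calibration and prediction sets.

    RPD uses the sample SD (ddof=1) of the prediction set's reference values
    over RMSEP.  A zero RMSEP (perfect predictions) makes RPD undefined and
    raises.
    """
    y_cal = np.asarray(y_cal, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    pc = np.asarray(model.predict(X_cal), dtype=float).ravel()
    pp = np.asarray(model.predict(X_pred), dtype=float).ravel()
    rmse_pred = _rmse(y_pred, pp)
    if rmse_pred == 0.0:
        raise ZeroDivisionError("RMSEP is zero: RPD undefined for perfect predictions")
    rpd = float(np.std(y_pred, ddof=1)) / rmse_pred
    return ModelReport(
        r2_cal=_r2(y_cal, pc),
        rmse_cal=_rmse(y_cal, pc),
        r2_pred=_r2(y_pred, pp),
        rmse_pred=rmse_pred,
        rpd=rpd,
        best_params=best_params or {},
        n_features=(
            n_features if n_features is not None
            else (X_cal.shape[1] if hasattr(X_cal, "shape") else 0)
        ),
    )


def relative_change(baseline: float, improved: float, kind: str = "increase") -> float:
    """Percent change between two reported metrics, to one decimal.

    ``kind='increase'`` reports 100 (improved - baseline) / baseline (e.g. an
    R2p gain); ``kind='reduction'`` reports 100 (baseline - improved) /
    baseline (e.g. an RMSEP drop).
    """
    if baseline == 0:
        raise ZeroDivisionError("relative change undefined for zero baseline")
    if kind == "increase":
        pct = 100.0 * (improved - baseline) / baseline
    elif kind == "reduction":
        pct = 100.0 * (baseline - improved) / baseline
    else:
        raise ValueError("kind must be 'increase' or 'reduction'")
    return round(pct, 1)
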