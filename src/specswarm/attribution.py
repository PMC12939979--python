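"""Shapley-value attribution for boosted-tree ensembles on the prediction set.

The explainer computes *interventional* Shapley values: the value of a
feature coalition S at a sample x is the mean model output over a background
set when features in S take x's values and the rest take the background
row's values.  For a decision tree this game is, per leaf, a unanimity-style
game determined by which path constraints x and the background row each
satisfy, so the Shapley value has a closed form per (leaf, background row):

* let A be the path features whose constraints only x satisfies and B those
  only the background row satisfies (a = |A|, b = |B|); if some path feature
  is satisfied by neither, the leaf contributes nothing;
* each feature in A receives ``leaf_value * (a-1)! b! / (a+b)!`` and each
  feature in B receives ``-leaf_value * a! (b-1)! / (a+b)!``.

Averaging over background rows and summing over leaves and trees yields
attributions that satisfy local accuracy exactly (base value + attributions
= model output) and give exactly zero to features no tree uses.  The
``exact_shapley`` enumeration oracle verifies the same game by brute force
for p <= 12.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import xgboost as xgb


@dataclass
class AttributionMatrix:
    """Per-sample, per-feature Shapley values in target units."""

    values: np.ndarray            # (n_samples, n_features)
    base_value: float             # expected model output over the background
    feature_labels: np.ndarray    # wavelengths in nm (or column labels)
    predictions: np.ndarray       # model output per sample (target units)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.predictions = np.asarray(self.predictions, dtype=float)
        self.feature_labels = np.asarray(self.feature_labels)
        if self.values.shape != (self.predictions.size, self.feature_labels.size):
            raise ValueError("attribution matrix shape mismatch")

    def local_accuracy_error(self) -> float:
        """Max |base + sum(attributions) - prediction| over samples."""
        recon = self.base_value + self.values.sum(axis=1)
        return float(np.max(np.abs(recon - self.predictions)))


# ---------------------------------------------------------------------------
# tree extraction
# ---------------------------------------------------------------------------

class _Leaf:
    __slots__ = ("value", "features", "lo", "hi")

    def __init__(self, value, features, lo, hi):
        self.value = value
        self.features = np.asarray(features, dtype=int)
        self.lo = np.asarray(lo, dtype=np.float32)
        self.hi = np.asarray(hi, dtype=np.float32)


def _as_booster(model) -> xgb.Booster:
    if isinstance(model, xgb.Booster):
        return model
    get = getattr(model, "get_booster", None)
    if get is not None:
        booster = get()
        if isinstance(booster, xgb.Booster):
            return booster
    raise TypeError(
        "tree_shapley requires an XGBoost tree ensemble "
        f"(Booster or wrapper), got {type(model).__name__}"
    )


def _feature_index(name: str, feature_names) -> int:
    if feature_names:
        return feature_names.index(name)
    return int(name.lstrip("f"))


def _collect_leaves(node: dict, bounds: dict, leaves: list, feature_names) -> None:
    if "leaf" in node:
        feats = sorted(bounds)
        leaves.append(
            _Leaf(
                float(node["leaf"]),
                feats,
                [bounds[f][0] for f in feats],
                [bounds[f][1] for f in feats],
            )
        )
        return
    f = _feature_index(node["split"], feature_names)
    t = np.float32(node["split_condition"])
    lo, hi = bounds.get(f, (np.float32(-np.inf), np.float32(np.inf)))
    children = {c["nodeid"]: c for c in node["children"]}
    # yes branch: x < t  ->  tighten the upper bound
    _collect_leaves(children[node["yes"]], {**bounds, f: (lo, min(hi, t))},
                    leaves, feature_names)
    # no branch: x >= t  ->  tighten the lower bound
    _collect_leaves(children[node["no"]], {**bounds, f: (max(lo, t), hi)},
                    leaves, feature_names)


def _parse_ensemble(booster: xgb.Booster) -> tuple[list[_Leaf], float]:
    leaves: list[_Leaf] = []
    names = booster.feature_names
    for tree_json in booster.get_dump(dump_format="json"):
        _collect_leaves(json.loads(tree_json), {}, leaves, names)
    config = json.loads(booster.save_config())
    base = float(config["learner"]["learner_model_param"]["base_score"])
    return leaves, base


# ---------------------------------------------------------------------------
# explainer
# ---------------------------------------------------------------------------

class TreeShapExplainer:
    """Interventional Shapley explainer for an XGBoost regression ensemble.

    ``background`` supplies the off-coalition feature values (conventionally
    the calibration set); ``max_background`` optionally subsamples it
    deterministically to bound cost.  ``predict`` re-evaluates the ensemble
    in double precision from the extracted trees, so the local-accuracy
    identity holds to machine precision against it.
    """

    def __init__(
        self,
        model,
        background: np.ndarray,
        max_background: int | None = None,
        seed: int = 0,
    ) -> None:
        booster = _as_booster(model)
        self._leaves, self.base_offset = _parse_ensemble(booster)
        background = np.asarray(background, dtype=np.float32)
        if background.ndim != 2 or background.shape[0] == 0:
            raise ValueError("background must be a non-empty 2-D matrix")
        if max_background is not None and background.shape[0] > max_background:
            rng = np.random.default_rng([41, int(seed)])
            pick = rng.choice(background.shape[0], size=max_background, replace=False)
            background = background[np.sort(pick)]
        self.background = background
        self.base_value = float(np.mean(self.predict(background)))

    # -- ensemble evaluation ------------------------------------------------
    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        out = np.full(X.shape[0], self.base_offset, dtype=float)
        for leaf in self._leaves:
            if leaf.features.size == 0:
                out += leaf.value
                continue
            cols = X[:, leaf.features]
            hit = np.all((cols >= leaf.lo) & (cols < leaf.hi), axis=1)
            out[hit] += leaf.value
        return out

    # -- Shapley values -----------------------------------------------------
    def shap_values(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        n_fg = X.shape[0]
        n_bg = self.background.shape[0]
        n_feat = X.shape[1]
        phi = np.zeros((n_fg, n_feat), dtype=float)

        depth_max = max((l.features.size for l in self._leaves), default=0)
        fact = np.array([math.factorial(k) for k in range(2 * depth_max + 1)],
                        dtype=float)
        # weight tables indexed by (a, b); WA needs a >= 1, WB needs b >= 1
        D = depth_max
        WA = np.zeros((D + 1, D + 1))
        WB = np.zeros((D + 1, D + 1))
        for a in range(1, D + 1):
            for b in range(0, D + 1 - 0):
                if a + b <= 2 * D:
                    WA[a, b] = fact[a - 1] * fact[b] / fact[a + b]
        for a in range(0, D + 1):
            for b in range(1, D + 1):
                WB[a, b] = -fact[a] * fact[b - 1] / fact[a + b]

        for leaf in self._leaves:
            m = leaf.features.size
            if m == 0:
                continue
            fg = X[:, leaf.features]
            bg = self.background[:, leaf.features]
            P_fg = (fg >= leaf.lo) & (fg < leaf.hi)          # (n_fg, m)
            P_bg = (bg >= leaf.lo) & (bg < leaf.hi)          # (n_bg, m)
            Ffg = P_fg.astype(float)
            Fbg = P_bg.astype(float)
            a_mat = Ffg @ (1.0 - Fbg).T                       # |A| per pair
            b_mat = (1.0 - Ffg) @ Fbg.T                       # |B| per pair
            dead = ((1.0 - Ffg) @ (1.0 - Fbg).T) > 0.5        # unreachable
            ai = a_mat.astype(np.intp)
            bi = b_mat.astype(np.intp)
            wa = WA[ai, bi]
            wb = WB[ai, bi]
            wa[dead] = 0.0
            wb[dead] = 0.0
            scale = leaf.value / n_bg
            for j in range(m):
                col = leaf.features[j]
                # features in A: foreground passes, background fails
                contrib_a = (wa @ (1.0 - Fbg[:, j])) * Ffg[:, j]
                # features in B: background passes, foreground fails
                contrib_b = (wb @ Fbg[:, j]) * (1.0 - Ffg[:, j])
                phi[:, col] += scale * (contrib_a + contrib_b)
        return phi

    def attribute(self, X: np.ndarray, feature_labels=None) -> AttributionMatrix:
        values = self.shap_values(X)
        if feature_labels is None:
            feature_labels = np.arange(X.shape[1])
        return AttributionMatrix(
            values=values,
            base_value=self.base_value,
            feature_labels=np.asarray(feature_labels),
            predictions=self.predict(X),
        )


def tree_shapley(
    model,
    X_pred: np.ndarray,
    background: np.ndarray,
    feature_labels=None,
    max_background: int | None = None,
    seed: int = 0,
) -> AttributionMatrix:
    """Interventional Shapley attributions of ``model`` on the prediction set.

    ``background`` defaults the expectation over off-coalition features; pass
    the calibration spectra (selected columns only).  Returns an
    :class:`AttributionMatrix` satisfying local accuracy against the
    double-precision ensemble evaluation.
    """
    explainer = TreeShapExplainer(
        model, background, max_background=max_background, seed=seed
    )
    return explainer.attribute(X_pred, feature_labels=feature_labels)


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------

def exact_shapley(
    predict_fn, x: np.ndarray, background: np.ndarray, p_limit: int = 12
) -> np.ndarray:
    """Classical Shapley values by exhaustive subset enumeration.

    The value of a coalition S is the mean of ``predict_fn`` over background
    rows with features in S replaced by ``x``.  Exponential in the feature
    count; refuses more than ``p_limit`` features.
    """
    x = np.asarray(x, dtype=float).ravel()
    background = np.asarray(background, dtype=float)
    p = x.size
    if p > p_limit:
        raise ValueError(f"exact enumeration limited to {p_limit} features, got {p}")
    n_subsets = 1 << p
    v = np.empty(n_subsets, dtype=float)
    for s in range(n_subsets):
        mixed = background.copy()
        for j in range(p):
            if s >> j & 1:
                mixed[:, j] = x[j]
        v[s] = float(np.mean(predict_fn(mixed)))
    phi = np.zeros(p)
    fact = [math.factorial(k) for k in range(p + 1)]
    for s in range(n_subsets):
        size = bin(s).count("1")
        for j in range(p):
            if s >> j & 1:
                continue
            w = fact[size] * fact[p - size - 1] / fact[p]
            phi[j] += w * (v[s | (1 << j)] - v[s])
    return phi


def rank_features(am: AttributionMatrix, top_k: int) -> list[tuple[float, float]]:
    """Top-k features by mean absolute attribution.

    Returns ``[(feature_label, mean |attribution|), ...]`` in descending
    importance; ties resolve toward the lower wavelength.
    """
    if top_k > am.values.shape[1]:
        raise ValueError("top_k exceeds the number of features")
    scores = np.mean(np.abs(am.values), axis=0)
    labels = am.feature_labels.astype(float)
    order = np.lexsort((labels, -scores))
    return [(float(labels[i]), float(scores[i])) for i in order[:top_k]]
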