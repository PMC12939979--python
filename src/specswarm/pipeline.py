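"""End-to-end orchestration: split -> preprocess -> select -> fit -> explain.

`run_pipeline` executes the full regression workflow for one indicator and
writes five artefacts into the run directory — ``mask.csv``, ``trace.csv``,
``report.json``, ``shap.csv`` and ``manifest.json`` — such that rerunning
the same config reproduces ``report.json`` bit for bit.  Every stochastic
stage receives a seed derived from the master seed by a fixed name hash, so
stages cannot perturb each other's draws.

`compare_selectors` produces one metrics row per selection method on the
shared split, plus per-iteration convergence curves for the evolutionary
methods (CARS has no comparable fitness trajectory and is excluded from the
curves, with a logged note).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import zlib
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dataset import read_spectra_csv, write_mask
from .modeling import HyperGrid, evaluate, grid_search_fit
from .partition import spxy_split
from .preprocess import (
    METHOD_ORDER, PreprocessMethod, apply_preprocessor, bake_off,
    fit_preprocessor,
)
from .attribution import rank_features, tree_shapley
from .selection import SELECTORS, SelectorConfig, cars_select

log = logging.getLogger("specswarm")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@contextmanager
def _stage(name: str):
    t0 = time.perf_counter()
    try:
        yield
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {name!r} failed: {exc}") from exc
    log.info("stage=%s elapsed=%.2fs", name, time.perf_counter() - t0)


def derive_seed(master: int, stream: str) -> int:
    """Stable per-stage seed below 2^31, derived from the master seed."""
    return (int(master) * 1_000_003 + zlib.crc32(stream.encode())) % (2**31)


@dataclass
class RunConfig:
    """Plain-data configuration of one pipeline run; YAML round-trippable."""

    spectra_path: str
    references_path: str
    out_dir: str
    indicator: str = "tvbn"
    preprocess: str = "auto"          # method name, or "auto" for the bake-off
    sg_window: int = 11
    sg_polyorder: int = 2
    split_ratio: float = 0.75
    selector: str = "psoga"
    selector_overrides: dict = field(default_factory=dict)
    hypergrid: dict = field(default_factory=dict)
    cars_runs: int = 50
    shap_max_background: int = 100
    seed: int = 0

    def selector_config(self) -> SelectorConfig:
        return SelectorConfig(
            seed=derive_seed(self.seed, "select"), **self.selector_overrides
        )

    def hyper_grid(self) -> HyperGrid:
        return HyperGrid(**self.hypergrid) if self.hypergrid else HyperGrid()

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _load_and_split(cfg: RunConfig):
    ds = read_spectra_csv(cfg.spectra_path, cfg.references_path)
    rows = ds.rows_with(cfg.indicator)
    dropped = ds.n_samples - rows.size
    if dropped:
        log.info("dropping %d samples lacking %r", dropped, cfg.indicator)
    ds = ds.subset(rows)
    y = ds.indicator_values(cfg.indicator)
    split = spxy_split(ds.reflectance, y, cfg.split_ratio)
    return ds, y, split


def _choose_method(cfg: RunConfig, ds, split) -> tuple[PreprocessMethod, pd.DataFrame | None]:
    if cfg.preprocess != "auto":
        return PreprocessMethod(cfg.preprocess, cfg.sg_window, cfg.sg_polyorder), None
    methods = [
        PreprocessMethod(name, cfg.sg_window, cfg.sg_polyorder)
        for name in METHOD_ORDER
    ]
    table = bake_off(
        ds, cfg.indicator, methods, split, seed=derive_seed(cfg.seed, "bakeoff")
    )
    winner = str(table.iloc[0]["method"])
    log.info("bake-off winner: %s", winner)
    return PreprocessMethod(winner, cfg.sg_window, cfg.sg_polyorder), table


def _preprocess(cfg: RunConfig, ds, split, method: PreprocessMethod):
    X = ds.reflectance
    cal, pred = split.calibration_idx, split.prediction_idx
    fp = fit_preprocessor(method, X[cal])
    Xc = apply_preprocessor(fp, X[cal], ds.grid.step_nm)
    Xp = apply_preprocessor(fp, X[pred], ds.grid.step_nm)
    return Xc, Xp


def _select(cfg: RunConfig, Xc, y_cal):
    if cfg.selector == "cars":
        mask = cars_select(
            Xc, y_cal, runs=cfg.cars_runs,
            cv_folds=cfg.selector_overrides.get("cv_folds", 3),
            seed=derive_seed(cfg.seed, "select"),
        )
        return mask, None
    if cfg.selector not in SELECTORS:
        raise ValueError(
            f"unknown selector {cfg.selector!r}; choose from "
            f"{sorted(SELECTORS) + ['cars']}"
        )
    trace = SELECTORS[cfg.selector](Xc, y_cal, cfg.selector_config())
    return trace.best_mask, trace


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the full workflow; returns the run directory."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    with _stage("load+split"):
        ds, y, split = _load_and_split(cfg)
        cal, pred = split.calibration_idx, split.prediction_idx
    with _stage("preprocess"):
        method, bake_table = _choose_method(cfg, ds, split)
        Xc, Xp = _preprocess(cfg, ds, split, method)
    with _stage("select"):
        mask, trace = _select(cfg, Xc, y[cal])
        write_mask(mask, ds.grid, out / "mask.csv")
        frame = trace.to_frame() if trace is not None else pd.DataFrame(
            columns=["iteration", "best_mse", "n_selected"]
        )
        frame.to_csv(out / "trace.csv", index=False)
    with _stage("fit"):
        cols = mask.indices()
        model, best_params = grid_search_fit(
            Xc[:, cols], y[cal], cfg.hyper_grid(), cv_folds=3,
            seed=derive_seed(cfg.seed, "fit"),
        )
        report = evaluate(
            model, Xc[:, cols], y[cal], Xp[:, cols], y[pred],
            n_features=mask.n_selected, best_params=best_params,
        )
    with _stage("explain"):
        am = tree_shapley(
            model, Xp[:, cols], Xc[:, cols],
            feature_labels=ds.grid.values[cols],
            max_background=cfg.shap_max_background,
            seed=derive_seed(cfg.seed, "shap"),
        )
        shap_df = pd.DataFrame(
            am.values, columns=[f"{w:g}" for w in am.feature_labels]
        )
        shap_df.insert(0, "sample_id", ds.sample_ids[pred])
        shap_df["base_value"] = am.base_value
        shap_df["prediction"] = am.predictions
        shap_df.to_csv(out / "shap.csv", index=False)

    with _stage("report"):
        payload = {
            "indicator": cfg.indicator,
            "preprocess": method.name,
            "selector": cfg.selector,
            **report.to_dict(),
            "n_selected": mask.n_selected,
            "top_features_nm": [w for w, _ in rank_features(am, min(10, mask.n_selected))],
            "calibration_size": int(cal.size),
            "prediction_size": int(pred.size),
        }
        if bake_table is not None:
            payload["bake_off"] = bake_table.to_dict(orient="records")
        _write_json(out / "report.json", payload)
        _write_json(out / "manifest.json", _manifest(cfg))
    return out


def _manifest(cfg: RunConfig) -> dict:
    import sklearn
    import xgboost

    cfg_dict = dataclasses.asdict(cfg)
    return {
        "config": cfg_dict,
        "config_hash": zlib.crc32(
            json.dumps(cfg_dict, sort_keys=True).encode()
        ),
        "derived_seeds": {
            name: derive_seed(cfg.seed, name)
            for name in ("bakeoff", "select", "fit", "shap")
        },
        "versions": {
            "specswarm": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "xgboost": xgboost.__version__,
            "scikit-learn": sklearn.__version__,
        },
    }


def _write_json(path: Path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# selector comparison
# ---------------------------------------------------------------------------

def compare_selectors(
    cfg: RunConfig, methods: list[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit and score one model per selection method on the shared split.

    Returns ``(table, curves)``: a metrics row per method (R2c, RMSEC, R2p,
    RMSEP, RPD, n_selected) and the per-iteration best-fitness curves of the
    evolutionary methods only.
    """
    if len(methods) < 1:
        raise ValueError("compare_selectors needs at least one method")
    ds, y, split = _load_and_split(cfg)
    cal, pred = split.calibration_idx, split.prediction_idx
    method, _ = _choose_method(cfg, ds, split)
    Xc, Xp = _preprocess(cfg, ds, split, method)

    rows, curve_frames = [], []
    for name in methods:
        run_cfg = dataclasses.replace(cfg, selector=name)
        mask, trace = _select(run_cfg, Xc, y[cal])
        cols = mask.indices()
        model, best_params = grid_search_fit(
            Xc[:, cols], y[cal], cfg.hyper_grid(), cv_folds=3,
            seed=derive_seed(cfg.seed, "fit"),
        )
        report = evaluate(
            model, Xc[:, cols], y[cal], Xp[:, cols], y[pred],
            n_features=mask.n_selected, best_params=best_params,
        )
        rows.append(
            {
                "method": name,
                "R2c": report.r2_cal, "RMSEC": report.rmse_cal,
                "R2p": report.r2_pred, "RMSEP": report.rmse_pred,
                "RPD": report.rpd, "n_selected": mask.n_selected,
            }
        )
        if trace is not None:
            frame = trace.to_frame()
            frame.insert(0, "method", name)
            curve_frames.append(frame)
        else:
            log.info("CARS excluded from convergence curves (non-evolutionary)")
    curves = (
        pd.concat(curve_frames, ignore_index=True)
        if curve_frames
        else pd.DataFrame(columns=["method", "iteration", "best_mse", "n_selected"])
    )
    return pd.DataFrame(rows), curves


def plot_convergence(curves: pd.DataFrame, path: str | Path) -> None:
    """Best-effort convergence-curve figure (one line per method)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for name, sub in curves.groupby("method"):
        ax.plot(sub["iteration"], sub["best_mse"], label=str(name))
    ax.set_xlabel("iteration")
    ax.set_ylabel("best CV MSE")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
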