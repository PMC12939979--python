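# specswarm

Metaheuristic wavelength selection and boosted-tree regression for Vis-NIR
spectroscopy, built for food-quality assessment problems such as predicting
meat freshness indicators (TVB-N in mg/100 g; CIELAB L*, a*, b*) from
400–1800 nm reflectance spectra.

High-dimensional Vis-NIR spectra (351 variables at 4 nm resolution) are
strongly collinear, and full-spectrum models generalise poorly.  The package
implements a hybrid particle-swarm / genetic-algorithm selector (**PSOGA**)
that searches the space of wavelength subsets:

* particles hold continuous positions **x** ∈ [0, 1]^p, thresholded at 0.5
  into inclusion masks;
* the fitness of a mask is the 3-fold cross-validated MSE of an XGBoost
  regressor restricted to the masked wavelengths;
* each iteration the swarm splits into an *elite* subpopulation, refined by
  PSO updates `v ← w(t)·v + c₁r₁(p−x) + c₂r₂(g−x)` under the nonlinear
  inertia schedule `w(t) = w_min + (w_max − w_min)(1 − t/T)²`, and an
  *ordinary* subpopulation regenerated by tournament crossover and
  Lévy-amplified polynomial mutation;
* initial positions come from chaotic logistic-map orbits `x ← 4x(1 − x)`.

Around the selector sits the full chemometric workflow: SNV / MSC /
Savitzky-Golay preprocessing with a data-driven bake-off, SPXY sample-set
partitioning (max-min selection on `dx/max dx + dy/max dy`), baseline
selectors (PSO, GA, grey wolf optimisation, CARS), grid-searched XGBoost
modelling with the standard report (R²c, RMSEC, R²p, RMSEP,
RPD = SD(y_pred)/RMSEP), an interventional tree-Shapley explainer with an
exact enumeration oracle, and a synthetic planted-band spectra generator
that provides ground truth for benchmarking.  See `docs/methods.md` for the
full model description.

## Worked example

Simulate spectra with three planted absorption bands (420, 480, 540 nm)
driving a TVB-N-like response, then run the full pipeline — SPXY split,
PSOGA selection, grid-searched model, Shapley attribution:

```python
import json
from specswarm import RunConfig, run_pipeline, write_spectra_csv
from specswarm.synthetic import SyntheticSpec, generate, make_grid

spec = SyntheticSpec(
    n_samples=160, grid=make_grid(400, 588, 4),
    bands=((420., 8., 0.15), (480., 8., 0.2), (540., 10., 0.18)),
    informative_idx=(0, 1, 2), seed=7,
)
ds, truth = generate(spec)
write_spectra_csv(ds, "spectra.csv", "references.csv")

cfg = RunConfig(
    spectra_path="spectra.csv", references_path="references.csv",
    out_dir="run", indicator="tvbn", preprocess="RAW", selector="psoga",
    selector_overrides={"pop_size": 14, "max_iter": 12,
                        "fitness_n_estimators": 40, "fitness_max_bin": 32},
    hypergrid={"n_estimators": [200, 400], "learning_rate": [0.1, 0.2],
               "max_depth": [3]},
    shap_max_background=60, seed=7,
)
out = run_pipeline(cfg)
print(json.loads((out / "report.json").read_text()))
```

The run directory contains `mask.csv`, `trace.csv`, `report.json`,
`shap.csv` and `manifest.json`; rerunning the same config reproduces
`report.json` bit for bit.  The report printed by this example:

```
R2c   0.9995    RMSEC  0.236
R2p   0.8754    RMSEP  3.418    RPD  2.87
n_selected 27   best_params {'learning_rate': 0.1, 'max_depth': 3, 'n_estimators': 200}
top_features_nm [420.0, 476.0, 540.0, 480.0, 544.0, ...]
```

The model explains 88 % of prediction-set variance from 27 of 48
wavelengths, and the top Shapley-ranked wavelengths sit on or within one
grid step of the three planted band centres (420, 480, 540 nm) — the
attribution recovers exactly the structure that generated the response.

The same workflow is scriptable from the shell:

```bash
specswarm simulate --seed 7 --out-dir data/
specswarm split --spectra data/spectra.csv --references data/references.csv \
    --ratio 3:1 --out split.csv
specswarm select --spectra data/spectra.csv --references data/references.csv \
    --method psoga --seed 7 --out mask.csv --trace trace.csv
specswarm fit --spectra data/spectra.csv --references data/references.csv \
    --mask mask.csv --out report.json
```

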