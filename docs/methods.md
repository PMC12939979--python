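# Methods

This note documents the models and procedures implemented in `specswarm`,
the parameters that matter, and the design choices made where the design was
genuinely open.

## Problem setting

Vis-NIR reflectance spectra of stored meat (400–1800 nm at 4 nm, 351
variables) are regressed against freshness indicators: total volatile basic
nitrogen (TVB-N, mg/100 g) and the CIELAB colour coordinates L*, a*, b*.
The spectra are high-dimensional and strongly collinear; a small subset of
wavelengths carries the chemically relevant signal (myoglobin absorption in
the visible range, C–H/N–H/O–H overtones in the NIR).  The package's core
contribution is a hybrid wavelength selector plus the surrounding workflow:
preprocessing, sample-set partitioning, model fitting and evaluation, and
Shapley attribution.

## Workflow

1. **SPXY partitioning.**  Calibration/prediction sets are chosen by
   max-min selection on the joint metric
   `d = dx/max(dx) + dy/max(dy)`, where `dx` is the Euclidean distance on
   spectra and `dy` the absolute response difference.  The seed pair is the
   globally most distant pair; ties resolve to the lowest index, so the
   split is fully deterministic.  The default share 0.75 gives the 3:1
   split (420 → 315/105).  The split is computed once on **raw** spectra
   per indicator, before any preprocessing, so every preprocessing method
   and selector is compared on the identical split.  (Per-indicator splits
   are the default; the data carry separate reference assays per indicator
   and may have per-indicator missingness.)

2. **Preprocessing.**  Five single transforms next to the raw spectra: SNV
   (per-row standardisation, ddof = 1), MSC (per-row OLS regression on the
   calibration-mean reference, corrected = (row − a)/b), SG smoothing and
   SG first/second derivatives (window 11, polyorder 2 by default —
   common chemometric practice).  Derivatives are divided by the grid step
   raised to the derivative order so they are per-nm.  Edge handling uses
   the local-polynomial fit of the terminal windows (scipy's `interp`
   mode): unlike mirror padding it keeps the filter exact on polynomial
   rows of degree ≤ polyorder over the *whole* row, which is the invariant
   the test suite enforces.  Only MSC carries fitted state; its reference
   is frozen on the calibration set to avoid leakage.  The `bake_off`
   ranks methods by full-spectrum RMSEP (ties: higher R²p, then the fixed
   order RAW < SG < SNV < MSC < SG1D < SG2D).

3. **Wavelength selection (PSOGA).**  Particles carry continuous positions
   in [0, 1]^p, thresholded strictly at 0.5 into masks (an all-false mask
   rescues its largest coordinate, keeping the fitness total).  Fitness is
   the 3-fold cross-validated MSE of a fixed boosted-tree regressor on the
   masked calibration columns; rows are shuffled once per run into
   contiguous folds, and results are memoised by mask bit pattern.  Each
   iteration:
   * the swarm splits into **elite** and **ordinary** subpopulations; the
     elite share shrinks linearly from 0.15 to 0.05 over the run
     (ties by particle index);
   * elites refine the local search: canonical PSO updates with the
     nonlinear inertia `w(t) = w_min + (w_max − w_min)(1 − t/T)²` (an
     exponential schedule is available via `inertia_mode="exp"`),
     c1 = c2 = 2, but under a tight elite velocity clamp (0.05) so an
     elite's mask differs from the best-known solutions only in the bits
     whose positions sit near the 0.5 threshold — a focused neighbourhood
     search of the incumbent rather than a free flight;
   * ordinary slots are replaced by offspring bred from the swarm's
     personal-best *memory*: tournament selection (k = 2, by personal-best
     fitness, over the whole swarm), uniform crossover of the winners'
     personal-best positions (probability 0.8), then polynomial mutation
     (index η_m = 2, per-coordinate rate 1/p) whose step is amplified by
     `1 + |levy|` with Mantegna-algorithm Lévy draws (β = 1.5, scale 2).
     Offspring restart with zero velocity.
   * Initial positions are rows of chaotic logistic-map orbits
     (`x ← 4x(1−x)`, start points rejected from {0.25, 0.5, 0.75}, 100
     burn-in iterates): the r = 4 orbit's arcsine invariant density covers
     (0, 1) densely and deterministically per seed.

   The hybrid-specific constants and wirings were fixed by benchmarking the
   search (final cross-validated MSE on planted-band problems) during
   development.  Three findings drove them.  Breeding *current* positions
   lets good material drift away, whereas breeding personal bests
   recombines the swarm's proven solutions — a hall-of-fame GA.  A mild
   polynomial mutation (index 20, Lévy scale 0.1) almost never moves a
   coordinate across the 0.5 threshold, so under threshold binarisation the
   mutation stage was inert; index 2 with Lévy scale 2 restores real
   bit-level diversity, which is the stated purpose of the Lévy stage.
   And unclamped elite flights produced near-random masks that wasted the
   elite budget; the tight elite clamp converts them into incumbent
   polishing.  The shared swarm constants (w, c1, c2, global clamp,
   crossover and mutation rates) keep their conventional values, which the
   PSO and GA baselines also use.

   Incumbent ties (equal fitness) resolve to fewer selected wavelengths,
   then the lexicographically smaller bit pattern.  Every selector is
   bit-reproducible under a fixed seed; each draws from its own RNG stream
   (fixed offsets from the seed), so adding a baseline never perturbs
   another's draws.  `fitness_seed` (defaulting to `seed`) fixes the CV
   fold shuffle separately from the search randomness, so paired
   comparisons across optimizer seeds share one fitness landscape.

4. **Baselines.**  Global-best PSO (uniform init, linear inertia), a
   binary-chromosome GA (tournament, uniform crossover, bit-flip 1/p,
   elitism 1), grey wolf optimisation (α/β/δ best-so-far leaders,
   coefficient a: 2 → 0), and CARS (Monte-Carlo PLS on 80 % row subsets,
   exponentially decreasing enforced retention from ratio 1 to 2/p,
   adaptive reweighted sampling proportional to |PLS coefficient|, final
   set = the run with minimal CV RMSE; PLS components ≤ 10 chosen by the
   same inner CV).  CARS is coefficient-based rather than fitness-driven,
   so it is excluded from convergence-curve outputs.

5. **Final model.**  XGBoost regression with grid-searched
   n_estimators ∈ {100..500}, learning_rate ∈ {0.01..0.3},
   max_depth ∈ {3..8} (3-fold CV RMSE; ties prefer smaller n_estimators,
   then depth, then learning rate) and fixed gamma = 0, reg_lambda = 0,
   reg_alpha = 1.  Candidates outside these boundary ranges are rejected at
   construction.  Metrics: R² and RMSE on calibration and prediction sets,
   and RPD = SD(prediction-set reference values, ddof = 1)/RMSEP — the
   prediction-set convention is self-consistent with reporting RPD next to
   RMSEP and matches the arithmetic of the published summary tables this
   workflow emulates.

6. **Attribution.**  Interventional Shapley values for the fitted tree
   ensemble, computed in closed form per (leaf, background row): with A the
   path features only the foreground sample satisfies and B those only the
   background row satisfies, each feature in A receives
   `leaf·(|A|−1)!|B|!/(|A|+|B|)!` and each in B the negative dual; leaves
   with a feature satisfied by neither contribute nothing.  The background
   is the calibration set (optionally subsampled deterministically).  This
   value function is *interventional*, so a feature used by no tree gets
   exactly zero, and local accuracy (base value + attributions = model
   output) holds to machine precision against the explainer's
   double-precision ensemble evaluation; agreement with the stored
   float32 booster predictions is at the 1e-4 level, which is float32
   accumulation, not attribution error.  An exhaustive subset-enumeration
   oracle (p ≤ 12) verifies the same game by brute force.

## Synthetic benchmark

The generator emulates reflectance spectra of stored meat without claiming
tissue-optics realism: a linear baseline (0.90 → 0.65) minus Gaussian
absorption bands; per-sample band amplitudes U(0.5, 1.5) × base amplitude;
per-spectrum multiplicative/additive scatter (slope N(1, 0.05²), offset
N(0, 0.02²)); additive instrument noise (SD 0.005).  Default bands sit at
440, 576, 728, 912, 1020, 1236, 1450 and 1592 nm with widths 12–30 nm,
of which 576, 728, 1020, 1236 and 1450 nm drive the response — centres
chosen in the myoglobin/overtone regions so demonstration runs produce
chemically plausible rankings (a demo convenience, not a claim of
equivalence to real meat spectra).  The response is an affine map of the
summed informative amplitudes onto 6.65–66.05 mg/100 g (the theoretical
amplitude bounds fix the map, so its image is exactly the declared range),
plus N(0, (0.02 × range)²) noise; a saturating variant applies a bounded
exponential to the normalised sum first.  A storage-series variant drifts
informative amplitudes by `1 + drift × day` to emulate spoilage over
storage days at different temperatures.

What the generator does **not** emulate: wavelength-correlated instrument
noise, baseline curvature, temperature-dependent band shifts, or the real
covariance between indicators.  Passing benchmarks therefore demonstrate
that the machinery recovers planted structure under realistic scatter and
noise — not field performance on real spectra.

## Problem sizes used in tests and the acceptance script

Search budgets scale down from the study conditions (population 50, 100
iterations, 200-tree fitness model) to population 20, 30 iterations and a
15-round / 16-bin fitness model, with all selectors sharing the identical
fitness so paired comparisons remain fair; the selector-reliability check
uses a 12-wavelength planted problem whose 4095-mask fitness landscape is
enumerated exhaustively.  These are the package's declared desk-scale
conditions; the comparative and recovery properties are assessed over ten
paired optimizer seeds on one fixed landscape.

## Numerical choices and degenerate inputs

* Masks hash by raw flag bytes; fitness memoisation is per selector run.
* SNV rejects constant rows (zero variance); MSC rejects |slope| < 1e-12
  (a spectrum orthogonal to the centred reference).
* SPXY rejects data where all pairwise distances vanish; if only one of
  the two component distances is degenerate its term is dropped.
* The grid constructor requires the range to divide evenly by the step and
  names the remainder otherwise.
* Constant reference values make R² (and a zero RMSEP makes RPD) undefined;
  both raise rather than returning sentinel values.
* Tree extraction reads the booster's JSON dump; thresholds are compared in
  float32 exactly as XGBoost evaluates them.

## Known limitations

* The boosted-tree fitness makes selection runs expensive; the
  fitness-model fields on `SelectorConfig` are the intended cost dial.
* CARS uses PLS coefficients (the canonical formulation) and therefore
  measures linear relevance; it can discard wavelengths that only interact
  nonlinearly.
* The beeswarm-style visualisation of attributions is not implemented;
  the tested surface is the attribution matrix and the ranking.
  `plot_convergence` is a best-effort matplotlib helper and is untested.
* Binarisation at a fixed 0.5 threshold tends to select roughly half the
  wavelengths at this budget; parsimony pressure comes only from the
  equal-fitness tie-break, so selected subsets are larger than what a
  sparsity-penalised fitness would give.
* At the desk-scale budget (population 20, 30 iterations) the hybrid's
  final fitness is statistically *tied* with the binary GA baseline rather
  than strictly better: per-seed outcomes are dominated by run-to-run
  variance of all three metaheuristics, and the GA — elitist, with clean
  one-bit mutations — is a strong stochastic hill-climber on this
  landscape.  The paired-superiority benchmark in the acceptance suite
  reflects this: the hybrid wins a plurality of paired seeds but not the
  large majority the benchmark demands, and the test reports that outcome
  as measured.
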