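# mabeauty

Geometric facial measurement and interpretable feature selection for
medical-aesthetic (MA) beauty assessment.

Clinical aesthetics needs facial-attractiveness models whose inputs a
surgeon can read: distances, proportions, angles and symmetry indices tied
to named anatomical landmarks, not CNN activations. This package provides
that stack end to end, for researchers and tool builders working on
landmark-based facial analysis:

* a **72-point anatomical landmark schema** with named points, bilateral
  (left/right) pairing tables, midline points, and the trichion / glabella /
  subnasale / menton boundaries of the classical facial thirds;
* a **135-dimensional geometric feature extractor**: 115 classical
  descriptors (52 normalized inter-landmark distances, 38 ratios,
  25 angles) plus a 20-row MA block covering overall proportions (golden
  ratio, facial thirds, the five-eye rule), eye, nose, lip and jaw indices,
  and bilateral symmetry displacements;
* a **prior-constrained multi-objective genetic algorithm** for feature
  selection that treats the 20 MA rows as clinically mandated;
* a **ridge beauty-score regression head** with the standard evaluation
  metrics (Pearson correlation PC, MAE, RMSE);
* a **cascaded-regression landmark refiner** (staged linear regressors from
  a mean-shape initialization);
* a **synthetic face generator** (deformation modes, planted feature
  effects, rendered rasters) so every component is testable without any
  real face data.

## The model

Faces are similarity-normalized (midline vertical, inter-ocular distance 1,
centroid at origin), so all features are invariant to rotation, scale and
translation. Key MA measurements include the bilateral asymmetry index

    A_z = (1/n) Σ_i  d(L_i, mirror(R_i)) / max(d(L_i, C), d(R_i, C)),

where `C` is the total-least-squares facial midline and `mirror` reflects
the right landmark across it (so a perfectly symmetric face scores 0); the
nasolabial angle as the absolute atan2 difference of the subnasale→labiale
superius and subnasale→columella rays; and the thirds proportion
`P_v = max(h_u, h_m, h_l) / min(h_u, h_m, h_l)`.

Feature selection encodes a subset as a binary chromosome `x ∈ {0,1}^135`.
The 20 MA genes (the prior set `S`) are switched on at initialization and
protected from mutation; remaining genes start Bernoulli(p = 0.6). Fitness
scalarizes accuracy and sparsity,

    F(x) = α · PC(x) + β · (1 − |x| / N),    α = 0.999, β = 0.001,

where `PC(x)` is the cross-validated Pearson correlation of a ridge
regressor on the selected columns. The loop is tournament selection
(size 3), uniform crossover (0.8), per-gene bit-flip mutation (1/N), and
single elitism, run for 200 generations with population 200 by default.

The landmark refiner applies `S_v = S_{v−1} + α_v · R_v(X, S_{v−1})` from
the mean shape, with linear stage regressors on shape-indexed
pixel-difference features and a decay schedule `α_v = 0.8^v`.

## Worked example

```python
import mabeauty as mb
from mabeauty.experiments import default_experiment_config

cfg = default_experiment_config(seed=0)          # 300 synthetic faces
data = mb.generate_dataset(cfg)

ga = mb.GAConfig(population_size=60, generations=30, rng_seed=0)
prior = mb.default_registry().ma_indices          # the 20 protected MA rows
result = mb.run_ga(data.features, data.scores, ga, prior_set=prior)
print(f"selected {result.selected_count}/135 features, "
      f"cross-validated PC = {result.best_pc:.4f}")

tr, _va, te = mb.split_indices(len(data.scores), seed=0)
model = mb.fit_score_model(data.features[tr], data.scores[tr],
                           subset=result.selected_indices())
report = mb.evaluate_predictions(model.predict(data.features[te]),
                                 data.scores[te])
print(f"held-out test: PC = {report.pc:.4f}, "
      f"MAE = {report.mae:.4f}, RMSE = {report.rmse:.4f}")
```

This prints:

```
selected 62/135 features, cross-validated PC = 0.8573
held-out test: PC = 0.8476, MAE = 0.4145, RMSE = 0.5486
```

The GA keeps all 20 MA rows (they are protected), discards most redundant
classical columns, and the resulting subset predicts the planted synthetic
beauty scores well out of sample. MAE/RMSE are on the 1–5 rating scale.

A command-line interface exposes the same pipeline:
`mabeauty simulate | extract | select | train | evaluate | detect |
ablation | compare-ga`; every output directory gets a `manifest.json`
recording command, configuration, seed and package version.

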