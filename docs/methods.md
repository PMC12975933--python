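# Methods

This note documents the models, conventions and design choices behind
`mabeauty`, including where the design was genuinely open and what the
synthetic experiments do and do not demonstrate.

## Landmark schema and coordinate conventions

The 72-point registry uses the image convention (x rightward, y downward,
0-based indices). Regions: 17 contour, 10 brow, 12 eye, 9 nose (including
subnasale, columella and alar-base points), 12 mouth (including labiale
superius and stomion), 6 zygomatic, 4 orbital-rim and 2 chin points. Every
point is either one of 30 bilateral left/right pairs or one of 12 midline
points, which makes mirror-symmetry operations total. Published 72-point MA
landmark figures do not enumerate per-point anatomy, so this registry is a
documented reconstruction; it is versioned (`ma72-1`) and loadable from
YAML so alternative mappings can be declared without code changes.

The facial midline is the total-least-squares line through the midline
landmarks (glabella, nasion, nasal tip, columella, subnasale, lip midline
points, menton, pogonion), not the raster's vertical axis; this keeps
symmetry measurements robust to residual head roll. Facial thirds are
bounded by trichion, glabella, subnasale and menton, with heights measured
as projections onto the midline direction.

**Normalization.** A landmark set is similarity-aligned so the midline is
vertical (chin below glabella), the outer-canthal (inter-ocular) distance
is 1 and the centroid is the origin. The transform is uniquely determined
by those constraints, hence idempotent, and every downstream feature is
computed on normalized coordinates, which makes the full 135-vector
invariant to rotation, isotropic scaling and translation (verified
property-based). Distances are therefore reported in inter-ocular units,
ratios are dimensionless, and angles in degrees.

## The 135-dimensional feature vector

Entries 0–114 are a frozen classical catalog: 52 inter-landmark distances
over canonical pairs (eye widths and openings, intercanthal/outer-canthal
spans, brow metrics, nasal lengths and widths, lip heights, facial widths
at temple/zygion/gonion level, thirds heights, …), 38 ratios of those
distances, and 25 angles at anatomical vertices. The literature reports
115-feature geometric sets only pictorially, so the exact composition is a
package design decision; it is fully described by the `FeatureRegistry`
(versioned `ma135-1`, serializable to YAML) with per-entry landmark
indices, so the catalog is inspectable and replaceable.

Entries 115–134 are the 20 MA rows. Operationalizations worth noting:

* **Asymmetry index / symmetry rows (15–17).** The printed form of the
  index uses the direct distance d(L, R), which is nonzero even for a
  perfectly symmetric face. Because the clinical reading of symmetry rows
  is "difference ≤ 1 mm" — zero difference for a symmetric face — the
  default implementation measures d(L, mirror(R)) across the midline, and
  symmetric faces score exactly 0. The literal reading remains available
  via `asymmetry_index(..., literal=True)`.
* **Nasolabial angle.** Implemented with the full-quadrant arctangent
  (atan2) difference of the two rays at the subnasale, wrapped to
  (−180°, 180°] and reported as an absolute angle, avoiding the ±90°
  singularities of a ratio arctangent. Whether clinical angles are signed
  is not standardized; absolute values are reported throughout.
* **Ptosis index.** With no iris landmark available, upper-lid droop is
  proxied as `clip(1 − h/(w/3), 0, 1)` per eye — the encroachment of the
  palpebral opening h on a nominal iris of diameter w/3 — averaged over
  both eyes.
* **Profile angles.** Nasofrontal and jaw angles are measured as their
  frontal-view projections at nasion and gonion respectively; on a
  perfectly frontal symmetric face the nasofrontal projection is 180° and
  deviations encode brow/nasal geometry. True profile angles require a
  lateral view, which 2D frontal landmarks cannot supply.
* **Reference ranges.** Clinical target ranges (golden ratio ±5%, jaw
  angle 110–130°, …) are stored as registry metadata for reporting and
  out-of-range flagging only; they never enter feature computation.

Degenerate geometry (coincident landmarks, zero heights, pairs lying on
the midline) raises a `DegeneracyError` naming the offending feature index
rather than returning NaN.

## Wrapper feature selection

The GA follows the prior-constrained design: chromosomes are 135-bit
masks; the 20 MA genes are forced on at initialization and exempt from
mutation, so they survive every generation (asserted in-loop and verified
across full runs in tests); other genes initialize Bernoulli(p = 0.6).
Fitness is the scalarization F(x) = α·PC(x) + β·(1 − S/N) with α = 0.999,
β = 0.001; population 200, 200 generations, tournament size 3, crossover
probability 0.8.

Choices the published description leaves open, resolved as follows:

* **PC(x) evaluator.** Ridge regression (λ = 1 on standardized columns)
  under 5-fold cross-validation with a fixed fold seed; PC(x) is the mean
  held-out Pearson correlation. Cross-validated rather than training
  correlation, so fitness rewards generalization rather than subset size.
  Subsets yielding constant predictions in a fold contribute 0 with a
  warning instead of crashing. The evaluator precomputes per-fold Gram
  matrices once and solves a |subset|-sized ridge system per fold per
  chromosome, memoized by gene mask — this is what makes a full
  200×200 run take seconds rather than hours on one CPU.
* **Operators.** Uniform crossover (features carry no positional
  structure), per-gene mutation rate 1/N, single-individual elitism (which
  guarantees the non-decreasing best-so-far trace). Loop order is
  selection → crossover → mutation → elitist replacement.
* **Multi-objective treatment.** The dual criterion is scalarized, as in
  the source design; α ≫ β means sparsity only breaks near-ties in PC.

With an empty prior set and p = 0.5 the same loop degrades to a plain GA,
which is exactly the baseline used by the `compare-ga` experiment.

## Score model and metrics

The regression head is ridge with intercept on standardized selected
columns — the same family as the wrapper evaluator, so selection fitness
and final evaluation are consistent — with predictions clipped to the
[1, 5] rating scale shared by the public facial-beauty datasets. The
evaluation protocol is a seeded 60/20/20 train/validation/test split;
reported metrics come from the test split. PC, MAE and RMSE are
implemented directly from their definitions (tested against brute-force
loops at 1e-12 and against scipy), and every `EvalReport` enforces
RMSE ≥ MAE ≥ 0.

## Cascaded landmark refinement

The refiner is classic explicit shape regression: S_0 is the training mean
shape; stage v computes 200 pixel-difference features at seeded random
landmark-anchored integer offsets (radius 6 px), fits a ridge-regularized
linear map to the current residuals, and advances estimates by α_v times
its prediction. The decay coefficient is 0.8; since only the coefficient
is standard, the schedule is a design choice — geometric α_v = 0.8^v by
default, with a constant-0.8 mode. Stage count defaults to V = 5. Whether
stage regressors should consume appearance features or raw coordinates is
ambiguous in the source description; appearance (pixel-difference) mode is
the default since coordinate-only regressors cannot use the image.
Nearest-pixel sampling is clamped at raster bounds; prediction is
deterministic given model and image.

## Synthetic generator: what it emulates, and what it does not

Faces are the symmetric mean shape deformed along 8 interpretable linear
modes (overall width and height, eye/brow spacing, nose length, jaw width,
mouth width and lip spread, brow height; SDs ≈ 6–8% per mode), plus an
optional lateral asymmetry displacement of the left zygomatic/cheek points
and isotropic landmark jitter (default 0.01 inter-ocular units ≈ 1 px at
portrait resolution, typical of manual annotation noise). Scores are
linear-Gaussian in standardized planted feature columns, centred at 3,
noise SD 0.5 (matching the rater-SD reported for the public datasets), and
clipped to [1, 5]. Rendered rasters are sums of per-region Gaussian blobs
anchored at the true landmarks.

Because the shape space has only 8 modes plus jitter, many catalog columns
are nearly linear combinations of others; a planted effect on such a
column is unidentifiable in principle (any equivalent subset reproduces
the scores). Parameter-recovery experiments therefore plant effects on a
`recovery_panel`: the 10 classical columns with the lowest leave-one-out
R² against the remaining candidates, computed from the feature table alone
(never the scores). Similarly, the default planted MA rows for the
ablation and GA-comparison experiments are rows the classical catalog does
not duplicate (thirds proportion, ptosis, bridge deviation, the three
symmetry displacements, eye–nose coordination) — planting on, say, the
width/height ratio would be invisible because an equivalent classical
ratio column already carries it.

Passing these experiments shows the machinery is correct and the selection
mechanism recovers identifiable planted signal under realistic noise; it
does not show that the 20 MA rows predict human attractiveness judgments,
which requires real rated photographs and is explicitly out of scope.

## Problem sizes and numerical notes

Default experiment sizes — 300-face cohorts, full 200×200 GA runs, 200
training / 50 held-out renders for the cascade, 5-seed medians for
experiment comparisons, a 10-gene toy problem for exhaustive-search
agreement — are chosen so the whole pipeline at study conditions runs in
well under a minute per experiment while leaving clear statistical margins
(3-standard-error bands for rate checks, ≥8/10 recovery, strict baseline
improvements). All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; GA runs, cohorts and renders are reproducible
bit-for-bit. Tolerances: geometric identities at 1e-9, similarity
invariance at 1e-6 (accumulated floating-point error under large
rotations/scales), metric oracles at 1e-12.

## Known limitations

* Texture and color are absent by design; only landmark geometry enters.
* No physical calibration: distances are in inter-ocular units, so
  millimeter-valued clinical thresholds can only be checked as ratios.
* The registry's anatomical naming and the classical catalog are
  reconstructions and alternatives are expected; both are declared in
  versioned YAML for that reason.
* The synthetic renderer is far from photo-realistic; cascade results on
  it bound nothing about real-photo landmarking accuracy.
* 2D frontal geometry only; profile angles are projections and 3D
  volumetric aesthetics are out of scope.
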