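# Methods

## Scope and design

The package implements the classical block-statistics mammography CAD
chain — enhancement, segmentation, feature extraction, classification,
wrapper feature selection, evaluation, and rotation/flip augmentation —
as a library of plain functions on 8-bit grayscale numpy arrays. Clinical
mammogram archives are not required: a phantom generator emulates the
geometry the pipeline relies on and provides exact ground-truth masks, so
every stage is validated by construction rather than by eye.

## The phantom generator

A phantom is a 256×256 (configurable) 8-bit image composed of:

- **Background**: noise at level 6 ± 3, clipped to [0, 17], i.e. strictly
  below the global segmentation threshold of 18.
- **Breast**: a half-ellipse anchored on the chest-wall edge, filled with
  clipped Gaussian parenchyma texture, mean 100 and sd 16 (clipped at 24
  from below so thresholding cannot fragment the region). Clipped white
  noise is the simplest texture whose block statistics respond to a
  lesion.
- **Pectoral muscle**: a filled triangle covering `pectoral_frac`
  (default 0.35) of the top edge and ~1.6× that fraction of the chest
  edge, intensity 150 ± 5. 150 is within ±15 of the dense-tissue tail of
  the parenchyma (mean + ~2.5 sd ≈ 140), which is exactly why pectoral
  removal is needed, while its low internal sd is what lets seeded region
  growing recover it.
- **Labels**: bright (≈230) rectangles placed near the non-breast edge
  with a guaranteed ≥2 px gap to the breast, so they are always
  disconnected components.
- **Lesion** (abnormal class only): a disk of default radius 22 px whose
  pixels get +48 intensity (3× the parenchyma sd) and extra texture noise
  of sd 14. These defaults were fixed so that the generator meets its own
  separability contract — a 3σ lesion must make the classes separable in
  at least one aggregated feature (single-feature AUC ≥ 0.95) and
  learnable by the default random forest (5-fold CV accuracy ≥ 0.95) on a
  50/50 cohort. A radius of ~22 px means the mass spans roughly 5–7 of
  the 256 blocks, a small but realistic fraction of the breast.

Cohorts jitter the per-phantom parameters: global brightness ±1 (a mild
exposure variation; larger drifts would be normalized away by enhancement
in a real pipeline and would otherwise dominate the intensity features),
pectoral extent ±0.01, lesion position ±8 px and radius ±2 px, with a
fresh render seed per phantom. Emission order is all normals then all
abnormals.

What the phantom does **not** model: X-ray physics, anatomical texture
correlation (real parenchyma is spatially correlated; white noise is
not), spiculated lesion margins, CC views, or calcifications. Passing
tests therefore demonstrate that the pipeline's machinery is correct and
internally consistent — not that the accuracies transfer to clinical
images.

## Enhancement (CLAHE)

Tiles default to an 8×8 grid with clip fraction 0.01 of the tile pixel
count (common practice; both are config-exposed). The clip level is
floored at ⌈n_pixels/256⌉ so redistribution is always feasible. Excess
histogram mass is reallocated uniformly over the remaining headroom,
iterated until every count is placed — a fixed point identical to any
other mass-conserving redistribution. Mappings are cumulative histograms
scaled to [0, 255]; pixels interpolate bilinearly between the four
nearest tile mappings with edge clamping. With one tile and clip = 1 the
transform reduces exactly to plain histogram equalization, which the
tests exploit as an oracle.

## Segmentation

- **Orientation** compares thresholded foreground counts of the left and
  right image halves and mirrors when the right dominates; ties keep the
  image as-is, making the operation idempotent.
- **Artifact suppression** binarizes at 18 (the working global threshold
  for film-digitized mammograms), opens with a disk of radius
  max(1, round(min(H, W)/200)) (scales with image size; falls back to the
  raw threshold mask if opening empties a tiny image), and keeps the
  largest 8-connected component.
- **Seeded region growing** accepts a pixel when its intensity differs
  from the running regional mean by at most the tolerance (default 32,
  about 2× the phantom parenchyma sd; config-exposed). The frontier is
  FIFO with row-major neighbour enumeration and each pixel is examined
  once, which makes the result deterministic; 8-connectivity is used
  throughout the package. At tolerance 0 the procedure coincides with a
  flood fill over pixels equal to the seed intensity.
- **Pectoral removal** seeds at the topmost-then-leftmost breast pixel in
  the top-left quarter window. If the grown region exceeds half the
  breast area the segmentation is declared failed: a warning is logged,
  the over-grown region is returned flagged, and the image is left
  un-blacked. This is the safe behaviour when no distinct pectoral region
  exists (a homogeneous corner lets the region flood the parenchyma); in
  that case nothing is removed rather than most of the breast.

## Features

Blocks are full 16×16 tiles in raster order; partial edge blocks are
discarded so every formula sees exactly F·G pixels. Entropy uses log
base 2 over 256 grey levels (bits); variance uses the population divisor
F·G. The RMS statistic defaults to the root mean square of the block's
pixels, which is block-local and rotation-invariant like the other seven;
a directional variant (`rms_mode="row_col"`: RMS of the per-row and
per-column block means) is available for comparison but is not
rotation-symmetric. Blocks outside the breast are included by default
(no masking rule is imposed); `mask_blocks=True` excludes blocks with
zero overlap with a supplied mask. All eight default features are exactly
invariant under 90° rotations of a square image whose side is a multiple
of the block size, since rotation permutes blocks and rotates block
contents.

## Classifiers and ensembles

- **k-NN**: k = 2, Euclidean distance on features min-max scaled to
  [0, 1] with parameters learned from the training fold only (the raw
  features span ~4 orders of magnitude). Distance ties resolve by
  training index; an even-k vote tie is decided by the nearer neighbour,
  and coincident opposite-label neighbours fall back to class 0.
- **Trees**: greedy top-down binary splits on midpoint thresholds
  maximizing gain ratio (ties → lower feature index, then lower
  threshold); stop on purity, node size < `min_leaf` (default 2), or no
  positive-gain split. J48 optionally applies reduced-error pruning
  against a stratified internal 25% validation split (the exact pruning
  constants of the original C4.5 are not reproduced; reduced-error
  pruning is a documented substitute). The random tree samples
  ⌈log₂ d + 1⌉ features per node and is never pruned.
- **Random forest**: 10 random trees on bootstrap resamples; probability
  = member mean. With one member and bootstrapping disabled it reduces
  exactly to a random tree with the same seed.
- **Bagging**: n-sample bootstrap per member, probability mean; 10
  members by default.
- **AdaBoost**: M1 with weight-proportional *resampling* (not
  reweighting). Per round: resample by weights, fit, compute weighted
  error ε_t on the full set, stop at ε_t ≥ 0.5 (keeping the single
  round-1 member if it happens immediately) or ε_t = 0, weight the
  member by α_t = ½ ln((1−ε_t)/ε_t) (ε floored at 1/(2n) to cap α when
  ε_t = 0), multiply misclassified weights by e^{α_t} and renormalize.
  The class-1 probability is the logistic of the α-normalized vote
  margin — AUC needs a continuous score and the margin's monotone
  transform preserves the ranking.
- **Averaging fusion** takes the unweighted mean of ≥2 fitted members'
  probability rows; prediction ties go to class 0 everywhere.

## Feature selection

The subset objective is stratified k-fold CV accuracy of the chosen
classifier on the column-restricted data, with the fold assignment
frozen per search and all evaluations memoized. Best-first starts from
the empty set, expands the best evaluated subset into single-feature
additions (and deletions, bidirectionally), and stops after
`stale_limit` (default 5, the common convention) consecutive expansions
without improving the incumbent; with an unlimited stale budget it
enumerates the full lattice, so on the 8-feature space exhaustive
validation (255 subsets) is always feasible and is used as the standing
oracle. Random search starts from a uniformly random nonempty subset and
spends its budget (default 100) on deduplicated proposals, half
single-feature mutations of the incumbent and half uniform subsets,
falling back to deterministic enumeration of unseen subsets when random
proposals keep colliding. Equal-objective ties always prefer the smaller,
then lexicographically earlier subset. Selection inside an outer CV loop
should use `nested_select`-style protocols to avoid leakage; the searches
themselves are single-level.

## Evaluation

Abnormal is the positive class. Zero-denominator ratios report 0 with an
explicit `undefined` flag instead of raising, so pooled CV survives
degenerate folds. AUC is computed by midranks (exactly the all-pairs
Mann–Whitney probability, ties counted half). Cross-validation is
stratified with seed-controlled shuffling (the safer default for
imbalanced cohorts); both pooled-count metrics and per-fold metrics are
reported, since pooling convention is otherwise a silent choice. Nested
CV picks, per outer training split, the candidate with the best
inner-CV accuracy (ties to the earlier candidate).

## Problem sizes and determinism

Default study conditions: 50 normal + 50 abnormal phantoms of 256×256
pixels (256 blocks each), fivefold CV, forests/ensembles of 10 members.
These sizes keep the full test suite and the acceptance script in the
seconds-to-minutes range while leaving every statistical check
well-powered. Every stochastic component takes an explicit seed
(`numpy.random.default_rng`); fits and searches are reproducible
bit-for-bit under a fixed seed.

## Known limitations

- The phantom's white-noise texture makes the classification task easier
  than clinical data; reported accuracies characterize the pipeline, not
  mammography.
- SRG examines each pixel once; a pixel rejected early is not
  reconsidered after the regional mean drifts. This is deterministic and
  matches flood-fill at tolerance 0, but differs from variants that
  re-test boundary pixels.
- The J48-style tree is a gain-ratio CART-like binary tree, not a clone
  of any particular C4.5 release (no categorical splits, no pessimistic
  pruning).
- Boosted k-NN is well-defined only because members are fit on resamples;
  its rounds often stop early since resampled k-NN can have near-zero
  training error.
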