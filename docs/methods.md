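# Methods

## Pipeline model

The package treats glioma subtype diagnosis from H&E whole-slide images as
five-way tile classification over the classes
`(ac, odg, gbm, normal, necrosis)` with a fixed order used everywhere
(probability columns, confusion matrices, argmax tie-breaks). The central
assumption, used both by tiling and by the pseudo-label filter, is the
**slide-consistency rule**: a slide carries one diagnosis *d*, and tiles on
it can only belong to *d*, normal tissue or necrosis. For normal-control
slides we take the strict reading — normal tissue only; necrotic tissue on
a non-cancer control is not represented. This control rule is a design
choice of this package (the tumor-diagnosis rule determines the tumor case,
not the control case) and is configurable through `ClassScheme`.

### Tiling

Coordinates are 0-based and rectangles half-open. ROIs are cut into square
tiles of side `T` (512 px at full scale) at stride `round(T·(1−overlap))`
(default overlap 0.5), keeping only tiles fully inside the ROI — no edge
padding, so the closed-form count
`(⌊(W−T)/s⌋+1)·(⌊(H−T)/s⌋+1)` holds exactly. A tile that fits inside two
ROIs of different classes is an annotation conflict and raises. Training
tiles get the full 8-member dihedral orbit (identity included); we read
"8 augmented views" as the complete D4 orbit. Test tiles are never
augmented, enforced at the API level. The inference grid uses the same
50 % overlap as training so heatmaps are smooth; this is configurable. A
tissue filter (fraction of pixels darker than an intensity cutoff) exists
but is off by default.

### Normalization and training

Tiles are standardized per channel with mean/std pooled over the pixels of
the training fold only (the validation fold and the test split are
transformed with those statistics — no leakage; standard deviations are
floored at 1e−6). Class imbalance is handled in the loss: categorical
cross-entropy with inverse-frequency weights `w_c = N/(K·n_c)`. This
normalization (mean-1 weights under the class frequencies) keeps the loss
scale comparable across imbalance levels and makes the total training
weight exactly `N`, which the tests verify in rational arithmetic.

Epoch selection: the trainer holds out a validation fraction (default 0.2)
**grouped by slide**, so correlated tiles from one slide never straddle the
split, and keeps the weights of the epoch with the best validation balanced
accuracy (ties go to the earliest epoch). Selecting the best epoch against
the *test* set would be leakage, so we deliberately select on a validation
split instead. When a class occupies so few slides that no grouped split
can keep every class in the training fold, the trainer falls back to a
stratified per-tile split with a warning — this only happens on degenerate
toy cohorts.

### Backbone

The default backbone, `pooled-mlp`, is a pooled-color-feature multilayer
perceptron: each tile is summarized by channel means over a 4×4 spatial
partition plus per-channel standard deviations (51 features), feeding one
ReLU hidden layer (64 units) and a softmax head, trained with Adam
(learning rate 0.01, batch 64, 10 epochs by default). This is sufficient
for textures whose class identity is carried by local color statistics —
exactly what the synthetic cohort produces — and trains in seconds on one
CPU. The backbone registry (`register_backbone`) accepts heavier
user-provided architectures with the same
`extract_features`/`init_params`/`forward`/`backward` surface; none are
shipped.

### Semi-supervised step

Step 1 fits on the ground-truth tiles. The fitted model predicts the grid
tiles of the *training* slides that do not intersect any ROI (test slides
are never pseudo-labeled; the tests assert the slide-id intersection is
empty). A prediction is kept iff confidence ≥ 0.90 (inclusive) and the
predicted class is allowed under the slide diagnosis. When a record fails
both gates the manifest reports `low_confidence` (confidence is checked
first). Argmax ties break to the first class in scheme order, so runs are
reproducible. Step 2 retrains a *fresh* model (same initialization
procedure, seed derived from the step-1 seed) on ground truth + pseudo
tiles; we read "retrained" as a full retrain rather than a warm start, and
expose the choice through the estimator. One pseudo-labeling round is
performed. Pseudo tiles are **not** dihedral-augmented by default
(`augment_pseudo` flag exists): augmenting noisy labels amplifies noise,
and merged-dataset sizes then need not be multiples of 8.

### Evaluation

Balanced accuracy is the macro-average of per-class recall; it is computed
once and reported under both names. Macro precision/recall/F1 are
one-vs-all with equal class weights; macro-F1 is the mean of per-class F1
values, not the F1 of macro-precision/recall (the two differ, and a test
pins the distinction). Zero-division convention: a never-predicted class
contributes precision 0 (and F1 0) with a warning; a zero-support class is
excluded from balanced accuracy with a warning; an all-zero matrix is an
error. The binary collapse partitions classes into tumor
(`ac, odg, gbm`) and non-tumor (`normal, necrosis`) and reports
P(predicted tumor | true non-tumor) ("false alarm") and
P(predicted non-tumor | true tumor) ("missed cancer"). Metrics are
tile-level; slide-level readings live in the heatmap summary.

### Heatmaps

Tile probability vectors are accumulated on the stride lattice; each cell's
score is the unweighted **mean** of all covering tiles' vectors, which
preserves probability semantics (cells stay on the simplex) — max-pooling
would not. How overlapping predictions should be combined is not dictated
by the workflow itself; the mean is this package's choice and is recorded
in the grid metadata. Uncovered cells are NaN with coverage 0, never
zero-filled. Overlays are rendered at grid resolution and upscaled
nearest-neighbor so no interpolation invents confidence. The slide summary
assigns each covered cell to its argmax class, reports area fractions, and
calls the tumor class with the largest fraction; when the top two tumor
fractions differ by less than a margin (default 0.1, configurable) the
call is flagged *inconclusive* — an operationalization of the qualitative
oligodendroglioma/astrocytoma confusion seen in practice.

## Synthetic cohort

The generator emulates the statistics an annotated glioma WSI archive
presents to this pipeline, not histology:

* **Texture family** — a marked Poisson point process: blob count
  ~ Poisson(density · area), blob disks in a hematoxylin-like foreground
  color over an eosin-like background, plus Gaussian pixel noise. Chosen
  because class identity must be recoverable from local texture alone
  (tiles carry no spatial context), and because it is seedable and has a
  clean difficulty parameterization. Per-class defaults sketch the
  morphology: glioblastoma hypercellular (high density), oligodendroglioma
  sparse large cells, necrosis nearly acellular and dull.
* **Difficulty** — every numeric texture parameter is interpolated
  linearly toward the across-class mean; at difficulty 1 all classes are
  identically distributed (verified by a KS test), at difficulty 0 a
  linear classifier on channel means exceeds 0.9 balanced accuracy.
* **Geometry** — slides are vertical class strips of whole block columns
  (one block = one tile side), so ROI tile counts have the closed form
  `(2k−1)(2·ny−1)` for a k-column strip at 50 % overlap. Column
  allocation is a greedy quota method in tile space followed by
  single-column hill-climbing on the relative share deviation, so realized
  ground-truth tile shares track the configured imbalance targets (defaults
  mirror an archive training set with ≈18:1 normal:necrosis and ≈43 %
  normal tiles) to within a few percent. An explicit `roi_plan` overrides
  the allocator; plans that cannot tile the slide are rejected.
* **Cohort shape** — 29 slides by default (8 `ac`, 8 `odg`, 12 `gbm`,
  1 normal control), apportioned by largest remainder for other sizes.
* **Partial annotation** — `annotated_fraction` f annotates a
  √f × √f sub-rectangle of each strip (minimum one block), leaving the
  rest as unannotated tissue for pseudo-labeling.
* **Randomness** — one root seed spawns a child stream per slide, so
  cohorts are reproducible slide by slide and byte-identical per
  (config, seed).

What the generator does **not** emulate: nuclear morphology, stain
variation/deconvolution physics, scanner artifacts, pen marks, blurry
regions, or multi-resolution pyramids. Passing tests therefore demonstrate
that the pipeline's bookkeeping, gates, metrics and learning dynamics are
correct, and that pseudo-labeling helps when unannotated tissue is
informative — they do not certify performance on real H&E slides, where
feature quality (the backbone) dominates.

## Problem sizes

The shipped evaluation scale uses 64-px tiles on 512×384-px slides (8×6
blocks), 20-slide cohorts, and 10 training epochs — the geometry is
identical to full scale (only the tile side changes), and one two-step run
completes in well under a minute on a single CPU. The full-scale defaults
(512-px tiles, 29 slides) are the generator's defaults and run the same
code path.

## Numerical choices

* Probabilities clipped to `[1e−12, 1]` inside the loss; softmax uses the
  max-subtraction trick.
* Channel std floored at 1e−6.
* Confidence gate is inclusive (≥); thresholds above 1 are legal and
  retain nothing (used to express "no pseudo-labels").
* Argmax ties (prediction, heatmap cell assignment) resolve to the first
  class in scheme order.
* Tile identity is `(slide_id, x, y, size, augmentation_tag)`; merging
  ground truth with pseudo-labels errors on identity collisions.

## Known limitations

* The default backbone ignores spatial texture beyond a 4×4 color layout;
  classes separable only by fine morphology would need a plugged-in
  convolutional backbone.
* One pseudo-labeling round; no confidence calibration (temperature
  scaling) before gating.
* The grouped validation split is best-effort stratified; with very few
  slides per class it falls back to per-tile stratification.
* Heatmap overlays are single-class red blends; no multi-class composite
  color scheme.
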