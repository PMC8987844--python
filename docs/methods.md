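# Methods

## The chopped-picture method

`tilecover` maps the cover of a yellow-flowering target plant (modelled on
tall goldenrod, *Solidago altissima*) in ordinary RGB field photographs.
Instead of segmenting the image — impractical for dense, amorphous flower
masses — the image is *chopped* into small square tiles of side
`t = 30 px` that overlap 50 % in both directions (stride
`s = t(1 − f) = 15 px`), and a binary classifier labels each tile as
target / non-target.  Tile `(r, c)` is anchored at pixel
`(x, y) = (c·s, r·s)` (0-based, half-open rectangles); trailing pixels
that cannot form a complete tile are dropped, because the classifier
needs fixed-size input.  A full-resolution 5184 × 3888 frame yields
344 × 258 = 88 752 tiles.

Mapping the per-tile calls back onto the image gives a red/green mosaic
of detections, and the fraction of positive cells estimates the plant's
cover — the quantity a surveyor or invasive-species manager actually
wants.

## Training data

Positive material comes from photographs dominated by the target in
flower; negative material from photographs known to contain none of it.
Positive sources carry a size class derived from the pixel length of a
reference object (the primary inflorescence branch): S = 10–50 px,
M = 51–100 px, L = 101–300 px.  These three intervals partition
[10, 300]; when `mix_sizes` is enabled the sampler keeps every size class
represented, so one model sees flowers at all apparent scales.

Positive tiles are screened by the **green-purity rule**: a tile whose
green-foliage pixel fraction is ≥ 0.2 is discarded.  The rule
operationalises the manual curation of "mostly flower" squares with an
HSV predicate: hue ∈ [80°, 170°], S ≥ 0.25, V ≥ 0.15.  The 80° floor
(rather than a floor at the nominal yellow/green border near 70°) leaves
headroom for flower pixels whose hue drifts upward under cool colour
balances; all four parameters are configurable.

Augmentation follows the usual mild recipe for small tiles — horizontal
and vertical shifts (default ±10 % of the tile edge), horizontal flips,
zoom (default ±20 %) — and every tile is rescaled to [0, 1] by dividing
by 255.  Shift and zoom magnitudes are conventional defaults; nothing in
the protocol pins them.

The default split is 80/20 train/validation, stratified by label and
seeded.

## The classifier

A deliberately shallow CNN, adequate because 30-px tiles are decided by
colour and coarse texture:

    Conv(32, 3×3, same, ReLU) → MaxPool(2×2)
    → Conv(64, 3×3, same, ReLU) → MaxPool(2×2)
    → Flatten → Dense(64, ReLU) → Dropout(0.2) → Dense(1, sigmoid)

Zero ("same") padding keeps each convolution's spatial size constant.
Training minimises binary cross-entropy with Adam at learning rate 0.001,
batch size 128, dropout 0.2, 30 epochs by default; the decision threshold
on the sigmoid output is 0.5.  All of these are exposed in `TrainConfig`;
the architecture itself is a JSON-serialisable layer list, so variants
round-trip through persistence.

The network is implemented directly in NumPy (im2col convolutions,
inverted dropout, a standard Adam) — for tiles this small a CPU handles
the default architecture comfortably, and keeping the arithmetic in NumPy
makes training bit-reproducible for a fixed seed, which the test suite
exploits.

## Hard-negative mining (Model 1 → Model 2)

A first-generation model ("Model 1") trained on clean positives and
ordinary negatives fires on look-alikes: sun-lit leaves and non-target
yellow flowers.  Mining runs Model 1 over images known to be target-free,
harvests every tile called positive (a guaranteed false positive), adds
them to the negative *training* class and retrains from scratch
("Model 2").  Harvested tiles never enter the validation split — a
duplicate of a validation tile raises a leakage error — so the two model
generations stay comparable.  One mining round is the default; the
procedure can be iterated.

## Evaluation

Test material follows the pure-cover protocol: images nearly 100 %
covered by the target, and images free of it, are chopped with 50 %
overlap and a fixed number of test tiles (default 500) is sampled.  The
positive share of the sample defaults to 0.5 (the protocol fixes only the
total), so 250 + 250; it is configurable.  From the confusion counts:

    accuracy  = (TP + TN) / n        recall = TP / (TP + FN)
    precision = TP / (TP + FP)
    kappa     = (p_o − p_e) / (1 − p_e),
    p_e = [(TP+FN)(TP+FP) + (TN+FN)(TN+FP)] / n²

Metrics with an empty denominator are reported as explicit `None`
("undefined"), never silently as 0 or NaN.  Note that `p_e = 1` forces
`p_o = 1`, so kappa's 0/0 case cannot occur; the one-class perfect tables
report kappa = 1.

Transferability is the same evaluation run as a matrix: every per-source
model against every source's test set, with the per-model "Average"
column computed as the arithmetic mean of kappa across test sources.

## Coverage estimation and overlays

With 50 % overlap each stride-sized cell lies inside up to four tiles.
Cell probability is the mean over those tiles and the cell call
thresholds that mean; `positive_fraction` = positive cells / cells.
Overlays tint positive cells red and negative cells green, alpha-blended
over the photograph; cells beyond the last full tile footprint stay
untinted.

When the classifier is confident, boundary cells average saturated
probabilities and a 0.5 threshold dilates every detected patch by roughly
one cell, biasing cover upward (worst near 50 % cover, where boundary
length peaks).  `calibrate_cell_threshold` therefore selects the cell
threshold (grid 0.50–0.80, step 0.05) that minimises the mean absolute
cover error on *calibration* scenes whose true masks are known and which
are disjoint from all evaluation material.  The uncalibrated default
stays 0.5.

## Synthetic scenes

The generator renders the data regime the pipeline is built for, with a
per-pixel ground-truth mask:

- **Background**: green foliage with coarse brightness mottle, brown soil
  patches (default 12 % of area), optionally a sky band.
- **Target**: dark-yellow textured elliptical clusters
  (RGB ≈ 200±25, 180±25, 30±20 with dark speckle) whose characteristic
  diameter is the scene's inflorescence length; clusters are added and
  grown radially until the mask reaches the requested cover, so realised
  cover tracks the target within a few percent (enforced to ±0.05 for
  covers 0.1–0.9; covers above 0.95 are rejected as infeasible).
- **Distractors**: "sun-lit leaf" patches — bright warm-yellow
  (215, 195, 55), canopy-scale (25–70 px) so that some tiles are fully
  covered — and small pale non-target flowers (235, 225, 75).  The
  sun-lit colour sits inside the flower colour manifold on purpose: a
  first-generation model reliably fires on it, which is the false-positive
  mode the mining loop exists to fix.  Texture (no speckle), shape and a
  blue-channel offset leave Model 2 enough signal to reject it.
- **Camera emulation**: a per-channel gain/offset applied after sensor
  noise (σ = 4 by default), so two simulated cameras differ by a pure
  colour transform.  The default pair ("warm" gain (1.08, 1.0, 0.9),
  offset (+5, 0, −5); "cool" gain (0.9, 1.0, 1.1), offset (−5, 0, +5)) is
  strong enough to degrade cross-camera transfer but mild enough that the
  green-purity rule still tells foliage from flowers under either
  profile.

Per-tile truth labels call a tile positive when its masked fraction is
≥ 0.5 (configurable).  Scenes are bit-reproducible from their seed; corpus
generation derives per-scene seeds from a root seed.

What the generator does **not** emulate: perspective and scale gradients,
specular highlights, motion blur, JPEG artefacts, within-species colour
variation, and real canopy geometry.  Passing tests on synthetic scenes
therefore demonstrate that the pipeline's machinery is correct and that
its qualitative dynamics (learnability, mining benefit, transfer
degradation, cover recovery) behave as designed — not that any particular
accuracy will be achieved on field photographs.

## Problem sizes and numerical choices

The end-to-end experiments run at desk scale by choice: 200 × 200-px
scenes (144 tiles each at the default chop), corpora of tens of scenes,
roughly 1 000–1 250 tiles per class after sampling, and 3–5 training
epochs — the colour-dominated synthetic task converges within the first
epoch, so longer schedules only polish the boundary.  The full two-camera
experiment (two model generations per camera, mining, transfer matrices,
overlays) completes in a few minutes on one CPU.

Other fixed choices: network weights use Glorot-uniform init and float32
arithmetic; Adam uses β₁ = 0.9, β₂ = 0.999, ε = 1e-7; max-pooling drops
trailing rows/columns; prediction batches are 256 tiles; ties at the
decision threshold (p exactly 0.5) are called positive.  Degenerate
inputs fail loudly: images smaller than one tile yield an empty grid with
a warning, an empty class after filtering raises a dataset error naming
the class, and a test-set request that cannot be filled reports the
shortfall.

## Known limitations

- The purity rule is a colour heuristic; extreme colour balances (beyond
  the default camera profiles) can still push flower hues into its band.
- Cell-threshold calibration requires scenes with known cover, so on real
  imagery it needs reference quadrats or manual annotation of a few
  frames.
- Coverage is estimated at stride-cell resolution (15 px); structures
  finer than a cell are invisible by construction.
- Mining assumes its input images are truly target-free; contaminated
  inputs would poison the negative class.
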