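# Methods

This note records the models implemented in `osteoseg`, the defaults chosen
where the design was genuinely open, and the limits of what the synthetic
phantom study shows.

## Phantom generator (`osteoseg.phantom`)

Each phantom emulates a T1-weighted osteosarcoma slice: an elliptical bright
body (mean 170 gray levels) on a dark background (mean 25), containing a tumor
blob whose mean intensity (120) is deliberately close to the body's, with
Gaussian boundary blur and additive noise (σ = 8).  The tumor outline is an
ellipse (aspect drawn in [0.7, 1]) with optional radial harmonics k = 3..5 of
total relative amplitude ≤ 0.12, giving irregular but star-convex shapes.  The
ground-truth area is the shoelace area of the dense analytic polygon (4096
vertices), so rasterization never biases the reference value; rasterization
uses polygon scan conversion with pixel centers at (i + 0.5)·spacing.

Defaults: 128×128 pixels at 0.5 mm/px, mean tumor radius in [6, 16] mm, blur
σ drawn per slice from [0.6, 2.4] px.  The US/NS (useful vs normal/difficult)
label is synthetic by construction: US iff the tumor-pixel fraction is ≥ 0.08
(about the median for the size range, so the area cue is informative) **and**
the blur σ is ≤ 1.8 px.  Under these defaults roughly 35–40 % of slices are
US.  The label rule is a stand-in — the clinical notion of a "useful" slice is
only described verbally in the source setting — so curation results on
phantoms say that the Mean-Teacher machinery can recover a latent
area+sharpness rule, not that it reproduces radiologists' judgments.

What the phantoms do not emulate: anatomy (bones, muscle compartments), bias
fields, multi-component tumors, partial-volume effects at thick slices, and
plane-dependent appearance (axial/coronal/sagittal are metadata tags only).

The augmentation operator applies identical geometric transforms to image and
mask (90°-step rotations, flips, zoom with nearest-neighbour mask resampling).
Rotations are counter-clockwise on row-major arrays with origin top-left; a
pixel (r, c) of an H×W image maps to (W−1−c, r) under one 90° step.

## Preprocessing (`osteoseg.preprocess`)

The binarization threshold maximizes a weighted between-class scatter

    T = argmax_g  ρ₀·n_{<g}·(μ − μ_{<g})² + ρ₁·n_{≥g}·(μ − μ_{≥g})²,

with ρ₀ = 0.67, ρ₁ = 0.33 (ρ₀ = ρ₁ recovers Otsu's criterion; the asymmetric
weights favour a tight dark class, which suits MRI backgrounds).  The argmax
runs over g = 1..255 with ties broken toward the smallest g; a constant image
is degenerate and returns value+1 with a warning.  Morphological closing
cannot remove isolated *bright* spots, so cleanup is implemented as
small-component removal (default < 9 px, ≈ 3×3) followed by filling of fully
enclosed dark holes.  The credible region is the tight bounding box of the
cleaned body mask, used either as a crop or as a zero-outside stencil;
x is the column axis and y the row axis, inclusive 0-based bounds.

## Curation (`osteoseg.curation`)

ResNet-7 = six residual blocks (3×3 conv–BN–ReLU ×2 with identity or 1×1
projection skip) with 3×3/stride-2 max pooling between blocks, global average
pooling, and a 2-way softmax head.  Default widths (16, 32, 32, 64, 64, 128);
input slices are resampled to 64×64 and per-image standardized.  32×32 input
was rejected: downsampling by 4 erases the boundary-blur cue the NS class
depends on.

Training follows the Mean-Teacher scheme: supervised cross-entropy on the
labeled split plus the symmetrized KL consistency
½KL(P_s‖P_t) + ½KL(P_t‖P_s) on the unlabeled split (implemented exactly in
that form, not as the mixture-based Jensen–Shannon divergence), teacher
updated per optimizer step by θ_t′ = αθ_t + (1−α)θ_s′ with α = 0.99.  Two
choices that the scheme leaves open mattered at desk scale:

- **EMA warm-up.**  A fixed α = 0.99 over the few hundred optimizer steps of
  a desk-scale run leaves the teacher dominated by its random initialization
  (0.99²⁰⁰ ≈ 0.13 of the initial weights).  The update therefore uses the
  standard warm-up α_t = min(1 − 1/(t+1), α): the teacher starts as a plain
  running average and anneals to the slow EMA.
- **Consistency views.**  Student and teacher receive *independently*
  flip-augmented views of each unlabeled batch.  With identical views the
  consistency term degenerates into self-distillation, which at this scale
  entrenches the student's early errors on the unlabeled pool (observed as a
  marked accuracy drop and a drifting US fraction).
- **Teacher targets with batch statistics.**  Early in training the teacher's
  averaged parameters combined with its exponentially averaged batch-norm
  running statistics do not form a working network in inference mode — it
  emits confidently wrong, near-constant targets for several epochs, and the
  consistency loss drags the student toward them.  Consistency targets are
  therefore computed with batch statistics (train-mode batch norm, with the
  running statistics saved and restored so inference stats are unaffected);
  the final US/NS split still uses the teacher in inference mode, whose
  statistics have converged by then.

Cross-entropy is computed from log-softmax logits inside the trainer (the
clipped-probability form has zero gradient wherever the softmax saturates);
the public `ce_loss`/`kl_divergence`/`js_consistency_loss` functions implement
the clipped probability formulas (ε = 1e−7) for reporting and testing.
Label-preserving flips augment the labeled batches.  After training, slices
are split at teacher P(US) ≥ 0.5 and ordered US before NS so a downstream
network sees simple samples first (two-phase curriculum: US-only epochs, then
the full set).

## Segmentation (`osteoseg.sepunet`)

SepUNet: four encoder levels, each a DoubleConv (two 3×3 conv–BN–ReLU)
followed by a SeparableBlock (depthwise 3×3 then pointwise 1×1, BN–ReLU),
with 3×3/stride-2/padding-1 max pooling between levels; a DoubleConv
bottleneck; four decoder levels of bilinear ×2 upsampling, skip concatenation
and DoubleConv; a 1×1 sigmoid head.  A depthwise-separable stage spends
C·9 + C·C′ weights where a plain 3×3 convolution spends 9·C·C′.  Channel
widths are a free knob (base 16 doubling per level by default; base 8 for
desk-scale runs) because the reference architecture's widths are not pinned
by its parameter count alone.  Inputs are reflection-padded to multiples of
16 and un-padded after the forward pass.

Training: Adam on L = 0.5·L_BCE + 0.5·soft-Dice (soft Dice over the batch
during training, hard Dice for reporting; smoothing ε = 1e−6 covers empty
masks).  The learning-rate schedule is the full-scale recipe scaled down:
initial 1e−3, hard drop to 1e−4 at a configurable epoch fraction (200/300 in
the full-scale setting), cosine annealing over the tail.  Test-time rotation
ensembling averages the four back-rotated probability maps with weights
(0.4, 0.2, 0.2, 0.2); the ensemble runs before CRF refinement.

Desk-scale study conditions (used by the tests and the acceptance script):
50 training and 10 held-out phantoms at 64×64/1 mm, base 8 channels,
20 epochs, batch 8 — chosen to exercise the full training loop at a size a
single CPU handles in about two minutes.

## CRF (`osteoseg.crf`)

The refinement stage is a grid CRF whose energy combines unary potentials
−w_u·log p(y_i) from the network probabilities with intensity-modulated Potts
pairwise potentials w_p·exp(−(I_i−I_j)²/2σ²)·[y_i ≠ y_j] over a 4- or
8-connected neighborhood (the neighbor sum runs over ordered pairs, so each
edge is counted from both ends; inference accounts for the factor of two).
The published form of this model is schematic — unary + neighborhood +
normalizer — so the concrete potentials here are a documented choice, not a
reproduction of a specific reference model; a fully connected CRF with
permutohedral filtering is out of scope.  Inference: mean-field (default,
5 iterations, explicitly normalized per pixel) or ICM (raster sweeps, energy
non-increasing, fixed points are local minima).  Defaults w_u = w_p = 1,
σ = 10 gray levels.

## Area (`osteoseg.area`)

Boundary: sub-pixel marching-squares contour of the largest component
(pixel-center convention consistent with the generator), lightly smoothed by
a 5-vertex circular moving average to remove the pixel staircase (which
otherwise inflates arc length by ~5 %), then resampled to uniform 1 mm arc
length.

Smoothing: a bootstrap particle filter over boundary positions.  The process
drift is the step of a low-pass reference path (circular moving average of
the observations) — raw point-to-point increments would re-inject the very
jitter being filtered — plus Gaussian process noise (0.3 mm); observations
are the sampled points with 0.8 mm noise; systematic resampling is followed
by a Metropolis move step to fight degeneracy; one burn-in lap then a
recording lap around the closed curve; posterior means form the output.
Deterministic under its seed.  A circular moving-average smoother is provided
behind the same interface as a deterministic alternative.

Grid: the minimal axis-aligned rectangle of the smoothed curve is tiled by
4 mm cells anchored at its min corner; cells are classified none/partial/full
against the curve polygon (robust geometric predicates).  A full cell
contributes S_c = 16 mm².  For a partial cell, the boundary piece crossing
the cell is expressed as a single-valued function along the axis on which it
is monotone, using Lagrange interpolation on at most 6 of its points (higher
degrees oscillate); the inside-width profile is integrated by the composite
Newton–Cotes rule — 10 panels, each subdivided in quarters, closed 5-point
Boole weights h·(7, 32, 12, 32, 7)/90, exact to degree 5 — over the crossing
span, plus all-or-nothing strips beyond it.  Results are clipped to
[0, S_c], and any cell whose crossing geometry defeats the single-valued
representation (multiple pieces, non-monotone piece, or an interpolant
straying far from the exact clip) falls back to exact polygon clipping and is
counted in the result metadata.  The total is S_os = ΣSᵢ + M₁·S_c.

On clean rasterized disks, ellipses and 3-lobed shapes (0.5 mm/px) the
end-to-end error is below 1 %.  Isotropic spacing is assumed throughout; no
cross-slice volume estimation.

## Pipeline (`osteoseg.pipeline`)

Stage order: preprocess (optional) → rotation-ensemble prediction → credible
region stencil → CRF (optional) → 0.5 threshold → area.  With every optional
stage off the output is exactly the thresholded plain prediction.  One
top-level seed drives the only stochastic stage (the boundary smoother).
Ablation rows base / +crf / +prop mirror the stage toggles on a fixed
evaluation set.  Plane (axial/coronal/sagittal) is carried as metadata only.

## Acceptance script

`scripts/acceptance.py` regenerates every reported number at run time: disk
area recovery (radius 20 mm at 0.5 mm/px), quadrature monomial exactness,
threshold-vs-exhaustive agreement (100 random 16×16 images), the desk-scale
segmentation run (held-out DSC, plain and full-pipeline), its area error on
network output, and the curation recovery run (200 labeled + 100 unlabeled
phantoms).  Problem sizes are the desk-scale study conditions above.
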