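# Methods

This note documents the models and procedures implemented in `capest`, the
choices made where the design space was genuinely open, and what the
synthetic experiments do and do not establish.

## The detection problem

Field images of crop pests (sticky traps, canopy photographs) contain many
small instances: typical relative scales — box area divided by image area —
sit between 0.1% and 1%, several instances per image are common, and a
minority of images are densely populated. Anchor-free single-stage
detectors suit this regime: every feature-grid point predicts class scores,
four boundary distances and a centerness score, so no anchor-shape tuning
is needed for objects tens of pixels across.

## Model

### Coordinate attention (CA)

For a feature map `x` of shape `C x H x W`, directional average pooling
with kernels `(H, 1)` and `(1, W)` yields per-row descriptors
`zh[c, h] = mean_i x[c, h, i]` and per-column descriptors
`zw[c, w] = mean_j x[c, j, w]`. These are concatenated along the spatial
axis, passed through a shared 1x1 bottleneck (C to `ceil(C/r)` channels)
with a ReLU, split back, and restored to C channels by two independent 1x1
transforms. Sigmoids turn the restored maps into row gates `gh` and column
gates `gw`, and the output is `o[c, i, j] = x[c, i, j] * gh[c, i] * gw[c, j]`.
Because each gate lies strictly in (0, 1), the block contracts its input
elementwise; it is differentiable everywhere and cheap (three pointwise
convolutions over pooled vectors).

Open choices and their resolutions:

* the two restore transforms are distinct (`convh` for the row path,
  `convw` for the column path) — a single shared transform cannot produce
  both an `H`-length and a `W`-length gate;
* the intermediate nonlinearity is ReLU (configurable); no normalization
  is inserted after the bottleneck by default (a flag enables a
  trainable-affine batch-norm);
* the reduction ratio defaults to `r = 3.5` with the bottleneck width
  rounded up, i.e. 74 channels at `C = 256`. This is a calibration: one
  block then holds 769·74 + 512 = 57,418 parameters and the three pyramid
  blocks together add 0.17 M, matching the published size delta of this
  detector family. No integer ratio lands in that window (r = 4 gives
  0.15 M, r = 3 gives 0.20 M).

### Coordinate-attention feature pyramid (CAFPN)

The pyramid is the standard top-down construction: 1x1 lateral projections
of the three deepest backbone stages (strides 8, 16, 32) to a uniform
256-channel width, nearest-neighbour 2x up-sampling of the coarser fused
map, elementwise addition, and a 3x3 smoothing convolution after each
fusion. Two extra levels (P6, P7) come from stride-2 3x3 convolutions on
P5, the single-stage convention. With attention enabled, a CA block
modulates the up-sampled map entering each of the two top-down merges, and
a third CA block modulates the projected deepest map that seeds the
pyramid — three blocks in total, one per fused level. With attention
disabled the module reproduces the plain pyramid bit for bit given the
same weights; the ablation switch changes no other code path.

Odd spatial grids (800x600 inputs give 100/50/25-cell levels) are handled
by cropping the up-sampled map to the lateral's exact size.

### Detection head

A shared-weight head runs over all pyramid levels: a classification tower
and a second tower shared by the regression and centerness branches (four
3x3 convolutions each with group normalization at full scale). Distances
are made positive via `exp(scale_l * raw) * stride_l` with one learnable
scalar per level. The classification bias is initialized to the usual
rare-positive prior (`p = 0.01`). Decoding forms `box = (x-l, y-t, x+r,
y+b)` at every point, scores it as `sqrt(p_cls * p_ctr)`, and applies
class-wise greedy NMS (IoU 0.6, score floor 0.05, 100 detections per
image by default). The regression is class-agnostic: a per-class
4C-channel regressor would add millions of parameters for no measurable
gain at these scales.

### Dynamic soft sample weighting

Each ground-truth object is routed to one pyramid level by its longest box
side (desk profile: <24 px to stride 8, 24-48 px to stride 16, the rest to
stride 32; full profile uses the standard 64/128/256/512 ranges). Its
candidate set is that level's grid points inside the box; a box containing
no point adopts the single nearest point. Displacements `d` are measured
from the point to the box center and normalized by the half extent per
axis, so the prior is scale-free across pest sizes.

Positive weights use the learnable category-specific Gaussian prior
`G(d | mu_c, theta_c) = exp(-sum_a (d_a - mu_a)^2 / theta_a^2)`,
normalized to sum to one over each object's candidate set. `mu` (shape
`(C, 2)`, init 0) captures per-class annotation-center offsets; `theta`
(init 1, stored as `exp(rho)` so positivity is unconditional) controls how
many points effectively contribute.

Negative weights are IoU-driven: with `k_i` the maximum IoU between the
point's predicted box and all ground-truth boxes,
`w-_i = 1 - N(1/(1-k_i))` where `N` max-normalizes over the in-box
samples, so the best-IoU sample incurs no negative penalty; points outside
every box keep `w- = 1`. The soft negative weight relaxes only the class
channel of the object(s) containing the location — every other channel
remains a definite negative with weight 1. Without this the classifier is
never pushed down on wrong classes at object locations, and class
confusion dominates (observed directly on the synthetic scenes).

### Losses

Classification: `-w+ ln p - w- ln(1-p)` per (location, class), normalized
by the number of positive samples. Regression: positive-weighted GIoU loss
(robust when a predicted and a target box do not overlap; plain IoU loss
selectable). Centerness: binary cross-entropy against
`sqrt((min(l,r)/max(l,r)) * (min(t,b)/max(t,b)))` at positive samples.
Components are summed with unit weights.

Gradients reach `(mu, theta)` only through the positive weights of the
classification term; the regression copy of `w+` and all negative weights
are treated as constants (a switch flips this). `mu` uses a 3x learning
rate multiplier — its gradients are averages of per-object normalized
weights and run an order of magnitude smaller than conv-weight gradients —
while `rho` keeps the base rate (large steps on a log-spread destabilize
the weight distribution).

## Parameter accounting

`count_parameters` counts trainable scalars only, reproducing the
conventions of public detection frameworks: the backbone stem and first
residual stage are frozen, and in the caffe-style ResNet-50 every
batch-norm affine transform is frozen as well. Under these conventions
the reference configuration (stock 80-category head) holds 32,020,122
trainable parameters (32.02 M) without coordinate attention and
32,192,376 (32.19 M) with it; the 21-class pest configuration holds
31.88 M / 32.06 M. The head's final classification convolution is the
only term that depends on the class count.

## Synthetic scenes

The generator emulates the summary statistics of dense small-pest
datasets, not their appearance: instances are textured ellipses with
class-specific hue and aspect on a smooth textured background. Defaults
(the full-scale conditions): 800x600 images, 21 classes, at least one
instance per image, 20% of images with more than five instances and a
geometric tail reaching past forty, relative scales log-uniform on
[0.0001, 0.01]. Class-frequency weights mimic rare classes; per-class
annotation-center offsets (in box half-extent units) support the prior
recovery study. Placement picks, among eight candidate positions, the one
least overlapped with already-placed instances — physical
non-coincidence — but does not forbid overlap.

The desk profile scales this to 128x128, 4 classes, relative scales
[0.006, 0.1] (boxes roughly 10-40 px, preserving the full-scale
box-to-stride ratios over strides 8-32) and shortens the dense tail
(geometric p = 0.3, so >5 instances in ~20% of scenes but rarely beyond
~15): a 128x128 canvas cannot hold forty 20-px boxes without near-total
occlusion, a regime the full-scale sub-1% setting never enters.

What passing tests on these scenes do show: the assignment, the losses,
the pyramid and the head learn jointly from scratch and localize and
classify dense small objects; the soft-weighting path is differentiable
down to the prior; the evaluation pipeline matches independent references.
What they do not show: robustness to real pest appearance — deformable
bodies, occlusion by foliage, illumination, camera blur, inter-class
visual similarity — nor anything about transfer to photographic data.

## Desk-scale experiments

Training at desk scale uses the same schedule shape as the full-scale
recipe (SGD, momentum 0.9, weight decay 1e-4, x10 lr drops at 2/3 and
11/12 of the run) compressed to 12 epochs over 200 scenes with batch 4,
base lr 0.005, and a 100-iteration linear warmup; held-out evaluation uses
60 scenes. One run takes roughly 50 s on one CPU core. The ablation
compares {CAFPN + dynamic weighting} against {plain FPN + fixed center
sampling} (uniform positives within 1.5 strides of the box center, hard
negatives) over five seeds, by median held-out AP at IoU 0.5 — a
directional check, not a magnitude claim.

The prior recovery study offsets class-0 annotation centers by +0.3 (half
widths) along x, trains on 150 scenes for 12 epochs, and inspects the sign
of the learned `mu[0, x]`. Two details matter and are deliberate:
horizontal flip augmentation is disabled (a flip mirrors the offset and
cancels the asymmetry being probed), and the prior stays detached for the
first 3 epochs so the classifier localizes on the actual objects before
`mu` starts listening to it — without this, `mu` can lock onto early
classifier noise and run away in the wrong direction.

## Numerical choices

* Tensors run in float32 for training; every operation preserves float64
  when given it, which the finite-difference tests use (central
  differences, step 1e-4).
* Probabilities are clamped to [1e-6, 1 - 1e-6] inside log losses; the
  sigmoid is evaluated on the negative half-line only (no overflow).
* IoU denominators carry a 1e-6 floor; zero-area boxes have IoU 0 by
  convention; degenerate ground-truth boxes are excluded from regression
  with a warning.
* NMS ties are broken by stable sort on score, then input order.
* The evaluator reports -1 for any stratum with no ground truth.

## Known limitations

* The backbone is randomly initialized; no pretrained weights are loaded,
  so full-scale (800x600, ResNet-50) training from scratch is possible
  but far beyond desk-scale compute budgets.
* The COCO evaluator is a faithful but compact reimplementation; crowd
  annotations are not supported.
* GFLOPs and frames-per-second are not reported: both are convention- and
  hardware-dependent, unlike the parameter counts.
* The dynamic weighting assumes axis-aligned boxes and a unimodal
  (Gaussian) center prior per class.
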