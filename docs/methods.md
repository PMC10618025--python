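# Methods

This note records the model, the conventions, and the design decisions
behind `spikenet`, in the package's own terms. Everything quantitative
stated here is computed by the test suite or by `scripts/acceptance.py`.

## Problem and model

Wheat spikes in nadir UAV imagery are small (tens of pixels), dense,
elongated and arbitrarily oriented, and their color — and the canopy
background's — changes strongly between the grain-filling stage
(green-dominant) and maturity (golden/red-dominant). A detector trained on
one stage degrades badly on the other. `spikenet` couples two networks
trained jointly end-to-end:

1. **Color-transform front end.** A stride-4 convolutional stem, three
   residual blocks (`out = x + W2·relu(W1·x)`, 16 channels), and a
   channel-attention *domain adapter*: with `avg = GAP(x)`, a softmax branch
   `F2 = softmax(W2 avg)` and a plain branch `F3 = W3 relu(avg)` are
   multiplied into per-channel weights applied to the feature grid. A
   bag-of-visual-words pooling layer then maps the grid to a histogram over
   32 learnable codewords — per-location soft memberships
   `softmax_k(-‖x-Y_k‖/m_k)` averaged over locations (`m_k > 0` kept
   positive by a log-space parameterization) — and a fully connected softmax
   head emits per-band factors `α ∈ Δ²`. The transformed image is
   `I' = clamp(c·α_c·I_c)` per band. Because `Σα = 1` would darken every
   image by ~3x, a fixed rescale constant `c = 3` (config-exposed) makes an
   untrained network approximate the identity. `α` is computed per image,
   not per batch.
2. **Oriented one-stage detector.** A reduced CSP-style backbone (four
   stride-2 stages over a stride-2 stem; widths 16/32/48/64/80 at base
   width 16) with batch normalization throughout, an FPN-style top-down
   neck (width 32), and four 1x1-conv heads at strides 4, 8, 16, 32. The
   stride-4 *micro-scale* head exists for spikes whose long side is below
   ~16 px; switching it off recovers the standard three-layer layout for
   ablation. Each head predicts per cell and anchor: box offsets
   (`center = (2σ(t) - 0.5 + cell)·stride`, `side = (2σ(t))²·anchor`),
   an objectness logit, a class logit (single class, kept for architectural
   fidelity), and `K` angle-class logits.

### Oriented boxes and angles

A box is `(cx, cy, w, h, θ, cls)` with `w ≤ h` (short/long sides) and `θ ∈
[0°, 180°)` the angle of the long side from +x toward +y in image
coordinates (y down). `θ = 180` normalizes to 0; squares keep their stored
angle. Rotated IoU uses exact convex-polygon intersection (shapely).
Angle differences are always circular on the 180°-periodic axis
(`d = min(|p-q|, 180-|p-q|)`); a plain difference would count 179° vs 1° as
178° although the orientations are 2° apart.

### Circular smooth label (CSL)

The angle is classified over `K` bins; the target is a circularly wrapped
Gaussian window `exp(-d²/2σ²)` for circular bin distance `d ≤ β`, zero
outside, so near-miss predictions are only mildly penalized. The library
default is `K = 180, β = 6, σ = β/3` (1° bins; window edge ≈ 0.011); the
desk-scale detector default is `K = 36, β = 2, σ = 0.7` (5° bins), which
keeps the heads small enough for CPU training. Decoding is the argmax bin
center; all-equal scores resolve to bin 0. The angle loss is element-wise
binary cross-entropy against the soft window; note this has an entropy
floor (the BCE of a soft target against itself), which matters when
reasoning about loss limits.

### Target assignment and losses

A ground-truth box is assigned to every (layer, anchor) whose two side
ratios are below the gate (4.0), in its center cell plus up to two nearest
neighbor cells; in crowded scenes where all such slots are taken by other
boxes, the best-ratio free slot is used so every box trains at least one
position. The multi-task loss is

`L = w_loc·CIoU + w_obj·BCE(objectness) + w_cls·BCE(class) + w_ang·BCE(CSL)`

with CIoU = `1 - IoU + l²/d² + γ`, where `l` is the center distance, `d`
the diagonal of the smallest enclosing axis-aligned rectangle and
`γ = v²/((1-IoU)+v)`, `v = (4/π²)(arctan(w_t/h_t) - arctan(w_a/h_a))²` on
(short, long) pairs. The differentiable localization term is evaluated in
the ground-truth box's rotated frame: predicted and target geometry share
the gt angle there, so the IoU reduces to an axis-aligned intersection and
stays differentiable, while orientation itself is learned by the CSL
branch. The general rotated CIoU (`rotgeom.ciou_loss`, enclosing box
axis-aligned in the *image* frame) is the analysis/oracle version; the two
agree exactly on axis-aligned pairs. Objectness targets at assigned
positions are the detached rotated IoU of the currently decoded box (angle
from the CSL argmax) — confidence learns to predict localization quality —
with per-layer balance weights (4, 1, 0.4, 0.1) from stride 4 to 32.
A config switch replaces CIoU by plain `1 - IoU`, changing only the
localization component (ablation hook).

Default component weights follow the common one-stage convention
(0.05, 1.0, 0.5, 0.5); they are config-exposed, and the desk-scale recipe
below re-weights them.

## Tensor engine

The networks run on a small reverse-mode automatic-differentiation engine
over NumPy (`spikenet.nn`): closure-based backward graphs, im2col/col2im
convolutions, batch normalization (batch statistics in training, running
estimates at inference), and SGD with momentum and weight decay. Every
operation's gradient is checked against central finite differences in the
test suite. Float32 is used throughout training.

## Training recipe

The reference hyperparameters are SGD, momentum 0.9, weight decay 1e-3,
batch 16, base learning rate 0.005, cosine decay, 100 epochs — all
config-exposed. Desk-scale runs (the test suite and the acceptance script)
use deliberately small problem sizes so everything trains on one CPU in
minutes: batch 8, 120–250 steps, 20 warmup steps, base learning rate 4.0,
and loss weights (0.3, 2.0, 0.5, 3.0), with the color-transform front end trained at its own, much lower learning rate (0.2) since it has no batch normalization. The much higher learning rate than
the reference is deliberate: with batch normalization, near-zero-initialized
heads (final 1x1 convs scaled by 0.01, objectness bias -4) and only a few
hundred steps, the schedule must traverse most of its progress in its first
hundred steps; constant schedules at this rate diverge, cosine decay does
not. These sizes are the package's desk-scale study conditions, not tuned
per test.

## Synthetic canopy generator

Scenes are 150x150 tiles: low-frequency color blotches plus per-pixel noise
around a stage palette (filling background mean (70, 110, 55), spike
(150, 160, 90); maturity background (150, 130, 70), spike (195, 170, 110);
σ = 12), and a Poisson(25) number of spikes rendered as anti-aliased
ellipses with short awn streaks, long side 12–36 px, aspect 2.5–5, uniform
orientation, pairwise rotated IoU capped at 0.3. Ground truth is each
ellipse's tight rotated rectangle. The two palettes reproduce the
qualitative stage contrast of real canopies (maturity red-shifted ~40–80
gray levels); a one-feature threshold on mean (R-G) separates the stages
almost perfectly, which is exactly the distribution shift the transform
front end must bridge. The generator does **not** model 3-D canopy
structure, cast shadows, motion blur, perspective, or inter-plant
occlusion beyond the IoU cap — passing tests show the method works under a
clean, known color shift, not that it meets any accuracy level on real UAV
imagery.

## Data preparation

roLabelImg XML stores (cx, cy, w, h, angle[rad]) with the w side along the
stored angle; reading converts to the internal convention (sides ordered
short ≤ long, angle rotated 90° when the stored h side is the longer one)
preserving the corner polygon exactly. Tiling center-crops to 300x300 and
cuts 2x2 tiles of 150x150, assigning each box to the tile containing its
center (half-open intervals, so a center on the shared edge goes to the
right/lower tile). The 8x augmentation is the dihedral-4 set {identity,
rot90, rot180, rot270} x {no-flip, hflip}, each followed by "brightness
balance" — gray-world scaling of the mean luminance to 128, the simplest
deterministic illumination normalization. Splits are 7:2:1 by source tile
(all eight variants stay together); group-atomic largest-deficit assignment
makes the split exact to one item whenever group sizes permit. Inputs are
letterboxed 150 -> 160 with gray padding (160 is the smallest multiple of
32 above the tile size; no rescaling, so scale statistics are preserved).

## Evaluation conventions

Matching is greedy in descending confidence at rotated IoU ≥ 0.5 (the
threshold is config-exposed; the field standard is used since no other
value is mandated by the method). AP is the exact area under the monotone
precision envelope of the all-point PR curve. Angle errors (RMSE, MAE in
degrees, circular) pool all matched pairs across images in a single sum;
counting errors (RMSE, rRMSE, MAE) compare per-image detection counts to
labeled counts, with the relative term normalized by the labeled count
(NaN if a labeled count is zero; absolute errors are still reported).
Degenerate conventions: precision = 0 with no detections, recall = 0 with
no ground truth, AP = 0 with no ground truth anywhere; angle errors on
zero matches raise instead of returning 0.

## Numerical choices and tie-breaks

- NMS sorts by confidence, ties broken by smaller input index; detections
  are capped to the top 300 before NMS.
- CSL decode ties resolve to bin 0; `encode` uses a closed window
  (`d ≤ β`), so the support is exactly `2β + 1` bins.
- The box/anchor ratio gate is strict (`< 4.0`); duplicate (layer, cell,
  anchor) slots keep the first assignment.
- Monte-Carlo IoU oracles in the tests use ≥ 10^6 uniform samples over the
  joint bounding box (standard error well below the 0.01 asserted tolerance).
- Tiny epsilons (1e-9 … 1e-12) guard divisions in IoU, BVWP distances and
  batch-norm; they are below every tolerance asserted in tests.

## Known limitations

- At desk scale the jointly trained color transform reliably learns
  *stage-dependent* band factors, but the detection loss does not by itself
  push those factors toward cross-stage alignment: short schedules tend to
  learn per-stage contrast enhancement instead, which can widen rather than
  shrink the filling/maturity band gap. The distribution-shift test in the
  test suite documents this: the alignment effect reported for this
  architecture appears to require full-scale training, and the
  distribution-shift test can fail honestly at minutes-scale schedules.

- The engine is CPU-only and unbatched across processes; problem sizes are
  chosen for minutes-scale runs, far below field-scale training.
- The transform front end learns a *global linear* per-band scale; it
  cannot express spatially varying or nonlinear illumination effects.
- Rotated IoU is exact but scalar-loop based for single pairs; the
  vectorized path covers the training-time bulk work.
- The synthetic generator's realism limits (above) mean accuracy numbers
  here do not transfer to real UAV datasets.
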