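# Methods

This package implements a lightweight one-stage detector for dense
small-target imagery (sticky-trap pest monitoring is the motivating
application), together with the loss functions, profiling utilities,
evaluator and a synthetic scene generator that make every component
testable on a CPU with no external dataset.

## Model family

The detector is assembled from four parts; each is available separately
and the ablation presets combine them with the reference YOLOv8n pieces.

**StarNet backbone.** Four stages of Star Blocks behind a stride-2 stem.
A Star Block mixes spatially with a 7x7 depthwise convolution, expands the
channels with two parallel 1x1 convolutions, multiplies the two branches
element-wise (one passed through ReLU6), projects back with a 1x1
convolution, applies a second depthwise convolution and adds the residual.
Batch normalisation follows the first depthwise convolution and the
projection; ReLU6 is the only activation. Stage *i* downsamples by 2 and
doubles the width, so the stem + stages yield pyramid taps P2/P3/P4/P5 at
strides 4/8/16/32. The `s100` variant uses base width 20, depths
(1, 2, 4, 1) and expansion 4 — the reference demo configuration of the
StarNet family; `s050`/`s150` scale it down/up. Convolutions inside the
backbone carry biases (the reference StarNet convention), unlike the
bias-free conv+BN blocks used elsewhere.

**DCPGAttention.** A channel attention placed at the end of the backbone
(on the P5 tap). Each channel is pooled to its spatial mean and population
standard deviation; a learnable per-channel pair (alpha_mu, alpha_sigma)
contracts the two statistics to a scalar s_c (the small constant xi = 1e-5
is added to each statistic first); the vector s is L2-normalised across
channels and scaled by sqrt(C); the gate multiplies the channel by
1 + tanh(gamma_c * s_hat_c + beta_c). Design choices made here:

* The per-channel embedding weight is a 2-vector (one weight per pooled
  statistic), the minimal reading of a "learnable weighting factor that
  adaptively balances" the two statistics; `shared_alpha` collapses the
  pair to a single weight multiplying mu + sigma.
* The normalisation scale is sqrt(C) rather than C, following the gated
  channel transformation construction this module derives from; `c_scale`
  overrides it.
* Normalisation pools over channels within each batch element, never
  across the batch, so inference is batch-size invariant.
* Initialisation is alpha = 1, gamma = beta = 0, which makes a freshly
  inserted module an exact identity — safe to add to a trained network.
* A module on C channels holds exactly 4C learnable scalars, which is why
  enabling it does not move the two-decimal million-parameter figure.

**Small-Neck.** A bidirectional feature pyramid over P2..P5. Backbone taps
are projected by 1x1 conv+BN laterals to fixed per-level widths
(P2 32, P3 40, P4 80, P5 112 by default — P3/P4 equal the s100 tap widths
and the deep P5 level is pruned below its 160-channel tap, reflecting how
little coarse context matters for small targets). One top-down sweep is
followed by one bottom-up sweep; every node merges its inputs by *fast
normalised fusion*: relu(w_i)-weighted sum divided by sum(relu(w)) + xi
(xi = 1e-4), so coefficients are non-negative and sum to slightly below 1.
Bottom-up nodes at P3/P4 take three inputs (lateral skip, top-down
intermediate, downsampled finer output); the P5 node takes two. Each fused
map passes through a VoVGSCSP block (a cross-stage-partial block whose
bottlenecks are GSConv pairs); resampling uses nearest-neighbour x2
upsampling with a 1x1 GSConv width projection, and stride-2 3x3 GSConv
downsampling. GSConv computes half its output with a dense conv and half
with a 5x5 depthwise conv on that half, then interleaves the two halves by
channel shuffle. An ablation switch replaces all GS blocks with plain 3x3
conv+BN and (with `level_widths=None`) keeps the unpruned tap widths,
giving the plain a-BiFPN variant; pruned and unpruned variants differ only
through the `level_widths`/`pruned_channels` entries of the neck config.
P2 participates in fusion only; detection heads sit on P3/P4/P5.

**Head.** The retained YOLOv8 anchor-free head: per level, a two-conv box
branch ending in a 4 x 16-bin distribution (decoded by softmax
expectation to left/top/right/bottom distances in stride units) and a
two-conv class branch with per-class logits. The 16-entry integral
projection is a fixed buffer, not a learnable parameter.

## Loss functions

For center-form boxes B = (cx, cy, w, h):

* `iou` — intersection over union, per-axis overlaps clamped at zero; a
  zero-area union is defined as IoU 0 with a warning (predicted boxes may
  transiently collapse during training, so degenerate inputs warn rather
  than raise).
* `wiou_distance_penalty` — exp(d^2 / D) with d the center distance and
  D = Wg^2 + Hg^2 from the smallest enclosing box. D is detached from the
  gradient (treated as a constant within each step). The literal
  (Wg + Hg)^2 form is available as `denominator_mode="squared_sum"`;
  the sum-of-squares form with detachment is the default because it is
  the original Wise-IoU construction.
* `wiou_v1` = penalty x (1 - IoU).
* `wiou_v3` = r x v1 with r = beta / (delta * alpha^(beta - delta)),
  beta = (1 - IoU, detached) / running mean of the IoU loss. Defaults
  alpha = 1.9, delta = 3 (the Wise-IoU paper's defaults; no values are
  printed for this model). The running mean is an exponential moving
  average with momentum 0.01, updated once per batch from the batch-mean
  IoU loss, seeded by the first batch, and never differentiated through.
  Batch reduction is the mean of per-box losses after the per-box gain.
* `inner_iou(ratio)` — IoU of the two boxes scaled about their centers by
  ratio in [0.5, 1.5]. ratio < 1 yields auxiliary boxes smaller than the
  originals, which sharpens gradients for high-IoU pairs; ratio > 1 widens
  the effective regression range for low-IoU pairs. The library default is
  0.7; 1.05 is the recommended value for scenes dominated by small, dense
  targets and is what the toy trainer uses.
* `inner_wiou_loss` = wiou_v3 + IoU - inner_iou(ratio). At ratio = 1 the
  correction vanishes and the loss is exactly WIoU v3; at pred = gt the
  loss is identically zero.

Gradient semantics: the focusing gain r and the penalty denominator D are
constants of each step, so finite-difference checks must freeze them; the
test suite's oracle does exactly that and agrees with the autodiff
gradients to ~1e-10 relative error.

## Profiling conventions

Parameters are the exact count of learnable scalars (BN affine weights
included, fixed buffers such as BN running statistics and the DFL
projection excluded). GFLOPs are 2 x convolution multiply-accumulates of
one forward pass at 640 x 640; normalisation, activations, pooling and
resampling count as zero (the fused-model convention under which the
YOLOv8n baseline profiles at ~8.1). The counter runs inside the real
forward pass, so it reflects the executed graph, not a separate
re-derivation. Under these conventions the five presets profile at
3.02 M / 2.39 M / 1.88 M / 1.47 M / 1.47 M parameters and 8.1 / 5.6
GFLOPs for the baseline / full model. The retained-neck widths of the
backbone-swap preset and the Small-Neck level widths are the package's
chosen integration of components whose published description does not pin
every dimension; they were fixed against the published complexity budget
and are exposed in the configs.

## Evaluator

Greedy matching per class and IoU threshold: detections in descending
score order claim the unused ground truth with the highest IoU above the
threshold. AP is 101-point interpolated precision-recall integration per
class; mAP@50 averages classes at IoU 0.5 and mAP@50~95 averages the ten
thresholds 0.5:0.05:0.95. Precision/recall are the dataset-level
TP / (TP + FP) and TP / (TP + FN) at IoU 0.5 over all supplied detections
(so they depend on the caller's confidence cut). Classes with no ground
truths are excluded from the means with a warning; with no detections at
all, precision is reported as 0 by convention. A brute-force matcher in
the test suite reproduces the evaluator exactly over randomized scenes.

## Synthetic scenes

`generate_scene` renders anti-aliased, slightly irregular ellipses on a
smoothly textured beige board. Per-class signatures (colour from a
golden-ratio hue palette, aspect/wobble keyed to the class index) make
classes separable; a configurable fraction of objects is deliberately
placed overlapping a previous object to emulate occlusion; class
frequencies follow a long-tailed power law by default (the motivating
dataset spans three orders of magnitude between its most and least
frequent species). Boxes are computed from the rendered coverage mask, so
they are tight around the visible blob even when clipped at the image
border. Defaults keep objects at 1-6 % of the image side.

What the generator does *not* emulate: photorealistic insect morphology,
within-class appearance variation beyond colour jitter, lighting
gradients, motion blur, or the label noise of real trap imagery. Passing
tests therefore demonstrate that the architecture, losses, training loop
and evaluator are implemented correctly and can fit legible data — not
that the model reaches any particular accuracy on real pest datasets.

Augmentations: flips and 90-degree rotation remap boxes exactly;
translations fill with the background median and drop boxes retaining
less than 20 % of their area (the drop rule is this package's choice);
mosaic tiles four scenes around a randomized center with per-quadrant
affine box remapping and the same 20 % drop rule; mixup blends pixels
convexly and takes the union of the two annotation lists (the standard
detection-style reading — blending classification labels has no box
analogue).

## Toy training

`train_toy` is deliberately simple: center-cell assignment (each ground
truth goes to the coarsest head level whose 4 x stride window covers its
longer side, at the cell containing its center), binary cross-entropy on
the class map normalised by the number of positives, and the Inner-WIoU
loss (ratio 1.05) on the decoded boxes at positive cells; SGD with
momentum 0.9 and weight decay 5e-4. It is not the full training recipe of
a production detector (no task-aligned assignment, no mosaic/mixup in the
loop, no cosine schedule) — it exists to demonstrate end-to-end
differentiability and that the loss actually trains a detector.

Problem sizes were chosen for a single CPU: the `toy` preset (StarNet base
width 12, depths (1,1,1,1), expansion 3, neck widths 16/24/32/48, reg_max
8, ~0.33 M parameters) trains on 200 synthetic 160 x 160 scenes with 3
classes, objects at 5-15 % of the image side, mean 6 objects per scene and
long-tailed frequencies (0.6/0.3/0.1). Thirty epochs at learning rate 0.05
take a few minutes and lift held-out mAP@50 from ~0 by well over 30
points; runs are bit-reproducible per seed. The object scale here is larger than
the generator's 1-6 % default: at 160-pixel resolution the default scale
leaves 2-9-pixel blobs whose boxes cannot be localised at IoU 0.5 by any
30-epoch CPU run, so the smoke test uses legible object sizes while the
generator's defaults keep the harder study conditions.

## Numerical choices and limitations

* Arrays are float32 in the network path; box-loss tests run in float64.
* The population (divide-by-HW) standard deviation in the attention pool
  adds 1e-12 under the square root to keep the gradient finite on exactly
  constant channels.
* IoU is clamped to [0, 1] after division to absorb float round-off on
  identical boxes.
* Max pooling breaks ties by first index; nearest-neighbour upsampling
  backpropagates by 2x2 block summation.
* BN uses momentum 0.03 running statistics; training-mode forward
  differentiates through batch statistics.
* The gate multiplier lies in the open interval (0, 2) mathematically;
  under float32 saturation tanh can reach exactly +-1, so extreme
  parameters can touch the closed bounds.
* Convolutions support dense and depthwise groups only — the set the
  architecture family actually uses.
* Model serialisation is a JSON-config + NPZ-weights archive with
  round-trip forward parity; it is a native format of this package, not
  an interchange format.
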