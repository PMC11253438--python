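# Methods

This note records the model as implemented, the parameters that matter, the
numerical choices made where the design was genuinely open, and what the
synthetic data can and cannot show.

## Detection model

The detector is a set-prediction network: a fixed set of Q learnable
queries jointly predicts class distributions over {field ridge, single
barnyard grass plant, barnyard grass patch, no-object} and normalized
(cx, cy, w, h) boxes.  Training assigns ground truths to queries by
minimum-cost bipartite matching (scipy's Hungarian solver) over a cost
λ_cls·(−p(class)) + λ_l1·‖b−b̂‖₁ + λ_giou·(−GIoU); matched queries receive
cross-entropy, L1 and GIoU losses, unmatched ones a cross-entropy toward
no-object down-weighted by 0.1.  Defaults λ_cls = 1, λ_l1 = 5, λ_giou = 2
follow the established DETR recipe, as does auxiliary supervision after
every decoder layer with shared heads.

### Backbone

The architecture's constraints fix only the pyramid: s3/s4/s5 at strides
8/16/32 with 128/256/512 channels for a 640 input.  The backbone behind it
is a compact residual CNN — stem of two stride-2 3×3 convolutions, then
three stages of one stride-2 downsampling convolution plus `depth`
(default 2) residual blocks — with a 1×1 projection at each tap.  Inputs
must be divisible by 32; the pyramid invariant then holds at any size.

### Hybrid encoder

* Transformer branch (on s5): tokens are the row-major flattening of the
  grid plus a fixed 2-D sinusoidal positional encoding (half the channels
  encode rows, half columns), followed by `layers` (default 1) blocks of
  cascaded group attention and a feed-forward of ratio `ffn_ratio`.  Zero
  layers degenerate to the identity.
* Cascaded group attention: C channels are split contiguously across h
  heads; head j attends over its split plus the previous head's output;
  per-head Q/K dimension defaults to the split width C/h and the V
  dimension equals the split width so the concatenation restores C.
  Attention logits are scaled by 1/√key_dim.  The head count for the
  512-channel branch defaults to 8.
* Dilated branch (on s3): three parallel 3×3 convolutions with dilations
  (6, 12, 18) and same-padding d, each BN+ReLU with a 1×1 residual
  projection, all at 80 channels; concatenation (240) is fused to 80 by a
  1×1 convolution.  The branch output y2 is then expanded 80 → 256 by a
  final 1×1 convolution so fusion arithmetic closes; the expansion can be
  disabled (`expand_output=False`), in which case y2 keeps the fused width.
* Cross-scale fusion: 1×1 lateral on y1 (512→256) → 2× nearest upsample →
  add 1×1(s4) → 3×3 conv → 2× upsample → concatenate with y2 (512) → 3×3
  conv keeping 512.  This is the minimal top-down pathway reproducing the
  target shapes; inputs must have spatial ratios 1:2:4.

### Partial convolution

`PConv2d` convolves a contiguous slab of c_p = r·c channels (first or last;
default first, r = 1/4) and passes the remaining channels through
bit-identically.  Analytics: FLOPs h·w·k²·c_p² (ratio r² to dense), memory
access h·w·2c_p + k²·c_p² (ratio ≈ r when h·w ≫ k²·c_p).  A factory swaps
PConv into any stride-1, channel-preserving 3×3 position when the
`use_pconv` flag is on; channel-changing or strided convolutions stay
dense, and no 1×1 mixing convolution is appended after a PConv.  Toggling
the flag never changes an output shape.

### Decoder

Standard transformer decoder: query self-attention, cross-attention over
the flattened y3 grid plus sinusoidal positional encoding, feed-forward;
depth 6 and Q = 100 by default, with a `memory_stride` knob to subsample
cross-attention tokens.  Class head is a linear + softmax over 4 classes;
the box head is a 3-layer MLP with sigmoid output.

Two choices here departed from the most common reference wiring, both for
trainability under the modest step counts this package targets:

* **Pre-norm residual blocks** (encoder and decoder).  With post-norm
  blocks, LayerNorm repeatedly renormalises the residual stream and the
  per-query identity carried by the query embeddings decays; under plain
  SGD the decoder then collapses to identical outputs for every query (a
  stable equilibrium, since query identity re-enters only through attention
  weights).  Pre-norm keeps the identity path unnormalised and eliminates
  the collapse.
* **Decoder state seeded with the query embedding** rather than zeros, so
  each query's identity flows through the value path from layer 1.

## Training

`TrainConfig` defaults are the reference settings: SGD, base learning rate
0.001, momentum 0.9, weight decay 1e-4, batch 4, 500 iterations, learning
rate decayed as base_lr·(1 − iter/max_iterations)^p with floor 0.  The
decay exponent p is not fixed by those settings; the conventional p = 0.9
is the default and is exposed in the config.  Gradient clipping at global
norm 0.1 (the DETR convention) is on by default and disableable
(`grad_clip=0`).  "Iterations" are optimizer steps taken literally; with
14k-image datasets 500 steps is a schedule, not an epoch count, so the
loop simply samples seeded batches per step.

An `optimizer="adam"` option exists because set-prediction heads are, in
our experiments, untrainable by plain SGD within a few hundred steps at
any learning rate: the model settles into predicting the per-class mean
box (cross-attention stays near uniform, so no localisation signal flows),
and escaping that equilibrium is precisely the slow phase that reference
DETR implementations spend hundreds of epochs of AdamW on.  Adaptive
per-parameter steps break the equilibrium quickly; SGD remains the
default.

### Desk-scale preset

`paddydetr.presets` defines the configuration used by the end-to-end
learning checks: a quarter-width model (pyramid 32/64/128, one residual
block per stage, 1 encoder layer, 3 decoder layers, 12 queries), 32
synthetic 128-px scenes with one object each (classes cycling), and
full-batch Adam at 3e-3 with the polynomial decay, 300 iterations, no
clipping.  This trains in ~4 minutes on one CPU and reaches a training-set
mAP50 of ~0.86.  The preset exists to verify that matching, losses and
gradients genuinely teach the model to detect; it makes no claim about
field-scale accuracy.

## Synthetic scenes

`generate_scene` renders: a green canvas with a periodic darker row-stripe
(row-crop texture) and Gaussian pixel noise; full-width brown ridge bands;
large dark elliptical patches; and small bright elliptical single plants
whose centres are rejected from ridge bands (single plants grow between
ridges — the positional cue the detector can exploit).  Placement is
rejection sampling with a retry budget; shortfalls are reported in
`meta["placement_failures"]`.  Annotation boxes are the tight bounding
boxes of the rendered masks.  Default size ranges on the 600-px canvas put
single plants in the COCO small/medium strata (side 12–90 px) and patches
(120–300 px) and ridges (full width × 30–60 px) in the large stratum.

What the generator does *not* emulate: occlusion between rice and weed,
the visual similarity of barnyard grass to rice (synthetic classes are
colour-separable), illumination variation, orthomosaic stitching
artefacts, and realistic object-count distributions.  Passing tests
therefore demonstrate correctness of the pipeline and learnability of
well-separated targets, not field-level accuracy.

## Data pipeline

* Coordinates are 0-based, half-open, (x, y) = (column, row), matching the
  COCO convention the evaluator uses.
* Tiling cuts non-overlapping tile×tile sub-images; border remainders are
  dropped.  Annotations are reassigned to every tile they intersect and
  clipped; a clipped box is discarded if it keeps < 25% of its area or a
  side < 4 px.  The same clip policy is reused by the random-crop augment.
* Augmentation is exactly fourfold: the original plus three transforms
  drawn without replacement from {random crop re-padded to size, HSV
  colour jitter, additive Gaussian noise, rotation by 90°/180°/270° with
  exact box remapping}, all seeded.
* The 7:2:1 split takes floor(n·r/Σr) for validation and test and gives
  the remainder to training (deterministic, maximises training data).
* All randomness flows from one master seed via derived per-stage seeds.

## Evaluation

The COCO protocol is used throughout: per-class greedy matching in
descending score order (ties broken by detection index), 101-point
interpolated AP, size strata on ground-truth box area with boundaries 32²
and 96² (small ≤ 32² < medium ≤ 96² < large), AP/AR averaged over IoU
0.50:0.05:0.95, AR at up to 100 detections per image, and ignore semantics
for out-of-stratum boxes.  The fixed operating point filters detections at
score ≥ 0.5 and matches at IoU ≥ 0.5.  Undefined quantities are sentinels:
precision with an empty prediction set is NaN, an empty stratum reports
−1, and classes absent from the ground truth are excluded from the mAP50
mean.  The pooled PR curve sweeps score thresholds and integrates by
trapezoid over recall, anchored at recall 0 with the highest-threshold
precision.  A 1e-10 tolerance guards recall-grid lookups against float
rounding at exact fractions.

## Known limitations

* The numpy engine is single-device and eager; full-width training at
  640-px inputs is out of reach on CPU (a full-size forward pass takes
  seconds) — the package's training claims are desk-scale only.
* The backbone is a stand-in satisfying the published pyramid shapes; no
  pretrained weights exist, so absolute accuracies are not comparable to
  GPU-trained systems.
* Eq-level cost models count multiply-accumulates symbolically; they are
  not wall-clock predictions.
* The evaluator is validated against an independent in-repo
  reimplementation of the COCO protocol, not against an external binary.
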