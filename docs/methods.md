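# Methods

## The model

`vesselseg` implements a retinal-vessel segmentation network that combines a
four-stage Transformer front end with a convolutional U-Net, connected in
series.  The input is not a whole fundus photograph but a 64×64 patch of the
preprocessed image together with its 32/16/8 downsampled companions (a
`PatchPyramid`); the output is a per-pixel vessel probability map at 64×64.

**Transformer stages.** Stage 1 embeds the 64×64 patch with a 3×3
convolutional stem to 32 channels and runs one TPA block.  Stages 2–4 halve
the side and double the channels with a patch-embedding operator — written
as `x' = Proj(BN(x))` with `Proj` a 3×3 stride-2 convolution, gated by
`Sigmoid(Conv3×3(x')) · x'` — then fuse in a 1×1-projected copy of the
matching pyramid level (concatenate + 1×1 fuse) and run their own TPA
blocks.  The channel schedule is 32/64/128/256 over sides 64/32/16/8.

**TPA block.** Each block applies, in order:

1. a *positional-encoding gate*: `Sigmoid(DepthwiseConv3×3(x)) · x`;
2. *TMSA* — multi-head self-attention in which queries come from the full
   token grid while keys/values come from a map reduced by a stride-`s`
   convolution with layer norm (`s` = 8/4/2/1 per stage, heads 1/2/4/8).
   The per-head logit stack `Q·Kᵀ/√d_k` is mixed across the head axis by a
   learned 1×1 convolution before the softmax over keys; the context is
   layer-normed, linearly projected, and added residually, followed by a
   residual feed-forward network (expansion 4) on layer-normed tokens;
3. *criss-cross position attention*, applied twice with one shared set of
   1×1 projections: each pixel attends to the H+W−1 positions in its own
   row and column (the pixel itself counted once — the duplicate row slot
   is masked before the softmax), aggregates the value map, and adds the
   input residually.  One pass propagates along rows and columns; the
   second pass reaches every pixel pair, which the tests verify by checking
   that the gradient of every output pixel with respect to every input
   pixel is nonzero.

**CNN encoder/decoder.** Each stage output feeds a feature-extraction (FE)
block: 1×1 reduction to half the output width, parallel 3×3 convolution and
3×3 transposed convolution, concatenation, 1×1 bottleneck, batch norm,
ReLU, and a residual add of the (1×1-projected) input.  Downsampling (DS)
blocks — adaptive average pooling to half the side, batch norm, ReLU, 3×3
convolution — chain the encoder levels.  (The description of the DS module
as three consecutive batch normalizations collapses to a single affine map;
one norm is the default and a literal three-norm mode is available via
`ds_triple_norm`.)  All four FE outputs are average-pooled to 8×8,
concatenated, and fused by 1×1 convolution (shallow-information fusion);
a pyramid-pooling module (grids 1/2/3/6, one 1×1 conv per branch, bilinear
upsampling, concat + 1×1 fuse) expands the receptive field; a final DS
block halves the result to 4×4.  Four decoder blocks (bilinear ×2 upsample,
1×1 channel alignment, **additive** skip from the matching FE output, FE
refinement) restore 64×64, and a 1×1 convolution + sigmoid yields the
probability map.  The head uses a *small-head initialization*: its weights
are scaled down by 10× and its bias starts at the logit of the vessel
prior (0.1).  Dice-only training is prone to saturated all-foreground or
all-background fixed points when early logits overshoot (the sigmoid's
derivative vanishes there and the loss cannot recover); keeping the
initial output near the prior with low-variance logits keeps gradients
alive and makes short training runs reproducible across seeds.

**Reference configuration.** One TPA block per stage, heads 1/2/4/8,
spatial reduction 8/4/2/1, FFN expansion 4, shared-weight double
criss-cross, additive skips, pyramid-pooling grids 1/2/3/6, decoder widths
608/576/512/480.  This totals 11 824 853 trainable parameters (11.8 M).
The decoder widths are the calibrated quantity: with the FE design above, a
decoder that simply mirrors the encoder (256/128/64/32) gives ~5.3 M
parameters, so the decoder carries the remaining capacity in a descending
schedule.  The desk profile used by the tests keeps the same topology at
channels 8/16/32/64 with decoder 64/32/16/8 (~334 k parameters).

## Numerical engine

The network runs on a small reverse-mode autodiff engine written on numpy
(`vesselseg.nn`): tensors record a dynamic graph; convolution is im2col +
einsum with a col2im adjoint; adaptive pooling follows the floor/ceil
region convention; bilinear resizing is a pair of constant interpolation
matrices (so its adjoint is exact); batch/layer norm are composed from
primitive ops.  Every spatial primitive is verified against central finite
differences in the test suite.  The default dtype is float64; training
loops switch to float32 for speed.  The optimizer is Adam at the protocol's
initial learning rate 0.001 (optional global-norm gradient clipping is
available but off by default — Adam's update is nearly invariant to
uniform gradient rescaling, so clipping buys little here).  All computation
is plain numpy on one CPU and fully deterministic given the seeds.

## Preprocessing

Fuse R/G/B with weights 0.299/0.587/0.114 (the dominant weight on green,
which carries vessel contrast; the weights must sum to 1), standardize
per-image and min–max rescale to [0, 1], apply CLAHE (scikit-image
`equalize_adapthist`, clip limit 0.02 in its [0, 1] convention, 8×8 tile
grid), then gamma-correct with γ = 1.2.  Patches are extracted either at
uniformly random origins whose patch center lies inside the field of view
(training) or on a stride-32 grid covering every pixel (inference); the
pyramid levels are exact 2×2 average poolings of the 64×64 base.
Whole-image probability maps are reassembled by averaging overlapping patch
predictions.  Coordinates are 0-based, row-major, half-open.

## Training protocol

Random patches are cut from the training images (200 per image at full
scale, 10 in the desk profile), 10% held out for validation; the model is
optimized against the Dice loss `1 − (2Σpg + w)/(Σp + Σg + w)` with
smoothing `w = 1e−5`, batch 32 (desk: 8), and the checkpoint with the best
validation soft Dice is kept.  After the best weights are restored, one
cumulative-average pass over the training patches re-estimates the
batch-norm running statistics; with short runs the exponentially averaged
statistics otherwise lag the final weights and depress evaluation scores.
Evaluation tiles each image on a stride-32 grid, stitches, thresholds at
0.5 (0.48 in the leave-one-out protocol), and computes Dice, accuracy,
sensitivity, specificity and precision from the confusion matrix inside
the field of view, plus trapezoidal ROC and precision–recall areas.
"Training Dice" for an overfit run means the pooled hard Dice over all
training-patch pixels — the quantity the Dice loss itself optimizes.

The leave-one-out protocol follows the study's STARE variant literally:
fold *i* trains on sample *i* alone and tests on the remaining *n − 1*
images; the conventional train-on-rest variant is available behind a flag.

## Synthetic data

The generator emulates the features the pipeline depends on: branching
curvilinear vessels occupying ~10% of a circular field of view (radius
0.48 × side) with widths tapering within 1–5 px, drawn as disk
cross-sections along random walks rooted near an off-center optic-disc
location, with a per-step branch probability of 0.025; growth stops just
below the target density so the seed-averaged vessel fraction lands on
target.  Rendering places vessels ~45% darker than the background in the
green channel, adds a smooth radial illumination fall-off and zero-mean
Gaussian noise (σ = 8 intensity levels), and sets pixels outside the FOV
near-black.  What it does **not** emulate: lesions (exudates,
hemorrhages), the optic disc and macula as image structures, central
vessel reflexes, JPEG artifacts, or inter-image color variation.  Passing
the learning tests therefore demonstrates that the architecture, losses
and pipeline are implemented coherently and can learn vessel morphology
from realistic geometry — not that the printed benchmark numbers on DRIVE,
STARE or CHASE DB1 would be reproduced; those require the real datasets
and GPU-scale training and are out of scope here.

## Problem sizes in the test suite

The suite trains only the desk-profile network: an overfit run (8 patches
from one 128×128 synthetic image, 200 optimizer steps, full-batch) and a
small generalization study (5 training images × 10 patches, 3 held-out
images, 3 seeds, 100 optimizer steps per seed at an effective batch of 32
via gradient accumulation).  These sizes were chosen so the whole suite
runs in minutes on one CPU while still exercising every architectural
component end to end.  Longer desk-scale runs improve both scores —
the overfit run crosses Dice 0.9 at roughly 300 steps, and converged
generalization runs (200 effective-batch-32 steps, several times the
suite's step budget) reach held-out Dice ≈ 0.70 on inits that avoid the
degenerate basin — so the short-budget numbers measure the training
dynamics at these problem sizes, not the architecture's capacity.

## Design choices on genuinely open points

- The patch-embedding equations are not shape-consistent if read as
  elementwise products throughout; the implementation applies the stride-2
  projection to the batch-normed input and gates the result (see above).
  The projection kernel size is configurable (`proj_kernel`, default 3).
- The criss-cross set size is H+W−1 (row ∪ column, self counted once).
- The two criss-cross passes share projection weights (recurrent
  application), keeping the block light.
- Stage-1 tokenization (unspecified): 3×3 convolutional stem.
- Multi-scale injection merge (unspecified): concat + 1×1 fuse.
- Encoder–decoder skips are additive, not concatenative.
- The bottom sits at the deepest FE output (8×8) so all pyramid-pooling
  grids up to 6 are legal; the fourth DS block then halves it to 4×4
  before the decoder.
- Optimizer (unstated): Adam, no schedule; validation split 10%.

## Known limitations

- Pure-numpy training is orders of magnitude slower than a GPU framework;
  the full-size profile is provided and correct but is only practical for
  parameter counting and small forward passes on CPU.
- Dice-only training on very small patch sets is chaotic: microscopic
  perturbations (even floating-point summation order) can flip a run
  between a good minimum and a degenerate saturated one.  The small-head
  initialization and batch-norm re-estimation are the stabilizers used;
  they make the outcome reproducible but convergence at very short step
  budgets remains slower than at full scale.
- CLAHE clip limits follow scikit-image's [0, 1] convention, not OpenCV's.
- The STARE-style leave-one-out trains on a single image per fold by
  design, which is statistically weak; it is implemented as specified for
  protocol fidelity.
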