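# Methods

`secotr` implements a single-stage instance-segmentation network for
low-contrast ("green-on-green") fruit imagery, together with the synthetic
scene generator, training loop and evaluation stack needed to exercise it
end to end.  This note records the model, its assumptions, the numerical
choices, and what the synthetic benchmark does and does not demonstrate.

## Network

The network predicts instance masks directly, without a box-detection
stage:

1. **Backbone + FPN.**  An inverted-residual (MobileNetV2-style) backbone
   (expand 1×1 → depthwise 3×3 → project 1×1, residual at stride 1) feeds
   a top-down feature pyramid with levels P2–P5 at strides 4/8/16/32 and a
   uniform channel width C.  Normalisation is GroupNorm throughout: it is
   batch-size independent, which makes small-batch CPU training exactly
   reproducible (`norm_kind` is configurable).  No pretrained weights are
   used; initialisation is fan-out Kaiming from a seeded generator.
2. **Coordinate transformer (COTR).**  P5 is pooled to an N×N patch grid,
   a learned positional embedding is added once, and k pre-norm
   transformer layers are applied in which the token-mixing step is
   *coordinate attention* rather than pairwise self-attention: each
   channel is mean-pooled along rows and columns, the two directional
   summaries are jointly encoded through a shared 1×1 transform with
   reduction ratio r and a hard-swish nonlinearity, split, and mapped to
   sigmoid gates g^h (per row) and g^w (per column) that re-weight the
   input multiplicatively, y_c(i,j) = x_c(i,j)·g^h_c(i)·g^w_c(j).  The
   width gate is indexed by the width coordinate; both gates lie in (0,1),
   so the block can only attenuate.  Each residual branch carries a
   per-channel learned scale (initialised at 1); zeroing the scales makes
   a layer an exact identity, which the composition tests exploit.  The
   final grid is emitted both as flattened sequence features and, resized
   bilinearly to P5's spatial size, as the refined P5 consumed by JPU.
3. **Joint pyramid upsampling (JPU).**  P2–P4 from the FPN and refined P5
   from COTR are projected to a common width, upsampled bilinearly
   (×2/×4/×8) to stride 4, concatenated, and read by four parallel
   depthwise-separable 3×3 convolutions with dilation rates 1/2/4/8; their
   concatenation is reduced to the unified mask feature F at (H/4, W/4).
   Masks are later upsampled to full image resolution at decode time, so
   the stride-4 internal resolution and the full-resolution output are
   consistent.
4. **Function heads.**  Each prediction level is pooled to its own N×N
   grid (per-level positional embedding) and three *shared* linear heads
   emit, per cell: a dynamic-convolution kernel (D = γ²·C_mask values), M
   class logits, and 4 box-edge offsets.  The class-head bias starts at
   −log((1−π)/π) with π = 0.01 so the focal loss sees a realistic
   foreground prior; head weights use a small-std (0.01) init, without
   which the initial loss is dominated by random logits and SGD diverges.
5. **Mask decoding.**  Each cell's kernel is reshaped to (C_mask, γ, γ)
   and convolved with F (a per-pixel dot product when γ = 1), giving one
   mask-logit channel per cell.  At inference, cells with class
   probability above 0.1 become candidates; masks are binarised at 0.5;
   scores are multiplied by the mean in-mask confidence ("maskness");
   Matrix NMS decays duplicates (gaussian mode, σ = 2); survivors above
   the keep threshold 0.5 are truncated to the top 100 per image.

## Training objective and label assignment

An instance is routed to the level(s) whose sqrt-area range contains
√area.  Within a level, cells overlapping the shrunken center region (box
center ± ε·half-extent, ε = 0.2) whose own centers lie inside the box are
positive; sub-cell instances fall back to the single cell containing the
box center, and when instances compete for a cell the smaller wins
(assignment runs largest-first and overwrites).  Box targets are
offsets from the cell's projected coordinate to the box edges, normalised
by stride×8 and clamped at 0; mask targets are the instance mask resampled
to stride 4 (bilinear, threshold 0.5, strongest pixel kept if the
resampled mask would vanish, so every positive cell supervises a nonempty
mask).

The loss is L = L_focal + L_smoothL1 + 3·L_dice.  Focal loss uses
α = 0.25, γ = 2, summed over all cells and divided by the positive count;
α = 1 disables the class weighting, making the γ = 0 case plain BCE.
Dice uses the squared-denominator dialect with ε = 1e−6.  Optimisation is
SGD with momentum 0.9 and weight decay 1e−4; full-scale defaults are lr
0.0025, batch 8, 24 epochs with ×0.1 steps at epochs 16 and 22.  Two
standard stabilisers are always on: linear LR warmup (from 10% of lr) and
global-norm gradient clipping at 10 — without them the box branch can blow
up within the first tens of iterations at usable learning rates.

## Numerical substrate

The differentiable core (`secotr.nn`) is a compact reverse-mode autograd
engine on float32 NumPy arrays: convolution by kernel-tap decomposition
(dense and depthwise, strided/dilated), bilinear resizing and adaptive
average pooling expressed as fixed row/column mixing matrices, Group/Layer
norm, and SGD.  Every primitive is verified against central finite
differences in the test suite.  Float64 tensors are supported for the loss
closed-form checks; mask IoU is always computed in float64 because exact
threshold boundary cases (e.g. IoU = 252/280 = 0.9) otherwise flip under
float32 rounding.

## Synthetic orchard scenes

The generator emulates the conditions that make green-fruit segmentation
hard: elliptical fruits whose mean colour differs from the local canopy by
at most `contrast_delta` per channel (default 25/255 — hue-matched, small
lightness offset), three size strata with a configurable mix, bounded
pairwise overlap at placement (IoU ≤ 0.25), and leaf-shaped occluders
drawn over the fruit layer and carved out of the masks, so ground truth is
always the visible region.  Scenes are 600×400 by default (the nominal
capture resolution) with 3–8 fruits; the scale mix defaults to
0.3/0.5/0.2 small/medium/large, a medium-dominant mix typical of orchard
imagery at that working distance.  Area strata follow the COCO convention
(32², 96²) scaled by image area relative to the 600×400 reference.
Determinism: scene i of a config is a pure function of (config.seed, i).

What the generator does **not** model: photorealistic shading and texture
of real canopies, specular droplets, motion blur, perspective-correlated
fruit size, or labeling noise.  Passing tests therefore demonstrate that
the architecture, losses, assignment and metrics are implemented
correctly and can fit and generalise within this family of scenes — not
field performance on real orchard photographs.

## Desk-scale configuration and the learning check

`tiny_model_config()`/`tiny_scene_config()` shrink the pipeline to CPU
scale while preserving every structural element: 128×128 scenes with 1–3
fruits, a reduced-depth backbone, 32-channel pyramid, one COTR layer
(r = 4, 4×4 grid on P5), heads on P3/P4 with grids 12/8, γ = 1
(~0.13 M parameters).  The learning check trains this model for 300 SGD
iterations (batch 4, lr 0.01) on 64 generated scenes and evaluates mask AP
on 16 held-out scenes; the smoothed loss halves and AP at IoU 0.5 exceeds
0.5 in most seeds (the acceptance suite requires 2 of 3).  These problem
sizes were chosen so a full train-evaluate cycle takes about two minutes
per seed on one CPU core.

## Evaluation

Matching is greedy on mask IoU, highest score first, one match per ground
truth.  AP at a threshold is the 101-point interpolated area under the
precision–recall curve (precision envelope sampled at recalls 0, 0.01, …,
1); mAP averages the ten thresholds 0.50–0.95.  Scale-stratified mAP
restricts ground truth to an area band, ignoring detections matched to
out-of-band ground truth and unmatched detections whose own area is out of
band.  With no ground truth in a stratum the AP is reported as 0 and the
stratum is flagged `undefined` rather than excluded.  P/R/F1 are reported
at IoU 0.5 over the decoder's final detection set.  The evaluator is
cross-checked in the tests against an independently written straight-line
AP implementation on randomized fixtures.

## Known limitations

- Dense convolution supports groups ∈ {1, C} only — all this architecture
  needs, but not general grouped convolution.
- Polygon-mode COCO serialisation cannot represent interior holes
  (occluded fruits can have them); RLE mode is the default and is
  bit-exact.
- Training is single-process CPU; there is no multi-device path, mixed
  precision, or pretraining support.
- The full-scale (256-channel, four-level, k = 3) configuration is wired
  and shape-tested but not trained anywhere in the repository; trained
  results shown are desk-scale.
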