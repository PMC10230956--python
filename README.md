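# secotr

Single-stage instance segmentation for **low-contrast fruit imagery** —
the "green-on-green" problem where immature fruit is nearly the same
colour as the surrounding canopy, fruits overlap, and foliage occludes
them.  The package is aimed at researchers in agricultural machine vision
who need a segmentation-by-location pipeline that runs, trains and
evaluates end to end on CPU, with every numerical component unit-tested
against independent oracles.

Because no public green-fruit dataset ships with the package, a
procedural **synthetic orchard generator** stands in for field data: it
renders elliptical low-chroma fruits on textured green backgrounds with
occluding foliage and exact visible-region ground truth, and reads/writes
standard COCO JSON.

## Model

The network segments instances directly, without a box-detection stage:

- **MobileNetV2-style backbone + FPN** → multi-scale features P2–P5 at
  strides 4/8/16/32.
- **Coordinate transformer (COTR)** on P5: N×N patch grid + positional
  embedding, k transformer layers whose mixing step is *coordinate
  attention*:

      z_c(h) = (1/W) Σ_i x_c(h,i),        z_c(w) = (1/H) Σ_j x_c(j,w)
      f      = δ(F₁([z_h, z_w]))
      g_h    = σ(F_h(f_h)),   g_w = σ(F_w(f_w))
      y_c(i,j) = x_c(i,j) · g_h_c(i) · g_w_c(j)

- **Joint pyramid upsampling (JPU)**: P2–P4 and the refined P5 are
  projected, upsampled to stride 4, concatenated, and read by four
  parallel separable convolutions with dilation rates 1/2/4/8, producing
  the unified mask feature F at (H/4, W/4).
- **Function heads** (shared linear layers on per-level patch grids)
  predict per cell: a dynamic-convolution kernel (D = γ²·C_mask), class
  scores, and box offsets.
- **Mask decoding**: Z = F ∗ K gives one mask channel per grid cell;
  duplicates are resolved by **Matrix NMS** (score decay by pairwise mask
  IoU), keeping the top 100 detections per image.

Training uses focal loss (classification), smooth-L1 (boxes) and dice
(masks) under SGD with momentum.  Evaluation reports P/R/F1 and COCO-style
mAP over mask-IoU thresholds 0.50–0.95, including scale-stratified
mAP_S/M/L.  The deep-learning substrate is a compact, finite-difference-
verified reverse-mode autograd core on NumPy (`secotr.nn`).

## Worked example

Generate scenes, train the desk-scale model for 300 iterations, and
evaluate on held-out scenes (about four minutes on one CPU core):

```python
from secotr.model import SECOTR, tiny_model_config
from secotr.synthetic import tiny_scene_config, build_dataset
from secotr.train import TrainConfig, train, evaluate_run

train_ds, val_ds = build_dataset(tiny_scene_config(seed=11), 80, 0.8)
model = SECOTR(tiny_model_config(), seed=1)
train(model, train_ds, TrainConfig.tiny(seed=1, iterations=300), "run/")
print(evaluate_run(model, val_ds).summary())
```

Output from this exact run:

```
TP=19 FP=4 FN=13
P=0.8261 R=0.5938 F1=0.6909
mAP=0.3042  AP50=0.5577  AP75=0.3709
mAP_S=0.0000 mAP_M=0.1084 mAP_L=0.3656
```

Reading it: on 16 held-out 128-px scenes the freshly trained model finds
60% of the fruits (R = 0.59) with most of its detections correct
(P = 0.83); AP at the permissive IoU 0.5 threshold is 0.56, while the
strict-overlap average over thresholds 0.50–0.95 (mAP = 0.30) is much
lower — typical of a short CPU training run.  Large fruits are segmented
far better than small ones (mAP_L vs mAP_S), the same ordering field-scale
models show.

The same pipeline is scriptable from the shell:

```
secotr synth --n-images 80 --seed 0 --out data/
secotr train --seed 0 --out run/
secotr demo --checkpoint run/checkpoint.npz --image data/val/scene_00001.png --out overlay.png
```

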