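# croprow

Crop-row perception for agricultural machine vision: a lightweight semantic
segmentation network that separates crop rows from soil/weed background, and
a geometric pipeline that turns the resulting binary masks into per-row
navigation lines a field robot or high-clearance sprayer can steer by.

The package is aimed at researchers and engineers working on vision-based
guidance in row crops (maize at the 3–5 leaf stage is the motivating case),
who need a testable, CPU-friendly reference implementation of the full
image → mask → line chain, including a synthetic field-scene generator so
every stage can be exercised without field data.

## What is inside

**Segmentation (SAC-DeepLabV3+).** An encoder–decoder network:

* *Encoder*: MobileNetV2 inverted-residual backbone in which each 3×3
  depthwise convolution is replaced by a **split-attention convolution
  (SAC)** — `radix` parallel depthwise branches re-weighted by softmax
  attention computed from a globally pooled descriptor. The deep branch runs
  at output stride 16; a shallow tap at stride 4 feeds the decoder.
* *Head*: **DenseASPP + strip pooling.** Dilated 3×3 convolutions at rates
  d ∈ {3, 6, 12, 18, 24}, densely connected so branch *l* consumes
  `[y_{l-1}, …, y_0, x]`, plus horizontal and vertical strip pooling for
  long-range row context, fused by a 1×1 convolution.
* *Decoder*: shallow features (1×1-projected) are concatenated with the 4×
  upsampled head output, refined by **CBAM**
  (`M_c = σ(MLP(AvgPool F) + MLP(MaxPool F))`, then
  `M_s = σ(conv[AvgPool; MaxPool])`), compressed by two 3×3 convolutions and
  upsampled 4× to the input size.

The full configuration holds **8.24 M trainable parameters**, and the four
ablation presets `A` → `A+B` → `A+B+C` → `A+B+C+D` (backbone only, +SAC,
+DenseASPP/SP, +CBAM) have strictly increasing counts
(6.08 < 7.00 < 8.23 < 8.24 M).

Training minimises `L_total = L_focal + L_dice` with
`L_focal = −α_t (1−p_t)^γ log p_t` (γ = 2, α = 0.25) and the soft Dice loss
`1 − 2|A∩B|/(|A|+|B|)`, under Adam (β₁ = 0.9, lr 10⁻³ cosine-annealed to
10⁻⁵, decoupled weight decay 5·10⁻⁴, batch 8, 50 epochs). Evaluation uses
the binary confusion matrix: IoU/mIoU, precision, recall, mPA, f1 (= Dice
for hard masks) and overall accuracy.

The network, its autodiff and its optimiser are implemented in
`croprow.nn`, a compact numpy-based reverse-mode autodiff library that ships
with the package — the whole stack runs on a plain CPU with no deep-learning
framework.

**Navigation-line extraction.** From a binary mask: per-band
connected-component representatives are clustered by **DBSCAN** on their
x-coordinates (eps 30 px, min_samples 5) into row instances; instances are
vertically closed; **anchor points** are sampled at 10 equidistant heights
as mask-moment centroids; missing heights are repaired from the nearest
valid anchor (up–down search); a seeded **RANSAC** (K = 100, inlier
threshold T = 5 px, minimum 10 inliers) fits `ax + by + c = 0` per row with
a total-least-squares refit, followed by a spatial-consistency filter. The
middle three rows are returned with left/middle/right labels.

**Evaluation of lines.** Angle deviation (degrees), horizontal distance
deviation (pixels, averaged over sampling heights) and anchor-point fitting
accuracy, summarised as mean ± std per row position.

**Synthetic scenes.** `croprow.synthfield` renders seeded field scenes —
quasi-parallel rows of lobed plant canopies (straight or curved), missing
seedlings, weed clutter (image only, never mask), illumination gradients —
with exact ground-truth centerlines, at a default scale of 2 px/cm
(60 cm row spacing → 120 px).

## Worked example

```python
import numpy as np
from croprow import synthfield, navline, naveval

cfg = synthfield.SceneConfig(n_rows=5, image_width=640, row_spacing=120, seed=7)
scene = synthfield.generate_scene(cfg)
print("mask foreground px:", int(scene.mask.sum()))
lines = navline.extract_navigation_lines(scene.mask, seed=0)
for nl in lines:
    truth = min(scene.rows, key=lambda r: abs(r.x_at(np.array([256.0]))[0]
                                              - nl.line.x_at([256.0])[0]))
    t = navline.LineModel(*truth.centerline)
    print(f"{nl.label:>6}: a={nl.line.a:+.4f} b={nl.line.b:+.4f} "
          f"c={nl.line.c:+8.2f}  inliers={nl.line.inlier_count}  "
          f"angle_dev={naveval.angle_deviation(nl.line, t):.3f} deg")
```

prints

```
mask foreground px: 36101
  left: a=+1.0000 b=-0.0004 c= -199.36  inliers=10  angle_dev=0.024 deg
middle: a=+1.0000 b=+0.0006 c= -319.67  inliers=10  angle_dev=0.034 deg
 right: a=+1.0000 b=+0.0022 c= -440.32  inliers=10  angle_dev=0.128 deg
```

i.e. on a five-row scene the pipeline keeps the middle three rows, every
anchor of every row is a RANSAC inlier, and each fitted line is within
0.13° of its generating centerline (`a ≈ 1, b ≈ 0` — near-vertical rows;
`−c` is the row's x-intercept in pixels).

The same stack is available as sklearn-style estimators
(`CropRowSegmenter(...).fit(X, y).predict(X)`,
`NavigationLineExtractor(...).transform(masks)`) and as a CLI:

```bash
croprow synth -n 20 --seed 1 -o scenes/
croprow train --scenes scenes/ --preset desk --epochs 30 -o run/
croprow segment --checkpoint run/best.npz --images scenes/ -o pred/
croprow navline --masks pred/ -o lines/
croprow eval-nav --lines lines/ --truth scenes/ -o nav_report.csv
```

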