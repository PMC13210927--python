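# Methods

This note records the modelling assumptions, parameter choices and numerical
conventions behind `croprow`, and what the synthetic experiments do and do
not demonstrate.

## Problem setting

Vision-guided field machinery needs the image-plane centerlines of the crop
rows ahead of it. The package decomposes the problem in the standard way:
(1) binary semantic segmentation of crop-row canopy vs everything else
(soil, stones, shadows, weeds), and (2) geometric extraction of one straight
reference line per row from the mask. All geometry is in image coordinates
(0-based, x rightward, y downward); no camera calibration or ground-plane
projection is attempted.

## Segmentation network

**Backbone.** MobileNetV2 with the canonical stage schedule
(t, c, n, s) = (1,16,1,1), (6,24,2,2), (6,32,3,2), (6,64,4,2), (6,96,3,1),
(6,160,3,2), (6,320,1,1), a 3×3 stride-2 stem (32 channels) and a closing
1×1 convolution to 1280 channels. The deep branch is capped at output
stride 16: stride-2 stages past that point run at stride 1 with doubled
dilation. The shallow decoder tap is taken after the 24-channel stage
(output stride 4), the standard low-level feature choice for this decoder
family. Batch normalisation + ReLU6 follow every convolution except
attention-logit layers.

**Split-attention convolution (SAC).** Each bottleneck's depthwise 3×3 is
replaced by `radix` parallel depthwise 3×3 branches. Branch outputs are
summed, globally average-pooled, passed through a bottleneck MLP
(1×1 conv → BN → ReLU → 1×1 conv) and reshaped to per-branch logits; a
softmax across the radix axis yields the recombination weights. Defaults:
radix 2, cardinality 1, attention bottleneck width `C / reduction` with
reduction 16. The reduction value was fixed by closed-form parameter
arithmetic: with 16, enabling SAC adds ≈ 0.93 M parameters across the
backbone, consistent with the ~1 M increment the architecture is budgeted
for; smaller reductions inflate the attention MLPs several-fold. With
radix 1 the softmax is identically one and the block reduces to a plain
depthwise path (unit-tested).

**DenseASPP + strip pooling head.** Five dilated 3×3 branches at rates
3/6/12/18/24; branch *l* consumes the channel concatenation of the head
input and all previous branch outputs (so its input width is
`1280 + l·growth`). Each branch is a 1×1 bottleneck (width 320 = input/4)
followed by the dilated 3×3 producing `growth = 64` channels. Two strip
branches pool the head input along full rows / full columns, project 1×1 to
64 channels and broadcast back — row crops are long, thin, axis-aligned
structures, which is exactly the context strip pooling captures. Everything
is fused by a 1×1 convolution to 256 channels. The bottleneck width is the
one genuinely free width in the design; 320 places the complete network at
8.24 M trainable parameters, matching the ~8.35 M budget of the full
configuration within ~1.3%.

**Ablation presets.** `A` = backbone + plain ASPP (1×1 reduction to 256,
then 1×1/three dilated 3×3/image-pooling branches, rates 6/12/18), no SAC,
no CBAM; `A+B` adds SAC; `A+B+C` swaps the head for DenseASPP+SP; `A+B+C+D`
adds CBAM. The plain-ASPP fallback reduces 1280 → 256 *before* the pyramid
so that the dense head is strictly larger than the fallback and the
parameter ordering across presets is strictly monotone (6.08 < 7.00 < 8.23
< 8.24 M).

**CBAM.** Channel attention with a shared MLP (reduction 16) over global
average- and max-pooled descriptors, then spatial attention from a 7×7
convolution over the channel-wise mean and max maps; both sigmoid-gated and
applied multiplicatively, channel first. It sits on the decoder's merged
(256 + 48 = 304 channel) features.

**Numerical engine.** The network, losses and optimiser run on
`croprow.nn`, a small reverse-mode autodiff library over numpy float32
arrays (im2col convolutions, a shift-and-add depthwise kernel, exact-adjoint
sparse-matrix bilinear resizing, standard batch-norm backward). Explicit
float64 inputs are preserved end-to-end, which is how the loss formulas are
validated against closed forms at 1e-9 tolerances. Gradients of every op
are checked against central finite differences in the test suite. Forward
passes in evaluation mode are deterministic; a single seed fixes weight
initialisation, batch shuffling and RANSAC sampling.

## Losses and metrics

`L_total = L_focal + L_dice`, unweighted. Focal: mean over pixels of
`−α_t (1−p_t)^γ log p_t`, γ = 2 and α = 0.25 by default (standard focal-loss
practice; the exponent and weight are config-exposed), with `p_t` clamped at
1e-7 before the logarithm. Dice uses the soft (probability) formulation
during training with smoothing ε = 1e-6 against empty masks, and the hard
argmax formulation in evaluation. Evaluation metrics are all derived from
the binary confusion matrix; mIoU and mPA average the two classes with the
background treated symmetrically (TN as its TP). Degenerate 0/0 ratios are
reported as 1 when the class is absent from both prediction and truth, else
0, and flagged. Overall accuracy, listed among the metrics without a
defining equation in the source material, is implemented as
`(TP+TN)/total`.

## Training recipe

Adam with β₁ = 0.9 (the "momentum factor" — Adam has no classical momentum,
so the first-moment coefficient is the natural reading), initial learning
rate 1e-3, cosine-annealed to 1e-5 over the epoch budget, decoupled weight
decay 5e-4, batch size 8, 50 epochs. Linear batch-size scaling of the
initial rate is exposed (`scale_lr_with_batch`) but off by default, since
the exact coupling rule is a free choice. The best-by-validation-loss
weights are kept. A weight-loading hook (`load_state_dict` /
`load_checkpoint`) supports warm-starting from pretrained weights; none
ship with the package.

## Navigation-line pipeline

* **Clustering.** The mask is cut into 20 equal-height bands; per band,
  connected components are reduced to centroid representatives, and DBSCAN
  (eps 30 px, min_samples 5) clusters the pooled representatives on their
  x-coordinate alone — the 1-D reading of "density of the x-coordinate".
  Running DBSCAN on representatives rather than raw pixels keeps
  min_samples meaningful (any canopy blob would trivially satisfy it at
  pixel level). Noise representatives are discarded; component pixels
  inherit their representative's cluster, so instances are exactly disjoint.
* **Repair of broken rows.** Each instance mask is closed with a vertical
  1×15 px structuring element. Canny edges (σ = 1) are stored per instance
  as boundary diagnostics only; centroids come from mask moments.
* **Anchors.** 10 equidistant bands; anchor x is the zeroth/first-moment
  centroid of the instance slice, anchor y the band center. Bands with
  fewer than 12 foreground pixels are treated as missing: a few edge pixels
  of a lobed canopy otherwise produce centroids many pixels off the row
  axis, and because the RANSAC minimum-inlier gate equals the anchor count,
  one such sliver can suppress an entire row. Missing bands are repaired by
  copying the x of the nearest valid anchor in |Δy| (ties toward smaller
  y), so every fitted row has exactly 10 anchors.
* **RANSAC.** K = 100 seeded two-point samples, perpendicular-distance
  inlier test at T = 5 px (strict), best model kept only if it reaches
  Min = 10 inliers; coincident samples are redrawn without consuming the
  iteration. The best inlier set is refit by total least squares (the minor
  principal axis of the centred points) — orthogonal regression is the
  right least-squares notion for a general line `ax+by+c=0` when rows are
  near-vertical. Inliers are re-audited against the refit line so the
  stored set always satisfies the distance bound. Coefficients are
  normalised to a² + b² = 1 with a canonical sign (a > 0, or b > 0 when
  a = 0).
* **Consistency filter.** Inliers are ordered by their projection along the
  line; a point whose gap to the previously retained point exceeds 3× the
  median inter-anchor gap is dropped, with a refit when anything was
  removed. Fewer than 3 inliers: no meaningful gap statistic, returned
  unchanged.
* **Row selection.** Instances ranked by mean x; the middle three are kept
  and labelled left/middle/right.

Curved rows are fitted with straight lines all the same — the consistency
filter retains the dominant straight segment — so curved-scene accuracy is
intrinsically lower; that trade-off is inherited from the line model.

## Line-quality measures

Angle deviation is the acute angle between direction vectors,
`arccos |d₁·d₂|`, symmetric and invariant to coefficient-sign flips.
Horizontal deviation is `mean_y |x_pred(y) − x_truth(y)|` over the anchor
sampling heights (an averaged rather than single-height reading, documented
here because either is defensible); horizontal lines are rejected by name.
Anchor fitting accuracy is the fraction of anchors within tol = 5 px
(the RANSAC threshold, the only stated pixel tolerance) of the line.
Summaries are sample means and (n−1)-denominator standard deviations per
row position; positions with a single entry report std 0 and are flagged.

## Synthetic scenes: what they emulate and what they do not

The generator emulates the *structure* of early-season row-crop imagery:
several quasi-parallel rows (straight, or curved via
`x(y) = x0 + s·y + curvature·(y − H/2)²`), per-plant lobed canopies (3–6
cosine lobes, ±10–25% radial perturbation, mild anisotropy) so centroid
extraction never sees idealised discs, Bernoulli missing seedlings, Poisson
weed clutter drawn into the image only (weeds are background by the
labelling convention; they are rendered paler and yellower than crop
canopies, as young weeds typically read), soil noise and a horizontal
multiplicative illumination gradient. The default scale is 2 px/cm — the
agronomic 60 cm row spacing and 28 cm plant spacing become 120 px and
56 px — since no px/cm scale is derivable without a camera model.
Row slope jitter defaults to 0 and is set to ±0.03–0.05 in the experiments,
matching near-vertical rows under a forward-facing camera.

It does **not** emulate perspective foreshortening, soil texture statistics,
canopy overlap between adjacent plants of *different* rows, specular
lighting, or motion blur. Consequently, passing tests demonstrate that the
implementation is correct and that the geometry pipeline is robust to the
modelled degradations (gaps, weeds, illumination, outlier anchors); they do
not certify field-image segmentation accuracy, which depends on training
data the package does not ship.

## Experiment scales

The test suite and the worked examples run at desk scale on one CPU: the
line-recovery experiments use 100 seeded 384×384 scenes with three rows at
110 px spacing; the learnability run trains a width-0.35 variant of the
network (≈ 0.97 M parameters, `NetConfig.desk_scale()`) for 30 epochs on 20
scenes at 128×128 and evaluates foreground IoU on 5 held-out scenes. These
sizes are the package's chosen demonstration scales; the full-size network
(8.24 M parameters) is instantiated and audited for parameter accounting
and shape contracts, and can be trained with the same code on real data.

## Known limitations

* Straight-line row model only; curvature handling is selection, not
  fitting.
* Binary (crop-row vs background) segmentation; no multi-class support.
* The DBSCAN stage clusters on x alone, so rows that cross in x (sharp
  curves, lens distortion) can merge.
* Inference timing from `measure_inference_time` is hardware-dependent
  diagnostics, not a performance claim; the numpy engine is far slower than
  a GPU framework.
* `min_anchor_support` (12 px) and the vertical closing kernel (1×15 px)
  assume roughly 512-px-scale imagery; rescale them with the input.
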