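# Methods

## Problem and model

`immunoaizer` implements a semi-supervised adversarial framework for
predicting per-pixel cellular-biomarker class maps from H&E-like RGB
patches, together with the downstream machinery that makes such maps
useful: patch preparation, macro-averaged evaluation metrics,
tumor-infiltrating-lymphocyte (TIL) and PD-1 quantification, and a
multilabel classifier for tumor gene mutation status (APC, TP53, KRAS).

Four classes are used throughout: 0 background, 1 PanCK-positive tumor,
2 CD3/CD20-positive TIL (the two lymphocyte markers are merged into one
TIL class), 3 DAPI nuclei.

### Segmentation objective

The generator S maps an H x W x 3 patch to a probability map S(X) of shape
H x W x C. A fully convolutional discriminator D maps a class-probability
map to a per-pixel confidence in [0, 1] scoring how ground-truth-like the
map looks. The generator minimizes

    L_seg = L_ce + lambda_adv * L_adv + lambda_semi * L_semi

with

* `L_ce = -sum_{h,w,c} Y[h,w,c] log S(X)[h,w,c]` — multiclass cross
  entropy against the one-hot mask Y (labeled data only);
* `L_adv = -sum_{h,w} log D(S(X))[h,w]` — rewards predictions the
  discriminator cannot tell from ground truth;
* `L_semi = -sum_{h,w,c} I(D(S(X)) > T_semi) Yhat[h,w,c] log S(X)[h,w,c]`
  — self-training on unlabeled data with argmax pseudo-labels `Yhat`,
  restricted to the "trustworthy region" where the confidence exceeds
  `T_semi`.

The discriminator minimizes the spatial real/fake cross entropy
`-sum_{h,w} [log(1 - D(S(X))) + log D(Y)]`.

Defaults: `lambda_adv` = 0.01 (labeled) / 0.001 (unlabeled),
`lambda_semi` = 0.1, `T_semi` = 0.5. All losses are written as pixel sums,
exactly as the objective is defined; the trainers use an optional
per-pixel-mean reduction (the default in the schedules) so that gradient
scale does not depend on patch resolution.

Design choices where the objective is ambiguous, all flagged in code:

* The adversarial expression is minimized as printed (the generator
  "fools" the discriminator by pushing confidences toward 1).
* `L_semi` applies to unlabeled batches only — pseudo-labels are redundant
  where ground truth exists. A `semi_on_labeled` flag restores the literal
  three-term objective.
* Logs are epsilon-clamped at 1e-8; clamped pixels receive zero gradient.
* Argmax ties (in pseudo-labels and in map compression) resolve to the
  lowest class index.

## Networks

No deep-learning framework is used: `immunoaizer.nn` is a small,
deterministic numpy layer stack (im2col convolutions, batch norm, max/avg
pooling, bilinear resize, channel softmax) with hand-written backprop and
SGD/Adam/RMSprop optimizers. Parameter initialization is Kaiming-normal
from an explicit seed, so builders are pure functions of (config, seed).
Gradient correctness is established in the test suite by central finite
differences on every layer type.

* **Generator** — encoder-decoder: 3x3 conv stem, first max-pool, two
  residual blocks, an inception-style stage (parallel 1x1, factorized
  1x3+3x1, double 3x3 and pooled branches), a second pooling level with
  further inception stages, and a 1x1 "promotion" stage that widens the
  representation; the decoder upsamples bilinearly and concatenates the
  encoder features at each scale (U-Net-style skips), ending in a 1x1 conv
  and per-pixel softmax. Inception-block internals follow the standard
  Inception-V3 topologies; widths scale with a single `width_multiplier`.
* **Discriminator** — five 4x4 stride-2 convolutions with channels
  64/128/256/512/1 (scaled by the width multiplier), batch norm + leaky
  ReLU after the first four, bilinear upsampling back to the input size,
  sigmoid squash. Normalizing the single-channel score of the fifth layer
  before the squash would be pathological, so the fifth convolution is
  left bare — a deliberate deviation recorded here.
* **Mutation classifier** — inputs are centered to [-0.5, 0.5]; a 1x1
  color-projection stem (which gives global average pooling a direct path
  to per-class color-fraction features) feeds three stride-2 conv/BN/ReLU
  stages, global average pooling and two fully connected layers ending in
  three independent sigmoids; the penultimate FC activations are exported
  as patch embeddings for external visualization (e.g. t-SNE). A plain
  small CNN is used at desk scale in place of channel-shuffle units; the
  head (per-label sigmoid + mean binary cross entropy) is what makes the
  classifier multilabel.

The `tiny` preset (width multiplier 0.125, 64 x 64 inputs) takes a
forward+backward step in well under a second on one CPU core.

## Training schedules

Reference recipe, kept as the defaults of `SemiSupSchedule`: batch 8;
generator lr 1e-3, discriminator lr 1e-6; Adam with beta1 = 0.9 and
additive L2 weight decay 1e-8; 10,000 generator-only warmup steps, then
300,000 joint steps with the self-training term activated at step 100,000.
`SemiSupSchedule.scaled(f)` multiplies the three step counts by `f`,
preserving phase proportions. The mutation classifier uses RMSprop
(lr 0.01, momentum 0.9, weight decay 1e-8), 100 epochs, batch 16, also as
defaults.

Per joint step: (a) the discriminator updates on the (prediction, one-hot
truth) pair from a labeled batch; (b) the generator updates on the labeled
batch; (c) after activation, the generator additionally updates on an
unlabeled batch, where the confidence map only gates the pseudo-label mask
(the indicator has zero gradient). The discriminator sees labeled-batch
pairs only. Warmup is cross-entropy-only; the activation step is counted
on the global step index. Batches are drawn with replacement from
counter-seeded streams, labeled and unlabeled streams kept separate, which
gives the exact reduction property: with all adversarial/self-training
weights at zero, the semi-supervised trainer reproduces the supervised
trainer parameter-for-parameter.

Desk-scale presets used by the benchmarks in this repository (chosen once
as the smallest sizes at which the learning signal is unambiguous):
supervised benchmark 50 labeled 64 x 64 scenes, 300 steps; paired
semi-supervised comparison 20 labeled + 200 unlabeled scenes, schedule
30/150/60, 3 seeds; mutation benchmark 900 patches (800 train / 100
test), 20 epochs at learning rate 1e-3 — the reference rate of 0.01 is
tuned for a much larger network and destabilizes the tiny preset, so the
desk presets lower it while the schedule defaults keep the reference
value.

## Metrics

Per-class one-vs-rest confusion counts give IoU = TP/(TP+FP+FN),
Dice = 2TP/(2TP+FP+FN), precision = TP/(TP+FP), recall = TP/(TP+FN),
macro-averaged over classes. A class absent from both prediction and truth
is excluded from the macro average (0/0 carries no information); a class
present in exactly one scores 0. "Accuracy" is overall pixel accuracy
(micro), documented as an interpretation since headline accuracy figures
in this literature rarely state a formula. Evaluation pools one global
confusion table over all test pixels by default; a per-patch averaging
mode is provided since either aggregation is defensible.

AUC is computed by the tie-aware Mann-Whitney rank statistic (exact
probability of correct ranking, ties worth one half), not by integrating a
binned curve; ROC points come from scikit-learn.

## Synthetic data: what it emulates and what it does not

`synthetic.generate_scene` paints axis-aligned elliptical "cell regions"
(2-5 blobs per foreground class, radii 4-10 px on a 64 x 64 canvas, later
blobs overwriting earlier ones in a shuffled z-order) over a bright
background, then colors each pixel with its class's mean RGB (an H&E-like
palette) plus Gaussian noise (sigma 0.04) clipped to [0, 1]. The config
validator enforces pairwise class-mean separation of at least three noise
sigmas in some channel, which guarantees the segmentation task is
learnable from color alone; nearest-palette-color classification recovers
at least 95% of mask labels under the defaults. Fluorescence masks light up
connected target-class regions with a given probability (plus an
off-target rate), and never touch background. Mutation labels are planted
as thresholded patch statistics — nearest-palette class fractions with
thresholds at 0.10, near the median of each statistic under the default
scene so both polarities are common — optionally flipped with probability
`flip_noise`. Statistics are evaluated on the emitted image (not the
mask), so labels are exactly recomputable from a patch at any noise level.

What passing these benchmarks shows: the losses, schedule mechanics,
filters, metrics and quantification arithmetic are correct, and the
training loop extracts a planted signal that is genuinely present. What it
does not show: performance on real H&E tissue. Real slides have stain
variability, texture (the synthetic classes differ in color only),
occlusion, cell-scale structure and annotation noise that the generator
deliberately omits; no photorealistic or stain-physics simulation is
attempted.

## Quantification

Quantification is pixel-based, not cell-instance-based: class pixel
fractions are the stated proxy for the cell percentages that commercial
nucleus-anchored pipelines report, since nucleus detection is out of
scope. PD-1-expressing TILs are counted as predicted-TIL pixels
intersecting the binarized fluorescence mask; both denominators (TIL
pixels and all non-background pixels) are reported because either
normalization of a "positive cell percentage" is plausible. Fluorescence
binarization offers Otsu and fixed thresholds; a constant image is an
explicit degenerate case (all-zero mask, warning). Pearson correlation
(with the t-distribution p value, n-2 df) is provided for comparing
fraction series; zero-variance input raises.

## Patch pipeline choices

* Color normalization is Reinhard-style mean/std matching in CIELAB, with
  the reference statistics supplied explicitly; a zero-variance channel is
  degenerate and returns the patch unchanged with a warning. The interface
  is pluggable for stain-deconvolution variants.
* Background on mask-free patches is grayscale luminance > 0.8
  (configurable), the usual whole-slide-tile convention; on masks it is
  class 0. The semi-supervised filter keeps background fraction
  strictly < 0.5; tumor-patch selection requires argmax-PanCK area
  strictly > 0.5 — both boundaries are strict as printed, and tested at
  exactly 0.50.
* Tiling is row-major with 0-based half-open origins; edge remainders
  smaller than the tile are dropped rather than padded.
* Augmentation is the 8 dihedral transforms with small seeded HSV jitter
  (mask-safe by construction).

## Numerical and degenerate-input conventions

Float64 throughout; epsilon clamps at 1e-8 inside logs; argmax ties to
the lowest index; max-pool ties to the first window slot; bilinear resize
uses the half-pixel-center convention; batch-norm epsilon 1e-5 with
momentum 0.1 running statistics. Empty inputs, single-polarity label
columns, constant images and zero denominators are all explicit error,
warning or `None` paths rather than silent NaNs.

## Known limitations

* Pixel-level quantification ignores cell instances; fractions are not
  cell counts.
* The numpy backend is single-threaded BLAS-bound and meant for desk-scale
  presets, not full-resolution (512 x 512, width 1.0) training.
* The synthetic task is color-separable by design; it validates mechanism,
  not histology-scale generalization.
* Registration of H&E to multiplexed-stain images, annotation tooling and
  molecular (methylation/RNA-seq) cell-fraction benchmarks are out of
  scope.
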