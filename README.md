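# immunoaizer

Semi-supervised adversarial segmentation of cellular biomarkers in H&E
histology patches, with the downstream analyses that make the class maps
useful: tumor / tumor-infiltrating-lymphocyte (TIL) quantification,
PD-1-expressing-TIL percentages, and multilabel detection of APC, TP53
and KRAS mutations from patch images.

## Who this is for

Computational-pathology researchers who want a tested, fully seeded,
CPU-runnable reference implementation of the confidence-map self-training
scheme for biomarker segmentation — the losses, the training schedule, the
macro metrics and the quantification read-outs — exercised end-to-end on
synthetic tissue scenes, with no slide downloads or GPUs required.

## The model

A generator S maps an H x W x 3 patch to a per-pixel class distribution
over C = 4 classes (background, PanCK⁺ tumor, CD3/CD20⁺ TIL, DAPI
nuclei). A fully convolutional discriminator D scores, per pixel, how
ground-truth-like a class-probability map looks. The generator minimizes

```
L_seg = L_ce + λ_adv · L_adv + λ_semi · L_semi

L_ce   = −Σ_{h,w,c} Y[h,w,c] · log S(X)[h,w,c]          (labeled data)
L_adv  = −Σ_{h,w} log D(S(X))[h,w]
L_semi = −Σ_{h,w,c} 1(D(S(X)) > T_semi) · Ŷ[h,w,c] · log S(X)[h,w,c]
```

where Ŷ is the argmax pseudo-label of S(X) and the indicator restricts
self-training on unlabeled data to the "trustworthy region" whose
confidence exceeds T_semi. The discriminator minimizes the spatial
real/fake cross entropy −Σ[log(1 − D(S(X))) + log D(Y)]. Defaults:
λ_adv = 0.01 (labeled) / 0.001 (unlabeled), λ_semi = 0.1, T_semi = 0.5.

Evaluation uses macro-averaged IoU, Dice, precision and recall from
per-class pixel confusion counts, plus overall pixel accuracy; mutation
detection is scored with tie-aware rank-statistic ROC/AUC per gene.

The networks are built on a small deterministic numpy layer stack
(`immunoaizer.nn`) with hand-written backprop — no deep-learning framework
is required. See `docs/methods.md` for architecture and schedule details.

## Worked example

Simulate a labeled synthetic dataset, train the tiny generator, predict
and quantify — everything seeded:

```
$ immunoaizer simulate --out demo/data --n-labeled 30 --seed 7
$ immunoaizer train-seg --data demo/data --mode supervised --scale 0.001 --seed 0 --out demo/run
held-out metrics: {'accuracy': 0.948974609375, 'precision': 0.8909912189916488,
                   'recall': 0.8918804348674396, 'dice': 0.8859672837378512,
                   'iou': 0.8036142343144104}
$ immunoaizer predict --checkpoint demo/run/generator.npz --images demo/data/labeled --out demo/preds
$ immunoaizer quantify --pred demo/preds --pd1 demo/data/labeled --out demo/quant
$ cat demo/quant/report.json
{
  "pooled_tumor_fraction": 0.07508138020833334,
  "pooled_til_fraction": 0.11644694010416666,
  "pd1_positive_til_pixels": 7309,
  "til_pixels": 14309,
  "cell_pixels": 36854,
  "pd1_fraction_of_tils": 0.5107974002376127,
  "pd1_fraction_of_cells": 0.1983231128235741,
  ...
}
```

Reading the numbers: after ~300 training steps the network labels ~95% of
held-out pixels correctly with macro Dice 0.89 on the color-separable
synthetic task. The quantification step then reports that tumor covers
7.5% and TILs 11.6% of the predicted tissue, and that 51% of predicted
TIL pixels fall inside the (simulated) anti-PD-1 fluorescence mask —
the pixel-level analogue of a PD-1-expressing-TIL percentage. Semi-mode
(`--mode semi`) adds a discriminator and unlabeled patches
(`simulate --n-unlabeled ...`).

The same workflow is available as library calls
(`generate_dataset` / `train_supervised` / `train_semi_supervised` /
`evaluate_segmentation` / `pd1_til_quantification`), which is what the
test suite and the acceptance script use.

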