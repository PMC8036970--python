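"""Objectives of the semi-supervised adversarial segmentation scheme.

The generator S maps an RGB patch to a per-pixel class distribution
S(X) of shape H x W x C; the discriminator D maps a class-probability map
to a per-pixel confidence D(.) in [0, 1] scoring how ground-truth-like the
map looks. The generator minimises

    L_seg = L_ce + lambda_adv * L_adv + lambda_semi * L_semi

where L_ce is the multiclass cross entropy against the one-hot mask
(labeled data only), L_adv = -sum log D(S(X)) rewards fooling the
discriminator, and L_semi self-trains on unlabeled data using argmax
pseudo-labels restricted to the trustworthy region where the confidence
exceeds a threshold T_semi. The discriminator minimises the spatial
real/fake cross entropy.

Conventions
-----------
* Probability maps are arrays with the class channel LAST: ``(..., H, W, C)``.
* Confidence maps are ``(..., H, W)`` or ``(..., H, W, 1)``.
* Losses are SUMS over pixels, exactly as the objective is defined; pass
  ``reduction="mean"`` for a per-pixel mean (scale-invariant variant used by
  the tiny training presets).
* Logs are epsilon-clamped at 1e-8; clamped pixels get zero gradient.
* Each ``*_grad`` companion returns the analytic gradient of the loss with
  the same reduction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

EPS = 1e-8


@dataclass
class LossWeights:
    """Weights of the multitask generator objective.

    Defaults follow the reference training recipe: the adversarial term is
    weighted 0.01 on labeled and 0.001 on unlabeled batches, the
    self-training term 0.1, and the trustworthy-region threshold is 0.5.
    """

    lambda_adv_labeled: float = 0.01
    lambda_adv_unlabeled: float = 0.001
    lambda_semi: float = 0.1
    t_semi: float = 0.5

    def __post_init__(self):
        if min(self.lambda_adv_labeled, self.lambda_adv_unlabeled, self.lambda_semi) < 0:
            raise ValueError("loss weights must be non-negative")
        if not 0.0 <= self.t_semi <= 1.0:
            raise ValueError("t_semi must lie in [0, 1]")


def _npix(a: np.ndarray, channel_last: bool) -> int:
    shape = a.shape[:-1] if channel_last else a.shape
    return int(np.prod(shape))


def _conf(d: np.ndarray) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if d.ndim >= 3 and d.shape[-1] == 1:
        d = d[..., 0]
    return d


def _scale(reduction: str, npix: int) -> float:
    if reduction == "sum":
        return 1.0
    if reduction == "mean":
        return 1.0 / npix
    raise ValueError(f"unknown reduction {reduction!r}")


def cross_entropy_loss(s, y, reduction="sum") -> float:
    """Multiclass cross entropy -sum_{h,w,c} Y[h,w,c] log S[h,w,c].

    ``s`` is a probability map (class channel last), ``y`` the matching
    one-hot mask. Zero iff S equals Y exactly.
    """
    s = np.asarray(s, dtype=float)
    y = np.asarray(y, dtype=float)
    if s.shape != y.shape:
        raise ValueError(f"shape mismatch {s.shape} vs {y.shape}")
    val = -(y * np.log(np.maximum(s, EPS))).sum()
    return float(val) * _scale(reduction, _npix(s, True))


def cross_entropy_grad(s, y, reduction="sum") -> np.ndarray:
    s = np.asarray(s, dtype=float)
    y = np.asarray(y, dtype=float)
    g = np.where(s > EPS, -y / np.maximum(s, EPS), 0.0)
    return g * _scale(reduction, _npix(s, True))


def adversarial_loss(dmap, reduction="sum") -> float:
    """Generator-side adversarial term -sum_{h,w} log D(S(X))[h,w].

    Minimised when the discriminator is fully fooled (confidence 1
    everywhere).
    """
    d = _conf(dmap)
    val = -np.log(np.maximum(d, EPS)).sum()
    return float(val) * _scale(reduction, d.size)


def adversarial_grad(dmap, reduction="sum") -> np.ndarray:
    d = _conf(dmap)
    g = np.where(d > EPS, -1.0 / np.maximum(d, EPS), 0.0)
    return g * _scale(reduction, d.size)


def pseudo_one_hot(s) -> np.ndarray:
    """Argmax pseudo-labels of a probability map; ties go to the lowest class."""
    s = np.asarray(s, dtype=float)
    idx = s.argmax(axis=-1)
    out = np.zeros_like(s)
    np.put_along_axis(out, idx[..., None], 1.0, axis=-1)
    return out


def semi_supervised_loss(s, dmap, t_semi=0.5, reduction="sum") -> float:
    """Self-training loss on the trustworthy region.

    -sum_{h,w,c} I(D > T_semi) Yhat[h,w,c] log S[h,w,c] with Yhat the argmax
    pseudo one-hot of S. Pixels whose confidence is at or below the
    threshold contribute exactly zero.
    """
    s = np.asarray(s, dtype=float)
    d = _conf(dmap)
    if d.shape != s.shape[:-1]:
        raise ValueError(f"confidence shape {d.shape} incompatible with map {s.shape}")
    yhat = pseudo_one_hot(s)
    mask = (d > t_semi).astype(float)
    val = -(mask[..., None] * yhat * np.log(np.maximum(s, EPS))).sum()
    return float(val) * _scale(reduction, _npix(s, True))


def semi_supervised_grad(s, dmap, t_semi=0.5, reduction="sum") -> np.ndarray:
    """Gradient w.r.t. S; pseudo-labels and the confidence mask are fixed."""
    s = np.asarray(s, dtype=float)
    d = _conf(dmap)
    yhat = pseudo_one_hot(s)
    mask = (d > t_semi).astype(float)[..., None]
    g = np.where(s > EPS, -mask * yhat / np.maximum(s, EPS), 0.0)
    return g * _scale(reduction, _npix(s, True))


def generator_total_loss(
    lce: float,
    ladv: float,
    lsemi: float,
    w: LossWeights,
    labeled: bool,
    semi_on_labeled: bool = False,
) -> float:
    """Combine the multitask terms for one batch.

    Labeled batches: L_ce + lambda_adv_labeled * L_adv (the self-training
    term is redundant where ground truth exists, unless ``semi_on_labeled``
    requests the literal three-term objective). Unlabeled batches: cross
    entropy is unavailable, so lambda_adv_unlabeled * L_adv +
    lambda_semi * L_semi.
    """
    if labeled:
        total = lce + w.lambda_adv_labeled * ladv
        if semi_on_labeled:
            total += w.lambda_semi * lsemi
        return float(total)
    return float(w.lambda_adv_unlabeled * ladv + w.lambda_semi * lsemi)


def discriminator_loss(d_on_s, d_on_y, reduction="sum") -> float:
    """Spatial real/fake cross entropy.

    -sum_{h,w} [ log(1 - D(S(X))) + log D(Y) ]: the generator output is the
    fake class (flag 0), the one-hot ground truth the real class (flag 1).
    """
    ds = _conf(d_on_s)
    dy = _conf(d_on_y)
    val = -(np.log(np.maximum(1.0 - ds, EPS)).sum() + np.log(np.maximum(dy, EPS)).sum())
    return float(val) * _scale(reduction, ds.size)


def discriminator_loss_grads(d_on_s, d_on_y, reduction="sum"):
    """Gradients w.r.t. D(S(X)) and D(Y)."""
    ds = _conf(d_on_s)
    dy = _conf(d_on_y)
    gs = np.where(1.0 - ds > EPS, 1.0 / np.maximum(1.0 - ds, EPS), 0.0)
    gy = np.where(dy > EPS, -1.0 / np.maximum(dy, EPS), 0.0)
    k = _scale(reduction, ds.size)
    return gs * k, gy * k


def multilabel_bce(probs, labels, reduction="mean") -> float:
    """Mean binary cross entropy over independent per-gene sigmoid outputs."""
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels, dtype=float)
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch {p.shape} vs {y.shape}")
    val = -(
        y * np.log(np.maximum(p, EPS)) + (1.0 - y) * np.log(np.maximum(1.0 - p, EPS))
    ).sum()
    n = p.size if reduction == "mean" else 1
    return float(val) / n


def multilabel_bce_grad(probs, labels, reduction="mean") -> np.ndarray:
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels, dtype=float)
    g = -y * np.where(p > EPS, 1.0 / np.maximum(p, EPS), 0.0) + (1.0 - y) * np.where(
        1.0 - p > EPS, 1.0 / np.maximum(1.0 - p, EPS), 0.0
    )
    if reduction == "mean":
        g = g / p.size
    return g
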