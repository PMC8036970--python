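"""Independent brute-force reference implementations used only by tests.

Every function here is written as plain scalar loops (or O(n^2)
enumeration) so it shares no code path with the package implementation.
"""

import math

import numpy as np


def loop_cross_entropy(s, y, eps=1e-8):
    total = 0.0
    h, w, c = s.shape
    for i in range(h):
        for j in range(w):
            for k in range(c):
                total -= y[i, j, k] * math.log(max(s[i, j, k], eps))
    return total


def loop_adversarial(d, eps=1e-8):
    total = 0.0
    h, w = d.shape
    for i in range(h):
        for j in range(w):
            total -= math.log(max(d[i, j], eps))
    return total


def loop_semi(s, d, t_semi, eps=1e-8):
    total = 0.0
    h, w, c = s.shape
    for i in range(h):
        for j in range(w):
            if d[i, j] > t_semi:
                best = 0
                for k in range(1, c):
                    if s[i, j, k] > s[i, j, best]:
                        best = k
                total -= math.log(max(s[i, j, best], eps))
    return total


def loop_discriminator(d_on_s, d_on_y, eps=1e-8):
    total = 0.0
    h, w = d_on_s.shape
    for i in range(h):
        for j in range(w):
            total -= math.log(max(1.0 - d_on_s[i, j], eps))
            total -= math.log(max(d_on_y[i, j], eps))
    return total


def loop_multilabel_bce(p, y, eps=1e-8):
    total = 0.0
    for pi, yi in zip(p, y):
        total -= yi * math.log(max(pi, eps)) + (1 - yi) * math.log(max(1 - pi, eps))
    return total / len(p)


def pairwise_auc(scores, labels):
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def loop_confusion(pred, truth, n_classes):
    tp = [0] * n_classes
    fp = [0] * n_classes
    tn = [0] * n_classes
    fn = [0] * n_classes
    for p, t in zip(np.ravel(pred), np.ravel(truth)):
        for c in range(n_classes):
            if t == c and p == c:
                tp[c] += 1
            elif t != c and p == c:
                fp[c] += 1
            elif t == c and p != c:
                fn[c] += 1
            else:
                tn[c] += 1
    return tp, fp, tn, fn


def paint_scene_oracle(config, seed):
    """Independent rasterisation of the blob-painting process.

    Samples the same blob distribution with the same generator stream, but
    paints with an independent per-pixel loop instead of the package's
    vectorised ellipse mask.
    """
    rng = np.random.default_rng(seed)
    h, w = config.height, config.width
    mask = np.zeros((h, w), dtype=int)
    blobs = []
    r_lo, r_hi = config.blob_radius_range
    for cls in range(1, config.n_classes):
        lo, hi = config.counts_for(cls)
        n_blobs = int(rng.integers(lo, hi + 1)) if hi > 0 else 0
        for _ in range(n_blobs):
            cy = rng.uniform(0, h)
            cx = rng.uniform(0, w)
            ry = rng.uniform(r_lo, r_hi)
            rx = rng.uniform(r_lo, r_hi)
            blobs.append((cy, cx, ry, rx, cls))
    for k in rng.permutation(len(blobs)):
        cy, cx, ry, rx, cls = blobs[k]
        for i in range(h):
            for j in range(w):
                if ((i - cy) / ry) ** 2 + ((j - cx) / rx) ** 2 <= 1.0:
                    mask[i, j] = cls
    return mask


def finite_difference_grad(f, x, eps=1e-6):
    g = np.zeros_like(x, dtype=float)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        idx = it.multi_index
        orig = x[idx]
        x[idx] = orig + eps
        fp = f(x)
        x[idx] = orig - eps
        fm = f(x)
        x[idx] = orig
        g[idx] = (fp - fm) / (2 * eps)
        it.iternext()
    return g
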