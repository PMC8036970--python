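"""Patch preparation: tiling, color normalization, filtering, encoding.

Mirrors the data-preparation rules of the H&E pipeline:

* whole images are tiled into fixed-size patches (edge remainders dropped);
* color is normalized by Reinhard-style mean/std matching in CIELAB;
* patches with background proportion of 50% or more are excluded from
  semi-supervised training (strict ``< 0.5`` keeps a patch);
* tumor patches for mutation detection are those whose predicted
  PanCK-positive area exceeds 50% (strict ``> 0.5`` selects);
* masks convert to one-hot encodings for the losses.

Class legend (repo-wide): 0 background, 1 PanCK tumor, 2 CD3+CD20 TIL,
3 DAPI nuclei.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from skimage import color as skcolor

#: luminance above this is background on unlabeled (mask-free) patches
DEFAULT_BACKGROUND_LUMINANCE = 0.8

TUMOR_CLASS = 1


@dataclass
class ImagePatch:
    """An RGB patch with provenance: 0-based (row, col) origin in its source."""

    pixels: np.ndarray
    origin: tuple = (0, 0)
    source_id: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be H x W x 3")
        if self.pixels.size == 0:
            raise ValueError("empty patch")

    @property
    def shape(self):
        return self.pixels.shape


@dataclass
class LabelMask:
    """Integer per-pixel class assignment."""

    labels: np.ndarray
    n_classes: int = 4

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.min() < 0 or self.labels.max() >= self.n_classes:
            raise ValueError("mask values must lie in [0, n_classes)")


def as_pixels(patch) -> np.ndarray:
    return patch.pixels if isinstance(patch, ImagePatch) else np.asarray(patch, dtype=float)


def as_labels(mask) -> np.ndarray:
    return mask.labels if isinstance(mask, LabelMask) else np.asarray(mask)


# ---------------------------------------------------------------------------
# tiling
# ---------------------------------------------------------------------------

def tile_image(image, tile: int, stride: int | None = None, source_id: str = "") -> list[ImagePatch]:
    """Row-major tiling; remainders smaller than ``tile`` are dropped."""
    img = as_pixels(image)
    stride = tile if stride is None else stride
    h, w = img.shape[:2]
    if tile > min(h, w):
        raise ValueError(f"tile {tile} exceeds image extent {h}x{w}")
    if stride <= 0:
        raise ValueError("stride must be positive")
    patches = []
    for r in range(0, h - tile + 1, stride):
        for c in range(0, w - tile + 1, stride):
            patches.append(
                ImagePatch(pixels=img[r : r + tile, c : c + tile].copy(), origin=(r, c), source_id=source_id)
            )
    return patches


def paste_tiles(patches: Sequence[ImagePatch], height: int, width: int) -> np.ndarray:
    """Reassemble tiles at their origins (inverse of exact tiling)."""
    out = np.zeros((height, width, 3))
    for p in patches:
        r, c = p.origin
        th, tw = p.pixels.shape[:2]
        out[r : r + th, c : c + tw] = p.pixels
    return out


# ---------------------------------------------------------------------------
# color normalization (Reinhard mean/std matching in CIELAB)
# ---------------------------------------------------------------------------

@dataclass
class NormalizationReference:
    """Per-channel target mean/std in CIELAB."""

    mean: np.ndarray
    std: np.ndarray

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.std = np.asarray(self.std, dtype=float)
        if np.any(self.std <= 0):
            raise ValueError("reference stds must be positive")

    @classmethod
    def from_image(cls, image) -> "NormalizationReference":
        lab = skcolor.rgb2lab(as_pixels(image))
        return cls(lab.reshape(-1, 3).mean(axis=0), lab.reshape(-1, 3).std(axis=0))


def normalize_color(patch, ref: NormalizationReference, _degenerate_std=1e-6):
    """Match the patch's CIELAB channel statistics to the reference.

    A (near) zero-variance source channel is degenerate: the patch is
    returned unchanged with a warning.
    """
    img = as_pixels(patch)
    lab = skcolor.rgb2lab(img)
    mean = lab.reshape(-1, 3).mean(axis=0)
    std = lab.reshape(-1, 3).std(axis=0)
    if np.any(std < _degenerate_std):
        warnings.warn("degenerate (constant) channel; returning patch unchanged", stacklevel=2)
        return patch
    out_lab = (lab - mean) / std * ref.std + ref.mean
    out = np.clip(skcolor.lab2rgb(out_lab), 0.0, 1.0)
    if isinstance(patch, ImagePatch):
        return ImagePatch(pixels=out, origin=patch.origin, source_id=patch.source_id)
    return out


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def luminance(img: np.ndarray) -> np.ndarray:
    return 0.2126 * img[..., 0] + 0.7152 * img[..., 1] + 0.0722 * img[..., 2]


def background_fraction(mask_or_patch, luminance_threshold: float = DEFAULT_BACKGROUND_LUMINANCE) -> float:
    """Fraction of background pixels.

    Integer masks: class 0. RGB patches (no mask available): pixels whose
    grayscale luminance exceeds the threshold, the standard convention for
    unannotated whole-slide tiles.
    """
    if isinstance(mask_or_patch, LabelMask):
        m = mask_or_patch.labels
        return float((m == 0).mean())
    arr = np.asarray(mask_or_patch.pixels if isinstance(mask_or_patch, ImagePatch) else mask_or_patch)
    if arr.ndim == 2 and not np.issubdtype(arr.dtype, np.floating):
        return float((arr == 0).mean())
    return float((luminance(arr.astype(float)) > luminance_threshold).mean())


def filter_for_semisup(patches: Iterable, luminance_threshold: float = DEFAULT_BACKGROUND_LUMINANCE) -> list:
    """Keep patches with background proportion strictly below 50%."""
    return [p for p in patches if background_fraction(p, luminance_threshold) < 0.5]


def select_tumor_patches(prob_maps: Sequence[np.ndarray], min_fraction: float = 0.5, tumor_class: int = TUMOR_CLASS) -> list[int]:
    """Indices of maps whose argmax-PanCK area strictly exceeds ``min_fraction``."""
    selected = []
    for i, s in enumerate(prob_maps):
        labels = np.asarray(s).argmax(axis=-1)
        if (labels == tumor_class).mean() > min_fraction:
            selected.append(i)
    return selected


# ---------------------------------------------------------------------------
# encoding and augmentation
# ---------------------------------------------------------------------------

def one_hot_encode(mask, n_classes: int = 4) -> np.ndarray:
    """H x W class ids -> H x W x C one-hot array."""
    m = as_labels(mask)
    if m.max() >= n_classes or m.min() < 0:
        raise ValueError("mask label out of range")
    return np.eye(n_classes, dtype=float)[m]


def apply_dihedral(image: np.ndarray, mask: np.ndarray | None, k_rot: int, flip: bool):
    """Rotate by k*90 degrees then optionally flip horizontally, jointly."""
    img = np.rot90(image, k_rot, axes=(0, 1))
    msk = None if mask is None else np.rot90(mask, k_rot, axes=(0, 1))
    if flip:
        img = img[:, ::-1]
        msk = None if msk is None else msk[:, ::-1]
    return np.ascontiguousarray(img), (None if msk is None else np.ascontiguousarray(msk))


def hsv_jitter(image: np.ndarray, rng: np.random.Generator, max_shift: float = 0.02) -> np.ndarray:
    """Small seeded HSV perturbation; spatial structure untouched."""
    hsv = skcolor.rgb2hsv(image)
    shift = rng.uniform(-max_shift, max_shift, size=3)
    hsv[..., 0] = np.mod(hsv[..., 0] + shift[0], 1.0)
    hsv[..., 1] = np.clip(hsv[..., 1] * (1 + shift[1]), 0, 1)
    hsv[..., 2] = np.clip(hsv[..., 2] * (1 + shift[2]), 0, 1)
    return skcolor.hsv2rgb(hsv)


def augment(patch, mask, seed: int = 0, jitter: float = 0.02) -> list:
    """All 8 dihedral (flip/rot90) variants with seeded HSV jitter.

    The identity transform comes first and is returned untouched. The same
    spatial transform is applied to patch and mask; jitter affects pixel
    values only, never mask classes.
    """
    img = as_pixels(patch)
    msk = as_labels(mask)
    if img.shape[:2] != msk.shape:
        raise ValueError("patch/mask shape mismatch")
    rng = np.random.default_rng(seed)
    out = [(img.copy(), msk.copy())]
    for flip in (False, True):
        for k in range(4):
            if k == 0 and not flip:
                continue
            ai, am = apply_dihedral(img, msk, k, flip)
            if jitter > 0:
                ai = hsv_jitter(ai, rng, jitter)
            out.append((ai, am))
    return out
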