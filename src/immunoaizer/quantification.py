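"""Downstream read-outs of predicted class maps.

Class-fraction and PD-1 quantification are pixel-based: the fraction of
pixels assigned to a class stands in for the cell percentage that
nucleus-anchored commercial pipelines report. Both PD-1 denominators are
computed — TIL pixels and all non-background ("cell") pixels — since either
normalization is defensible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from skimage.filters import threshold_otsu

from .pipeline import as_labels

TUMOR_CLASS, TIL_CLASS = 1, 2

#: render colors for merged overlays: class colors + orange for PD-1+ TILs
DEFAULT_RENDER_PALETTE = (
    (1.00, 1.00, 1.00),  # background
    (0.85, 0.20, 0.50),  # PanCK tumor
    (0.20, 0.30, 0.90),  # TIL
    (0.15, 0.15, 0.45),  # nuclei
)
PD1_OVERLAY_COLOR = (1.00, 0.55, 0.00)


@dataclass
class ClassFractions:
    """Pooled per-class pixel fractions over one or more masks."""

    fractions: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        self.fractions = np.asarray(self.fractions, dtype=float)
        self.counts = np.asarray(self.counts, dtype=np.int64)

    @property
    def tumor_fraction(self) -> float:
        return float(self.fractions[TUMOR_CLASS])

    @property
    def til_fraction(self) -> float:
        return float(self.fractions[TIL_CLASS])


@dataclass
class Pd1Report:
    pd1_positive_til_pixels: int
    til_pixels: int
    cell_pixels: int
    fraction_of_tils: float | None
    fraction_of_cells: float | None

    def as_dict(self) -> dict:
        return {
            "pd1_positive_til_pixels": self.pd1_positive_til_pixels,
            "til_pixels": self.til_pixels,
            "cell_pixels": self.cell_pixels,
            "fraction_of_tils": self.fraction_of_tils,
            "fraction_of_cells": self.fraction_of_cells,
        }


def class_fractions(masks, n_classes: int = 4) -> ClassFractions:
    """Pool pixel counts over all masks; fractions sum to one."""
    if hasattr(masks, "labels") or (isinstance(masks, np.ndarray) and masks.ndim == 2):
        masks = [masks]
    counts = np.zeros(n_classes, dtype=np.int64)
    for m in masks:
        counts += np.bincount(as_labels(m).ravel(), minlength=n_classes)[:n_classes]
    total = counts.sum()
    if total == 0:
        raise ValueError("no pixels to quantify")
    return ClassFractions(counts / total, counts)


def binarize_fluorescence(channel: np.ndarray, method: str = "otsu", threshold: float | None = None) -> np.ndarray:
    """Threshold a single-channel stain image to a binary mask.

    ``otsu`` picks the threshold from the histogram; a constant image is
    degenerate and yields an all-zero mask with a warning. ``fixed``
    requires an explicit threshold.
    """
    img = np.asarray(channel, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a single-channel image")
    if method == "fixed":
        if threshold is None:
            raise ValueError("fixed method requires a threshold")
        return img > threshold
    if method == "otsu":
        if np.ptp(img) == 0:
            warnings.warn("constant image: Otsu threshold undefined, returning all-zero mask",
                          stacklevel=2)
            return np.zeros_like(img, dtype=bool)
        return img > threshold_otsu(img)
    raise ValueError(f"unknown method {method!r}")


def pd1_til_quantification(pred, pd1: np.ndarray) -> Pd1Report:
    """Count PD-1-positive TIL pixels against both denominators.

    Zero denominators yield ``None`` fractions (explicitly undefined).
    """
    labels = as_labels(pred)
    pd1 = np.asarray(pd1).astype(bool)
    if labels.shape != pd1.shape:
        raise ValueError(f"shape mismatch {labels.shape} vs {pd1.shape}")
    til = labels == TIL_CLASS
    cells = labels != 0
    pos = int((til & pd1).sum())
    n_til = int(til.sum())
    n_cell = int(cells.sum())
    return Pd1Report(
        pd1_positive_til_pixels=pos,
        til_pixels=n_til,
        cell_pixels=n_cell,
        fraction_of_tils=(pos / n_til) if n_til else None,
        fraction_of_cells=(pos / n_cell) if n_cell else None,
    )


def merge_overlay(pred, pd1: np.ndarray, palette=DEFAULT_RENDER_PALETTE, overlay_color=PD1_OVERLAY_COLOR) -> np.ndarray:
    """Render class colors with PD-1-positive TIL pixels recolored."""
    labels = as_labels(pred)
    pd1 = np.asarray(pd1).astype(bool)
    if labels.shape != pd1.shape:
        raise ValueError("shape mismatch between prediction and PD-1 mask")
    pal = np.asarray(palette, dtype=float)
    out = pal[labels]
    out[(labels == TIL_CLASS) & pd1] = overlay_color
    return out


def pearson_correlation(x, y):
    """Product-moment correlation with its two-sided t-test p value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be matching 1-D series")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
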