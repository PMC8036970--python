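"""Seeded synthetic tissue scenes, fluorescence masks and mutation labels.

The generator emulates the inputs of the H&E biomarker-segmentation
pipeline at desk scale: 4-class scenes (0 = background, 1 = PanCK-positive
tumor, 2 = CD3/CD20-positive TIL, 3 = DAPI nuclei) built from elliptical
"cell region" blobs painted on a bright background, with per-class mean
colors loosely mimicking H&E appearance plus Gaussian pixel noise. Class
colors are guaranteed separable (pairwise mean separation of at least three
noise standard deviations in some channel), so a segmentation network can
in principle recover the mask from color alone — this is what makes the
scaled-down training benchmarks meaningful.

Everything is a pure function of (config, seed); per-item seeds in dataset
generators derive from the master seed through a counter-based scheme
(``default_rng([master, stream, counter])``), so the i-th item is
reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .pipeline import ImagePatch

#: Repo-wide class legend.
BACKGROUND, TUMOR, TIL, NUCLEI = 0, 1, 2, 3

CLASS_NAMES = ("background", "tumor", "til", "nuclei")

#: H&E-like mean colors (RGB fractions) for background / PanCK tumor /
#: CD3+CD20 TIL / DAPI nuclei.
DEFAULT_CLASS_MEANS = (
    (0.92, 0.90, 0.93),
    (0.78, 0.48, 0.66),
    (0.38, 0.32, 0.68),
    (0.22, 0.16, 0.42),
)


class ConfigError(ValueError):
    """Invalid generator configuration."""


@dataclass
class SceneConfig:
    """Parameters of one synthetic tissue scene.

    ``class_means``/``class_stds`` hold one RGB entry per class;
    ``class_stds`` defaults to ``noise_sigma`` in every channel.
    ``blob_count_range``/``blob_radius_range`` apply to each non-background
    class (a per-class sequence of ranges is also accepted for counts).
    """

    height: int = 64
    width: int = 64
    n_classes: int = 4
    class_means: Sequence = DEFAULT_CLASS_MEANS
    class_stds: Sequence | None = None
    blob_count_range: Sequence = (2, 5)
    blob_radius_range: Sequence = (4, 10)
    noise_sigma: float = 0.04
    seed: int = 0

    means: np.ndarray = field(init=False, repr=False)
    stds: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        if self.height <= 0 or self.width <= 0:
            raise ConfigError("scene dimensions must be positive")
        if self.n_classes < 2:
            raise ConfigError("need at least background + one foreground class")
        means = np.asarray(self.class_means, dtype=float)
        if means.shape != (self.n_classes, 3):
            raise ConfigError(
                f"palette must have exactly {self.n_classes} RGB entries, got {means.shape}"
            )
        if self.class_stds is None:
            stds = np.full((self.n_classes, 3), float(self.noise_sigma))
        else:
            stds = np.asarray(self.class_stds, dtype=float)
            if stds.shape != (self.n_classes, 3):
                raise ConfigError("class_stds must match the palette shape")
        # learnability guarantee: class means pairwise separated by at least
        # 3 sigma in some channel
        sigma = max(float(stds.max()), 1e-12)
        for i in range(self.n_classes):
            for j in range(i + 1, self.n_classes):
                if np.abs(means[i] - means[j]).max() < 3.0 * sigma:
                    raise ConfigError(
                        f"classes {i} and {j} are closer than 3 noise sigma in every channel"
                    )
        self.means = means
        self.stds = stds

    def counts_for(self, cls: int) -> tuple[int, int]:
        rng_spec = np.asarray(self.blob_count_range)
        if rng_spec.ndim == 1:
            lo, hi = rng_spec
        else:
            lo, hi = rng_spec[cls - 1]
        return int(lo), int(hi)


def _paint_ellipse(mask: np.ndarray, cy, cx, ry, rx, cls: int):
    h, w = mask.shape
    rr = np.arange(h)[:, None]
    cc = np.arange(w)[None, :]
    inside = ((rr - cy) / ry) ** 2 + ((cc - cx) / rx) ** 2 <= 1.0
    mask[inside] = cls


def generate_scene(config: SceneConfig, seed: int | None = None):
    """Paint one scene; returns ``(ImagePatch, label mask)``.

    Blobs are axis-aligned ellipses painted in a shuffled order; later
    blobs overwrite earlier ones. The image is the per-class mean color
    plus Gaussian noise, clipped to [0, 1].
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    h, w = config.height, config.width
    mask = np.zeros((h, w), dtype=np.uint8)
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
    order = rng.permutation(len(blobs))
    for k in order:
        cy, cx, ry, rx, cls = blobs[k]
        _paint_ellipse(mask, cy, cx, ry, rx, cls)
    noise = rng.standard_normal((h, w, 3))
    image = config.means[mask] + noise * config.stds[mask]
    image = np.clip(image, 0.0, 1.0)
    sid = config.seed if seed is None else seed
    patch = ImagePatch(pixels=image, origin=(0, 0), source_id=f"synthetic-{sid}")
    return patch, mask


def generate_dataset(config: SceneConfig, n_labeled: int, n_unlabeled: int, master_seed: int | None = None):
    """Labeled pairs plus unlabeled patches from the same scene distribution."""
    if n_labeled < 0 or n_unlabeled < 0:
        raise ConfigError("counts must be non-negative")
    master = config.seed if master_seed is None else master_seed
    labeled = [generate_scene(config, seed=[master, 0, i]) for i in range(n_labeled)]
    unlabeled = [generate_scene(config, seed=[master, 1, j])[0] for j in range(n_unlabeled)]
    return labeled, unlabeled


def generate_fluorescence_mask(
    mask: np.ndarray,
    target_class: int = TIL,
    positivity_rate: float = 1.0,
    off_target_rate: float = 0.0,
    seed: int = 0,
    n_classes: int | None = None,
) -> np.ndarray:
    """Synthetic binary stain (e.g. anti-PD-1) spatially tied to one class.

    Each connected region of ``target_class`` lights up with probability
    ``positivity_rate``; regions of other non-background classes with
    probability ``off_target_rate``; background never.
    """
    mask = np.asarray(mask)
    n_classes = int(n_classes if n_classes is not None else max(4, mask.max() + 1))
    if not 1 <= target_class < n_classes:
        raise ConfigError(f"unknown or background target class {target_class}")
    if not (0 <= positivity_rate <= 1 and 0 <= off_target_rate <= 1):
        raise ConfigError("rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    out = np.zeros(mask.shape, dtype=bool)
    for cls in range(1, n_classes):
        regions, n_regions = ndimage.label(mask == cls)
        rate = positivity_rate if cls == target_class else off_target_rate
        for rid in range(1, n_regions + 1):
            if rng.random() < rate:
                out |= regions == rid
    return out


# ---------------------------------------------------------------------------
# planted mutation labels
# ---------------------------------------------------------------------------

def nearest_palette_labels(image: np.ndarray, means: np.ndarray) -> np.ndarray:
    """Classify each pixel by its nearest class mean color (Euclidean)."""
    img = np.asarray(image, dtype=float)
    d2 = ((img[..., None, :] - np.asarray(means)[None, None, :, :]) ** 2).sum(axis=-1)
    return d2.argmin(axis=-1)


def patch_statistic(name: str, image: np.ndarray, means: np.ndarray) -> float:
    """A scalar statistic computable from the patch pixels alone."""
    img = np.asarray(image, dtype=float)
    if name in ("til_fraction", "tumor_fraction", "nuclei_fraction", "background_fraction"):
        cls = {"background_fraction": BACKGROUND, "tumor_fraction": TUMOR,
               "til_fraction": TIL, "nuclei_fraction": NUCLEI}[name]
        labels = nearest_palette_labels(img, means)
        return float((labels == cls).mean())
    if name == "mean_luminance":
        lum = 0.2126 * img[..., 0] + 0.7152 * img[..., 1] + 0.0722 * img[..., 2]
        return float(lum.mean())
    if name == "mean_red":
        return float(img[..., 0].mean())
    raise ConfigError(f"unknown patch statistic {name!r}")


@dataclass(frozen=True)
class LabelRule:
    """label = 1 iff statistic(patch) is on the stated side of the threshold."""

    statistic: str
    threshold: float
    direction: str = ">"

    def apply(self, image: np.ndarray, means: np.ndarray) -> int:
        v = patch_statistic(self.statistic, image, means)
        return int(v > self.threshold) if self.direction == ">" else int(v < self.threshold)


#: Default planted rules, one per gene; thresholds sit near the median of
#: each statistic under the default SceneConfig so both label polarities
#: are well represented.
DEFAULT_LABEL_RULES = {
    "APC": LabelRule("til_fraction", 0.10),
    "TP53": LabelRule("tumor_fraction", 0.10),
    "KRAS": LabelRule("nuclei_fraction", 0.10),
}

GENES = ("APC", "TP53", "KRAS")


@dataclass
class MutationPlantConfig:
    n_patches: int = 200
    label_rules: dict = field(default_factory=lambda: dict(DEFAULT_LABEL_RULES))
    flip_noise: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.flip_noise < 0.5:
            raise ConfigError("flip_noise must lie in [0, 0.5)")
        if set(self.label_rules) != set(GENES):
            raise ConfigError(f"label_rules must cover exactly {GENES}")


def generate_mutation_dataset(scene_config: SceneConfig, plant_config: MutationPlantConfig):
    """Patches plus a 3-column binary label table (APC, TP53, KRAS).

    Labels are the planted rules evaluated on each emitted patch, then
    independently flipped with probability ``flip_noise``.
    """
    import pandas as pd

    # validate rules before any work
    probe_img = np.zeros((2, 2, 3))
    for gene in GENES:
        plant_config.label_rules[gene].apply(probe_img, scene_config.means)

    patches, rows = [], []
    for i in range(plant_config.n_patches):
        patch, _ = generate_scene(scene_config, seed=[plant_config.seed, 2, i])
        rng = np.random.default_rng([plant_config.seed, 3, i])
        row = {"patch_id": f"patch_{i:05d}"}
        for gene in GENES:
            label = plant_config.label_rules[gene].apply(patch.pixels, scene_config.means)
            if rng.random() < plant_config.flip_noise:
                label = 1 - label
            row[gene] = label
        patches.append(patch)
        rows.append(row)
    labels = pd.DataFrame(rows).set_index("patch_id")
    return patches, labels
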