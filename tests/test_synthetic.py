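"""Synthetic scene, fluorescence and mutation-label generators."""

import numpy as np
import pytest

from immunoaizer import (
    MutationPlantConfig,
    SceneConfig,
    generate_dataset,
    generate_fluorescence_mask,
    generate_mutation_dataset,
    generate_scene,
)
from immunoaizer.synthetic import (
    GENES,
    ConfigError,
    LabelRule,
    nearest_palette_labels,
    patch_statistic,
)
from oracles import paint_scene_oracle


def test_no_blobs_gives_all_background():
    cfg = SceneConfig(blob_count_range=(0, 0), seed=3)
    _, mask = generate_scene(cfg)
    assert (mask == 0).all()


def test_seeded_determinism(scene_config):
    p1, m1 = generate_scene(scene_config, seed=42)
    p2, m2 = generate_scene(scene_config, seed=42)
    np.testing.assert_array_equal(p1.pixels, p2.pixels)
    np.testing.assert_array_equal(m1, m2)
    p3, _ = generate_scene(scene_config, seed=43)
    assert not np.array_equal(p1.pixels, p3.pixels)


def test_scene_contract(scene_config):
    patch, mask = generate_scene(scene_config, seed=7)
    assert patch.pixels.shape == (64, 64, 3)
    assert mask.shape == (64, 64)
    assert mask.max() < scene_config.n_classes
    assert patch.pixels.min() >= 0 and patch.pixels.max() <= 1


def test_config_validation():
    with pytest.raises(ConfigError):
        SceneConfig(n_classes=1, class_means=[(0, 0, 0)])
    with pytest.raises(ConfigError):
        SceneConfig(class_means=[(0, 0, 0)] * 3)  # wrong palette size
    with pytest.raises(ConfigError):
        # two identical class colors: inseparable at any noise
        SceneConfig(class_means=[(1, 1, 1), (0.5, 0.5, 0.5), (0.5, 0.5, 0.5), (0, 0, 0)])
    with pytest.raises(ConfigError):
        SceneConfig(height=0)


def test_til_coverage_matches_independent_painting_oracle(scene_config):
    """Monte-Carlo TIL pixel frequency vs a per-pixel loop rasterizer."""
    freq = np.mean([
        (generate_scene(scene_config, seed=[5, 0, i])[1] == 2).mean() for i in range(400)
    ])
    oracle = np.mean([
        (paint_scene_oracle(scene_config, [5, 0, i]) == 2).mean() for i in range(60)
    ])
    assert freq == pytest.approx(oracle, rel=0.2)


def test_generate_dataset_counts_and_determinism(scene_config):
    labeled, unlabeled = generate_dataset(scene_config, 0, 5, master_seed=1)
    assert labeled == [] and len(unlabeled) == 5
    labeled, unlabeled = generate_dataset(scene_config, 8, 0, master_seed=1)
    assert len(labeled) == 8 and unlabeled == []
    again, _ = generate_dataset(scene_config, 8, 0, master_seed=1)
    for (p1, m1), (p2, m2) in zip(labeled, again):
        np.testing.assert_array_equal(p1.pixels, p2.pixels)
        np.testing.assert_array_equal(m1, m2)


def test_nearest_palette_recovery(scene_config):
    """Separability guarantee: color argmin recovers >= 95% of mask labels."""
    hits, total = 0, 0
    for i in range(20):
        patch, mask = generate_scene(scene_config, seed=[11, 0, i])
        rec = nearest_palette_labels(patch.pixels, scene_config.means)
        hits += (rec == mask).sum()
        total += mask.size
    assert hits / total >= 0.95


# -- fluorescence -----------------------------------------------------------

def _grid_mask(n_regions=200, cls=2):
    """Isolated 2x2 regions of one class on a grid."""
    side = int(np.ceil(np.sqrt(n_regions)))
    mask = np.zeros((side * 4, side * 4), dtype=int)
    count = 0
    for i in range(side):
        for j in range(side):
            if count >= n_regions:
                break
            mask[4 * i : 4 * i + 2, 4 * j : 4 * j + 2] = cls
            count += 1
    return mask


def test_fluorescence_trivial_rates(scene_config):
    _, mask = generate_scene(scene_config, seed=2)
    off = generate_fluorescence_mask(mask, positivity_rate=0, off_target_rate=0, seed=0)
    assert not off.any()
    on = generate_fluorescence_mask(mask, positivity_rate=1, off_target_rate=0, seed=0)
    np.testing.assert_array_equal(on, mask == 2)


def test_fluorescence_subset_of_nonbackground(scene_config):
    _, mask = generate_scene(scene_config, seed=9)
    fl = generate_fluorescence_mask(mask, positivity_rate=0.7, off_target_rate=0.3, seed=4)
    assert not (fl & (mask == 0)).any()


def test_fluorescence_rate_within_binomial_ci():
    mask = _grid_mask(200)
    fl = generate_fluorescence_mask(mask, positivity_rate=0.5, seed=8)
    # each region is 4 pixels; count positive regions
    positive_regions = fl.sum() / 4
    # binomial 99% CI around 0.5 with n=200
    half_width = 2.576 * np.sqrt(0.25 / 200)
    assert abs(positive_regions / 200 - 0.5) <= half_width


def test_fluorescence_unknown_target_class(scene_config):
    _, mask = generate_scene(scene_config, seed=2)
    with pytest.raises(ConfigError):
        generate_fluorescence_mask(mask, target_class=0)
    with pytest.raises(ConfigError):
        generate_fluorescence_mask(mask, target_class=9)


# -- planted mutation labels ------------------------------------------------

def test_rule_on_all_background_patch():
    cfg = SceneConfig(blob_count_range=(0, 0), seed=0)
    patch, mask = generate_scene(cfg)
    assert (mask == 0).all()
    rule = LabelRule("til_fraction", 0.2)
    assert rule.apply(patch.pixels, cfg.means) == 0


def test_mutation_labels_reproducible_from_patches(scene_config):
    plant = MutationPlantConfig(n_patches=40, flip_noise=0.0, seed=5)
    patches, labels = generate_mutation_dataset(scene_config, plant)
    assert len(patches) == 40
    assert list(labels.columns) == list(GENES)
    for patch, (_, row) in zip(patches, labels.iterrows()):
        for gene in GENES:
            expected = plant.label_rules[gene].apply(patch.pixels, scene_config.means)
            assert row[gene] == expected


def test_flip_noise_rate_within_binomial_ci(scene_config):
    plant = MutationPlantConfig(n_patches=500, flip_noise=0.1, seed=6)
    patches, labels = generate_mutation_dataset(scene_config, plant)
    disagreements = 0
    for patch, (_, row) in zip(patches, labels.iterrows()):
        for gene in GENES:
            clean = plant.label_rules[gene].apply(patch.pixels, scene_config.means)
            disagreements += int(row[gene] != clean)
    n = 500 * 3
    rate = disagreements / n
    half_width = 2.576 * np.sqrt(0.1 * 0.9 / n)
    assert abs(rate - 0.1) <= half_width


def test_unknown_statistic_rejected(scene_config):
    with pytest.raises(ConfigError):
        patch_statistic("entropy_of_vibes", np.zeros((2, 2, 3)), scene_config.means)
    plant = MutationPlantConfig(
        n_patches=2,
        label_rules={"APC": LabelRule("no_such_stat", 0.1),
                     "TP53": LabelRule("tumor_fraction", 0.1),
                     "KRAS": LabelRule("nuclei_fraction", 0.1)},
        seed=0,
    )
    with pytest.raises(ConfigError):
        generate_mutation_dataset(scene_config, plant)


def test_flip_noise_bounds():
    with pytest.raises(ConfigError):
        MutationPlantConfig(flip_noise=0.5)
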