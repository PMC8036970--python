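"""Training loop contracts: determinism, schedule mechanics, reduction."""

import numpy as np
import pandas as pd
import pytest

from immunoaizer import (
    GeneratorConfig,
    MutationPlantConfig,
    SceneConfig,
    SemiSupSchedule,
    TgmdnSchedule,
    build_discriminator,
    build_generator,
    build_tgmdn,
    evaluate_mutations,
    evaluate_segmentation,
    generate_dataset,
    generate_mutation_dataset,
    generate_scene,
    one_hot_encode,
    train_semi_supervised,
    train_supervised,
    train_tgmdn,
)
from immunoaizer.losses import LossWeights


def _params(net):
    return {k: p.data.copy() for k, p in net.named_parameters()}


def _assert_params_equal(a, b):
    assert a.keys() == b.keys()
    for k in a:
        np.testing.assert_array_equal(a[k], b[k])


@pytest.fixture(scope="module")
def tiny_labeled():
    cfg = SceneConfig(height=32, width=32, blob_count_range=(1, 3), blob_radius_range=(3, 7), seed=0)
    labeled, _ = generate_dataset(cfg, 6, 0, master_seed=3)
    return labeled


def _gen32(seed=0):
    return build_generator(GeneratorConfig(input_size=32, seed=seed))


def test_zero_steps_leaves_parameters_unchanged(tiny_labeled):
    g = _gen32()
    before = _params(g)
    sched = SemiSupSchedule(generator_warmup_steps=0, joint_steps=0, semi_activation_step=0, batch_size=2)
    g, history = train_supervised(g, tiny_labeled, sched)
    _assert_params_equal(before, _params(g))
    assert len(history) == 0


def test_supervised_determinism(tiny_labeled):
    sched = SemiSupSchedule(generator_warmup_steps=4, joint_steps=0, semi_activation_step=0,
                            batch_size=2, seed=9)
    g1, h1 = train_supervised(_gen32(), tiny_labeled, sched)
    g2, h2 = train_supervised(_gen32(), tiny_labeled, sched)
    _assert_params_equal(_params(g1), _params(g2))
    pd.testing.assert_frame_equal(h1, h2)


def test_supervised_requires_data():
    sched = SemiSupSchedule(generator_warmup_steps=1, joint_steps=0, semi_activation_step=0)
    with pytest.raises(ValueError):
        train_supervised(_gen32(), [], sched)


def test_history_steps_monotone(tiny_labeled):
    sched = SemiSupSchedule(generator_warmup_steps=5, joint_steps=0, semi_activation_step=0, batch_size=2)
    _, history = train_supervised(_gen32(), tiny_labeled, sched)
    assert (np.diff(history["step"]) == 1).all()
    assert np.isfinite(history["loss_ce"]).all()


def test_zero_weight_semi_reduces_to_supervised():
    cfg = SceneConfig(seed=0)
    labeled, unlabeled = generate_dataset(cfg, 4, 4, master_seed=5)
    sched = SemiSupSchedule(
        generator_warmup_steps=2, joint_steps=3, semi_activation_step=2, batch_size=2,
        weights=LossWeights(0.0, 0.0, 0.0, 0.5), seed=11,
    )
    g_sup, _ = train_supervised(build_generator(seed=2), labeled, sched)
    g_semi, _, _ = train_semi_supervised(
        build_generator(seed=2), build_discriminator(seed=3), labeled, unlabeled, sched
    )
    _assert_params_equal(_params(g_sup), _params(g_semi))


def test_semi_history_exposes_activation_schedule():
    cfg = SceneConfig(seed=0)
    labeled, unlabeled = generate_dataset(cfg, 4, 6, master_seed=6)
    sched = SemiSupSchedule(generator_warmup_steps=1, joint_steps=5, semi_activation_step=4,
                            batch_size=2, seed=0)
    _, _, history = train_semi_supervised(
        build_generator(seed=0), build_discriminator(seed=1), labeled, unlabeled, sched
    )
    before = history[history["step"] < 4]
    after = history[(history["step"] >= 4) & (history["phase"] == "joint")]
    assert (before["loss_semi"] == 0.0).all()
    assert len(after) > 0 and np.isfinite(after["loss_semi"]).all()
    assert set(history["phase"]) == {"warmup", "joint"}


def test_semi_determinism():
    cfg = SceneConfig(seed=0)
    labeled, unlabeled = generate_dataset(cfg, 3, 3, master_seed=7)
    sched = SemiSupSchedule(generator_warmup_steps=1, joint_steps=2, semi_activation_step=1,
                            batch_size=2, seed=21)
    runs = []
    for _ in range(2):
        g, d, _ = train_semi_supervised(
            build_generator(seed=4), build_discriminator(seed=5), labeled, unlabeled, sched
        )
        runs.append((_params(g), _params(d)))
    _assert_params_equal(runs[0][0], runs[1][0])
    _assert_params_equal(runs[0][1], runs[1][1])


def test_schedule_scaling_preserves_proportions():
    sched = SemiSupSchedule()
    small = sched.scaled(0.001)
    assert small.generator_warmup_steps == 10
    assert small.joint_steps == 300
    assert small.semi_activation_step == 100
    with pytest.raises(ValueError):
        SemiSupSchedule(generator_warmup_steps=1, joint_steps=1, semi_activation_step=10)


# -- mutation training ------------------------------------------------------

@pytest.fixture(scope="module")
def mutation_data():
    cfg = SceneConfig(seed=0)
    plant = MutationPlantConfig(n_patches=60, flip_noise=0.0, seed=8)
    return generate_mutation_dataset(cfg, plant)


def test_tgmdn_determinism(mutation_data):
    patches, labels = mutation_data
    sched = TgmdnSchedule(epochs=2, seed=13)
    c1, h1 = train_tgmdn(build_tgmdn(seed=6), patches[:32], labels.iloc[:32], sched)
    c2, h2 = train_tgmdn(build_tgmdn(seed=6), patches[:32], labels.iloc[:32], sched)
    _assert_params_equal(_params(c1), _params(c2))
    pd.testing.assert_frame_equal(h1, h2)


def test_tgmdn_loss_decreases_on_easy_preset(mutation_data):
    patches, labels = mutation_data
    sched = TgmdnSchedule(epochs=5, seed=1)
    _, history = train_tgmdn(build_tgmdn(seed=7), patches, labels, sched)
    assert history["loss"].iloc[-1] < history["loss"].iloc[0]


def test_tgmdn_warns_on_single_polarity(mutation_data):
    patches, labels = mutation_data
    degenerate = labels.iloc[:8].copy()
    degenerate["APC"] = 1
    with pytest.warns(UserWarning):
        train_tgmdn(build_tgmdn(seed=0), patches[:8], degenerate, TgmdnSchedule(epochs=1))


# -- evaluation -------------------------------------------------------------

class _OracleGenerator:
    """Stands in for a perfectly trained generator."""

    def __init__(self, masks, n_classes=4):
        self.masks = list(masks)
        self.config = GeneratorConfig(n_classes=n_classes)

    def predict(self, images, batch_size=8):
        return np.stack([one_hot_encode(m, self.config.n_classes) for m in self.masks])


class _ConstantGenerator:
    def __init__(self, cls=0, n_classes=4):
        self.cls = cls
        self.config = GeneratorConfig(n_classes=n_classes)

    def predict(self, images, batch_size=8):
        n = len(images)
        h, w = np.asarray(images[0].pixels if hasattr(images[0], "pixels") else images[0]).shape[:2]
        probs = np.zeros((n, h, w, self.config.n_classes))
        probs[..., self.cls] = 1.0
        return probs


def test_evaluate_with_oracle_generator(scene_config):
    pairs = [generate_scene(scene_config, seed=[1, 0, i]) for i in range(4)]
    report = evaluate_segmentation(_OracleGenerator([m for _, m in pairs]), pairs)
    for v in report.as_dict().values():
        assert v == pytest.approx(1.0)


def test_constant_background_predictor_accuracy_equals_bg_fraction(scene_config):
    pairs = [generate_scene(scene_config, seed=[2, 0, i]) for i in range(4)]
    report = evaluate_segmentation(_ConstantGenerator(0), pairs)
    bg = np.mean([(m == 0).mean() for _, m in pairs])
    assert report.accuracy == pytest.approx(bg, abs=1e-12)


def test_global_vs_per_patch_modes_differ_in_aggregation(scene_config):
    pairs = [generate_scene(scene_config, seed=[3, 0, i]) for i in range(3)]
    gen = _ConstantGenerator(0)
    g = evaluate_segmentation(gen, pairs, mode="global")
    p = evaluate_segmentation(gen, pairs, mode="per_patch")
    assert 0 <= p.accuracy <= 1 and 0 <= g.accuracy <= 1


class _OracleClassifier:
    def __init__(self, labels):
        self.labels = np.asarray(labels, dtype=float)

    def predict(self, patches, batch_size=16):
        return np.clip(self.labels * 0.8 + 0.1, 0, 1)


def test_evaluate_mutations_oracle_and_undefined(mutation_data):
    patches, labels = mutation_data
    result = evaluate_mutations(_OracleClassifier(labels.to_numpy()), patches, labels)
    assert list(result) == ["APC", "TP53", "KRAS"]
    for gene in result:
        assert result[gene]["auc"] == 1.0
    degenerate = labels.copy()
    degenerate["KRAS"] = 0
    result = evaluate_mutations(_OracleClassifier(degenerate.to_numpy()), patches, degenerate)
    assert result["KRAS"]["auc"] is None and result["KRAS"]["roc"] is None
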