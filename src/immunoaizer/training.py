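"""Training schedules and loops for the segmentation and mutation networks.

The semi-supervised schedule follows the reference recipe: the generator is
first warmed up alone on labeled data (cross entropy only), then generator
and discriminator are trained jointly in alternating per-step updates, and
the self-training term on unlabeled data switches on only after a fixed
activation step. Default step counts (10k warmup / 300k joint / activation
at 100k), batch size 8, generator/discriminator learning rates 1e-3/1e-6,
Adam with beta1 = 0.9 and additive L2 weight decay 1e-8 mirror that recipe;
``scaled()`` shrinks all step counts by one factor so phase proportions are
preserved in desk-size runs.

Every loop is a pure function of (inputs, schedule): batches are drawn from
counter-seeded generator streams, and the semi-supervised trainer reduces
exactly to the supervised one when the adversarial and self-training
weights are zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import losses as L
from . import metrics as M
from .losses import LossWeights
from .networks import Discriminator, Generator, MutationClassifier, _stack_nchw
from .nn import Adam, RMSprop
from .pipeline import as_labels, one_hot_encode


@dataclass
class SemiSupSchedule:
    generator_warmup_steps: int = 10_000
    joint_steps: int = 300_000
    semi_activation_step: int = 100_000
    batch_size: int = 8
    lr_generator: float = 1e-3
    lr_discriminator: float = 1e-6
    beta1: float = 0.9
    weight_decay: float = 1e-8
    weights: LossWeights = field(default_factory=LossWeights)
    seed: int = 0
    reduction: str = "mean"  # per-pixel mean keeps gradients resolution-invariant
    semi_on_labeled: bool = False

    def __post_init__(self):
        if self.semi_activation_step > self.generator_warmup_steps + self.joint_steps:
            raise ValueError("semi_activation_step must lie within the training run")
        if min(self.lr_generator, self.lr_discriminator) <= 0:
            raise ValueError("learning rates must be positive")

    def scaled(self, factor: float) -> "SemiSupSchedule":
        """Shrink all step counts by ``factor``, preserving phase proportions."""
        return replace(
            self,
            generator_warmup_steps=max(1, round(self.generator_warmup_steps * factor)),
            joint_steps=max(1, round(self.joint_steps * factor)),
            semi_activation_step=max(1, round(self.semi_activation_step * factor)),
        )


@dataclass
class TgmdnSchedule:
    epochs: int = 100
    batch_size: int = 16
    lr: float = 0.01
    momentum: float = 0.9
    weight_decay: float = 1e-8
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 0 or self.batch_size <= 0 or self.lr <= 0:
            raise ValueError("schedule fields must be positive")


def _prepare_pairs(labeled, n_classes: int):
    imgs = [p for p, _ in labeled]
    masks = [as_labels(m) for _, m in labeled]
    x = _stack_nchw(imgs)
    y = np.stack([one_hot_encode(m, n_classes) for m in masks], axis=0)  # N,H,W,C
    return x, y


def _nhwc(p_nchw):
    return p_nchw.transpose(0, 2, 3, 1)


def _nchw(g_nhwc):
    return g_nhwc.transpose(0, 3, 1, 2)


def train_supervised(generator: Generator, labeled, schedule: SemiSupSchedule, discriminator: Discriminator | None = None):
    """Cross-entropy training of the generator on labeled pairs.

    With a discriminator attached, the labeled adversarial term
    (weight ``lambda_adv_labeled``) is added; the discriminator itself is
    not updated here. Runs warmup + joint steps.
    """
    if not labeled:
        raise ValueError("labeled set must be non-empty")
    c = generator.config.n_classes
    x, y = _prepare_pairs(labeled, c)
    n = x.shape[0]
    steps = schedule.generator_warmup_steps + schedule.joint_steps
    rng = np.random.default_rng([schedule.seed, 17])
    opt = Adam(
        generator.parameters(),
        lr=schedule.lr_generator,
        betas=(schedule.beta1, 0.999),
        weight_decay=schedule.weight_decay,
    )
    w = schedule.weights
    red = schedule.reduction
    generator.train()
    rows = []
    for step in range(steps):
        idx = rng.integers(0, n, schedule.batch_size)
        s = generator(x[idx])  # N,C,H,W probabilities
        s_last = _nhwc(s)
        lce = L.cross_entropy_loss(s_last, y[idx], red)
        grad = L.cross_entropy_grad(s_last, y[idx], red)
        ladv = 0.0
        if discriminator is not None and w.lambda_adv_labeled > 0:
            d = discriminator(s)
            ladv = L.adversarial_loss(d, red)
            discriminator.zero_grad()
            grad_s = discriminator.backward(L.adversarial_grad(d, red))
            grad = grad + w.lambda_adv_labeled * _nhwc(grad_s)
        generator.zero_grad()
        generator.backward(_nchw(grad))
        opt.step()
        rows.append({"step": step, "kind": "labeled", "loss_ce": lce, "loss_adv": ladv,
                     "loss_semi": 0.0, "loss_d": np.nan})
    history = pd.DataFrame(rows, columns=["step", "kind", "loss_ce", "loss_adv", "loss_semi", "loss_d"])
    _assert_finite(history)
    return generator, history


def train_semi_supervised(generator: Generator, discriminator: Discriminator, labeled, unlabeled, schedule: SemiSupSchedule):
    """Adversarial semi-supervised training.

    Phase 1: generator-only warmup on labeled data (cross entropy).
    Phase 2, per step: (a) discriminator update on (generator prediction,
    one-hot ground truth) pairs from a labeled batch; (b) generator update
    on the labeled batch (cross entropy + weighted adversarial term); and,
    once the global step reaches ``semi_activation_step``, (c) a generator
    update on an unlabeled batch with the weighted adversarial +
    self-training terms, the confidence map acting as a fixed mask.
    """
    if not labeled or not unlabeled:
        raise ValueError("labeled and unlabeled sets must be non-empty")
    c = generator.config.n_classes
    x, y = _prepare_pairs(labeled, c)
    xu = _stack_nchw(unlabeled)
    n, nu = x.shape[0], xu.shape[0]
    rng_lab = np.random.default_rng([schedule.seed, 17])
    rng_unl = np.random.default_rng([schedule.seed, 23])
    opt_g = Adam(generator.parameters(), lr=schedule.lr_generator,
                 betas=(schedule.beta1, 0.999), weight_decay=schedule.weight_decay)
    opt_d = Adam(discriminator.parameters(), lr=schedule.lr_discriminator,
                 betas=(schedule.beta1, 0.999), weight_decay=schedule.weight_decay)
    w = schedule.weights
    red = schedule.reduction
    generator.train()
    discriminator.train()
    rows = []

    for step in range(schedule.generator_warmup_steps):
        idx = rng_lab.integers(0, n, schedule.batch_size)
        s_last = _nhwc(generator(x[idx]))
        lce = L.cross_entropy_loss(s_last, y[idx], red)
        generator.zero_grad()
        generator.backward(_nchw(L.cross_entropy_grad(s_last, y[idx], red)))
        opt_g.step()
        rows.append({"step": step, "phase": "warmup", "kind": "labeled", "loss_ce": lce,
                     "loss_adv": 0.0, "loss_semi": 0.0, "loss_d": np.nan,
                     "loss_adv_unlabeled": 0.0})

    for k in range(schedule.joint_steps):
        step = schedule.generator_warmup_steps + k
        idx = rng_lab.integers(0, n, schedule.batch_size)
        s = generator(x[idx])
        s_last = _nhwc(s)
        y_batch = y[idx]

        # (a) discriminator update: prediction is fake, one-hot truth is real.
        # The two loss terms are independent, so each forward is backpropped
        # with its own gradient before the next forward overwrites the caches.
        d_on_s = discriminator(s)
        gs, _ = L.discriminator_loss_grads(d_on_s, np.ones_like(d_on_s), red)
        discriminator.zero_grad()
        discriminator.backward(gs)
        d_on_y = discriminator(_nchw(y_batch))
        _, gy = L.discriminator_loss_grads(np.zeros_like(d_on_y), d_on_y, red)
        loss_d = L.discriminator_loss(d_on_s, d_on_y, red)
        discriminator.backward(gy)
        opt_d.step()

        # (b) generator update on the labeled batch
        lce = L.cross_entropy_loss(s_last, y_batch, red)
        grad = L.cross_entropy_grad(s_last, y_batch, red)
        ladv = 0.0
        if w.lambda_adv_labeled > 0:
            d = discriminator(s)
            ladv = L.adversarial_loss(d, red)
            discriminator.zero_grad()
            grad_s = discriminator.backward(L.adversarial_grad(d, red))
            grad = grad + w.lambda_adv_labeled * _nhwc(grad_s)
        generator.zero_grad()
        generator.backward(_nchw(grad))
        opt_g.step()

        # (c) self-training on an unlabeled batch after activation
        lsemi = 0.0
        ladv_u = 0.0
        if step >= schedule.semi_activation_step and (w.lambda_adv_unlabeled > 0 or w.lambda_semi > 0):
            uidx = rng_unl.integers(0, nu, schedule.batch_size)
            su = generator(xu[uidx])
            su_last = _nhwc(su)
            du = discriminator(su)
            grad_u = np.zeros_like(su_last)
            if w.lambda_semi > 0:
                lsemi = L.semi_supervised_loss(su_last, du, w.t_semi, red)
                grad_u = grad_u + w.lambda_semi * L.semi_supervised_grad(su_last, du, w.t_semi, red)
            if w.lambda_adv_unlabeled > 0:
                ladv_u = L.adversarial_loss(du, red)
                discriminator.zero_grad()
                grad_su = discriminator.backward(L.adversarial_grad(du, red))
                grad_u = grad_u + w.lambda_adv_unlabeled * _nhwc(grad_su)
            generator.zero_grad()
            generator.backward(_nchw(grad_u))
            opt_g.step()

        rows.append({"step": step, "phase": "joint", "kind": "labeled+unlabeled",
                     "loss_ce": lce, "loss_adv": ladv, "loss_semi": lsemi,
                     "loss_d": loss_d, "loss_adv_unlabeled": ladv_u})

    history = pd.DataFrame(rows, columns=["step", "phase", "kind", "loss_ce", "loss_adv",
                                          "loss_semi", "loss_d", "loss_adv_unlabeled"])
    _assert_finite(history)
    return generator, discriminator, history


def _assert_finite(history: pd.DataFrame):
    numeric = history.select_dtypes("number")
    if not np.isfinite(numeric.fillna(0.0).to_numpy()).all():
        raise FloatingPointError("non-finite loss encountered during training")


def train_tgmdn(classifier: MutationClassifier, patches, labels, schedule: TgmdnSchedule):
    """Multilabel mutation training with RMSprop (momentum + L2 decay)."""
    y = labels.to_numpy(dtype=float) if isinstance(labels, pd.DataFrame) else np.asarray(labels, dtype=float)
    x = _stack_nchw(patches)
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least two training patches")
    for j in range(y.shape[1]):
        if y[:, j].min() == y[:, j].max():
            warnings.warn(f"label column {j} has a single polarity; AUC will be undefined", stacklevel=2)
    rng = np.random.default_rng([schedule.seed, 31])
    opt = RMSprop(classifier.parameters(), lr=schedule.lr, momentum=schedule.momentum,
                  weight_decay=schedule.weight_decay)
    classifier.train()
    rows = []
    for epoch in range(schedule.epochs):
        perm = rng.permutation(n)
        losses = []
        for i in range(0, n, schedule.batch_size):
            b = perm[i : i + schedule.batch_size]
            p = classifier(x[b])
            losses.append(L.multilabel_bce(p, y[b]))
            classifier.zero_grad()
            classifier.backward(L.multilabel_bce_grad(p, y[b]))
            opt.step()
        rows.append({"epoch": epoch, "loss": float(np.mean(losses))})
    history = pd.DataFrame(rows, columns=["epoch", "loss"])
    if len(history) and not np.isfinite(history["loss"]).all():
        raise FloatingPointError("non-finite loss during mutation training")
    return classifier, history


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def evaluate_segmentation(generator: Generator, pairs, mode: str = "global") -> M.MetricsReport:
    """Five-metric report over a test set of (patch, mask) pairs.

    ``mode='global'`` pools one confusion table over all pixels of all
    patches; ``mode='per_patch'`` averages per-patch metric values.
    """
    if not pairs:
        raise ValueError("test set must be non-empty")
    c = generator.config.n_classes
    probs = generator.predict([p for p, _ in pairs])
    preds = M.compress_to_labels(probs)
    truths = np.stack([as_labels(m) for _, m in pairs])
    if mode == "global":
        counts = M.confusion_counts(preds, truths, c)
        return M.report_from_counts(counts)
    if mode == "per_patch":
        reports = [M.report_from_counts(M.confusion_counts(p, t, c)) for p, t in zip(preds, truths)]
        return M.MetricsReport(**{k: float(np.mean([r.as_dict()[k] for r in reports]))
                                  for k in reports[0].as_dict()})
    raise ValueError(f"unknown mode {mode!r}")


def evaluate_mutations(classifier: MutationClassifier, patches, labels) -> dict:
    """Per-gene ROC and AUC, in (APC, TP53, KRAS) column order.

    Genes with a single label polarity get ``{"roc": None, "auc": None}``.
    """
    if isinstance(labels, pd.DataFrame):
        genes = list(labels.columns)
        y = labels.to_numpy(dtype=int)
    else:
        y = np.asarray(labels, dtype=int)
        genes = [f"label_{j}" for j in range(y.shape[1])]
    scores = classifier.predict(patches)
    out = {}
    for j, gene in enumerate(genes):
        try:
            roc, auc = M.roc_auc(scores[:, j], y[:, j])
            out[gene] = {"roc": roc, "auc": auc}
        except ValueError:
            out[gene] = {"roc": None, "auc": None}
    return out
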