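"""The three trainable function families.

* ``Generator`` — encoder-decoder segmentation network: conv stem, first
  max-pool, two residual blocks, inception-style multi-resolution stages
  (parallel 1x1 / factorized 1x3+3x1 / double 3x3 / pooled branches) with a
  1x1 "promotion" stage widening the representation, then a decoder with
  bilinear upsampling and U-Net-style encoder skip concatenation, ending in
  a per-pixel channel softmax. Output is a valid probability map of the
  input's spatial size.
* ``Discriminator`` — fully convolutional: five 4x4 stride-2 convolutions
  (channels 64/128/256/512/1 scaled by the width multiplier), batch norm +
  leaky ReLU after the first four, bilinear upsampling back to the input
  size, then a sigmoid squash to [0, 1]. Normalization/activation after the
  single-channel fifth convolution is deliberately omitted (normalizing a
  1-channel score before the squash is pathological).
* ``MutationClassifier`` — a small strided-conv encoder with global average
  pooling and two fully connected layers ending in three independent
  sigmoids (APC, TP53, KRAS); the penultimate FC activations serve as
  patch embeddings.

All builders are pure: the same config and seed give identical initial
parameters. Arrays are NCHW internally; ``predict`` helpers accept/return
channel-last image stacks.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from . import nn


@dataclass
class GeneratorConfig:
    n_classes: int = 4
    width_multiplier: float = 0.125
    input_size: int = 64
    use_residual_stem: bool = True
    n_inception_stages: int = 2
    seed: int = 0


@dataclass
class DiscriminatorConfig:
    n_classes: int = 4
    width_multiplier: float = 0.125
    seed: int = 0


@dataclass
class MutationClassifierConfig:
    width_multiplier: float = 0.125
    n_hidden: int = 16
    n_labels: int = 3
    seed: int = 0


def _width(base: int, mult: float, floor: int = 4) -> int:
    return max(floor, int(round(base * mult)))


def _cbr(cin, cout, kernel, rng, stride=1, padding=0):
    return nn.Sequential(
        nn.Conv2d(cin, cout, kernel, stride=stride, padding=padding, rng=rng),
        nn.BatchNorm2d(cout),
        nn.ReLU(),
    )


class InceptionBlock(nn.Module):
    """Four parallel multi-resolution branches concatenated channel-wise.

    Branches: 1x1; 1x1 -> 1x3 -> 3x1 (factorized); 1x1 -> 3x3 -> 3x3; and
    3x3 average pooling -> 1x1. ``cout`` must be divisible by 4.
    """

    def __init__(self, cin: int, cout: int, rng):
        super().__init__()
        if cout % 4:
            raise ValueError("inception output width must be divisible by 4")
        b = cout // 4
        self.branch1 = _cbr(cin, b, 1, rng)
        self.branch2 = nn.Sequential(
            *_cbr(cin, b, 1, rng).layers,
            *_cbr(b, b, (1, 3), rng, padding=(0, 1)).layers,
            *_cbr(b, b, (3, 1), rng, padding=(1, 0)).layers,
        )
        self.branch3 = nn.Sequential(
            *_cbr(cin, b, 1, rng).layers,
            *_cbr(b, b, 3, rng, padding=1).layers,
            *_cbr(b, b, 3, rng, padding=1).layers,
        )
        self.branch4 = nn.Sequential(nn.AvgPool2d(3, padding=1), *_cbr(cin, b, 1, rng).layers)
        self._branches = [self.branch1, self.branch2, self.branch3, self.branch4]
        self.cat = nn.Concat()

    def forward(self, x):
        return self.cat([br(x) for br in self._branches])

    def backward(self, grad):
        gs = self.cat.backward(grad)
        gx = None
        for br, g in zip(self._branches, gs):
            gb = br.backward(g)
            gx = gb if gx is None else gx + gb
        return gx


class Generator(nn.Module):
    """Encoder-decoder biomarker-distribution prediction network."""

    def __init__(self, config: GeneratorConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        c = config.n_classes
        w1 = _width(32, config.width_multiplier)
        w2 = _width(64, config.width_multiplier, floor=8)
        w3 = _width(128, config.width_multiplier, floor=8)
        if config.input_size % 4:
            raise ValueError("input_size must be divisible by 4")

        self.stem = _cbr(3, w1, 3, rng, padding=1)
        self.pool1 = nn.MaxPool2d(2)
        if config.use_residual_stem:
            def res_body():
                return nn.Sequential(
                    nn.Conv2d(w1, w1, 3, padding=1, rng=rng),
                    nn.BatchNorm2d(w1),
                    nn.ReLU(),
                    nn.Conv2d(w1, w1, 3, padding=1, rng=rng),
                    nn.BatchNorm2d(w1),
                )
            self.res = nn.Sequential(nn.Residual(res_body()), nn.Residual(res_body()))
        else:
            self.res = nn.Sequential()
        self.inc_a = InceptionBlock(w1, w2, rng)
        self.pool2 = nn.MaxPool2d(2)
        self.stages = nn.Sequential(
            *[InceptionBlock(w2, w2, rng) for _ in range(config.n_inception_stages)]
        )
        self.promote = _cbr(w2, w3, 1, rng)  # high-dimensional promotion
        self.up1 = nn.BilinearUpsample(scale=2)
        self.cat1 = nn.Concat()
        self.dec1 = _cbr(w3 + w2, w2, 3, rng, padding=1)
        self.up2 = nn.BilinearUpsample(scale=2)
        self.cat2 = nn.Concat()
        self.dec2 = _cbr(w2 + w1, w1, 3, rng, padding=1)
        self.head = nn.Conv2d(w1, c, 1, rng=rng)
        self.softmax = nn.ChannelSoftmax()

    def forward(self, x):
        s0 = self.stem(x)                       # H, w1
        p1 = self.pool1(s0)                     # H/2
        r = self.res(p1)                        # H/2, w1
        a = self.inc_a(r)                       # H/2, w2
        q = self.pool2(a)                       # H/4
        b = self.stages(q)                      # H/4, w2
        e = self.promote(b)                     # H/4, w3
        u1 = self.up1(e)                        # H/2
        d1 = self.dec1(self.cat1([u1, a]))      # H/2, w2
        u2 = self.up2(d1)                       # H
        d2 = self.dec2(self.cat2([u2, s0]))     # H, w1
        return self.softmax(self.head(d2))

    def backward(self, grad):
        g = self.head.backward(self.softmax.backward(grad))
        g = self.dec2.backward(g)
        g_u2, g_s0_skip = self.cat2.backward(g)
        g = self.dec1.backward(self.up2.backward(g_u2))
        g_u1, g_a_skip = self.cat1.backward(g)
        g = self.promote.backward(self.up1.backward(g_u1))
        g = self.stages.backward(g)
        g_a = self.pool2.backward(g) + g_a_skip
        g_r = self.inc_a.backward(g_a)
        g_p1 = self.res.backward(g_r)
        g_s0 = self.pool1.backward(g_p1) + g_s0_skip
        return self.stem.backward(g_s0)

    def predict(self, images, batch_size: int = 8) -> np.ndarray:
        """Probability maps for a channel-last image stack (eval mode)."""
        x = _stack_nchw(images)
        was_training = self.training
        self.eval()
        outs = []
        for i in range(0, x.shape[0], batch_size):
            outs.append(self.forward(x[i : i + batch_size]))
        if was_training:
            self.train()
        return np.concatenate(outs, axis=0).transpose(0, 2, 3, 1)


def _stack_nchw(images) -> np.ndarray:
    """List/stack of H x W x 3 images (or ImagePatch) -> N x 3 x H x W."""
    arrs = []
    for im in images:
        a = getattr(im, "pixels", im)
        arrs.append(np.asarray(a, dtype=float))
    return np.stack(arrs, axis=0).transpose(0, 3, 1, 2)


class Discriminator(nn.Module):
    """Fully convolutional real-vs-generated confidence network."""

    DOWN_FACTOR = 32  # five stride-2 convolutions

    def __init__(self, config: DiscriminatorConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        wm = config.width_multiplier
        c1, c2, c3, c4 = (_width(64, wm), _width(128, wm), _width(256, wm), _width(512, wm))
        self.body = nn.Sequential(
            nn.Conv2d(config.n_classes, c1, 4, stride=2, padding=1, rng=rng),
            nn.BatchNorm2d(c1),
            nn.LeakyReLU(0.2),
            nn.Conv2d(c1, c2, 4, stride=2, padding=1, rng=rng),
            nn.BatchNorm2d(c2),
            nn.LeakyReLU(0.2),
            nn.Conv2d(c2, c3, 4, stride=2, padding=1, rng=rng),
            nn.BatchNorm2d(c3),
            nn.LeakyReLU(0.2),
            nn.Conv2d(c3, c4, 4, stride=2, padding=1, rng=rng),
            nn.BatchNorm2d(c4),
            nn.LeakyReLU(0.2),
            nn.Conv2d(c4, 1, 4, stride=2, padding=1, rng=rng),
            nn.BilinearUpsample(scale=self.DOWN_FACTOR),
            nn.Sigmoid(),
        )

    def forward(self, x):
        if x.shape[1] != self.config.n_classes:
            raise ValueError(
                f"discriminator expects {self.config.n_classes} channels, got {x.shape[1]}"
            )
        if x.shape[2] % self.DOWN_FACTOR or x.shape[3] % self.DOWN_FACTOR:
            raise ValueError(f"input spatial size must be divisible by {self.DOWN_FACTOR}")
        return self.body(x)[:, 0]  # N x H x W confidence

    def backward(self, grad):
        return self.body.backward(grad[:, None])


class MutationClassifier(nn.Module):
    """Multilabel mutation detector: encoder + GAP + two FC layers + sigmoid."""

    def __init__(self, config: MutationClassifierConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        wm = config.width_multiplier
        c0 = _width(32, wm)
        c1, c2, c3 = _width(64, wm), _width(128, wm), _width(256, wm, floor=8)
        # 1x1 color-projection stem: gives global average pooling a direct
        # path to per-class color-fraction features
        self.encoder = nn.Sequential(
            nn.Conv2d(3, c0, 1, rng=rng),
            nn.BatchNorm2d(c0),
            nn.ReLU(),
            nn.Conv2d(c0, c1, 3, stride=2, padding=1, rng=rng),
            nn.BatchNorm2d(c1),
            nn.ReLU(),
            nn.Conv2d(c1, c2, 3, stride=2, padding=1, rng=rng),
            nn.BatchNorm2d(c2),
            nn.ReLU(),
            nn.Conv2d(c2, c3, 3, stride=2, padding=1, rng=rng),
            nn.BatchNorm2d(c3),
            nn.ReLU(),
            nn.GlobalAvgPool(),
        )
        self.fc1 = nn.Linear(c3, config.n_hidden, rng=rng)
        self.act = nn.ReLU()
        self.fc2 = nn.Linear(config.n_hidden, config.n_labels, rng=rng)
        self.sigmoid = nn.Sigmoid()
        self._features = None

    def forward(self, x):
        z = self.encoder(x - 0.5)  # center [0,1] inputs
        feats = self.act(self.fc1(z))
        self._features = feats
        return self.sigmoid(self.fc2(feats))

    def backward(self, grad):
        g = self.fc2.backward(self.sigmoid.backward(grad))
        g = self.fc1.backward(self.act.backward(g))
        return self.encoder.backward(g)

    def features(self, x) -> np.ndarray:
        """Penultimate fully connected activations (patch embeddings)."""
        self.forward(x)
        return self._features

    def predict(self, images, batch_size: int = 16) -> np.ndarray:
        x = _stack_nchw(images)
        was_training = self.training
        self.eval()
        outs = [self.forward(x[i : i + batch_size]) for i in range(0, x.shape[0], batch_size)]
        if was_training:
            self.train()
        return np.concatenate(outs, axis=0)


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

def build_generator(config: GeneratorConfig | None = None, **kwargs) -> Generator:
    return Generator(config or GeneratorConfig(**kwargs))


def build_discriminator(config: DiscriminatorConfig | None = None, **kwargs) -> Discriminator:
    return Discriminator(config or DiscriminatorConfig(**kwargs))


def build_tgmdn(config: MutationClassifierConfig | None = None, **kwargs) -> MutationClassifier:
    return MutationClassifier(config or MutationClassifierConfig(**kwargs))


def export_penultimate_features(classifier: MutationClassifier, patches, batch_size: int = 16) -> np.ndarray:
    """One fixed-length embedding row per patch, in input order."""
    x = _stack_nchw(patches)
    was_training = classifier.training
    classifier.eval()
    rows = [classifier.features(x[i : i + batch_size]) for i in range(0, x.shape[0], batch_size)]
    if was_training:
        classifier.train()
    return np.concatenate(rows, axis=0)


def network_config_dict(net) -> dict:
    """JSON-serialisable config sidecar for checkpoints."""
    return {"class": type(net).__name__, "config": asdict(net.config)}
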