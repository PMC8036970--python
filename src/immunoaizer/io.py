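"""Disk formats: PNG rasters, CSV tables, JSON manifests, npz checkpoints."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from PIL import Image


def save_image(path, pixels: np.ndarray):
    """Write an RGB float image in [0, 1] as 8-bit PNG."""
    arr = np.clip(np.asarray(pixels) * 255.0 + 0.5, 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="RGB").save(path)


def load_image(path) -> np.ndarray:
    """Read a raster as H x W x 3 floats in [0, 1]."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"), dtype=float) / 255.0


def save_mask(path, labels: np.ndarray):
    Image.fromarray(np.asarray(labels).astype(np.uint8), mode="L").save(path)


def load_mask(path) -> np.ndarray:
    with Image.open(path) as im:
        return np.asarray(im.convert("L"), dtype=np.uint8)


def write_json(path, obj):
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonable) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")


def save_checkpoint(path, net, extra: dict | None = None):
    """npz parameter/buffer dump + JSON sidecar with the network config."""
    from .networks import network_config_dict

    path = Path(path)
    np.savez(path, **net.state_dict())
    sidecar = network_config_dict(net)
    sidecar.update(extra or {})
    write_json(path.with_suffix(".json"), sidecar)


def load_checkpoint(path):
    """Rebuild a network from its npz + JSON sidecar."""
    from . import networks

    path = Path(path)
    meta = read_json(path.with_suffix(".json"))
    cls = {
        "Generator": (networks.Generator, networks.GeneratorConfig),
        "Discriminator": (networks.Discriminator, networks.DiscriminatorConfig),
        "MutationClassifier": (networks.MutationClassifier, networks.MutationClassifierConfig),
    }[meta["class"]]
    net = cls[0](cls[1](**meta["config"]))
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as data:
        net.load_state_dict({k: data[k] for k in data.files})
    return net, meta
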