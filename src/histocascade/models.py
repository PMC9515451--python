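"""Network architectures: the patch classifier and the dual-input refiner.

The patch classifier is a pluggable backbone followed by a fixed head:
global average pooling, a 100-unit dense layer, 50% dropout, ReLU, batch
normalisation, and a final dense softmax over the classes.  The default
backbone (``builtin_small``) is a compact 4-block CNN that trains offline
in minutes; heavier ImageNet-style backbones can be registered without
changing the head.

The refiner is a symmetric U-Net style convolutional autoencoder taking a
4-channel input (low-resolution RGB image concatenated with the tumor
probability heatmap) and producing a per-pixel 2-class softmax.  Encoder
blocks are (convolution - batch norm - ReLU) x 2 followed by max pooling;
the decoder mirrors them with nearest-neighbour upsampling and skip
connections.  The full-scale configuration is depth 9 with filters
(8, 16, 32, 64, 128, 128, 256, 256, 512) on a 1024 px input; reduced
configurations (e.g. depth 7 at 256 px) are first-class for desk-scale
work.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass

import numpy as np

from . import _nn as nn
from .errors import ConfigError, ModelError

__all__ = [
    "ClassifierSpec",
    "RefinerSpec",
    "PatchClassifier",
    "Refiner",
    "build_patch_classifier",
    "build_refiner",
    "register_backbone",
    "save_model",
    "load_model",
]

DEFAULT_REFINER_FILTERS = (8, 16, 32, 64, 128, 128, 256, 256, 512)


@dataclass(frozen=True)
class ClassifierSpec:
    backbone_id: str = "builtin_small"
    n_classes: int = 2
    patch_size: int = 256
    patch_magnification: float = 100.0
    seed: int = 0


@dataclass(frozen=True)
class RefinerSpec:
    input_size: int = 1024
    in_channels: int = 4
    depth: int = 9
    filters: tuple[int, ...] = DEFAULT_REFINER_FILTERS
    seed: int = 0

    def validate(self) -> None:
        if len(self.filters) != self.depth:
            raise ConfigError(
                f"filters has {len(self.filters)} entries for depth {self.depth}"
            )
        if self.input_size % 2 ** (self.depth - 1):
            raise ConfigError(
                f"input_size {self.input_size} not divisible by 2^{self.depth - 1}"
            )


def _builtin_small(rng: np.random.Generator) -> tuple[nn.Sequential, int]:
    """Compact backbone: 4x average-pool stem then 4 conv blocks."""
    layers = [
        nn.AvgPoolN(4),
        nn.Conv2d(3, 8, rng=rng), nn.BatchNorm(8), nn.ReLU(), nn.MaxPool2(),
        nn.Conv2d(8, 16, rng=rng), nn.BatchNorm(16), nn.ReLU(), nn.MaxPool2(),
        nn.Conv2d(16, 32, rng=rng), nn.BatchNorm(32), nn.ReLU(), nn.MaxPool2(),
        nn.Conv2d(32, 32, rng=rng), nn.BatchNorm(32), nn.ReLU(),
    ]
    return nn.Sequential(layers), 32


_BACKBONES = {"builtin_small": _builtin_small}


def register_backbone(backbone_id: str, builder) -> None:
    """Register ``builder(rng) -> (Sequential, n_features)`` under an id."""
    _BACKBONES[backbone_id] = builder


class PatchClassifier:
    """Backbone + fixed head mapping patches to class probabilities."""

    def __init__(self, spec: ClassifierSpec):
        if spec.backbone_id not in _BACKBONES:
            raise ConfigError(f"unknown backbone {spec.backbone_id!r}")
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        self.backbone, nfeat = _BACKBONES[spec.backbone_id](rng)
        self.gap = nn.GlobalAvgPool()
        self.dense1 = nn.Dense(nfeat, 100, rng=rng)
        self.dropout = nn.Dropout(0.5)
        self.relu = nn.ReLU()
        self.bn = nn.BatchNorm(100)
        self.dense2 = nn.Dense(100, spec.n_classes, rng=rng)
        self._head = [self.gap, self.dense1, self.dropout, self.relu,
                      self.bn, self.dense2]

    def head_description(self) -> list[str]:
        return [
            "global_average_pool",
            "dense(100)",
            "dropout(0.5)",
            "relu",
            "batch_norm",
            f"dense({self.spec.n_classes})+softmax",
        ]

    def params(self) -> list[nn.Param]:
        out = self.backbone.params()
        for l in self._head:
            out.extend(l.params())
        return out

    def forward_logits(self, x: np.ndarray, train: bool = False,
                       rng: np.random.Generator | None = None) -> np.ndarray:
        z = self.backbone.forward(x.astype(nn.F32), train=train, rng=rng)
        for l in self._head:
            z = l.forward(z, train=train, rng=rng)
        return z

    def backward_logits(self, dz: np.ndarray) -> None:
        for l in reversed(self._head):
            dz = l.backward(dz)
        self.backbone.backward(dz)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Inference-mode class probabilities for a batch of patches."""
        return nn.softmax(self.forward_logits(x, train=False))


class _EncBlock:
    def __init__(self, cin, cout, rng):
        self.seq = nn.Sequential([
            nn.Conv2d(cin, cout, rng=rng), nn.BatchNorm(cout), nn.ReLU(),
            nn.Conv2d(cout, cout, rng=rng), nn.BatchNorm(cout), nn.ReLU(),
        ])

    def params(self):
        return self.seq.params()


class Refiner:
    """Dual-input U-Net: (image, heatmap) 4-channel input, 2-class softmax."""

    def __init__(self, spec: RefinerSpec):
        spec.validate()
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        f = spec.filters
        d = spec.depth
        self.enc = []
        cin = spec.in_channels
        for i in range(d):
            self.enc.append(_EncBlock(cin, f[i], rng))
            cin = f[i]
        self.pools = [nn.MaxPool2() for _ in range(d - 1)]
        self.ups = [nn.UpsampleNearest2() for _ in range(d - 1)]
        self.dec = []
        for i in range(d - 2, -1, -1):
            # input: upsampled deeper features (f[i+1]) + skip from level i
            cin_dec = f[i + 1] + f[i]
            self.dec.append(_EncBlock(cin_dec, f[i], rng))
        self.out_conv = nn.Conv2d(f[0], 2, k=1, rng=rng)

    def params(self) -> list[nn.Param]:
        out = []
        for b in self.enc:
            out.extend(b.params())
        for b in self.dec:
            out.extend(b.params())
        out.extend(self.out_conv.params())
        return out

    def forward_probs(self, x: np.ndarray, train: bool = False,
                      rng: np.random.Generator | None = None) -> np.ndarray:
        spec = self.spec
        if x.ndim != 4 or x.shape[1] != spec.input_size or x.shape[3] != spec.in_channels:
            raise ModelError(
                f"refiner expects (B,{spec.input_size},{spec.input_size},"
                f"{spec.in_channels}), got {x.shape}"
            )
        d = spec.depth
        z = x.astype(nn.F32)
        skips = []
        for i in range(d - 1):
            z = self.enc[i].seq.forward(z, train=train, rng=rng)
            skips.append(z)
            z = self.pools[i].forward(z)
        z = self.enc[d - 1].seq.forward(z, train=train, rng=rng)
        self._skip_channels = []
        for j, i in enumerate(range(d - 2, -1, -1)):
            z = self.ups[j].forward(z)
            skip = skips[i]
            self._skip_channels.append((z.shape[-1], skip.shape[-1]))
            z = np.concatenate([z, skip], axis=-1)
            z = self.dec[j].seq.forward(z, train=train, rng=rng)
        logits = self.out_conv.forward(z)
        probs = nn.softmax(logits, axis=-1)
        self._probs = probs
        return probs

    def backward_probs(self, dprobs: np.ndarray) -> None:
        dz = nn.softmax_backward(self._probs, dprobs)
        self._probs = None
        self.backward_logits(dz)

    def backward_logits(self, dz: np.ndarray) -> None:
        d = self.spec.depth
        dz = self.out_conv.backward(dz)
        dskips = {}
        for j in range(d - 2, -1, -1):
            i = d - 2 - j  # encoder level fed by decoder block j
            dz = self.dec[j].seq.backward(dz)
            c_up, c_skip = self._skip_channels[j]
            dskips[i] = dz[..., c_up:]
            dz = self.ups[j].backward(dz[..., :c_up].astype(nn.F32))
        dz = self.enc[d - 1].seq.backward(dz)
        for i in range(d - 2, -1, -1):
            dz = self.pools[i].backward(dz)
            dz = (dz + dskips[i]).astype(nn.F32)
            dz = self.enc[i].seq.backward(dz)


def build_patch_classifier(spec: ClassifierSpec | None = None) -> PatchClassifier:
    return PatchClassifier(spec or ClassifierSpec())


def build_refiner(spec: RefinerSpec | None = None) -> Refiner:
    return Refiner(spec or RefinerSpec())


def save_model(model, path) -> None:
    """Serialise a model (spec + parameters + batch-norm statistics)."""
    state = {
        "kind": type(model).__name__,
        "spec": model.spec,
        "params": [p.value for p in model.params()],
        "bn_stats": _bn_stats(model),
    }
    with open(path, "wb") as fh:
        pickle.dump(state, fh)


def load_model(path):
    with open(path, "rb") as fh:
        state = pickle.load(fh)
    if state["kind"] == "PatchClassifier":
        model = PatchClassifier(state["spec"])
    elif state["kind"] == "Refiner":
        model = Refiner(state["spec"])
    else:  # pragma: no cover
        raise ModelError(f"unknown model kind {state['kind']!r}")
    for p, v in zip(model.params(), state["params"]):
        p.value[...] = v
    for bn, (m, v) in zip(_bn_layers(model), state["bn_stats"]):
        bn.run_mean[...] = m
        bn.run_var[...] = v
    return model


def _bn_layers(model) -> list[nn.BatchNorm]:
    out = []

    def scan(obj):
        if isinstance(obj, nn.BatchNorm):
            out.append(obj)
        elif isinstance(obj, nn.Sequential):
            for l in obj.layers:
                scan(l)
        elif isinstance(obj, _EncBlock):
            scan(obj.seq)

    if isinstance(model, PatchClassifier):
        scan(model.backbone)
        for l in model._head:
            scan(l)
    else:
        for b in model.enc:
            scan(b)
        for b in model.dec:
            scan(b)
    return out


def _bn_stats(model):
    return [(bn.run_mean.copy(), bn.run_var.copy()) for bn in _bn_layers(model)]
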