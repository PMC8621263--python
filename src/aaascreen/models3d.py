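"""Three 3D two-class volume classifiers: AlexNet-, VGG-16- and
ResNet-18-style topologies with volumetric kernels.

All three follow the canonical 2D layouts of their namesakes with every
convolution and pooling operation made three-dimensional. Channel counts
are scaled by a configurable ``width_multiplier`` (default 0.25) to keep
the memory footprint of volumetric feature maps manageable, and a global
average pool feeds the classifier head so any input shape divisible by the
network's total downsampling factor is accepted. Hidden activations are
ReLU throughout; the output layer is a two-way softmax
(class 0: no AAA, class 1: AAA).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .preprocess import Patch

ARCH_NAMES = ("alexnet3d", "vgg3d", "resnet3d")

#: Total spatial downsampling factor per architecture (input dims must divide).
DOWNSAMPLING = {"alexnet3d": 16, "vgg3d": 32, "resnet3d": 32}


@dataclass(frozen=True)
class ArchitectureSpec:
    """Construction recipe for one of the three classifiers.

    width_multiplier scales every channel count of the canonical topology;
    channel counts are rounded to at least 1.
    """

    name: str
    input_shape: tuple[int, int, int]
    width_multiplier: float = 0.25

    def __post_init__(self):
        if self.name not in ARCH_NAMES:
            raise ValueError(f"unknown architecture {self.name!r}; choose from {ARCH_NAMES}")
        if self.width_multiplier <= 0:
            raise ValueError("width_multiplier must be positive")
        d = DOWNSAMPLING[self.name]
        if any(s % d for s in self.input_shape):
            raise ValueError(
                f"{self.name} requires input dims divisible by {d}, got {self.input_shape}"
            )

    def width(self, base: int) -> int:
        return max(1, int(round(base * self.width_multiplier)))

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "input_shape": list(self.input_shape),
            "width_multiplier": self.width_multiplier,
        }

    @staticmethod
    def from_dict(d: dict) -> "ArchitectureSpec":
        return ArchitectureSpec(
            d["name"], tuple(d["input_shape"]), d["width_multiplier"]
        )


@dataclass(frozen=True)
class Prediction:
    """Two-class softmax output with a thresholded decision.

    ``predicted_class`` is 1 iff ``prob_aaa`` reaches the discrimination
    threshold (ties count as positive — screening favours sensitivity).
    """

    prob_no_aaa: float
    prob_aaa: float
    predicted_class: int


@dataclass
class Model:
    """A built network plus everything needed to reproduce it."""

    net: nn.Sequential
    spec: ArchitectureSpec
    seed: int

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.net.forward(x)

    def set_train(self, mode: bool) -> None:
        self.net.set_train(mode)


def _conv_relu(c_in, c_out, k, rng, stride=1, pad=None, bias=True):
    pad = k // 2 if pad is None else pad
    return [nn.Conv3d(c_in, c_out, k, stride=stride, pad=pad, bias=bias, rng=rng), nn.ReLU()]


def _build_alexnet(spec: ArchitectureSpec, rng) -> nn.Sequential:
    w = spec.width
    layers = []
    layers += _conv_relu(1, w(64), 7, rng, stride=2, pad=3)
    layers += [nn.MaxPool3d()]
    layers += _conv_relu(w(64), w(192), 5, rng)
    layers += [nn.MaxPool3d()]
    layers += _conv_relu(w(192), w(384), 3, rng)
    layers += _conv_relu(w(384), w(256), 3, rng)
    layers += _conv_relu(w(256), w(256), 3, rng)
    layers += [nn.MaxPool3d(), nn.GlobalAvgPool3d()]
    layers += [
        nn.Dropout(0.5, rng=np.random.default_rng(rng.integers(2**31))),
        nn.Linear(w(256), w(512), rng=rng),
        nn.ReLU(),
        nn.Dropout(0.5, rng=np.random.default_rng(rng.integers(2**31))),
        nn.Linear(w(512), 2, rng=rng),
    ]
    return nn.Sequential(layers)


_VGG_PLAN = [(64, 2), (128, 2), (256, 3), (512, 3), (512, 3)]


def _build_vgg(spec: ArchitectureSpec, rng) -> nn.Sequential:
    w = spec.width
    layers = []
    c_in = 1
    for base, n_convs in _VGG_PLAN:
        for _ in range(n_convs):
            layers += _conv_relu(c_in, w(base), 3, rng)
            c_in = w(base)
        layers += [nn.MaxPool3d()]
    layers += [
        nn.GlobalAvgPool3d(),
        nn.Linear(c_in, w(512), rng=rng),
        nn.ReLU(),
        nn.Dropout(0.5, rng=np.random.default_rng(rng.integers(2**31))),
        nn.Linear(w(512), 2, rng=rng),
    ]
    return nn.Sequential(layers)


def _basic_block(c_in, c_out, stride, rng) -> nn.ResidualBlock:
    # the closing BN of each block starts at gamma = 0 so every block is
    # initially the identity; residual branches then grow into the task,
    # which markedly shortens the early optimization plateau
    bn2 = nn.BatchNorm3d(c_out)
    bn2.gamma[...] = 0.0
    main = nn.Sequential(
        [
            nn.Conv3d(c_in, c_out, 3, stride=stride, pad=1, bias=False, rng=rng),
            nn.BatchNorm3d(c_out),
            nn.ReLU(),
            nn.Conv3d(c_out, c_out, 3, stride=1, pad=1, bias=False, rng=rng),
            bn2,
        ]
    )
    shortcut = None
    if stride != 1 or c_in != c_out:
        shortcut = nn.Sequential(
            [
                nn.Conv3d(c_in, c_out, 1, stride=stride, pad=0, bias=False, rng=rng),
                nn.BatchNorm3d(c_out),
            ]
        )
    return nn.ResidualBlock(main, shortcut)


def _build_resnet(spec: ArchitectureSpec, rng) -> nn.Sequential:
    w = spec.width
    layers = [
        nn.Conv3d(1, w(64), 7, stride=2, pad=3, bias=False, rng=rng),
        nn.BatchNorm3d(w(64)),
        nn.ReLU(),
        nn.MaxPool3d(),
    ]
    c_in = w(64)
    for base, stride in [(64, 1), (128, 2), (256, 2), (512, 2)]:
        layers.append(_basic_block(c_in, w(base), stride, rng))
        layers.append(_basic_block(w(base), w(base), 1, rng))
        c_in = w(base)
    layers += [nn.GlobalAvgPool3d(), nn.Linear(c_in, 2, rng=rng)]
    return nn.Sequential(layers)


_BUILDERS = {"alexnet3d": _build_alexnet, "vgg3d": _build_vgg, "resnet3d": _build_resnet}


def build_model(spec: ArchitectureSpec, seed: int) -> Model:
    """Construct and initialize a classifier; deterministic given seed."""
    rng = np.random.default_rng(seed)
    net = _BUILDERS[spec.name](spec, rng)
    net.set_train(False)
    return Model(net, spec, int(seed))


def describe(model: Model) -> list[dict]:
    """Ordered stage description: one entry per layer with its operation
    kind and, where applicable, kernel/stride/output channels."""
    out = []
    for path, layer in nn.named_layers(model.net):
        entry = {"path": path, "op": type(layer).__name__}
        if isinstance(layer, nn.Conv3d):
            entry.update(kernel=layer.kernel, stride=layer.stride, channels=layer.c_out)
        elif isinstance(layer, nn.Linear):
            entry.update(channels=layer.n_out)
        out.append(entry)
    return out


def predict(model: Model, patch: Patch, threshold: float = 0.5) -> Prediction:
    """Run one patch through the network in inference mode."""
    if tuple(patch.shape) != tuple(model.spec.input_shape):
        raise ValueError(
            f"patch shape {tuple(patch.shape)} does not match model input "
            f"{tuple(model.spec.input_shape)}"
        )
    model.set_train(False)
    x = np.asarray(patch.data, dtype=np.float32)[None, None]
    probs = nn.softmax(model.forward(x).astype(np.float64))[0]
    return Prediction(
        prob_no_aaa=float(probs[0]),
        prob_aaa=float(probs[1]),
        predicted_class=int(probs[1] >= threshold),
    )


def predict_proba(model: Model, patches: np.ndarray) -> np.ndarray:
    """Batched AAA probabilities for an (N, X, Y, Z) stack of patches."""
    model.set_train(False)
    x = np.asarray(patches, dtype=np.float32)[:, None]
    return nn.softmax(model.forward(x).astype(np.float64))[:, 1]


def save_checkpoint(model: Model, path, manifest: dict | None = None) -> None:
    """Serialize parameters + architecture spec + preprocessing manifest
    into a single .npz file, so inference is self-describing."""
    meta = {
        "spec": model.spec.to_dict(),
        "seed": model.seed,
        "manifest": manifest or {},
    }
    arrays = {"param/" + k: v for k, v in nn.parameters(model.net).items()}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> tuple[Model, dict]:
    """Rebuild a model from a checkpoint; returns (model, manifest)."""
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["__meta__"]).decode())
        state = {k[len("param/"):]: npz[k] for k in npz.files if k.startswith("param/")}
    model = build_model(ArchitectureSpec.from_dict(meta["spec"]), meta["seed"])
    nn.set_state(model.net, state)
    return model, meta.get("manifest", {})
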