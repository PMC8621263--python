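"""Composite network containers: Sequential and residual blocks.

A network is a tree of layers; parameter access, gradient zeroing,
train/eval switching and (de)serialization all walk the tree with stable
path names, so checkpoints are plain mappings from path to array.
"""

from __future__ import annotations

import numpy as np

from .layers import BatchNorm3d, Layer, ReLU


class Sequential(Layer):
    def __init__(self, layers):
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def set_train(self, mode):
        self.train_mode = mode
        for layer in self.layers:
            layer.set_train(mode)

    def children(self):
        return self.layers


class ResidualBlock(Layer):
    """Two 3×3×3 convolutions with identity (or projected) shortcut,
    ``out = relu(main(x) + shortcut(x))``."""

    def __init__(self, main: Sequential, shortcut: Sequential | None):
        self.main = main
        self.shortcut = shortcut  # None means identity

    def forward(self, x):
        y_main = self.main.forward(x)
        y_short = self.shortcut.forward(x) if self.shortcut is not None else x
        s = y_main + y_short
        self._cache = (y_main, y_short, s > 0)
        return np.where(self._cache[2], s, 0.0).astype(np.float32)

    def backward(self, dout):
        _, _, mask = self._cache
        d = np.where(mask, dout, 0.0).astype(np.float32)
        dx = self.main.backward(d)
        if self.shortcut is not None:
            dx = dx + self.shortcut.backward(d)
        else:
            dx = dx + d
        return dx

    def set_train(self, mode):
        self.train_mode = mode
        self.main.set_train(mode)
        if self.shortcut is not None:
            self.shortcut.set_train(mode)

    def children(self):
        return [self.main] + ([self.shortcut] if self.shortcut is not None else [])


def _walk(layer: Layer, prefix: str = ""):
    yield prefix, layer
    for i, child in enumerate(layer.children()):
        yield from _walk(child, f"{prefix}{i}.")


def named_layers(net: Layer):
    """Depth-first (path, layer) pairs; paths are stable across rebuilds."""
    return list(_walk(net))


def parameters(net: Layer) -> dict:
    out = {}
    for path, layer in named_layers(net):
        for name, arr in layer.params().items():
            out[path + name] = arr
        if isinstance(layer, BatchNorm3d):
            for name, arr in layer.state().items():
                out[path + name] = arr
    return out


def gradients(net: Layer) -> dict:
    out = {}
    for path, layer in named_layers(net):
        for name, arr in layer.grads().items():
            out[path + name] = arr
    return out


def zero_grads(net: Layer) -> None:
    for _, layer in named_layers(net):
        for arr in layer.grads().values():
            arr[...] = 0.0


def get_state(net: Layer) -> dict:
    return {k: v.copy() for k, v in parameters(net).items()}


def set_state(net: Layer, state: dict) -> None:
    params = parameters(net)
    missing = set(params) ^ set(state)
    if missing:
        raise KeyError(f"checkpoint/architecture mismatch on keys: {sorted(missing)[:5]}")
    for key, arr in params.items():
        if arr.shape != state[key].shape:
            raise ValueError(f"shape mismatch for {key}: {arr.shape} vs {state[key].shape}")
        arr[...] = state[key]


def calibrate_batchnorm(net: Layer, batches) -> None:
    """Refresh batch-norm running statistics for the current weights.

    During training the exponential running estimates trail the rapidly
    changing weights, which can leave inference-mode normalization far
    from the statistics the final weights actually produce — a large
    train/eval gap on short runs. This pass freezes the weights, streams
    ``batches`` (an iterable of input arrays) through the network with
    per-batch normalization, accumulates exact first and second moments
    per channel, and installs them as the running statistics.
    """
    bns = [layer for _, layer in _walk(net) if isinstance(layer, BatchNorm3d)]
    if not bns:
        return
    net.set_train(False)  # dropout off; BN overridden by the calibrating flag
    for bn in bns:
        bn.calibrating = True
        bn._calib = {
            "count": 0.0,
            "sum": np.zeros(bn.c, dtype=np.float64),
            "sumsq": np.zeros(bn.c, dtype=np.float64),
        }
    try:
        for x in batches:
            net.forward(x)
    finally:
        for bn in bns:
            acc = bn._calib
            if acc["count"] > 0:
                mean = acc["sum"] / acc["count"]
                var = acc["sumsq"] / acc["count"] - mean**2
                bn.running_mean = mean.astype(np.float32)
                bn.running_var = np.maximum(var, 0).astype(np.float32)
            bn.calibrating = False
            bn._calib = None


def count_parameters(net: Layer) -> int:
    """Number of trainable scalars (running BN statistics excluded)."""
    total = 0
    for _, layer in named_layers(net):
        for arr in layer.params().values():
            total += arr.size
    return total
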