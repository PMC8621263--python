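"""Loss and optimizer for the classifier networks."""

from __future__ import annotations

import numpy as np

from .model import Layer, gradients, parameters


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy over the batch; returns (loss, dlogits)."""
    n = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    eps = 1e-12
    loss = -np.log(p[np.arange(n), labels] + eps).mean()
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return float(loss), (dlogits / n).astype(np.float32)


class Adam:
    """Adam with optional decoupled weight decay (AdamW), state keyed by
    parameter path. Weight decay is not applied to normalization
    parameters or biases."""

    def __init__(self, net: Layer, lr=1e-4, betas=(0.9, 0.999), eps=1e-8, weight_decay=0.0):
        self.net = net
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m: dict[str, np.ndarray] = {}
        self._v: dict[str, np.ndarray] = {}

    def step(self) -> None:
        self.t += 1
        grads = gradients(self.net)
        params = parameters(self.net)
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for key, g in grads.items():
            m = self._m.setdefault(key, np.zeros_like(g))
            v = self._v.setdefault(key, np.zeros_like(g))
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p = params[key]
            if self.weight_decay and key.endswith(".W"):
                p -= self.lr * self.weight_decay * p
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
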