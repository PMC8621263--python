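"""Layer-wise relevance propagation for the 3D classifiers.

The classifier's pre-softmax score for a target class is decomposed into
one signed relevance value per input voxel by propagating relevance
backwards through the network. Positive values are evidence *for* the
target class (AAA when ``target_class=1``), negative values evidence
against it. Maps are standardized by dividing by their sum.

Rules
-----
``epsilon`` (default)
    The stabilized z-rule: contributions are weighted by their share of
    the stabilized pre-activation, ``R_j = x_j * [W^T (R / (z + ε·sign z))]_j``.
    With ε = 0 and a bias-free network the rule is exactly conservative:
    relevance sums to the explained score at every layer.
``zplus``
    The α=1/β=0 rule: only positive contributions propagate.

Bias contributions are absorbed (not redistributed), the standard
simplification; exact conservation therefore holds only for bias-free
networks. Batch-normalization layers are folded into their preceding
convolution before propagation, turning the network into a pure
linear/ReLU cascade for which the rules are defined. Max-pooling routes
relevance to the winning voxel; average pooling redistributes it
proportionally to each input's share.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from . import nn
from .models3d import Model
from .preprocess import Patch
from .volume import CTVolume, write_volume

RULES = ("epsilon", "zplus")


class UnsupportedLayerError(NotImplementedError):
    pass


@dataclass
class RelevanceMap:
    """Per-voxel signed relevance for one target class, aligned with its
    source patch."""

    data: np.ndarray
    target_class: int
    rule: str
    normalized: bool = False
    layer_sums: list = field(default_factory=list)  # conservation diagnostics
    score: float = 0.0  # the pre-softmax score that was decomposed

    @property
    def shape(self):
        return self.data.shape


# --------------------------------------------------------------------------
# batch-norm folding
# --------------------------------------------------------------------------

def _fold_conv_bn(conv: nn.Conv3d, bn: nn.BatchNorm3d) -> nn.Conv3d:
    scale = bn.gamma / np.sqrt(bn.running_var + bn.eps)
    folded = nn.Conv3d(
        conv.c_in, conv.c_out, conv.kernel, conv.stride, conv.pad, bias=True
    )
    folded.W = (conv.W * scale[:, None, None, None, None]).astype(np.float32)
    b = conv.b if conv.b is not None else 0.0
    folded.b = ((b - bn.running_mean) * scale + bn.beta).astype(np.float32)
    return folded


def _clone_linear(lin: nn.Linear) -> nn.Linear:
    out = nn.Linear(lin.n_in, lin.n_out, bias=lin.b is not None)
    out.W = lin.W.copy()
    if lin.b is not None:
        out.b = lin.b.copy()
    return out


def _clone_conv(conv: nn.Conv3d) -> nn.Conv3d:
    out = nn.Conv3d(conv.c_in, conv.c_out, conv.kernel, conv.stride, conv.pad, bias=conv.b is not None)
    out.W = conv.W.copy()
    if conv.b is not None:
        out.b = conv.b.copy()
    return out


def fold_batchnorm(net: nn.Layer) -> nn.Layer:
    """Return an inference-equivalent copy with every batch-norm layer
    folded into the convolution directly preceding it."""
    if isinstance(net, nn.Sequential):
        out = []
        for layer in net.layers:
            if isinstance(layer, nn.BatchNorm3d):
                if not out or not isinstance(out[-1], nn.Conv3d):
                    raise UnsupportedLayerError(
                        "BatchNorm3d without a preceding Conv3d cannot be folded"
                    )
                out[-1] = _fold_conv_bn(out[-1], layer)
            elif isinstance(layer, (nn.Sequential, nn.ResidualBlock)):
                out.append(fold_batchnorm(layer))
            elif isinstance(layer, nn.Conv3d):
                out.append(_clone_conv(layer))
            elif isinstance(layer, nn.Linear):
                out.append(_clone_linear(layer))
            elif isinstance(layer, nn.MaxPool3d):
                out.append(nn.MaxPool3d(layer.kernel))
            elif isinstance(layer, nn.Dropout):
                out.append(nn.Dropout(layer.p))
            elif isinstance(layer, (nn.ReLU, nn.GlobalAvgPool3d)):
                out.append(type(layer)())
            else:
                raise UnsupportedLayerError(
                    f"cannot fold or clone layer type {type(layer).__name__}"
                )
        return nn.Sequential(out)
    if isinstance(net, nn.ResidualBlock):
        main = fold_batchnorm(net.main)
        shortcut = fold_batchnorm(net.shortcut) if net.shortcut is not None else None
        return nn.ResidualBlock(main, shortcut)
    return net


# --------------------------------------------------------------------------
# propagation
# --------------------------------------------------------------------------

def _stabilize(z: np.ndarray, eps: float) -> np.ndarray:
    return z + eps * np.where(z >= 0, 1.0, -1.0)


def _safe_div(r: np.ndarray, z: np.ndarray) -> np.ndarray:
    out = np.zeros_like(r, dtype=np.float64)
    np.divide(r, z, out=out, where=z != 0)
    return out


def _prop_affine(layer, R, rule, eps):
    x = layer._x if isinstance(layer, nn.Linear) else layer._cache[2]
    if rule == "epsilon":
        z = layer._lin(x, layer.W, layer.b).astype(np.float64)
        s = _safe_div(R, _stabilize(z, eps)).astype(np.float32)
        c = layer.input_grad(s, W=layer.W, x_shape=x.shape)
        return (x * c).astype(np.float64)
    if rule == "zplus":
        wp = np.maximum(layer.W, 0.0)
        wn = np.minimum(layer.W, 0.0)
        xp = np.maximum(x, 0.0).astype(np.float32)
        xn = np.minimum(x, 0.0).astype(np.float32)
        z = layer._lin(xp, wp, None).astype(np.float64) + layer._lin(xn, wn, None)
        s = _safe_div(R, _stabilize(z, eps)).astype(np.float32)
        return (xp * layer.input_grad(s, W=wp, x_shape=x.shape)).astype(np.float64) + (
            xn * layer.input_grad(s, W=wn, x_shape=x.shape)
        )
    raise ValueError(f"unknown rule {rule!r}; choose from {RULES}")


def _propagate(layer, R, rule, eps):
    if isinstance(layer, nn.Sequential):
        for sub in reversed(layer.layers):
            R = _propagate(sub, R, rule, eps)
        return R
    if isinstance(layer, (nn.Conv3d, nn.Linear)):
        return _prop_affine(layer, R, rule, eps)
    if isinstance(layer, (nn.ReLU, nn.Dropout)):
        return R
    if isinstance(layer, nn.MaxPool3d):
        return layer.scatter_to_winners(R.astype(np.float32)).astype(np.float64)
    if isinstance(layer, nn.GlobalAvgPool3d):
        x = layer._x
        z = x.mean(axis=(2, 3, 4)).astype(np.float64)
        s = _safe_div(R, _stabilize(z, eps))
        vol = np.prod(x.shape[2:])
        return x * (s / vol)[:, :, None, None, None]
    if isinstance(layer, nn.ResidualBlock):
        y_main, y_short, _ = layer._cache
        total = _stabilize((y_main + y_short).astype(np.float64), eps)
        r_main = R * _safe_div(y_main.astype(np.float64), total)
        r_short = R * _safe_div(y_short.astype(np.float64), total)
        out = _propagate(layer.main, r_main, rule, eps)
        if layer.shortcut is not None:
            out = out + _propagate(layer.shortcut, r_short, rule, eps)
        else:
            out = out + r_short
        return out
    raise UnsupportedLayerError(
        f"no relevance rule implemented for layer type {type(layer).__name__}"
    )


def relevance_map(
    model: Model,
    patch: Patch,
    target_class: int = 1,
    rule: str = "epsilon",
    epsilon: float = 1e-6,
) -> RelevanceMap:
    """Decompose the target class's pre-softmax score over the input voxels.

    Returns an unnormalized map; ``layer_sums`` holds the total relevance
    after each top-level propagation step (for conservation checks).
    """
    if rule not in RULES:
        raise ValueError(f"unknown rule {rule!r}; choose from {RULES}")
    folded = fold_batchnorm(model.net)
    folded.set_train(False)
    x = np.asarray(patch.data, dtype=np.float32)[None, None]
    logits = folded.forward(x)
    score = float(logits[0, target_class])
    R = np.zeros_like(logits, dtype=np.float64)
    R[0, target_class] = score

    sums = []
    for sub in reversed(folded.layers):
        R = _propagate(sub, R, rule, epsilon)
        sums.append(float(R.sum()))
    return RelevanceMap(
        data=R[0, 0],
        target_class=target_class,
        rule=rule,
        normalized=False,
        layer_sums=sums,
        score=score,
    )


def normalize_map(rmap: RelevanceMap, tol: float = 1e-8) -> RelevanceMap:
    """Divide the map by its total sum so it sums to one.

    Idempotent on already-normalized maps; raises if the sum is within
    ``tol`` of zero (the decomposition then carries no net evidence and
    cannot be standardized).
    """
    total = float(rmap.data.sum())
    if abs(total) < tol:
        raise ValueError(f"map sum {total:.3e} too close to zero to normalize")
    if rmap.normalized and abs(total - 1.0) < 1e-9:
        return rmap
    return RelevanceMap(
        data=rmap.data / total,
        target_class=rmap.target_class,
        rule=rmap.rule,
        normalized=True,
        layer_sums=list(rmap.layer_sums),
        score=rmap.score,
    )


# --------------------------------------------------------------------------
# export and the aorta-agreement surrogate
# --------------------------------------------------------------------------

#: diverging overlay: strong negatives light blue, negatives blue,
#: positives red, strong positives yellow
_OVERLAY_CMAP = matplotlib.colors.LinearSegmentedColormap.from_list(
    "relevance", ["#9bd4ff", "#0040ff", "#000000", "#ff2000", "#ffff00"]
)


def export_overlay(
    rmap: RelevanceMap,
    patch: Patch,
    out_dir,
    spacing=(1.0, 1.0, 1.0),
    alpha: float = 0.6,
) -> dict:
    """Write the raw map as NIfTI plus per-axial-slice PNG overlays.

    The overlay blends the grayscale patch with a diverging colormap:
    maximum positive relevance maps to the yellow end, maximum negative to
    the light-blue end. A ``legend.json`` records the convention. Returns
    a small manifest of written files.
    """
    if rmap.shape != tuple(patch.shape):
        raise ValueError(f"map shape {rmap.shape} does not match patch {tuple(patch.shape)}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    nifti_path = out_dir / "relevance.nii.gz"
    write_volume(CTVolume(rmap.data.astype(np.float32), spacing), nifti_path)

    vmax = float(np.abs(rmap.data).max())
    norm = matplotlib.colors.Normalize(vmin=-vmax if vmax else -1, vmax=vmax if vmax else 1)
    slices = []
    for z in range(patch.shape[2]):
        gray = (np.asarray(patch.data[:, :, z]).T + 1.0) / 2.0
        rgb = np.stack([gray] * 3, axis=-1)
        rel = rmap.data[:, :, z].T
        colored = _OVERLAY_CMAP(norm(rel))[..., :3]
        weight = alpha * (np.abs(rel) / vmax if vmax else np.zeros_like(rel))[..., None]
        blend = (1 - weight) * rgb + weight * colored
        png = out_dir / f"slice_{z:04d}.png"
        plt.imsave(png, np.clip(blend, 0, 1), origin="lower")
        slices.append(png.name)

    legend = {
        "colormap": "diverging",
        "max_positive": "yellow",
        "positive": "red",
        "negative": "blue",
        "max_negative": "light blue",
        "target_class": rmap.target_class,
        "rule": rmap.rule,
        "normalized": rmap.normalized,
    }
    (out_dir / "legend.json").write_text(json.dumps(legend, indent=2))
    return {"nifti": nifti_path.name, "slices": slices, "legend": "legend.json"}


def aorta_relevance_fraction(rmap: RelevanceMap, region_mask: np.ndarray) -> float:
    """Share of total absolute relevance lying inside a region mask.

    Positive and negative relevance count equally. The chance baseline is
    the mask's volume fraction; values above it mean the decision evidence
    concentrates in the region.
    """
    mask = np.asarray(region_mask, dtype=bool)
    if mask.shape != rmap.shape:
        raise ValueError(f"mask shape {mask.shape} does not match map {rmap.shape}")
    if not mask.any():
        raise ValueError("region mask is empty")
    total = float(np.abs(rmap.data).sum())
    if total == 0:
        raise ValueError("all-zero relevance map; fraction undefined")
    return float(np.abs(rmap.data[mask]).sum() / total)
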