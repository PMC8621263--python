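"""Minimal 3D neural-network layers in numpy.

Each layer implements ``forward`` (caching what backward needs),
``backward`` (returning the input gradient and accumulating parameter
gradients), and exposes its parameters/gradients by name. Convolutions use
an im2col lowering so the inner loop is a single BLAS matmul; pooling uses
a non-overlapping reshape. Everything runs in float32.

The layer set is deliberately small and fully introspectable, which is
what makes exact layer-wise relevance propagation possible downstream.

Array layout: activations are ``(N, C, X, Y, Z)``.
"""

from __future__ import annotations

from itertools import product

import numpy as np
import scipy.fft as sfft
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    """Base class: stateless by default, trainable layers override params()."""

    train_mode: bool = False

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def params(self) -> dict:
        return {}

    def grads(self) -> dict:
        return {}

    def set_train(self, mode: bool) -> None:
        self.train_mode = mode

    def children(self) -> list:
        return []


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Conv3d(Layer):
    """3D convolution with isotropic kernel, stride and zero padding.

    Two equivalent computational routes are used, chosen by kernel volume:
    im2col + BLAS matmul for small kernels (3³, 1³) and circular-FFT
    correlation for large ones (the 7³/5³ stem convolutions, where the
    im2col lowering would be memory-traffic bound). Both routes agree to
    float32 round-off; gradient tests cover both.
    """

    #: use the FFT route when c_in * kernel³ reaches this
    FFT_THRESHOLD = 300

    def __init__(self, c_in, c_out, kernel, stride=1, pad=0, bias=True, rng=None):
        self.c_in, self.c_out = int(c_in), int(c_out)
        self.kernel, self.stride, self.pad = int(kernel), int(stride), int(pad)
        rng = rng or np.random.default_rng(0)
        k = self.kernel
        fan_in = self.c_in * k ** 3
        self.W = _he_init(rng, (self.c_out, self.c_in, k, k, k), fan_in)
        self.b = np.zeros(self.c_out, dtype=np.float32) if bias else None
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b) if bias else None
        self._cache = None

    @property
    def _use_fft(self) -> bool:
        return self.c_in * self.kernel ** 3 >= self.FFT_THRESHOLD

    def out_shape(self, spatial):
        k, s, p = self.kernel, self.stride, self.pad
        return tuple((n + 2 * p - k) // s + 1 for n in spatial)

    # -- FFT route -------------------------------------------------------
    #
    # The circular-correlation identities used below:
    #   forward:      out[m] = full_corr(x, W)[(m·s − p) mod L]
    #   input grad:   dx[j]  = full_conv(up(dout), W)[(j + p) mod L]
    #   weight grad:  dW[t]  = full_corr(x, up(dout))[(t − p) mod L]
    # where up(·) is zero-insertion upsampling by the stride. Two exact
    # stride shortcuts avoid full-size transforms where possible: the
    # forward spectrum is phase-shifted and folded along the first two
    # axes, so the inverse transform is evaluated only on the subsampled
    # grid; and the spectrum of up(dout) equals the spectrum of dout at
    # size L/s tiled s times, so it is computed with small transforms.

    def _fshape(self, spatial):
        s = self.stride
        out = []
        for n in spatial:
            f = sfft.next_fast_len(n + 2 * self.pad)
            while f % s:
                f = sfft.next_fast_len(f + 1)
            out.append(f)
        return out

    def _fft_forward(self, x, W, b, xh_out=None):
        s, p, k = self.stride, self.pad, self.kernel
        spatial = x.shape[2:]
        fshape = self._fshape(spatial)
        xh = sfft.rfftn(x, fshape, axes=(2, 3, 4))
        if xh_out is not None:
            xh_out.append(xh)
        wh = sfft.rfftn(W, fshape, axes=(2, 3, 4))
        if self.c_in == 1:  # plain broadcast beats einsum for the outer product
            prod = xh * np.conj(wh)[None, :, 0]
        else:
            prod = np.einsum("ncxyz,fcxyz->nfxyz", xh, np.conj(wh))
        ox = self.out_shape(spatial)
        if s > 1:
            # fold axes 2 and 3 (full-length spectra): phase-shift by the
            # padding, then alias the spectrum down to length L/s, which
            # yields the DFT of the stride-subsampled output directly
            for ax, L in ((2, fshape[0]), (3, fshape[1])):
                phase = np.exp(-2j * np.pi * np.arange(L) * p / L).astype(np.complex64)
                shape = [1] * prod.ndim
                shape[ax] = L
                prod = prod * phase.reshape(shape)
                m = L // s
                split = prod.shape[:ax] + (s, m) + prod.shape[ax + 1 :]
                prod = prod.reshape(split).sum(axis=ax) / s
            small = (fshape[0] // s, fshape[1] // s, fshape[2])
            full = sfft.irfftn(prod, small, axes=(2, 3, 4))
            idz = (np.arange(ox[2]) * s - p) % fshape[2]
            out = full[:, :, : ox[0], : ox[1], idz]
        else:
            full = sfft.irfftn(prod, fshape, axes=(2, 3, 4))
            idx = [(np.arange(o) - p) % f for o, f in zip(ox, fshape)]
            out = full[:, :, idx[0]][:, :, :, idx[1]][:, :, :, :, idx[2]]
        if b is not None:
            out = out + b[None, :, None, None, None]
        return np.ascontiguousarray(out, dtype=np.float32)

    def _upsampled_spectrum(self, dout, fshape):
        """rfftn of the zero-inserted upsampling of ``dout`` on the fshape
        grid, computed from small transforms along the first two axes."""
        s = self.stride
        if s == 1:
            return sfft.rfftn(dout, fshape, axes=(2, 3, 4))
        small = (fshape[0] // s, fshape[1] // s, fshape[2])
        # z axis keeps the full length: upsample it in the spatial domain
        n, f, ox, oy, oz = dout.shape
        dz = np.zeros((n, f, ox, oy, fshape[2]), dtype=np.float32)
        dz[..., 0 : oz * s : s] = dout
        dh = sfft.rfftn(dz, (small[0], small[1], fshape[2]), axes=(2, 3, 4))
        return np.tile(dh, (1, 1, s, s, 1))

    def _fft_input_grad(self, dout, W, spatial, uh=None):
        p, k = self.pad, self.kernel
        fshape = self._fshape(spatial)
        if uh is None:
            uh = self._upsampled_spectrum(dout, fshape)
        wh = sfft.rfftn(W, fshape, axes=(2, 3, 4))
        prod = np.einsum("nfxyz,fcxyz->ncxyz", uh, wh)
        full = sfft.irfftn(prod, fshape, axes=(2, 3, 4))
        idx = [(np.arange(n) + p) % f for n, f in zip(spatial, fshape)]
        return np.ascontiguousarray(
            full[:, :, idx[0]][:, :, :, idx[1]][:, :, :, :, idx[2]], dtype=np.float32
        )

    def _fft_weight_grad(self, x, dout, uh=None, xh=None):
        p, k = self.pad, self.kernel
        spatial = x.shape[2:]
        fshape = self._fshape(spatial)
        if xh is None:
            xh = sfft.rfftn(x, fshape, axes=(2, 3, 4))
        if uh is None:
            uh = self._upsampled_spectrum(dout, fshape)
        prod = np.einsum("ncxyz,nfxyz->fcxyz", xh, np.conj(uh))
        full = sfft.irfftn(prod, fshape, axes=(2, 3, 4))
        idx = [(np.arange(k) - p) % f for f in fshape]
        return np.ascontiguousarray(
            full[:, :, idx[0]][:, :, :, idx[1]][:, :, :, :, idx[2]], dtype=np.float32
        )

    # -- im2col route ----------------------------------------------------

    def _im2col(self, x):
        k, s, p = self.kernel, self.stride, self.pad
        if p:
            x = np.pad(x, ((0, 0), (0, 0)) + ((p, p),) * 3, constant_values=0.0)
        view = sliding_window_view(x, (k, k, k), axis=(2, 3, 4))[:, :, ::s, ::s, ::s]
        n, c, ox, oy, oz = view.shape[:5]
        cols = np.ascontiguousarray(view.transpose(0, 2, 3, 4, 1, 5, 6, 7)).reshape(
            n * ox * oy * oz, c * k ** 3
        )
        return cols, (n, ox, oy, oz), x.shape

    def _lin(self, x, W, b):
        """Affine part of the layer with arbitrary weights, no caching
        (used by the relevance-propagation gradient trick)."""
        x = np.ascontiguousarray(x, dtype=np.float32)
        if self._use_fft:
            return self._fft_forward(x, W, b)
        cols, (n, ox, oy, oz), _ = self._im2col(x)
        out = cols @ W.reshape(self.c_out, -1).T
        if b is not None:
            out += b
        return np.ascontiguousarray(
            out.reshape(n, ox, oy, oz, self.c_out).transpose(0, 4, 1, 2, 3)
        )

    def forward(self, x):
        x = np.ascontiguousarray(x, dtype=np.float32)
        if self._use_fft:
            xh_out: list = []
            out = self._fft_forward(x, self.W, self.b, xh_out)
            self._cache = (None, x.shape, x, xh_out[0])
            return out
        cols, (n, ox, oy, oz), _ = self._im2col(x)
        out = cols @ self.W.reshape(self.c_out, -1).T
        if self.b is not None:
            out += self.b
        self._cache = (cols, x.shape, x)
        return np.ascontiguousarray(
            out.reshape(n, ox, oy, oz, self.c_out).transpose(0, 4, 1, 2, 3)
        )

    def input_grad(self, dout, W=None, x_shape=None):
        """Gradient w.r.t. the input for cotangent ``dout`` (shared by
        backprop and the relevance-propagation gradient trick)."""
        W = self.W if W is None else W
        x_shape = self._cache[1] if x_shape is None else x_shape
        if self._use_fft:
            return self._fft_input_grad(dout, W, x_shape[2:])
        k, s, p = self.kernel, self.stride, self.pad
        n, _, ox, oy, oz = dout.shape
        dmat = dout.transpose(0, 2, 3, 4, 1).reshape(-1, self.c_out)
        dcols = (dmat @ W.reshape(self.c_out, -1)).reshape(
            n, ox, oy, oz, self.c_in, k, k, k
        )
        padded = tuple(m + 2 * p for m in x_shape[2:])
        dxp = np.zeros((n, self.c_in) + padded, dtype=np.float32)
        dview = dcols.transpose(0, 4, 1, 2, 3, 5, 6, 7)
        for i, j, l in product(range(k), repeat=3):
            dxp[:, :, i : i + s * ox : s, j : j + s * oy : s, l : l + s * oz : s] += dview[
                ..., i, j, l
            ]
        if p:
            dxp = dxp[:, :, p:-p, p:-p, p:-p]
        return np.ascontiguousarray(dxp)

    def backward(self, dout):
        cols, x_shape, x = self._cache[:3]
        dmat = dout.transpose(0, 2, 3, 4, 1).reshape(-1, self.c_out)
        if self._use_fft:
            spatial = x_shape[2:]
            fshape = self._fshape(spatial)
            # one spectrum of the (upsampled) cotangent serves both grads
            uh = self._upsampled_spectrum(dout, fshape)
            self.dW += self._fft_weight_grad(x, dout, uh=uh, xh=self._cache[3])
            if self.b is not None:
                self.db += dmat.sum(axis=0)
            return self._fft_input_grad(dout, self.W, spatial, uh=uh)
        self.dW += (dmat.T @ cols).reshape(self.W.shape)
        if self.b is not None:
            self.db += dmat.sum(axis=0)
        return self.input_grad(dout)

    def params(self):
        p = {"W": self.W}
        if self.b is not None:
            p["b"] = self.b
        return p

    def grads(self):
        g = {"W": self.dW}
        if self.b is not None:
            g["b"] = self.db
        return g


class Linear(Layer):
    def __init__(self, n_in, n_out, bias=True, rng=None):
        rng = rng or np.random.default_rng(0)
        self.n_in, self.n_out = int(n_in), int(n_out)
        self.W = _he_init(rng, (n_out, n_in), n_in)
        self.b = np.zeros(n_out, dtype=np.float32) if bias else None
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b) if bias else None
        self._x = None

    def _lin(self, x, W, b):
        out = x @ W.T
        if b is not None:
            out += b
        return out

    def forward(self, x):
        self._x = x
        return self._lin(x, self.W, self.b)

    def input_grad(self, dout, W=None, x_shape=None):
        return dout @ (self.W if W is None else W)

    def backward(self, dout):
        self.dW += dout.T @ self._x
        if self.b is not None:
            self.db += dout.sum(axis=0)
        return self.input_grad(dout)

    def params(self):
        p = {"W": self.W}
        if self.b is not None:
            p["b"] = self.b
        return p

    def grads(self):
        g = {"W": self.dW}
        if self.b is not None:
            g["b"] = self.db
        return g


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, dout):
        return np.where(self._mask, dout, 0.0).astype(np.float32)


class MaxPool3d(Layer):
    """Non-overlapping max pooling (kernel = stride = 2).

    Spatial dimensions must be even; odd trailing voxels would silently
    change the receptive-field arithmetic, so they are rejected.
    """

    def __init__(self, kernel: int = 2):
        self.kernel = int(kernel)

    def forward(self, x):
        k = self.kernel
        n, c, X, Y, Z = x.shape
        if X % k or Y % k or Z % k:
            raise ValueError(f"MaxPool3d requires dims divisible by {k}, got {(X, Y, Z)}")
        view = x.reshape(n, c, X // k, k, Y // k, k, Z // k, k)
        view = view.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(
            n, c, X // k, Y // k, Z // k, k ** 3
        )
        self._argmax = view.argmax(axis=-1)
        self._in_shape = x.shape
        return np.ascontiguousarray(view.max(axis=-1))

    def scatter_to_winners(self, vals):
        """Place per-window values at the argmax position (used by both
        backward and winner-take-all relevance routing)."""
        k = self.kernel
        n, c, X, Y, Z = self._in_shape
        onehot = (
            self._argmax[..., None] == np.arange(k ** 3, dtype=self._argmax.dtype)
        )
        out = (onehot * vals[..., None]).reshape(
            n, c, X // k, Y // k, Z // k, k, k, k
        )
        return np.ascontiguousarray(
            out.transpose(0, 1, 2, 5, 3, 6, 4, 7).reshape(n, c, X, Y, Z)
        )

    def backward(self, dout):
        return self.scatter_to_winners(dout)


class GlobalAvgPool3d(Layer):
    """Mean over all spatial positions; output is (N, C)."""

    def forward(self, x):
        self._in_shape = x.shape
        self._x = x
        return x.mean(axis=(2, 3, 4))

    def backward(self, dout):
        n, c, X, Y, Z = self._in_shape
        return np.broadcast_to(
            dout[:, :, None, None, None] / (X * Y * Z), self._in_shape
        ).astype(np.float32)


class BatchNorm3d(Layer):
    """Per-channel batch normalization over (N, spatial)."""

    def __init__(self, c, momentum=0.1, eps=1e-5):
        self.c = int(c)
        self.momentum = momentum
        self.eps = eps
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.dgamma = np.zeros(c, dtype=np.float32)
        self.dbeta = np.zeros(c, dtype=np.float32)
        self._n_updates = 0
        self.calibrating = False  # see nn.model.calibrate_batchnorm
        self._calib = None

    def _bshape(self, x):
        return (1, self.c) + (1,) * (x.ndim - 2)

    def forward(self, x):
        bs = self._bshape(x)
        if self.calibrating:
            # statistics-refresh pass with frozen weights: normalize with
            # batch stats while accumulating exact moments over the pass
            axes = (0,) + tuple(range(2, x.ndim))
            count = x.size / self.c
            self._calib["count"] += count
            self._calib["sum"] += x.sum(axis=axes)
            self._calib["sumsq"] += (x.astype(np.float64) ** 2).sum(axis=axes)
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            inv = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean.reshape(bs)) * inv.reshape(bs)
            return (self.gamma.reshape(bs) * xhat + self.beta.reshape(bs)).astype(np.float32)
        if self.train_mode:
            axes = (0,) + tuple(range(2, x.ndim))
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            # seed the running estimates with the first batch so that
            # inference statistics are sane even after very short runs
            mom = 1.0 if self._n_updates == 0 else self.momentum
            self._n_updates += 1
            self.running_mean = ((1 - mom) * self.running_mean + mom * mean).astype(
                np.float32
            )
            self.running_var = ((1 - mom) * self.running_var + mom * var).astype(
                np.float32
            )
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(bs)) * inv.reshape(bs)
        self._cache = (xhat, inv, x.shape)
        return (self.gamma.reshape(bs) * xhat + self.beta.reshape(bs)).astype(np.float32)

    def backward(self, dout):
        xhat, inv, shape = self._cache
        bs = self._bshape(dout)
        axes = (0,) + tuple(range(2, dout.ndim))
        m = dout.size / self.c
        self.dgamma += (dout * xhat).sum(axis=axes)
        self.dbeta += dout.sum(axis=axes)
        if self.train_mode:
            dxhat = dout * self.gamma.reshape(bs)
            dx = (
                dxhat
                - dxhat.mean(axis=axes).reshape(bs)
                - xhat * (dxhat * xhat).mean(axis=axes).reshape(bs)
            ) * inv.reshape(bs)
        else:
            dx = dout * (self.gamma * inv).reshape(bs)
        return dx.astype(np.float32)

    def params(self):
        return {"gamma": self.gamma, "beta": self.beta}

    def grads(self):
        return {"gamma": self.dgamma, "beta": self.dbeta}

    def state(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, p=0.5, rng=None):
        self.p = float(p)
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x):
        if not self.train_mode or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p).astype(np.float32) / (1 - self.p)
        return x * self._mask

    def backward(self, dout):
        if self._mask is None:
            return dout
        return dout * self._mask
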