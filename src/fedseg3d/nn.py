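"""Minimal numpy neural-network engine for small 3D segmentation models.

Layers operate on single samples shaped ``(C, D, H, W)`` (the training batch
size is 1 throughout, which also sidesteps batch statistics — normalization
is group normalization, which is batch-size independent).  Every layer
caches what its backward pass needs; gradients are accumulated into
``layer.grads`` keyed like ``layer.params``.

Convolutions build their im2col matrix by 27 contiguous offset-slice copies
(rather than a strided gather) and run one BLAS matmul per pass; the input
gradient is reconstructed by the mirrored 27 slice-adds.  Compute is
float32 — at the parameter counts used here the memory traffic, not the
arithmetic, is the cost, and float32 halves it.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "DTYPE",
    "Layer",
    "Conv3d",
    "ConvTranspose3d",
    "GroupNorm",
    "ReLU",
    "Sigmoid",
    "MaxPool3d",
    "Adam",
    "he_normal",
]

DTYPE = np.float32


def he_normal(shape, fan_in: int, rng: np.random.Generator) -> np.ndarray:
    """He-normal initialization: N(0, sqrt(2/fan_in)) — matched to ReLU nets."""
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(DTYPE)


class Layer:
    """Base layer: parameter/grad dicts plus forward/backward contract."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def zero_grads(self) -> None:
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}


@njit(fastmath=True)
def _conv3_fwd(xp, W, out):
    """out[f] += sum_{c,i,j,l} W[f,i,j,l,c] * xp[c] shifted by (i,j,l)."""
    cout, cin = out.shape[0], xp.shape[0]
    d, h, w = out.shape[1], out.shape[2], out.shape[3]
    for f in range(cout):
        for c in range(cin):
            for i in range(3):
                for j in range(3):
                    for l in range(3):
                        wv = W[f, i, j, l, c]
                        for z in range(d):
                            for y in range(h):
                                for x in range(w):
                                    out[f, z, y, x] += wv * xp[c, z + i, y + j, x + l]


@njit(fastmath=True)
def _conv3_bwd(xp, W, g, gxp, gW):
    """Input and weight gradients of _conv3_fwd in one pass."""
    cout, cin = g.shape[0], xp.shape[0]
    d, h, w = g.shape[1], g.shape[2], g.shape[3]
    for f in range(cout):
        for c in range(cin):
            for i in range(3):
                for j in range(3):
                    for l in range(3):
                        wv = W[f, i, j, l, c]
                        s = np.float32(0.0)
                        for z in range(d):
                            for y in range(h):
                                for x in range(w):
                                    gv = g[f, z, y, x]
                                    s += gv * xp[c, z + i, y + j, x + l]
                                    gxp[c, z + i, y + j, x + l] += wv * gv
                        gW[f, i, j, l, c] += s


class Conv3d(Layer):
    """3D convolution, stride 1, 'same' zero padding; kernel 3 or 1.

    Weights are stored as a (cout, cin * k^3) matrix whose column order is
    offset-major: for offset index o = (i*k + j)*k + l the columns
    [o*cin, (o+1)*cin) hold the cin input channels at that kernel offset.
    The k=3 path runs compiled direct-convolution kernels; k=1 is a plain
    channel matmul.
    """

    def __init__(self, cin: int, cout: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        if kernel not in (1, 3):
            raise ValueError("kernel must be 1 or 3")
        self.cin, self.cout, self.k = cin, cout, kernel
        self.pad = kernel // 2
        fan_in = cin * kernel**3
        self.params["weight"] = he_normal((cout, fan_in), fan_in, rng)
        self.params["bias"] = np.zeros(cout, dtype=DTYPE)
        self.zero_grads()
        self._xp: np.ndarray | None = None
        self._shape: tuple | None = None

    def _w5(self, arr):
        # offset-major (cout, cin*27) matrix viewed as (cout, 3, 3, 3, cin)
        return arr.reshape(self.cout, 3, 3, 3, self.cin)

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=DTYPE)
        cin, d, h, w = x.shape
        assert cin == self.cin
        self._shape = (d, h, w)
        if self.k == 1:
            self._xp = x.reshape(cin, -1)
            out = self.params["weight"] @ self._xp
            out += self.params["bias"][:, None]
            return out.reshape(self.cout, d, h, w)
        xp = np.pad(x, [(0, 0)] + [(1, 1)] * 3)
        out = np.empty((self.cout, d, h, w), dtype=DTYPE)
        out[...] = self.params["bias"].reshape(-1, 1, 1, 1)
        _conv3_fwd(xp, self._w5(self.params["weight"]), out)
        self._xp = xp
        return out

    def backward(self, gout: np.ndarray) -> np.ndarray:
        d, h, w = self._shape
        g = np.ascontiguousarray(gout, dtype=DTYPE)
        self.grads["bias"] += g.reshape(self.cout, -1).sum(axis=1)
        if self.k == 1:
            gflat = g.reshape(self.cout, -1)
            self.grads["weight"] += gflat @ self._xp.T
            gx = self.params["weight"].T @ gflat
            self._xp = None
            return gx.reshape(self.cin, d, h, w)
        gxp = np.zeros_like(self._xp)
        _conv3_bwd(
            self._xp,
            self._w5(self.params["weight"]),
            g,
            gxp,
            self._w5(self.grads["weight"]),
        )
        self._xp = None
        return gxp[:, 1 : 1 + d, 1 : 1 + h, 1 : 1 + w]


class ConvTranspose3d(Layer):
    """Transposed 3D convolution, kernel 2, stride 2 — doubles each axis."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        super().__init__()
        self.cin, self.cout = cin, cout
        fan_in = cin * 8
        # stored as (8, cin, cout): one (cin, cout) matrix per output offset
        self.params["weight"] = he_normal((8, cin, cout), fan_in, rng)
        self.params["bias"] = np.zeros(cout, dtype=DTYPE)
        self.zero_grads()
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=DTYPE)
        cin, d, h, w = x.shape
        xf = x.reshape(cin, -1)
        self._x = xf
        out = np.empty((self.cout, d, 2, h, 2, w, 2), dtype=DTYPE)
        W = self.params["weight"]
        for o in range(8):
            i, j, l = o >> 2 & 1, o >> 1 & 1, o & 1
            out[:, :, i, :, j, :, l] = (W[o].T @ xf).reshape(self.cout, d, h, w)
        out = out.reshape(self.cout, 2 * d, 2 * h, 2 * w)
        out += self.params["bias"].reshape(-1, 1, 1, 1)
        self._shape = (d, h, w)
        return out

    def backward(self, gout: np.ndarray) -> np.ndarray:
        d, h, w = self._shape
        g = np.asarray(gout, dtype=DTYPE).reshape(self.cout, d, 2, h, 2, w, 2)
        self.grads["bias"] += gout.sum(axis=(1, 2, 3))
        gx = np.zeros((self.cin, d * h * w), dtype=DTYPE)
        W = self.params["weight"]
        for o in range(8):
            i, j, l = o >> 2 & 1, o >> 1 & 1, o & 1
            go = np.ascontiguousarray(g[:, :, i, :, j, :, l]).reshape(self.cout, -1)
            self.grads["weight"][o] += self._x @ go.T
            gx += W[o] @ go
        self._x = None
        return gx.reshape(self.cin, d, h, w)


class GroupNorm(Layer):
    """Group normalization over (channels-in-group x spatial), per sample."""

    def __init__(self, channels: int, groups: int, eps: float = 1e-5):
        super().__init__()
        if channels % groups:
            raise ValueError("groups must divide the channel count")
        self.c, self.g, self.eps = channels, groups, eps
        self.params["gamma"] = np.ones(channels, dtype=DTYPE)
        self.params["beta"] = np.zeros(channels, dtype=DTYPE)
        self.zero_grads()

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=DTYPE)
        xg = x.reshape(self.g, -1)
        mu = xg.mean(axis=1, keepdims=True)
        var = xg.var(axis=1, keepdims=True)
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = ((xg - mu) * self._inv).reshape(x.shape)
        return self._xhat * self.params["gamma"].reshape(-1, 1, 1, 1) + self.params[
            "beta"
        ].reshape(-1, 1, 1, 1)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        gout = np.asarray(gout, dtype=DTYPE)
        xhat = self._xhat
        self.grads["gamma"] += (gout * xhat).sum(axis=(1, 2, 3))
        self.grads["beta"] += gout.sum(axis=(1, 2, 3))
        dxhat = (gout * self.params["gamma"].reshape(-1, 1, 1, 1)).reshape(self.g, -1)
        xh = xhat.reshape(self.g, -1)
        gx = self._inv * (
            dxhat
            - dxhat.mean(axis=1, keepdims=True)
            - xh * (dxhat * xh).mean(axis=1, keepdims=True)
        )
        self._xhat = None
        return gx.reshape(gout.shape)


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.asarray(x, dtype=DTYPE) * self._mask

    def backward(self, gout: np.ndarray) -> np.ndarray:
        g = np.asarray(gout, dtype=DTYPE) * self._mask
        self._mask = None
        return g


class Sigmoid(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._y = 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=DTYPE)))
        return self._y

    def backward(self, gout: np.ndarray) -> np.ndarray:
        g = np.asarray(gout, dtype=DTYPE) * self._y * (1.0 - self._y)
        self._y = None
        return g


class MaxPool3d(Layer):
    """2x2x2 max pooling, stride 2; requires even spatial extents."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        c, d, h, w = x.shape
        if d % 2 or h % 2 or w % 2:
            raise ValueError("spatial extents must be even for 2x pooling")
        blocks = np.asarray(x, dtype=DTYPE).reshape(c, d // 2, 2, h // 2, 2, w // 2, 2)
        out = blocks.max(axis=(2, 4, 6))
        # route gradient to max positions (ties share; measure-zero for floats)
        self._mask = blocks == out[:, :, None, :, None, :, None]
        self._shape = x.shape
        return out

    def backward(self, gout: np.ndarray) -> np.ndarray:
        c, d, h, w = self._shape
        counts = self._mask.sum(axis=(2, 4, 6), dtype=DTYPE)
        g = (np.asarray(gout, dtype=DTYPE) / counts)[
            :, :, None, :, None, :, None
        ] * self._mask
        self._mask = None
        return g.reshape(c, d, h, w)


class Adam:
    """Adam over a dict of parameter arrays (keyed by qualified name)."""

    def __init__(self, lr: float = 1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        self.t += 1
        for k, p in params.items():
            g = grads[k].astype(np.float64)
            m = self.m.setdefault(k, np.zeros(p.shape))
            v = self.v.setdefault(k, np.zeros(p.shape))
            m += (1 - self.b1) * (g - m)
            v += (1 - self.b2) * (g * g - v)
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)
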