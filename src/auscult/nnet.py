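"""Minimal CPU backprop engine: conv/pool/dense layers with Adam.

Convolutions run as im2col + one BLAS GEMM per pass; the col2im scatter-add in the
backward pass is a numba kernel (the only place where slice-wise numpy accumulation
is the bottleneck). Everything is float32. Layers cache what the backward pass needs
when called with ``train=True``.

Shapes are channels-last: (batch, height, width, channels).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit
from numpy.lib.stride_tricks import as_strided

F32 = np.float32


# ---------------------------------------------------------------------------
# im2col / col2im
# ---------------------------------------------------------------------------

def same_pad(size: int, k: int, stride: int) -> tuple[int, int, int]:
    """TF-style SAME padding: output ceil(size/stride), excess padding at the end."""
    out = -(-size // stride)
    pad = max((out - 1) * stride + k - size, 0)
    return out, pad // 2, pad - pad // 2


def im2col(xp: np.ndarray, kh: int, kw: int, sr: int, sc: int,
           ho: int, wo: int, out: np.ndarray | None = None) -> np.ndarray:
    """Window extraction on a padded (B, Hp, Wp, C) array -> (B*ho*wo, kh*kw*C).

    Rows are ordered (ki, kj, c), matching a kernel reshaped as (kh*kw*C, Cout).
    ``out`` lets callers reuse a persistent buffer (these are the largest
    allocations in the package; reallocating them every step dominates runtime).
    """
    b, hp, wp, c = xp.shape
    s = xp.strides
    v = as_strided(xp, shape=(b, ho, wo, kh, kw * c),
                   strides=(s[0], s[1] * sr, s[2] * sc, s[1], s[3]))
    if out is None:
        out = np.empty((b * ho * wo, kh * kw * c), dtype=F32)
    np.copyto(out.reshape(b, ho, wo, kh, kw * c), v)
    return out


@njit(cache=True)
def _col2im_add(dcols, dxp, kh, kw, ho, wo, sr, sc):
    """Scatter-add column gradients back onto the padded input gradient."""
    b, hp, wpc = dxp.shape[0], dxp.shape[1], dxp.shape[2] * dxp.shape[3]
    c = dxp.shape[3]
    dx = dxp.reshape(b, hp, wpc)
    dc = dcols.reshape(b, ho, wo, kh, kw * c)
    for bi in range(b):
        for i in range(ho):
            for ki in range(kh):
                r = i * sr + ki
                for j in range(wo):
                    base = j * sc * c
                    for t in range(kw * c):
                        dx[bi, r, base + t] += dc[bi, i, j, ki, t]


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

class Conv2D:
    """SAME-padded 2-D convolution with optional ReLU."""

    def __init__(self, kh, kw, cin, cout, stride=(1, 1), relu=True, rng=None):
        rng = rng or np.random.default_rng(0)
        scale = math.sqrt(2.0 / (kh * kw * cin))
        self.w = (rng.standard_normal((kh, kw, cin, cout)) * scale).astype(F32)
        self.b = np.zeros(cout, dtype=F32)
        self.kh, self.kw, self.cin, self.cout = kh, kw, cin, cout
        self.stride = stride
        self.relu = relu
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._cache = None
        self._bufs: dict = {}  # persistent scratch, keyed by batch size

    @property
    def n_params(self) -> int:
        return (self.kh * self.kw * self.cin + 1) * self.cout

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]

    def _scratch(self, name: str, shape) -> np.ndarray:
        buf = self._bufs.get(name)
        if buf is None or buf.shape != shape:
            buf = np.empty(shape, dtype=F32)
            self._bufs[name] = buf
        return buf

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        b, h, w, _ = x.shape
        sr, sc = self.stride
        ho, pt, pb = same_pad(h, self.kh, sr)
        wo, pl, pr = same_pad(w, self.kw, sc)
        xp = self._scratch("xp", (b, h + pt + pb, w + pl + pr, self.cin))
        xp.fill(0.0)
        xp[:, pt:pt + h, pl:pl + w, :] = x
        cols = im2col(xp, self.kh, self.kw, sr, sc, ho, wo,
                      out=self._scratch("cols", (b * ho * wo, self.kh * self.kw * self.cin)))
        wm = self.w.reshape(-1, self.cout)
        z = np.matmul(cols, wm, out=self._scratch("z", (b * ho * wo, self.cout)))
        z += self.b
        out = z.reshape(b, ho, wo, self.cout)
        if self.relu:
            np.maximum(out, 0, out=out)
        if train:
            self._cache = (cols, out if self.relu else None,
                           (b, h, w, ho, wo, pt, pl, xp.shape))
        return out.copy() if not train else out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, act, (b, h, w, ho, wo, pt, pl, xpshape) = self._cache
        self._cache = None
        sr, sc = self.stride
        d = dout.reshape(-1, self.cout)
        if self.relu:
            d = d * (act.reshape(-1, self.cout) > 0)
        wm = self.w.reshape(-1, self.cout)
        # (cout, k) GEMM orientation is measurably faster than (k, cout) here
        self.dw += (d.T @ cols).T.reshape(self.w.shape)
        self.db += d.sum(axis=0)
        dcols = np.matmul(d, wm.T, out=self._scratch("dcols", cols.shape))
        dxp = self._scratch("dxp", xpshape)
        dxp.fill(0.0)
        _col2im_add(dcols.reshape(b, ho, wo, self.kh, self.kw * self.cin),
                    dxp, self.kh, self.kw, ho, wo, sr, sc)
        return dxp[:, pt:pt + h, pl:pl + w, :]


@njit(cache=True)
def _maxpool_fwd(x, out, idx, kh, kw):
    b, h, w, c = x.shape
    ho, wo = h // kh, w // kw
    for bi in range(b):
        for i in range(ho):
            for j in range(wo):
                for ci in range(c):
                    best = x[bi, i * kh, j * kw, ci]
                    arg = 0
                    for ki in range(kh):
                        for kj in range(kw):
                            v = x[bi, i * kh + ki, j * kw + kj, ci]
                            if v > best:
                                best = v
                                arg = ki * kw + kj
                    out[bi, i, j, ci] = best
                    idx[bi, i, j, ci] = arg


@njit(cache=True)
def _maxpool_bwd(dout, idx, dx, kh, kw):
    b, ho, wo, c = dout.shape
    for bi in range(b):
        for i in range(ho):
            for j in range(wo):
                for ci in range(c):
                    a = idx[bi, i, j, ci]
                    dx[bi, i * kh + a // kw, j * kw + a % kw, ci] = dout[bi, i, j, ci]


class MaxPool2D:
    """VALID max pooling; kernel equals stride (the only case the model needs).

    The first-maximum tie-break matches the raster scan order of the window.
    """

    def __init__(self, kh, kw):
        self.kh, self.kw = kh, kw
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        b, h, w, c = x.shape
        ho, wo = h // self.kh, w // self.kw
        x = np.ascontiguousarray(x[:, :ho * self.kh, :wo * self.kw, :], dtype=F32)
        out = np.empty((b, ho, wo, c), dtype=F32)
        idx = np.empty((b, ho, wo, c), dtype=np.int8)
        _maxpool_fwd(x, out, idx, self.kh, self.kw)
        if train:
            self._cache = (idx, (b, h, w, c))
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        idx, (b, h, w, c) = self._cache
        self._cache = None
        dx = np.zeros((b, h, w, c), dtype=F32)
        _maxpool_bwd(np.ascontiguousarray(dout, dtype=F32), idx, dx, self.kh, self.kw)
        return dx


class Dense:
    """Fully connected layer with optional activation ('relu', 'tanh', or None)."""

    def __init__(self, nin, nout, activation=None, rng=None):
        rng = rng or np.random.default_rng(0)
        scale = math.sqrt(2.0 / nin) if activation == "relu" else math.sqrt(1.0 / nin)
        self.w = (rng.standard_normal((nin, nout)) * scale).astype(F32)
        self.b = np.zeros(nout, dtype=F32)
        self.activation = activation
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._cache = None

    @property
    def n_params(self) -> int:
        return (self.w.shape[0] + 1) * self.w.shape[1]

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        z = x @ self.w + self.b
        if self.activation == "relu":
            out = np.maximum(z, 0)
        elif self.activation == "tanh":
            out = np.tanh(z)
        else:
            out = z
        if train:
            self._cache = (x, out)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x, out = self._cache
        self._cache = None
        if self.activation == "relu":
            dout = dout * (out > 0)
        elif self.activation == "tanh":
            dout = dout * (1.0 - out * out)
        self.dw += x.T @ dout
        self.db += dout.sum(axis=0)
        return dout @ self.w.T


# ---------------------------------------------------------------------------
# Loss and optimizer
# ---------------------------------------------------------------------------

def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_xent(logits: np.ndarray, y: np.ndarray,
                 denom: int | None = None) -> tuple[float, np.ndarray]:
    """Summed cross-entropy / denom and the gradient wrt logits.

    ``denom`` defaults to the number of rows; passing the full mini-batch size lets a
    large batch be accumulated over smaller forward/backward chunks.
    """
    p = softmax(logits.astype(np.float64))
    n = logits.shape[0]
    d = n if denom is None else denom
    loss = float(-np.log(np.clip(p[np.arange(n), y], 1e-30, None)).sum() / d)
    g = p.copy()
    g[np.arange(n), y] -= 1.0
    return loss, (g / d).astype(F32)


def zero_grads(layers) -> None:
    for layer in layers:
        if hasattr(layer, "params"):
            for _, g in layer.params():
                g.fill(0.0)


class Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)  # (value, grad) pairs; updated in place
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in self.params]
        self.v = [np.zeros_like(p) for p, _ in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * (g * g)
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
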