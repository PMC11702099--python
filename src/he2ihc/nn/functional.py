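"""Convolution, pooling, resampling and classification primitives.

Layout convention is NCHW throughout. Convolutions are realized as
im2col + GEMM with explicit adjoint passes, so the transposed convolution
is exactly the adjoint of the corresponding strided convolution.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor


# ----------------------------------------------------------- numpy conv core

def _pad_hw(x: np.ndarray, p: int) -> np.ndarray:
    if p == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))


def _im2col(x: np.ndarray, k: int, s: int, p: int):
    x = _pad_hw(x, p)
    n, c, h, w = x.shape
    ho = (h - k) // s + 1
    wo = (w - k) // s + 1
    sn, sc, sh, sw = x.strides
    cols = np.lib.stride_tricks.as_strided(
        x, (n, c, k, k, ho, wo), (sn, sc, sh, sw, sh * s, sw * s)
    )
    return np.ascontiguousarray(cols), ho, wo


def _col2im(cols6: np.ndarray, x_shape, k: int, s: int, p: int) -> np.ndarray:
    n, c, h, w = x_shape
    ho, wo = cols6.shape[4], cols6.shape[5]
    out = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=np.float32)
    for i in range(k):
        for j in range(k):
            out[:, :, i:i + s * ho:s, j:j + s * wo:s] += cols6[:, :, i, j]
    if p:
        out = out[:, :, p:p + h, p:p + w]
    return out


def conv_out_side(side: int, k: int, s: int, p: int) -> int:
    return (side + 2 * p - k) // s + 1


def _conv_fwd(x, w, s, p):
    co, ci, k, _ = w.shape
    cols, ho, wo = _im2col(x, k, s, p)
    n = x.shape[0]
    colsr = cols.reshape(n, ci * k * k, ho * wo)
    out = np.matmul(w.reshape(co, ci * k * k)[None], colsr)
    return out.reshape(n, co, ho, wo), cols


def _conv_bwd_x(gy, w, x_shape, s, p):
    co, ci, k, _ = w.shape
    n, _, ho, wo = gy.shape
    gyr = gy.reshape(n, co, ho * wo)
    dcols = np.matmul(w.reshape(co, ci * k * k).T[None], gyr)
    return _col2im(dcols.reshape(n, ci, k, k, ho, wo), x_shape, k, s, p)


def _conv_bwd_w(gy, cols, w_shape):
    co, ci, k, _ = w_shape
    n, _, ho, wo = gy.shape
    gyr = gy.reshape(n, co, ho * wo)
    colsr = cols.reshape(n, ci * k * k, ho * wo)
    gw = np.matmul(gyr, colsr.transpose(0, 2, 1)).sum(axis=0)
    return gw.reshape(w_shape)


# ------------------------------------------------------------- differentiable

def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, pad: int = 0) -> Tensor:
    y, cols = _conv_fwd(x.data, w.data, stride, pad)
    if b is not None:
        y = y + b.data.reshape(1, -1, 1, 1)
    children = (x, w) if b is None else (x, w, b)
    out = Tensor(y, _children=children)

    def bw(g):
        x._acc(_conv_bwd_x(g, w.data, x.data.shape, stride, pad))
        w._acc(_conv_bwd_w(g, cols, w.data.shape))
        if b is not None:
            b._acc(g.sum(axis=(0, 2, 3)))

    out._backward = bw
    return out


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 2,
                     pad: int = 1, out_side: int | None = None) -> Tensor:
    """Transposed conv; ``w`` has shape (Cin, Cout, k, k) — the adjoint conv's
    weight. Output side defaults to stride * input side (k=3, p=1, outpad=1)."""
    ci, co, k, _ = w.shape
    n, _, h, wd = x.shape
    ho = out_side if out_side is not None else stride * h
    wo = out_side if out_side is not None else stride * wd
    # x plays the gradient role of the adjoint convolution (co -> ci channels)
    y = _conv_bwd_x(x.data, w.data, (n, co, ho, wo), stride, pad)
    if b is not None:
        y = y + b.data.reshape(1, -1, 1, 1)
    children = (x, w) if b is None else (x, w, b)
    out = Tensor(y, _children=children)

    def bw(g):
        gy, cols = _conv_fwd(g, w.data, stride, pad)
        x._acc(gy)
        w._acc(_conv_bwd_w(x.data, cols, w.data.shape))
        if b is not None:
            b._acc(g.sum(axis=(0, 2, 3)))

    out._backward = bw
    return out


def depthwise_conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, pad: int = 1) -> Tensor:
    """Depthwise conv: one k×k filter per channel; ``w`` shape (C, k, k)."""
    c, k, _ = w.shape
    cols, ho, wo = _im2col(x.data, k, stride, pad)
    y = np.einsum("ncklhw,ckl->nchw", cols, w.data, optimize=True)
    if b is not None:
        y = y + b.data.reshape(1, -1, 1, 1)
    children = (x, w) if b is None else (x, w, b)
    out = Tensor(y, _children=children)

    def bw(g):
        gw = np.einsum("nchw,ncklhw->ckl", g, cols, optimize=True)
        gcols = np.einsum("nchw,ckl->ncklhw", g, w.data, optimize=True)
        x._acc(_col2im(gcols, x.data.shape, k, stride, pad))
        w._acc(gw)
        if b is not None:
            b._acc(g.sum(axis=(0, 2, 3)))

    out._backward = bw
    return out


def avg_pool2d(x: Tensor, k: int = 3, stride: int = 2, pad: int = 1) -> Tensor:
    """Average pooling (zero-padded borders included in the mean)."""
    cols, ho, wo = _im2col(x.data, k, stride, pad)
    y = cols.mean(axis=(2, 3))
    out = Tensor(y, _children=(x,))

    def bw(g):
        gcols = np.broadcast_to(
            g[:, :, None, None] / (k * k), (g.shape[0], g.shape[1], k, k, ho, wo)
        )
        x._acc(_col2im(np.ascontiguousarray(gcols), x.data.shape, k, stride, pad))

    out._backward = bw
    return out


def global_avg_pool(x: Tensor) -> Tensor:
    return x.mean(axis=(2, 3))


# ----------------------------------------------------------------- resampling

def _linear_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Bilinear interpolation matrix (align_corners=False, edge-clamped)."""
    m = np.zeros((n_out, n_in), dtype=np.float32)
    scale = n_in / n_out
    for o in range(n_out):
        src = (o + 0.5) * scale - 0.5
        src = min(max(src, 0.0), n_in - 1.0)
        lo = int(np.floor(src))
        hi = min(lo + 1, n_in - 1)
        t = src - lo
        m[o, lo] += 1.0 - t
        m[o, hi] += t
    return m


_RESIZE_CACHE: dict = {}


def bilinear_resize(x: Tensor, out_side: int) -> Tensor:
    """Separable bilinear resize of an NCHW tensor to out_side × out_side."""
    n, c, h, w = x.shape
    if h == out_side and w == out_side:
        return x
    key = (out_side, h, w)
    if key not in _RESIZE_CACHE:
        _RESIZE_CACHE[key] = (_linear_matrix(out_side, h), _linear_matrix(out_side, w))
    rh, rw = _RESIZE_CACHE[key]
    y = np.einsum("oh,nchw,pw->ncop", rh, x.data, rw, optimize=True)
    out = Tensor(y, _children=(x,))

    def bw(g):
        x._acc(np.einsum("oh,ncop,pw->nchw", rh, g, rw, optimize=True))

    out._backward = bw
    return out


# ------------------------------------------------------------------ embedding

def embedding(idx: np.ndarray, weight: Tensor) -> Tensor:
    idx = np.asarray(idx, dtype=np.int64)
    out = Tensor(weight.data[idx], _children=(weight,))

    def bw(g):
        gw = np.zeros_like(weight.data)
        np.add.at(gw, idx, g)
        weight._acc(gw)

    out._backward = bw
    return out


# -------------------------------------------------------------- normalization

def instance_norm(x: Tensor, gamma: Tensor | None = None, beta: Tensor | None = None,
                  eps: float = 1e-5) -> Tensor:
    """Per-sample, per-channel spatial standardization with optional affine."""
    mu = x.mean(axis=(2, 3), keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=(2, 3), keepdims=True)
    y = xc * (var + eps).pow(-0.5)
    if gamma is not None:
        y = y * gamma.reshape(1, -1, 1, 1) + beta.reshape(1, -1, 1, 1)
    return y


def adain(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Adaptive instance norm: standardize spatially then apply the
    condition-dependent per-sample, per-channel scale/shift (N, C)."""
    n, c = x.shape[0], x.shape[1]
    y = instance_norm(x, None, None, eps)
    return y * gamma.reshape(n, c, 1, 1) + beta.reshape(n, c, 1, 1)


# ------------------------------------------------------------ classification

def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy; ``labels`` are integer class indices."""
    labels = np.asarray(labels, dtype=np.int64)
    p = softmax(logits.data, axis=1)
    n = logits.shape[0]
    loss = -np.mean(np.log(np.maximum(p[np.arange(n), labels], 1e-12)))
    out = Tensor(loss, _children=(logits,))

    def bw(g):
        gl = p.copy()
        gl[np.arange(n), labels] -= 1.0
        logits._acc(g * gl / n)

    out._backward = bw
    return out
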