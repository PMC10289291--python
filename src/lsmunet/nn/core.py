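"""Minimal differentiable layer library on numpy + autograd.

All layers are pure functions ``f(params, x)`` over nested-dict parameter
trees of numpy arrays, so ``autograd.grad`` can differentiate a whole
network with respect to its parameters.  Feature maps use a channels-last
layout — ``(batch, H, W, C)`` in 2-D, ``(batch, D, H, W, C)`` in 3-D —
which keeps the convolution inner loop a plain BLAS matmul.

Convolutions are implemented as a sum over kernel taps of shifted
matmuls (9 taps for 3x3, 27 for 3x3x3), with 'same' zero padding and
stride 1.  Initialization is Kaiming-normal (fan-in) for conv/dense
weights.
"""

from __future__ import annotations

import autograd.numpy as anp
import numpy as np
from autograd.extend import defvjp, primitive


def kaiming(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


# --- convolutions -----------------------------------------------------------


def conv2d_init(rng, c_in: int, c_out: int, k: int = 3) -> dict:
    return {
        "w": kaiming(rng, (k, k, c_in, c_out), fan_in=k * k * c_in),
        "b": np.zeros(c_out, dtype=np.float32),
    }


@primitive
def _conv2d_raw(x, w, b):
    """'same' 2-D convolution as a sum of shifted matmuls (one tap each)."""
    k = w.shape[0]
    p = k // 2
    h, wd = x.shape[1], x.shape[2]
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
    out = np.zeros(x.shape[:3] + (w.shape[-1],), dtype=x.dtype)
    for dy in range(k):
        for dx in range(k):
            out += np.matmul(xp[:, dy : dy + h, dx : dx + wd, :], w[dy, dx])
    return out + b


def _conv2d_vjp_x(ans, x, w, b):
    k = w.shape[0]
    p = k // 2
    h, wd = x.shape[1], x.shape[2]

    def vjp(g):
        gxp = np.zeros((x.shape[0], h + 2 * p, wd + 2 * p, x.shape[3]), dtype=g.dtype)
        for dy in range(k):
            for dx in range(k):
                gxp[:, dy : dy + h, dx : dx + wd, :] += np.matmul(g, w[dy, dx].T)
        return gxp[:, p : p + h, p : p + wd, :]

    return vjp


def _conv2d_vjp_w(ans, x, w, b):
    k = w.shape[0]
    p = k // 2
    h, wd = x.shape[1], x.shape[2]
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))

    def vjp(g):
        gw = np.empty_like(w)
        for dy in range(k):
            for dx in range(k):
                gw[dy, dx] = np.tensordot(
                    xp[:, dy : dy + h, dx : dx + wd, :], g, axes=([0, 1, 2], [0, 1, 2])
                )
        return gw

    return vjp


defvjp(
    _conv2d_raw,
    _conv2d_vjp_x,
    _conv2d_vjp_w,
    lambda ans, x, w, b: lambda g: g.sum(axis=(0, 1, 2)),
)


def conv2d(params: dict, x):
    """3x3 'same' convolution, stride 1; x: (B, H, W, Cin)."""
    return _conv2d_raw(x, params["w"], params["b"])


def conv1x1_init(rng, c_in: int, c_out: int) -> dict:
    return {
        "w": kaiming(rng, (c_in, c_out), fan_in=c_in),
        "b": np.zeros(c_out, dtype=np.float32),
    }


def conv1x1(params: dict, x):
    """Pointwise convolution; works for any channels-last rank."""
    return anp.matmul(x, params["w"]) + params["b"]


def conv3d_init(rng, c_in: int, c_out: int, k: int = 3) -> dict:
    return {
        "w": kaiming(rng, (k, k, k, c_in, c_out), fan_in=k * k * k * c_in),
        "b": np.zeros(c_out, dtype=np.float32),
    }


@primitive
def _conv3d_raw(x, w, b):
    k = w.shape[0]
    p = k // 2
    d, h, wd = x.shape[1], x.shape[2], x.shape[3]
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (p, p), (0, 0)))
    out = np.zeros(x.shape[:4] + (w.shape[-1],), dtype=x.dtype)
    for dz in range(k):
        for dy in range(k):
            for dx in range(k):
                out += np.matmul(
                    xp[:, dz : dz + d, dy : dy + h, dx : dx + wd, :], w[dz, dy, dx]
                )
    return out + b


def _conv3d_vjp_x(ans, x, w, b):
    k = w.shape[0]
    p = k // 2
    d, h, wd = x.shape[1], x.shape[2], x.shape[3]

    def vjp(g):
        gxp = np.zeros(
            (x.shape[0], d + 2 * p, h + 2 * p, wd + 2 * p, x.shape[4]), dtype=g.dtype
        )
        for dz in range(k):
            for dy in range(k):
                for dx in range(k):
                    gxp[:, dz : dz + d, dy : dy + h, dx : dx + wd, :] += np.matmul(
                        g, w[dz, dy, dx].T
                    )
        return gxp[:, p : p + d, p : p + h, p : p + wd, :]

    return vjp


def _conv3d_vjp_w(ans, x, w, b):
    k = w.shape[0]
    p = k // 2
    d, h, wd = x.shape[1], x.shape[2], x.shape[3]
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (p, p), (0, 0)))

    def vjp(g):
        gw = np.empty_like(w)
        for dz in range(k):
            for dy in range(k):
                for dx in range(k):
                    gw[dz, dy, dx] = np.tensordot(
                        xp[:, dz : dz + d, dy : dy + h, dx : dx + wd, :],
                        g,
                        axes=([0, 1, 2, 3], [0, 1, 2, 3]),
                    )
        return gw

    return vjp


defvjp(
    _conv3d_raw,
    _conv3d_vjp_x,
    _conv3d_vjp_w,
    lambda ans, x, w, b: lambda g: g.sum(axis=(0, 1, 2, 3)),
)


def conv3d(params: dict, x):
    """3x3x3 'same' convolution, stride 1; x: (B, D, H, W, Cin)."""
    return _conv3d_raw(x, params["w"], params["b"])


# --- normalization / activation --------------------------------------------


def instance_norm_init(c: int) -> dict:
    return {"gamma": np.ones(c, dtype=np.float32), "beta": np.zeros(c, dtype=np.float32)}


def instance_norm(params: dict, x, eps: float = 1e-5):
    """Normalize per sample and channel over the spatial axes (affine)."""
    axes = tuple(range(1, x.ndim - 1))
    mu = anp.mean(x, axis=axes, keepdims=True)
    var = anp.mean((x - mu) ** 2, axis=axes, keepdims=True)
    return params["gamma"] * (x - mu) / anp.sqrt(var + eps) + params["beta"]


def leaky_relu(x, slope: float = 0.01):
    return anp.where(x > 0, x, slope * x)


def relu(x):
    return anp.maximum(x, 0.0)


def sigmoid(x):
    return 1.0 / (1.0 + anp.exp(-x))


def softmax(x, axis: int):
    z = x - anp.max(x, axis=axis, keepdims=True)
    e = anp.exp(z)
    return e / anp.sum(e, axis=axis, keepdims=True)


def log_softmax(x, axis: int):
    z = x - anp.max(x, axis=axis, keepdims=True)
    return z - anp.log(anp.sum(anp.exp(z), axis=axis, keepdims=True))


# --- pooling / resampling ---------------------------------------------------


def maxpool2d(x):
    """2x max pooling; x: (B, H, W, C) with even H, W."""
    b, h, w, c = x.shape
    return anp.max(anp.reshape(x, (b, h // 2, 2, w // 2, 2, c)), axis=(2, 4))


def maxpool3d(x):
    """2x max pooling over all three spatial axes; x: (B, D, H, W, C)."""
    b, d, h, w, c = x.shape
    return anp.max(
        anp.reshape(x, (b, d // 2, 2, h // 2, 2, w // 2, 2, c)), axis=(2, 4, 6)
    )


def upsample2x_nearest(x):
    """Nearest-neighbour 2x in-plane upsampling; x: (B, H, W, C)."""
    return anp.repeat(anp.repeat(x, 2, axis=1), 2, axis=2)


def linear_resize_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Dense (n_in, n_out) matrix performing 1-D linear interpolation.

    Sample positions follow the half-pixel convention
    ``src = (i + 0.5) * n_in / n_out - 0.5``, clamped at the borders.
    """
    m = np.zeros((n_in, n_out), dtype=np.float32)
    for i in range(n_out):
        src = (i + 0.5) * n_in / n_out - 0.5
        src = min(max(src, 0.0), n_in - 1.0)
        lo = int(np.floor(src))
        hi = min(lo + 1, n_in - 1)
        t = src - lo
        m[lo, i] += 1.0 - t
        m[hi, i] += t
    return m


def resize_bilinear(x, out_hw: tuple[int, int]):
    """Bilinear in-plane resize via fixed interpolation matrices.

    x: (B, H, W, C) -> (B, out_h, out_w, C).
    """
    h, w = x.shape[1], x.shape[2]
    my = linear_resize_matrix(h, out_hw[0])
    mx = linear_resize_matrix(w, out_hw[1])
    y = anp.tensordot(x, my, axes=([1], [0]))  # (B, W, C, Hout)
    y = anp.transpose(y, (0, 3, 1, 2))
    y = anp.tensordot(y, mx, axes=([2], [0]))  # (B, Hout, C, Wout)
    return anp.transpose(y, (0, 1, 3, 2))


# --- dense ------------------------------------------------------------------


def dense_init(rng, n_in: int, n_out: int) -> dict:
    return {
        "w": kaiming(rng, (n_in, n_out), fan_in=n_in),
        "b": np.zeros(n_out, dtype=np.float32),
    }


def dense(params: dict, x):
    return anp.matmul(x, params["w"]) + params["b"]
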