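"""Array-level building blocks for the CPU tensor-network engine.

All operators work on NCHW float arrays and come in forward/backward pairs so
the layers in :mod:`weedmap.nn.layers` can run plain reverse-mode
differentiation without a graph framework.  Convolution uses the dilated
(atrous) form throughout; a standard convolution is the special case
``dilation=1``.

Spatial sizing follows a "same, ceil-mode" convention: a layer with stride
``s`` maps a side of ``n`` pixels to ``ceil(n / s)``, with the input padded
symmetrically (extra pixel on the bottom/right) by whatever the effective
kernel needs.  This is the convention that sends 1000 -> 500 -> 250 -> 125
through a stride-8 trunk.
"""

from __future__ import annotations

import numpy as np


def effective_kernel_size(k: int, rate: int) -> int:
    """Side length of the receptive field of a K x K kernel dilated by ``rate``.

    Dilation inserts ``rate - 1`` implicit zeros between adjacent taps, so the
    field of view grows from K to (K - 1) * (rate - 1) + K while the number of
    nonzero taps (and hence parameters and multiplications) is unchanged.
    """
    if k < 1:
        raise ValueError(f"kernel size must be >= 1, got {k}")
    if rate < 1:
        raise ValueError(f"dilation rate must be >= 1, got {rate}")
    return (k - 1) * (rate - 1) + k


def same_pad_amount(n: int, k: int, stride: int, rate: int = 1) -> tuple[int, int]:
    """(before, after) padding so that output side = ceil(n / stride)."""
    k_eff = effective_kernel_size(k, rate)
    out = -(-n // stride)  # ceil division
    total = max((out - 1) * stride + k_eff - n, 0)
    before = total // 2
    return before, total - before


def conv_output_size(n: int, stride: int) -> int:
    return -(-n // stride)


def _im2col_indices(
    c: int, k: int, out_h: int, out_w: int, stride: int, rate: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Index arrays mapping a padded (C, Hp, Wp) image to (C*K*K, out_h*out_w)."""
    i0 = rate * np.repeat(np.arange(k), k)
    j0 = rate * np.tile(np.arange(k), k)
    i0 = np.tile(i0, c)
    j0 = np.tile(j0, c)
    i1 = stride * np.repeat(np.arange(out_h), out_w)
    j1 = stride * np.tile(np.arange(out_w), out_h)
    i = i0[:, None] + i1[None, :]
    j = j0[:, None] + j1[None, :]
    ch = np.repeat(np.arange(c), k * k)[:, None]
    return ch, i, j


def conv2d_forward(
    x: np.ndarray,
    w: np.ndarray,
    b: np.ndarray | None,
    stride: int = 1,
    rate: int = 1,
) -> tuple[np.ndarray, dict]:
    """Dilated 2-D convolution (cross-correlation) with same/ceil padding.

    Parameters
    ----------
    x : (N, C, H, W) input.
    w : (C_out, C, K, K) kernel; taps are applied ``rate`` pixels apart.
    b : (C_out,) bias or None.

    Returns the (N, C_out, ceil(H/stride), ceil(W/stride)) output and a cache
    for :func:`conv2d_backward`.
    """
    if stride < 1:
        raise ValueError(f"stride must be >= 1, got {stride}")
    if rate < 1:
        raise ValueError(f"dilation rate must be >= 1, got {rate}")
    n, c, h, wd = x.shape
    c_out, c_in, k, k2 = w.shape
    if c_in != c or k != k2:
        raise ValueError(f"kernel shape {w.shape} incompatible with input {x.shape}")
    ph = same_pad_amount(h, k, stride, rate)
    pw = same_pad_amount(wd, k, stride, rate)
    out_h = conv_output_size(h, stride)
    out_w = conv_output_size(wd, stride)
    xp = np.pad(x, ((0, 0), (0, 0), ph, pw))
    ch, i, j = _im2col_indices(c, k, out_h, out_w, stride, rate)
    cols = xp[:, ch, i, j]  # (N, C*K*K, out_h*out_w)
    wm = w.reshape(c_out, -1)
    y = np.einsum("ok,nkp->nop", wm, cols, optimize=True)
    if b is not None:
        y += b[None, :, None]
    y = y.reshape(n, c_out, out_h, out_w)
    cache = {
        "cols": cols,
        "w": w,
        "pads": (ph, pw),
        "x_shape": x.shape,
        "idx": (ch, i, j),
        "stride": stride,
        "rate": rate,
    }
    return y, cache


def conv2d_backward(
    dy: np.ndarray, cache: dict
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients (dx, dw, db) for :func:`conv2d_forward`."""
    cols = cache["cols"]
    w = cache["w"]
    ph, pw = cache["pads"]
    n, c, h, wd = cache["x_shape"]
    ch, i, j = cache["idx"]
    c_out = w.shape[0]
    dyf = dy.reshape(n, c_out, -1)
    dw = np.einsum("nop,nkp->ok", dyf, cols, optimize=True).reshape(w.shape)
    db = dyf.sum(axis=(0, 2))
    wm = w.reshape(c_out, -1)
    dcols = np.einsum("ok,nop->nkp", wm, dyf, optimize=True)
    dxp = np.zeros((n, c, h + ph[0] + ph[1], wd + pw[0] + pw[1]), dtype=dy.dtype)
    np.add.at(dxp, (slice(None), ch, i, j), dcols)
    dx = dxp[:, :, ph[0] : ph[0] + h, pw[0] : pw[0] + wd]
    return dx, dw, db


def maxpool2d_forward(
    x: np.ndarray, k: int = 3, stride: int = 2
) -> tuple[np.ndarray, dict]:
    """Max pooling with same/ceil padding (pad value -inf)."""
    n, c, h, wd = x.shape
    ph = same_pad_amount(h, k, stride)
    pw = same_pad_amount(wd, k, stride)
    out_h = conv_output_size(h, stride)
    out_w = conv_output_size(wd, stride)
    xp = np.pad(x, ((0, 0), (0, 0), ph, pw), constant_values=-np.inf)
    ch, i, j = _im2col_indices(1, k, out_h, out_w, stride, 1)
    # pool each channel independently: fold channels into the batch axis
    xpc = xp.reshape(n * c, 1, xp.shape[2], xp.shape[3])
    cols = xpc[:, ch, i, j]  # (N*C, K*K, P)
    arg = np.argmax(cols, axis=1)
    y = np.take_along_axis(cols, arg[:, None, :], axis=1)[:, 0, :]
    y = y.reshape(n, c, out_h, out_w)
    cache = {
        "arg": arg,
        "idx": (ch, i, j),
        "pads": (ph, pw),
        "x_shape": x.shape,
        "padded_shape": xp.shape,
    }
    return y, cache


def maxpool2d_backward(dy: np.ndarray, cache: dict) -> np.ndarray:
    n, c, h, wd = cache["x_shape"]
    ch, i, j = cache["idx"]
    ph, pw = cache["pads"]
    arg = cache["arg"]
    _, _, hp, wp = cache["padded_shape"]
    dyf = dy.reshape(n * c, -1)
    dxp = np.zeros((n * c, hp, wp), dtype=dy.dtype)
    p = dyf.shape[1]
    rows = np.take_along_axis(i[None, :, :].repeat(n * c, 0), arg[:, None, :], 1)[:, 0, :]
    colsx = np.take_along_axis(j[None, :, :].repeat(n * c, 0), arg[:, None, :], 1)[:, 0, :]
    batch = np.repeat(np.arange(n * c), p)
    np.add.at(dxp, (batch, rows.ravel(), colsx.ravel()), dyf.ravel())
    dx = dxp[:, ph[0] : ph[0] + h, pw[0] : pw[0] + wd]
    return dx.reshape(n, c, h, wd)


def _bilinear_axis_weights(n_in: int, n_out: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Half-pixel-center (align_corners=False) interpolation weights.

    Returns ``(i0, i1, t)`` with output[o] = (1 - t[o]) * x[i0[o]] + t[o] * x[i1[o]].
    """
    src = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    src = np.clip(src, 0.0, n_in - 1.0)
    i0 = np.floor(src).astype(np.intp)
    i1 = np.minimum(i0 + 1, n_in - 1)
    t = src - i0
    return i0, i1, t


def bilinear_upsample_forward(
    x: np.ndarray, out_h: int, out_w: int
) -> tuple[np.ndarray, dict]:
    """Channelwise bilinear interpolation of an (N, C, h, w) array.

    Uses half-pixel sample centers, the parameter-free convention of standard
    image resampling.  Exact for constant inputs; separable in H and W.
    """
    i0, i1, ti = _bilinear_axis_weights(x.shape[2], out_h)
    j0, j1, tj = _bilinear_axis_weights(x.shape[3], out_w)
    top = x[:, :, i0, :] * (1 - ti)[None, None, :, None] + x[:, :, i1, :] * ti[None, None, :, None]
    y = top[:, :, :, j0] * (1 - tj)[None, None, None, :] + top[:, :, :, j1] * tj[None, None, None, :]
    cache = {"h_idx": (i0, i1, ti), "w_idx": (j0, j1, tj), "x_shape": x.shape}
    return y, cache


def bilinear_upsample_backward(dy: np.ndarray, cache: dict) -> np.ndarray:
    i0, i1, ti = cache["h_idx"]
    j0, j1, tj = cache["w_idx"]
    n, c, h, w = cache["x_shape"]
    dtop = np.zeros((dy.shape[0], dy.shape[1], len(i0), w), dtype=dy.dtype)
    # transpose of the W interpolation
    tmp0 = dy * (1 - tj)[None, None, None, :]
    tmp1 = dy * tj[None, None, None, :]
    np.add.at(dtop, (slice(None), slice(None), slice(None), j0), tmp0)
    np.add.at(dtop, (slice(None), slice(None), slice(None), j1), tmp1)
    dx = np.zeros((n, c, h, w), dtype=dy.dtype)
    np.add.at(dx, (slice(None), slice(None), i0, slice(None)), dtop * (1 - ti)[None, None, :, None])
    np.add.at(dx, (slice(None), slice(None), i1, slice(None)), dtop * ti[None, None, :, None])
    return dx


def softmax(scores: np.ndarray, axis: int = -1) -> np.ndarray:
    """Numerically stabilized softmax (max subtraction) along ``axis``."""
    if np.isnan(scores).any():
        raise ValueError("softmax received NaN scores")
    z = scores - scores.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def cross_entropy_forward(
    logits: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean per-pixel cross-entropy.

    logits: (N, C, H, W); labels: (N, H, W) integer classes.
    Returns the scalar loss and d(loss)/d(logits).
    """
    n, c, h, w = logits.shape
    p = softmax(logits, axis=1)
    eps = 1e-12
    idx_n = np.arange(n)[:, None, None]
    idx_h = np.arange(h)[None, :, None]
    idx_w = np.arange(w)[None, None, :]
    picked = p[idx_n, labels, idx_h, idx_w]
    loss = float(-np.log(picked + eps).mean())
    grad = p.copy()
    onehot_scale = 1.0 / (n * h * w)
    grad[idx_n, labels, idx_h, idx_w] -= 1.0
    grad *= onehot_scale
    return loss, grad
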