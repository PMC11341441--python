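"""Convolution, pooling and rearrangement ops for 4-D (B, C, H, W) tensors.

Convolutions are computed by im2col + batched matrix multiply so the heavy
lifting is delegated to BLAS; the backward pass re-uses the cached column
matrix.  Grouped convolution covers the depth-wise case (groups == C).
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = ["conv2d", "max_pool2d", "pixel_shuffle", "space_to_depth", "upsample_nearest2x"]


def _im2col(x: np.ndarray, kh, kw, sh, sw, ph, pw, pad_value=0.0):
    B, C, H, W = x.shape
    if ph or pw:
        x = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)), constant_values=pad_value)
    Ho = (H + 2 * ph - kh) // sh + 1
    Wo = (W + 2 * pw - kw) // sw + 1
    cols = np.empty((B, C, kh, kw, Ho, Wo), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = x[:, :, i : i + sh * Ho : sh, j : j + sw * Wo : sw]
    return cols, Ho, Wo


def _col2im(cols: np.ndarray, x_shape, kh, kw, sh, sw, ph, pw):
    B, C, H, W = x_shape
    xp = np.zeros((B, C, H + 2 * ph, W + 2 * pw), dtype=cols.dtype)
    for i in range(kh):
        for j in range(kw):
            Ho, Wo = cols.shape[-2:]
            xp[:, :, i : i + sh * Ho : sh, j : j + sw * Wo : sw] += cols[:, :, i, j]
    if ph or pw:
        return xp[:, :, ph : ph + H, pw : pw + W]
    return xp


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, padding: int = 0, groups: int = 1) -> Tensor:
    """2-D cross-correlation. ``weight``: (Cout, Cin/groups, kh, kw)."""
    B, C, H, W = x.shape
    Cout, Cin_g, kh, kw = weight.shape
    if C != Cin_g * groups:
        raise ValueError(
            f"conv2d channel mismatch: input has {C} channels, "
            f"weight expects {Cin_g * groups} (groups={groups})"
        )
    if Cout % groups:
        raise ValueError("output channels must be divisible by groups")
    sh = sw = stride
    ph = pw = padding
    cols, Ho, Wo = _im2col(x.data, kh, kw, sh, sw, ph, pw)
    # (B, g, Cin/g*kh*kw, Ho*Wo)
    cols_m = cols.reshape(B, groups, Cin_g * kh * kw, Ho * Wo)
    w_m = weight.data.reshape(groups, Cout // groups, Cin_g * kh * kw)
    out = np.matmul(w_m[None], cols_m)  # (B, g, Cout/g, L)
    out = out.reshape(B, Cout, Ho, Wo)
    if bias is not None:
        out = out + bias.data.reshape(1, Cout, 1, 1)

    def backward(g):
        g_m = g.reshape(B, groups, Cout // groups, Ho * Wo)
        if weight.requires_grad:
            dw = np.matmul(g_m, cols_m.transpose(0, 1, 3, 2)).sum(axis=0)
            weight._accum(dw.reshape(weight.shape))
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dcols = np.matmul(w_m.transpose(0, 2, 1)[None], g_m)
            dcols = dcols.reshape(B, C, kh, kw, Ho, Wo)
            x._accum(_col2im(dcols, x.shape, kh, kw, sh, sw, ph, pw))

    parents = (x, weight) if bias is None else (x, weight, bias)
    out_t = Tensor(out)
    if any(p.requires_grad for p in parents):
        out_t.requires_grad = True
        out_t._prev = parents
        out_t._backward = backward
    return out_t


def max_pool2d(x: Tensor, kernel_size: int, stride: int | None = None,
               padding: int | None = None) -> Tensor:
    """Max pooling; default stride 1 with same-size padding (SPP style)."""
    k = kernel_size
    if stride is None:
        stride = 1
    if padding is None:
        padding = (k - 1) // 2 if stride == 1 else 0
    B, C, H, W = x.shape
    cols, Ho, Wo = _im2col(x.data, k, k, stride, stride, padding, padding,
                           pad_value=-np.inf)
    win = cols.reshape(B, C, k * k, Ho, Wo)
    arg = win.argmax(axis=2)
    out = np.take_along_axis(win, arg[:, :, None], axis=2)[:, :, 0]

    def backward(g):
        dwin = np.zeros_like(win)
        np.put_along_axis(dwin, arg[:, :, None], g[:, :, None], axis=2)
        x._accum(_col2im(dwin.reshape(B, C, k, k, Ho, Wo), x.shape,
                         k, k, stride, stride, padding, padding))

    out_t = Tensor(out)
    if x.requires_grad:
        out_t.requires_grad = True
        out_t._prev = (x,)
        out_t._backward = backward
    return out_t


def pixel_shuffle(x: Tensor, r: int = 2) -> Tensor:
    """Depth-to-space: (B, C*r^2, H, W) -> (B, C, H*r, W*r).

    Channel ordering convention: channel block ``c*r^2 + dy*r + dx`` maps to
    output channel ``c`` at spatial offset (dy, dx) within each r x r cell,
    so a 1x1 map with channels [a, b, c, d] (r=2) becomes [[a, b], [c, d]].
    """
    B, C, H, W = x.shape
    if C % (r * r):
        raise ValueError(f"channels {C} not divisible by r^2={r * r}")
    out = (
        x.reshape(B, C // (r * r), r, r, H, W)
        .transpose(0, 1, 4, 2, 5, 3)
        .reshape(B, C // (r * r), H * r, W * r)
    )
    return out


def space_to_depth(x: Tensor, r: int = 2) -> Tensor:
    """Inverse of :func:`pixel_shuffle`."""
    B, C, H, W = x.shape
    if H % r or W % r:
        raise ValueError("spatial dims must be divisible by r")
    return (
        x.reshape(B, C, H // r, r, W // r, r)
        .transpose(0, 1, 3, 5, 2, 4)
        .reshape(B, C * r * r, H // r, W // r)
    )


def upsample_nearest2x(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x upsampling (used in the PAN neck)."""
    B, C, H, W = x.shape
    idx_h = np.repeat(np.arange(H), 2)
    idx_w = np.repeat(np.arange(W), 2)
    return x[:, :, idx_h[:, None], idx_w[None, :]]
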