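"""Spatial primitives (convolution, pooling, resize) with custom vjps.

Convolution uses a strided sliding-window view plus grouped ``einsum``;
the input gradient is scattered back with an O(k^2) col2im loop, which is
plenty at the scales this package trains at.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import as_strided

from .tensor import Tensor, _make, as_tensor

__all__ = [
    "conv2d",
    "max_pool2d",
    "avg_pool2d",
    "adaptive_avg_pool2d",
    "upsample_nearest2d",
    "pad2d",
    "pad_edge2d",
    "spectral_highpass",
    "highpass_mask",
]


def _window_view(xp: np.ndarray, kh: int, kw: int, stride: int, dilation: int,
                 oh: int, ow: int) -> np.ndarray:
    sb, sc, sh, sw = xp.strides
    b, c = xp.shape[:2]
    return as_strided(
        xp,
        shape=(b, c, kh, kw, oh, ow),
        strides=(sb, sc, sh * dilation, sw * dilation, sh * stride, sw * stride),
        writeable=False,
    )


def conv2d(x, weight, bias=None, stride: int = 1, padding: int = 0,
           dilation: int = 1, groups: int = 1) -> Tensor:
    """2-D cross-correlation.  weight: (O, C/g, kh, kw)."""
    x = as_tensor(x)
    w = as_tensor(weight)
    b, c, h, wid = x.shape
    o, cg, kh, kw = w.shape
    if c % groups or o % groups:
        raise ValueError(f"channels {c}->{o} not divisible by groups={groups}")
    if cg != c // groups:
        raise ValueError("weight shape inconsistent with groups")
    oh = (h + 2 * padding - dilation * (kh - 1) - 1) // stride + 1
    ow = (wid + 2 * padding - dilation * (kw - 1) - 1) // stride + 1
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    view = _window_view(xp, kh, kw, stride, dilation, oh, ow)
    # (b, g, c/g*kh*kw, oh*ow)
    cols = view.reshape(b, groups, (c // groups) * kh * kw, oh * ow)
    wm = w.data.reshape(groups, o // groups, (c // groups) * kh * kw)
    out = np.einsum("gok,bgkp->bgop", wm, cols, optimize=True)
    out = out.reshape(b, o, oh, ow)
    if bias is not None:
        out = out + bias.data.reshape(1, o, 1, 1)
    parents = (x, w) if bias is None else (x, w, bias)

    def backward(g):
        gm = g.reshape(b, groups, o // groups, oh * ow)
        if w.requires_grad or w._prev:
            gw = np.einsum("bgop,bgkp->gok", gm, cols, optimize=True)
            w._accumulate(gw.reshape(w.shape))
        if bias is not None and (bias.requires_grad or bias._prev):
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad or x._prev:
            gcols = np.einsum("gok,bgop->bgkp", wm, gm, optimize=True)
            gcols = gcols.reshape(b, c, kh, kw, oh, ow)
            gxp = np.zeros_like(xp)
            hp, wp = xp.shape[2], xp.shape[3]
            for i in range(kh):
                hi = i * dilation
                for j in range(kw):
                    wj = j * dilation
                    gxp[:, :, hi:hi + stride * oh:stride,
                        wj:wj + stride * ow:stride] += gcols[:, :, i, j]
            if padding:
                gxp = gxp[:, :, padding:hp - padding, padding:wp - padding]
            x._accumulate(gxp)

    return _make(out, parents, backward)


def max_pool2d(x, kernel: int, stride: int | None = None, padding: int = 0) -> Tensor:
    x = as_tensor(x)
    stride = stride or kernel
    b, c, h, w = x.shape
    oh = (h + 2 * padding - kernel) // stride + 1
    ow = (w + 2 * padding - kernel) // stride + 1
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                constant_values=-np.inf)
    view = _window_view(xp, kernel, kernel, stride, 1, oh, ow)
    flat = view.reshape(b, c, kernel * kernel, oh, ow)
    idx = flat.argmax(axis=2)
    out = np.take_along_axis(flat, idx[:, :, None], axis=2)[:, :, 0]

    def backward(g):
        gxp = np.zeros_like(xp)
        ki, kj = np.divmod(idx, kernel)
        bb, cc, ii, jj = np.meshgrid(np.arange(b), np.arange(c), np.arange(oh),
                                     np.arange(ow), indexing="ij")
        np.add.at(gxp, (bb, cc, ii * stride + ki, jj * stride + kj), g)
        if padding:
            gxp = gxp[:, :, padding:padding + h, padding:padding + w]
        x._accumulate(gxp)

    return _make(out, (x,), backward)


def avg_pool2d(x, kernel: int, stride: int | None = None, padding: int = 0) -> Tensor:
    x = as_tensor(x)
    stride = stride or kernel
    b, c, h, w = x.shape
    oh = (h + 2 * padding - kernel) // stride + 1
    ow = (w + 2 * padding - kernel) // stride + 1
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    view = _window_view(xp, kernel, kernel, stride, 1, oh, ow)
    out = view.mean(axis=(2, 3))

    def backward(g):
        gxp = np.zeros_like(xp)
        gk = g / (kernel * kernel)
        for i in range(kernel):
            for j in range(kernel):
                gxp[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride] += gk
        if padding:
            gxp = gxp[:, :, padding:padding + h, padding:padding + w]
        x._accumulate(gxp)

    return _make(out, (x,), backward)


def _adaptive_bins(n: int, out: int) -> list[tuple[int, int]]:
    return [(int(np.floor(i * n / out)), int(np.ceil((i + 1) * n / out)))
            for i in range(out)]


def adaptive_avg_pool2d(x, output_size: int) -> Tensor:
    """Average pooling to an ``output_size`` x ``output_size`` grid.

    Bin edges follow the floor/ceil rule, so the bins tile the input
    exactly when the input size is a multiple of the output size.
    """
    x = as_tensor(x)
    b, c, h, w = x.shape
    s = int(output_size)
    if s == 1:
        out = x.data.mean(axis=(2, 3), keepdims=True)

        def backward1(g):
            x._accumulate(np.broadcast_to(g / (h * w), x.shape).astype(np.float32))

        return _make(out, (x,), backward1)

    hb = _adaptive_bins(h, s)
    wb = _adaptive_bins(w, s)
    out = np.empty((b, c, s, s), dtype=np.float32)
    for i, (h0, h1) in enumerate(hb):
        for j, (w0, w1) in enumerate(wb):
            out[:, :, i, j] = x.data[:, :, h0:h1, w0:w1].mean(axis=(2, 3))

    def backward(g):
        gx = np.zeros_like(x.data)
        for i, (h0, h1) in enumerate(hb):
            for j, (w0, w1) in enumerate(wb):
                area = (h1 - h0) * (w1 - w0)
                gx[:, :, h0:h1, w0:w1] += g[:, :, i:i + 1, j:j + 1] / area
        x._accumulate(gx)

    return _make(out, (x,), backward)


def upsample_nearest2d(x, scale: int = 2, size: tuple[int, int] | None = None) -> Tensor:
    x = as_tensor(x)
    b, c, h, w = x.shape
    if size is None:
        out = x.data.repeat(scale, axis=2).repeat(scale, axis=3)

        def backward(g):
            gx = g.reshape(b, c, h, scale, w, scale).sum(axis=(3, 5))
            x._accumulate(gx)

        return _make(out, (x,), backward)

    oh, ow = size
    ih = (np.arange(oh) * h // oh).clip(0, h - 1)
    iw = (np.arange(ow) * w // ow).clip(0, w - 1)
    out = x.data[:, :, ih[:, None], iw[None, :]]

    def backward_sz(g):
        gx = np.zeros_like(x.data)
        np.add.at(gx, (slice(None), slice(None), ih[:, None], iw[None, :]), g)
        x._accumulate(gx)

    return _make(out, (x,), backward_sz)


def pad_edge2d(x, pad: int) -> Tensor:
    """Replicate-pad the two trailing axes (edge mode)."""
    x = as_tensor(x)
    out = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)), mode="edge")
    h, w = x.shape[-2:]

    def backward(g):
        gx = g[:, :, pad:pad + h, pad:pad + w].copy()
        gx[:, :, 0, :] += g[:, :, :pad, pad:pad + w].sum(axis=2)
        gx[:, :, -1, :] += g[:, :, pad + h:, pad:pad + w].sum(axis=2)
        gx[:, :, :, 0] += g[:, :, pad:pad + h, :pad].sum(axis=3)
        gx[:, :, :, -1] += g[:, :, pad:pad + h, pad + w:].sum(axis=3)
        gx[:, :, 0, 0] += g[:, :, :pad, :pad].sum(axis=(2, 3))
        gx[:, :, 0, -1] += g[:, :, :pad, pad + w:].sum(axis=(2, 3))
        gx[:, :, -1, 0] += g[:, :, pad + h:, :pad].sum(axis=(2, 3))
        gx[:, :, -1, -1] += g[:, :, pad + h:, pad + w:].sum(axis=(2, 3))
        x._accumulate(gx)

    return _make(out, (x,), backward)


def pad2d(x, pad: int, value: float = 0.0) -> Tensor:
    x = as_tensor(x)
    out = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)),
                 constant_values=value)

    def backward(g):
        x._accumulate(g[:, :, pad:-pad, pad:-pad])

    return _make(out, (x,), backward)


# --------------------------------------------------------------- spectral ops

def highpass_mask(h: int, w: int, cutoff: float = 0.25) -> np.ndarray:
    """Radial high-pass mask on the rfft2 grid.

    `cutoff` is the normalized radius (0..0.5 Nyquist fraction) below which
    components are suppressed.  The mask is real and radially symmetric.
    """
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.rfftfreq(w)[None, :]
    r = np.sqrt(fy ** 2 + fx ** 2)
    return (r >= cutoff).astype(np.float32)


def spectral_highpass(x, mask: np.ndarray) -> Tensor:
    """Linear high-pass filter via the 2-D real FFT: irfft2(mask * rfft2(x)).

    The operator is a circular convolution with a real, even kernel, hence
    self-adjoint: the backward pass applies the same filter to the cotangent.
    """
    x = as_tensor(x)
    h, w = x.shape[-2:]

    def apply(a):
        spec = np.fft.rfft2(a, axes=(-2, -1))
        return np.fft.irfft2(spec * mask, s=(h, w), axes=(-2, -1)).astype(np.float32)

    out = apply(x.data)

    def backward(g):
        x._accumulate(apply(g))

    return _make(out, (x,), backward)
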