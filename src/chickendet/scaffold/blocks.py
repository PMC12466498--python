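"""Building blocks of the anchor-free nano detection substrate.

The block set mirrors the reference nano-scale architecture the novel
modules plug into: CBS convolutions, split-transform-merge CSP stages,
fast spatial pyramid pooling, a position-sensitive attention stage and a
decoupled detect head with distribution-focal box regression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .. import nn
from ..nn import functional as F
from ..nn.tensor import Tensor, concatenate, softmax

__all__ = [
    "ConvBlockSpec", "build_cbs", "autopad", "Conv", "DWConv", "Bottleneck",
    "C3k", "C3k2", "SPPF", "Attention", "PSABlock", "C2PSA", "Concat",
    "Detect", "dfl_expectation", "make_anchors",
]


def autopad(kernel: int, dilation: int = 1) -> int:
    return (dilation * (kernel - 1)) // 2


@dataclass(frozen=True)
class ConvBlockSpec:
    """Contract for a CBS block: conv (+ batch-norm) (+ activation)."""

    in_ch: int
    out_ch: int
    kernel: int = 1
    stride: int = 1
    dilation: int = 1
    groups: int = 1
    normalized: bool = True
    activation: str = "SiLU"

    def __post_init__(self):
        if self.kernel % 2 == 0:
            raise ValueError(f"even kernel {self.kernel} not supported (same-padding)")
        if self.in_ch % self.groups:
            raise ValueError(f"in_ch={self.in_ch} not divisible by groups={self.groups}")
        if min(self.in_ch, self.out_ch, self.stride, self.dilation, self.groups) < 1:
            raise ValueError("all ConvBlockSpec fields must be >= 1")
        if self.activation not in ("SiLU", "Sigmoid", "none"):
            raise ValueError(f"unknown activation {self.activation!r}")

    def out_hw(self, h: int, w: int) -> tuple[int, int]:
        return math.ceil(h / self.stride), math.ceil(w / self.stride)


class Conv(nn.Module):
    """CBS: conv2d (bias-free when normalized) + batch norm + SiLU."""

    def __init__(self, c1: int, c2: int, k: int = 1, s: int = 1,
                 p: int | None = None, g: int = 1, d: int = 1, act=True):
        super().__init__()
        self.conv = nn.Conv2d(c1, c2, k, s, autopad(k, d) if p is None else p,
                              d, g, bias=False)
        self.bn = nn.BatchNorm2d(c2)
        self.act = nn.SiLU() if act is True else (act if isinstance(act, nn.Module)
                                                  else nn.Identity())

    def forward(self, x):
        return self.act(self.bn(self.conv(x)))


def build_cbs(spec: ConvBlockSpec) -> nn.Module:
    act = {"SiLU": nn.SiLU(), "Sigmoid": nn.Sigmoid(), "none": nn.Identity()}[spec.activation]
    if spec.normalized:
        return Conv(spec.in_ch, spec.out_ch, spec.kernel, spec.stride,
                    g=spec.groups, d=spec.dilation, act=act)
    conv = nn.Conv2d(spec.in_ch, spec.out_ch, spec.kernel, spec.stride,
                     autopad(spec.kernel, spec.dilation), spec.dilation,
                     spec.groups, bias=True)
    return nn.Sequential(conv, act)


class DWConv(Conv):
    def __init__(self, c1: int, c2: int, k: int = 1, s: int = 1, d: int = 1, act=True):
        super().__init__(c1, c2, k, s, g=math.gcd(c1, c2), d=d, act=act)


class Bottleneck(nn.Module):
    def __init__(self, c1: int, c2: int, shortcut: bool = True, g: int = 1,
                 k=(3, 3), e: float = 0.5):
        super().__init__()
        c_ = int(c2 * e)
        self.cv1 = Conv(c1, c_, k[0], 1)
        self.cv2 = Conv(c_, c2, k[1], 1, g=g)
        self.add = shortcut and c1 == c2

    def forward(self, x):
        y = self.cv2(self.cv1(x))
        return x + y if self.add else y


class C3k(nn.Module):
    """CSP stage with three 1x1 convs and a chain of full-width bottlenecks."""

    def __init__(self, c1: int, c2: int, n: int = 1, shortcut: bool = True,
                 g: int = 1, e: float = 0.5, k: int = 3):
        super().__init__()
        c_ = int(c2 * e)
        self.cv1 = Conv(c1, c_, 1, 1)
        self.cv2 = Conv(c1, c_, 1, 1)
        self.cv3 = Conv(2 * c_, c2, 1)
        self.m = nn.Sequential(
            *(Bottleneck(c_, c_, shortcut, g, k=(k, k), e=1.0) for _ in range(n)))

    def forward(self, x):
        return self.cv3(concatenate([self.m(self.cv1(x)), self.cv2(x)], axis=1))


class C3k2(nn.Module):
    """Split-transform-merge stage: 1x1 expand, chunked transform chain, merge."""

    def __init__(self, c1: int, c2: int, n: int = 1, c3k: bool = False,
                 e: float = 0.5, g: int = 1, shortcut: bool = True):
        super().__init__()
        self.c = int(c2 * e)
        self.cv1 = Conv(c1, 2 * self.c, 1, 1)
        self.cv2 = Conv((2 + n) * self.c, c2, 1)
        self.m = nn.ModuleList(
            C3k(self.c, self.c, 2, shortcut, g) if c3k
            else Bottleneck(self.c, self.c, shortcut, g)
            for _ in range(n))

    def forward(self, x):
        y0 = self.cv1(x)
        ys = [y0[:, :self.c], y0[:, self.c:]]
        for m in self.m:
            ys.append(m(ys[-1]))
        return self.cv2(concatenate(ys, axis=1))


class SPPF(nn.Module):
    def __init__(self, c1: int, c2: int, k: int = 5):
        super().__init__()
        c_ = c1 // 2
        self.cv1 = Conv(c1, c_, 1, 1)
        self.cv2 = Conv(c_ * 4, c2, 1, 1)
        self.m = nn.MaxPool2d(k, 1, k // 2)

    def forward(self, x):
        ys = [self.cv1(x)]
        for _ in range(3):
            ys.append(self.m(ys[-1]))
        return self.cv2(concatenate(ys, axis=1))


class Attention(nn.Module):
    def __init__(self, dim: int, num_heads: int = 8, attn_ratio: float = 0.5):
        super().__init__()
        self.num_heads = num_heads
        self.head_dim = dim // num_heads
        self.key_dim = int(self.head_dim * attn_ratio)
        self.scale = self.key_dim ** -0.5
        nh_kd = self.key_dim * num_heads
        h = dim + nh_kd * 2
        self.qkv = Conv(dim, h, 1, act=False)
        self.proj = Conv(dim, dim, 1, act=False)
        self.pe = Conv(dim, dim, 3, 1, g=dim, act=False)

    def forward(self, x):
        b, c, hh, ww = x.shape
        n = hh * ww
        qkv = self.qkv(x).reshape(b, self.num_heads,
                                  self.key_dim * 2 + self.head_dim, n)
        q = qkv[:, :, :self.key_dim]
        k = qkv[:, :, self.key_dim:self.key_dim * 2]
        v = qkv[:, :, self.key_dim * 2:]
        attn = softmax((q.transpose(0, 1, 3, 2) @ k) * self.scale, axis=-1)
        out = (v @ attn.transpose(0, 1, 3, 2)).reshape(b, c, hh, ww)
        out = out + self.pe(v.reshape(b, c, hh, ww))
        return self.proj(out)


class PSABlock(nn.Module):
    def __init__(self, c: int, attn_ratio: float = 0.5, num_heads: int = 4):
        super().__init__()
        self.attn = Attention(c, num_heads=num_heads, attn_ratio=attn_ratio)
        self.ffn = nn.Sequential(Conv(c, c * 2, 1), Conv(c * 2, c, 1, act=False))

    def forward(self, x):
        x = x + self.attn(x)
        return x + self.ffn(x)


class C2PSA(nn.Module):
    def __init__(self, c1: int, c2: int, n: int = 1, e: float = 0.5):
        super().__init__()
        assert c1 == c2
        self.c = int(c1 * e)
        self.cv1 = Conv(c1, 2 * self.c, 1, 1)
        self.cv2 = Conv(2 * self.c, c1, 1)
        self.m = nn.Sequential(
            *(PSABlock(self.c, attn_ratio=0.5, num_heads=max(self.c // 64, 1))
              for _ in range(n)))

    def forward(self, x):
        y = self.cv1(x)
        a, b = y[:, :self.c], y[:, self.c:]
        b = self.m(b)
        return self.cv2(concatenate([a, b], axis=1))


class Concat(nn.Module):
    def __init__(self, axis: int = 1):
        super().__init__()
        self.axis = axis

    def forward(self, xs):
        return concatenate(xs, axis=self.axis)


class Detect(nn.Module):
    """Decoupled anchor-free head: per-level box-distribution + class logits.

    Box branch: two 3x3 CBS then a 1x1 projection to 4*reg_max bins.
    Class branch: two depthwise-separable CBS pairs then a 1x1 projection.
    """

    def __init__(self, nc: int, ch: tuple[int, ...], reg_max: int = 16):
        super().__init__()
        self.nc = nc
        self.reg_max = reg_max
        self.nl = len(ch)
        self.strides = [8, 16, 32][:self.nl]
        c2 = max(16, ch[0] // 4, reg_max * 4)
        c3 = max(ch[0], min(nc, 100))
        self.cv2 = nn.ModuleList(
            nn.Sequential(Conv(x, c2, 3), Conv(c2, c2, 3),
                          nn.Conv2d(c2, 4 * reg_max, 1))
            for x in ch)
        self.cv3 = nn.ModuleList(
            nn.Sequential(
                nn.Sequential(DWConv(x, x, 3), Conv(x, c3, 1)),
                nn.Sequential(DWConv(c3, c3, 3), Conv(c3, c3, 1)),
                nn.Conv2d(c3, nc, 1))
            for x in ch)

    def forward(self, xs):
        return [concatenate([self.cv2[i](x), self.cv3[i](x)], axis=1)
                for i, x in enumerate(xs)]


def dfl_expectation(box_logits: Tensor, reg_max: int = 16) -> Tensor:
    """Distribution-focal decode: softmax over bins -> expected offset.

    box_logits: (B, 4*reg_max, A) -> (B, 4, A) expected l/t/r/b distances.
    """
    b, _, a = box_logits.shape
    logits = box_logits.reshape(b, 4, reg_max, a)
    probs = softmax(logits, axis=2)
    bins = Tensor(np.arange(reg_max, dtype=np.float32).reshape(1, 1, reg_max, 1))
    return (probs * bins).sum(axis=2)


def make_anchors(shapes: list[tuple[int, int]], strides: list[int],
                 offset: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Anchor centre points (in input pixels) and per-anchor stride."""
    pts, strs = [], []
    for (h, w), s in zip(shapes, strides):
        xs = (np.arange(w) + offset) * s
        ys = (np.arange(h) + offset) * s
        gx, gy = np.meshgrid(xs, ys)
        pts.append(np.stack([gx.ravel(), gy.ravel()], axis=1))
        strs.append(np.full(h * w, s, dtype=np.float32))
    return (np.concatenate(pts).astype(np.float32), np.concatenate(strs))
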