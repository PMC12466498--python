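"""Multi-scale separation-and-enhancement attention and the detect head
that embeds it.

``MultiSEAM`` separates the input into non-overlapping patch embeddings
at three granularities (kernel = stride = 3, 5, 7), refines each with a
depthwise-separable convolution + SiLU, pools every branch (and the
original features) to per-channel vectors, and maps the concatenation
through a fully connected expansion to a per-channel attention vector
that re-weights the input.

``DHMSEAM`` is a drop-in decoupled detect head where the second
convolution of the box branch and the second depthwise-separable block of
the class branch are upgraded to MultiSEAM; raw output layout is
identical to the baseline head at every stride.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import nn
from .nn.tensor import Tensor, concatenate, sigmoid, silu
from .scaffold.blocks import Conv, Detect, DWConv
from .scaffold.model import register_block

__all__ = ["MultiSEAMSpec", "MultiSEAM", "DHMSEAM", "build_dhmseam_head"]

PATCH_SIZES = (3, 5, 7)


@dataclass(frozen=True)
class MultiSEAMSpec:
    channels: int
    patch_sizes: tuple[int, ...] = PATCH_SIZES
    expansion_ratio: float = 2.0

    def __post_init__(self):
        if len(self.patch_sizes) != 3:
            raise ValueError("MultiSEAM uses exactly three patch branches")
        if self.expansion_ratio <= 0:
            raise ValueError("expansion_ratio must be positive")

    def branch_hw(self, h: int, w: int) -> list[tuple[int, int]]:
        """Unpadded patch-embedding output sizes (stride = kernel)."""
        return [((h - k) // k + 1, (w - k) // k + 1) for k in self.patch_sizes]


class MultiSEAM(nn.Module):
    def __init__(self, channels: int, expansion_ratio: float = 2.0,
                 use_exp: bool = False):
        super().__init__()
        self.spec = MultiSEAMSpec(channels, PATCH_SIZES, expansion_ratio)
        self.use_exp = use_exp
        c = channels
        self.patch = nn.ModuleList(
            Conv(c, c, k, s=k, p=0) for k in PATCH_SIZES)
        pw_groups = 4 if c % 4 == 0 else 1
        self.dwsep = nn.ModuleList(
            nn.Sequential(DWConv(c, c, 5, act=False),
                          nn.Conv2d(c, c, 1, groups=pw_groups, bias=False))
            for _ in PATCH_SIZES)
        hidden = int(round(c * expansion_ratio))
        self.fc1 = nn.Linear(4 * c, hidden)
        self.fc2 = nn.Linear(hidden, c)

    def attention(self, x) -> Tensor:
        pooled = [x.mean(axis=(2, 3))]
        for patch, dwsep in zip(self.patch, self.dwsep):
            y = silu(dwsep(patch(x)))
            pooled.append(y.mean(axis=(2, 3)))
        z = self.fc2(silu(self.fc1(concatenate(pooled, axis=1))))
        return z.exp() if self.use_exp else sigmoid(z)

    def forward(self, x):
        h, w = x.shape[-2:]
        if h < max(PATCH_SIZES) or w < max(PATCH_SIZES):
            raise ValueError(
                f"input {h}x{w} smaller than the largest patch {max(PATCH_SIZES)}")
        attn = self.attention(x)
        b, c = attn.shape
        return x * attn.reshape(b, c, 1, 1)


class DHMSEAM(Detect):
    """Detect head with MultiSEAM on both branches; baseline output layout."""

    def __init__(self, nc: int, ch: tuple[int, ...], reg_max: int = 16,
                 expansion_ratio: float = 2.0):
        super().__init__(nc, ch, reg_max)
        c2 = max(16, ch[0] // 4, reg_max * 4)
        c3 = max(ch[0], min(nc, 100))
        self.cv2 = nn.ModuleList(
            nn.Sequential(Conv(x, c2, 3), MultiSEAM(c2, expansion_ratio),
                          nn.Conv2d(c2, 4 * reg_max, 1))
            for x in ch)
        self.cv3 = nn.ModuleList(
            nn.Sequential(
                nn.Sequential(DWConv(x, x, 3), Conv(x, c3, 1)),
                MultiSEAM(c3, expansion_ratio),
                nn.Conv2d(c3, nc, 1))
            for x in ch)


def build_dhmseam_head(num_classes: int, reg_max: int = 16,
                       ch: tuple[int, ...] = (64, 128, 256),
                       expansion_ratio: float = 2.0) -> DHMSEAM:
    if num_classes < 1:
        raise ValueError("num_classes must be >= 1")
    return DHMSEAM(num_classes, ch, reg_max, expansion_ratio)


@register_block("DHMSEAM")
def _b_dhmseam(cins, args, cfg):
    expansion = args[0] if args else 2.0
    return DHMSEAM(cfg["nc"], tuple(cins), cfg.get("reg_max", 16), expansion), 0
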