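"""Context-guided downsampling.

Replaces a plain stride-2 CBS with: stride-2 CBS, then two complementary
branches at the downsampled resolution — a 3x3 depthwise local branch and
a 3x3 dilation-2 context branch — concatenated, SiLU-activated, reduced
by a 1x1 CBS, and finally re-weighted by squeeze-style global channel
attention (GAP, two fully connected layers, sigmoid).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn.tensor import Tensor, concatenate, sigmoid, silu
from .scaffold.blocks import Conv, DWConv
from .scaffold.model import register_block

__all__ = ["CGDownSpec", "CGDown", "cg_global_attention"]


@dataclass(frozen=True)
class CGDownSpec:
    """Default contract: channel-doubling downsampler with dilation-2 context."""

    in_ch: int
    reduction_ratio: int = 16
    context_groups: int = 1

    def __post_init__(self):
        if self.out_ch % self.reduction_ratio:
            raise ValueError(
                f"reduction_ratio={self.reduction_ratio} must divide out_ch={self.out_ch}")
        if self.out_ch % self.context_groups:
            raise ValueError("context_groups must divide out_ch")

    @property
    def out_ch(self) -> int:
        return 2 * self.in_ch

    local_kernel: int = 3
    context_kernel: int = 3
    context_dilation: int = 2


class CGDown(nn.Module):
    def __init__(self, c1: int, c2: int | None = None, reduction: int = 16,
                 context_groups: int = 1, local_pointwise: bool = False,
                 local_kernel: int = 3):
        super().__init__()
        # out defaults to 2*c1 (backbone contract); stem/neck sites keep the
        # substrate's width schedule instead
        c2 = 2 * c1 if c2 is None else c2
        self.c1, self.c2 = c1, c2
        self.down = Conv(c1, c2, 3, 2)
        local = DWConv(c2, c2, local_kernel, act=False)
        self.fe_local = (nn.Sequential(local, nn.Conv2d(c2, c2, 1, bias=False))
                         if local_pointwise else local)
        self.fe_context = Conv(c2, c2, 3, d=2, g=context_groups, act=False)
        self.fe_joint = Conv(2 * c2, c2, 1)
        hidden = max(c2 // reduction, 4)
        self.fc1 = nn.Linear(c2, hidden)
        self.fc2 = nn.Linear(hidden, c2)

    def global_attention(self, j: Tensor) -> Tensor:
        """Per-channel weights in (0,1) from the GAP -> FC -> FC -> sigmoid path."""
        pooled = j.mean(axis=(2, 3))           # (B, C)
        return sigmoid(self.fc2(silu(self.fc1(pooled))))

    def forward(self, x):
        h, w = x.shape[-2:]
        if h % 2 or w % 2 or h < 4 or w < 4:
            raise ValueError(
                f"CGDown needs even H, W >= 4 for exact halving, got {h}x{w}")
        d = self.down(x)
        local = self.fe_local(d)
        context = self.fe_context(d)
        j = self.fe_joint(silu(concatenate([local, context], axis=1)))
        attn = self.global_attention(j)
        b, c = attn.shape
        return j * attn.reshape(b, c, 1, 1)


def cg_global_attention(j, fc1: nn.Linear, fc2: nn.Linear) -> np.ndarray:
    """Standalone global branch: sigmoid(fc2(silu(fc1(GAP(j))))), in (0,1)."""
    pooled = Tensor(np.asarray(j, dtype=np.float32).mean(axis=(2, 3)))
    return sigmoid(fc2(silu(fc1(pooled)))).data


@register_block("CGDown")
def _b_cgdown(cin, args, cfg):
    # args after scaling: [c2, reduction?, groups?, local_pointwise?, local_k?]
    c2 = args[0]
    reduction = args[1] if len(args) > 1 else 16
    groups = args[2] if len(args) > 2 else 1
    pointwise = bool(args[3]) if len(args) > 3 else False
    local_k = args[4] if len(args) > 4 else 3
    return CGDown(cin, c2, reduction, groups, pointwise, local_k), c2
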