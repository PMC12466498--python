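"""Multi-scale edge information extractor.

Three nested pieces:

* ``EIEnhance`` boosts high-frequency residuals (input minus a local
  low-pass) through a learnable 1x1 projection.
* ``DSM`` is a dual-domain selective mechanism: a sigmoid spatial weight
  map and a spectral high-pass branch, fused with the input by learnable
  per-channel gates that start at exact identity.
* ``MSEISelect`` pools the input to a fixed {3, 6, 9, 12} pyramid, edge-
  enhances each level, projects and sums them back at full resolution,
  and runs the result through the DSM.

``MSEIExtractor`` wraps MSEISelect in the substrate's split-transform-
merge stage layout so it can replace a backbone stage one-for-one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import functional as F
from .nn.tensor import Tensor, concatenate, sigmoid
from .scaffold.blocks import Conv
from .scaffold.model import register_block

__all__ = ["PoolPyramidSpec", "DSMFusionWeights", "EIEnhance", "DSM",
           "MSEISelect", "MSEIExtractor"]

PYRAMID_SCALES = (3, 6, 9, 12)


@dataclass(frozen=True)
class PoolPyramidSpec:
    scales: tuple[int, ...] = PYRAMID_SCALES

    def __post_init__(self):
        if tuple(self.scales) != PYRAMID_SCALES:
            raise ValueError(f"pyramid scales must be {PYRAMID_SCALES}, "
                             f"got {tuple(self.scales)}")


@dataclass
class DSMFusionWeights:
    """Learnable fusion gates; identity at initialization."""

    spatial_gate: np.ndarray
    frequency_gate: np.ndarray
    residual_gate: np.ndarray

    @classmethod
    def identity(cls, channels: int) -> "DSMFusionWeights":
        return cls(spatial_gate=np.zeros(channels, dtype=np.float32),
                   frequency_gate=np.zeros(channels, dtype=np.float32),
                   residual_gate=np.ones(channels, dtype=np.float32))


class EIEnhance(nn.Module):
    """out = x + proj(x - smooth(x)); smooth is a fixed 3x3 box filter.

    The box filter uses replicate padding and the projection is bias-free,
    so spatially constant inputs pass through exactly unchanged.
    """

    def __init__(self, channels: int, smooth_kernel: int = 3):
        super().__init__()
        self.channels = channels
        self.smooth_kernel = smooth_kernel
        k = smooth_kernel
        self._box = Tensor(np.full((channels, 1, k, k), 1.0 / (k * k),
                                   dtype=np.float32))
        self.proj = nn.Conv2d(channels, channels, 1, bias=False)

    def smooth(self, x):
        # replicate padding: a constant map stays exactly constant
        xp = F.pad_edge2d(x, self.smooth_kernel // 2)
        return F.conv2d(xp, self._box, stride=1, padding=0, groups=self.channels)

    def forward(self, x):
        residual = x + (-1.0) * self.smooth(x)
        return x + self.proj(residual)


class DSM(nn.Module):
    """Dual-domain (spatial + frequency) selective attention.

    ``out = r * x + a * (w(x) * x) + b * (g * highpass(x))`` where ``w``
    is a sigmoid spatial weight map, ``highpass`` a radial spectral
    filter, and ``r/a/b`` per-channel gates initialized to (1, 0, 0) so
    the block is exactly the identity at step 0.
    """

    def __init__(self, channels: int, spatial_hidden: int | None = None,
                 cutoff: float = 0.25):
        super().__init__()
        self.channels = channels
        self.cutoff = cutoff
        h = spatial_hidden or max(channels // 2, 4)
        self.ssm_conv = Conv(channels, h, 3)
        self.ssm_out = nn.Conv2d(h, 1, 1, bias=True)
        self.freq_weight = nn.Parameter(np.ones((1, channels, 1, 1)))
        self.residual_gate = nn.Parameter(np.ones((1, channels, 1, 1)))
        self.spatial_gate = nn.Parameter(np.zeros((1, channels, 1, 1)))
        self.frequency_gate = nn.Parameter(np.zeros((1, channels, 1, 1)))
        self._masks: dict[tuple[int, int], np.ndarray] = {}

    @property
    def fusion_weights(self) -> DSMFusionWeights:
        return DSMFusionWeights(spatial_gate=self.spatial_gate.data.ravel(),
                                frequency_gate=self.frequency_gate.data.ravel(),
                                residual_gate=self.residual_gate.data.ravel())

    def spatial_weight(self, x) -> Tensor:
        return sigmoid(self.ssm_out(self.ssm_conv(x)))

    def _mask(self, hw: tuple[int, int]) -> np.ndarray:
        if hw not in self._masks:
            self._masks[hw] = F.highpass_mask(*hw, self.cutoff)
        return self._masks[hw]

    def forward(self, x):
        h, w = x.shape[-2:]
        if h * w < 4 or min(h, w) < 2:
            raise ValueError(
                f"frequency branch needs a non-degenerate 2-D input, got {h}x{w}")
        spatial = self.spatial_weight(x) * x
        freq = self.freq_weight * F.spectral_highpass(x, self._mask((h, w)))
        return (self.residual_gate * x + self.spatial_gate * spatial
                + self.frequency_gate * freq)


class MSEISelect(nn.Module):
    """Four-scale pooling pyramid with edge enhancement and DSM selection.

    Each pyramid level is adaptively average-pooled, edge-enhanced,
    projected by a 1x1 conv and resized back (nearest, deterministic);
    the summed branches enter through a zero-initialized 1x1 fusion conv,
    so the whole block is the identity at initialization.
    """

    def __init__(self, channels: int, spatial_hidden: int | None = None,
                 scales: tuple[int, ...] = PYRAMID_SCALES,
                 proj_groups: int = 1, fuse_kernel: int = 1,
                 eie_shared: bool = False):
        super().__init__()
        self.spec = PoolPyramidSpec(tuple(scales))
        self.channels = channels
        if eie_shared:
            one = EIEnhance(channels)
            self.enhance = nn.ModuleList([one])
            self._enh_for = lambda i: one
        else:
            self.enhance = nn.ModuleList(
                EIEnhance(channels) for _ in self.spec.scales)
            self._enh_for = lambda i: self.enhance[i]
        self.proj = nn.ModuleList(
            nn.Conv2d(channels, channels, 1, groups=proj_groups, bias=False)
            for _ in self.spec.scales)
        self.fuse = nn.Conv2d(channels, channels, fuse_kernel,
                              padding=fuse_kernel // 2, bias=False)
        self.fuse.weight.data[:] = 0.0
        self.dsm = DSM(channels, spatial_hidden)

    def forward(self, x):
        h, w = x.shape[-2:]
        if h < max(self.spec.scales) or w < max(self.spec.scales):
            raise ValueError(
                f"input {h}x{w} smaller than the largest pyramid level "
                f"{max(self.spec.scales)}; resize the feature map (or pick a "
                f"shallower stage) so the pyramid is a true downsample")
        branches = None
        for i, (s, proj) in enumerate(zip(self.spec.scales, self.proj)):
            y = proj(self._enh_for(i)(F.adaptive_avg_pool2d(x, s)))
            y = F.upsample_nearest2d(y, size=(h, w))
            branches = y if branches is None else branches + y
        return self.dsm(x + self.fuse(branches))


class MSEIExtractor(nn.Module):
    """Stage block: split-transform-merge with MSEISelect on the transform path."""

    def __init__(self, c1: int, c2: int, n: int = 1, e: float = 0.5,
                 spatial_hidden: int | None = None, proj_groups: int = 1,
                 fuse_kernel: int = 1, eie_shared: bool = False):
        super().__init__()
        self.c = int(c2 * e)
        self.cv1 = Conv(c1, 2 * self.c, 1, 1)
        self.cv2 = Conv((2 + n) * self.c, c2, 1)
        self.m = nn.ModuleList(
            MSEISelect(self.c, spatial_hidden, PYRAMID_SCALES, proj_groups,
                       fuse_kernel, eie_shared) for _ in range(n))

    def forward(self, x):
        y0 = self.cv1(x)
        ys = [y0[:, :self.c], y0[:, self.c:]]
        for m in self.m:
            ys.append(m(ys[-1]))
        return self.cv2(concatenate(ys, axis=1))


@register_block("MSEIExtractor")
def _b_msei(cin, args, cfg):
    # args after scaling: [c2, n, e?, hidden?, proj_groups?, fuse_k?, shared?]
    c2, n = args[0], args[1]
    e = args[2] if len(args) > 2 else 0.5
    hidden = args[3] if len(args) > 3 else None
    proj_groups = args[4] if len(args) > 4 else 1
    fuse_k = args[5] if len(args) > 5 else 1
    shared = bool(args[6]) if len(args) > 6 else False
    return MSEIExtractor(cin, c2, n, e, hidden, proj_groups, fuse_k, shared), c2
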