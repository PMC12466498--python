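"""Config-driven graph builder for the detection substrate.

A model is described by a YAML-able dict: scaling factors plus a
``backbone``/``head`` layer list of ``[from, repeats, block, args]`` rows,
in the familiar one-row-per-layer dialect.  Channel arithmetic is resolved
at build time; novel blocks register themselves in ``BLOCK_REGISTRY``.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

from .. import nn
from ..nn.tensor import Tensor
from . import blocks as B

__all__ = ["FeatureMapSpec", "DetectionModel", "build_model", "build_yolo11n_baseline",
           "BLOCK_REGISTRY", "BASE_CONFIG", "make_divisible"]


@dataclass(frozen=True)
class FeatureMapSpec:
    """Batch/channel/spatial contract for a feature map."""

    batch: int
    channels: int
    height: int
    width: int

    def __post_init__(self):
        if min(self.batch, self.channels, self.height, self.width) < 1:
            raise ValueError("all FeatureMapSpec fields must be >= 1")

    def require_stride(self, stride: int = 32) -> None:
        if self.height % stride or self.width % stride:
            raise ValueError(
                f"input {self.height}x{self.width} not divisible by {stride}")

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return (self.batch, self.channels, self.height, self.width)


def make_divisible(x: float, divisor: int = 8) -> int:
    return max(divisor, int(x + divisor / 2) // divisor * divisor)


# Registered constructors: fn(c_in(s), scaled_args, cfg) -> (module, c_out).
BLOCK_REGISTRY: dict = {}


def register_block(name: str):
    def deco(fn):
        BLOCK_REGISTRY[name] = fn
        return fn
    return deco


@register_block("Conv")
def _b_conv(cin, args, cfg):
    c2, k, s = args
    return B.Conv(cin, c2, k, s), c2


@register_block("C3k2")
def _b_c3k2(cin, args, cfg):
    c2, n, c3k = args[0], args[1], args[2]
    e = args[3] if len(args) > 3 else 0.5
    return B.C3k2(cin, c2, n, c3k, e), c2


@register_block("SPPF")
def _b_sppf(cin, args, cfg):
    c2, k = args
    return B.SPPF(cin, c2, k), c2


@register_block("C2PSA")
def _b_c2psa(cin, args, cfg):
    c2, n = args
    return B.C2PSA(cin, c2, n), c2


@register_block("Upsample")
def _b_up(cin, args, cfg):
    return nn.Upsample(2), cin


@register_block("Concat")
def _b_concat(cins, args, cfg):
    return B.Concat(1), sum(cins)


@register_block("Detect")
def _b_detect(cins, args, cfg):
    nc = cfg["nc"]
    return B.Detect(nc, tuple(cins), reg_max=cfg.get("reg_max", 16)), 0


# Rows: [from, repeats, block, args].  Channel args are at nominal (x1.0)
# scale; width/depth multipliers shrink them to the nano operating point.
BASE_CONFIG = {
    "nc": 1,
    "reg_max": 16,
    "depth_multiple": 0.5,
    "width_multiple": 0.25,
    "max_channels": 1024,
    "backbone": [
        [-1, 1, "Conv", [64, 3, 2]],        # 0 P1/2
        [-1, 1, "Conv", [128, 3, 2]],       # 1 P2/4
        [-1, 2, "C3k2", [256, False, 0.25]],
        [-1, 1, "Conv", [256, 3, 2]],       # 3 P3/8
        [-1, 2, "C3k2", [512, False, 0.25]],
        [-1, 1, "Conv", [512, 3, 2]],       # 5 P4/16
        [-1, 2, "C3k2", [512, True]],
        [-1, 1, "Conv", [1024, 3, 2]],      # 7 P5/32
        [-1, 2, "C3k2", [1024, True]],
        [-1, 1, "SPPF", [1024, 5]],         # 9
        [-1, 2, "C2PSA", [1024]],           # 10
    ],
    "head": [
        [-1, 1, "Upsample", []],
        [[-1, 6], 1, "Concat", []],
        [-1, 2, "C3k2", [512, False]],      # 13
        [-1, 1, "Upsample", []],
        [[-1, 4], 1, "Concat", []],
        [-1, 2, "C3k2", [256, False]],      # 16 P3
        [-1, 1, "Conv", [256, 3, 2]],
        [[-1, 13], 1, "Concat", []],
        [-1, 2, "C3k2", [512, False]],      # 19 P4
        [-1, 1, "Conv", [512, 3, 2]],
        [[-1, 10], 1, "Concat", []],
        [-1, 2, "C3k2", [1024, True]],      # 22 P5
        [[16, 19, 22], 1, "Detect", []],
    ],
}

_CHANNEL_ARG_BLOCKS = {"Conv", "C3k2", "SPPF", "C2PSA", "CGDown", "MSEIExtractor"}


class DetectionModel(nn.Module):
    """Layer-graph executor with P3/P4/P5 detect outputs at strides 8/16/32."""

    def __init__(self, cfg: dict, seed: int = 0):
        super().__init__()
        nn.seed_all(seed)
        cfg = copy.deepcopy(cfg)
        self.cfg = cfg
        self.nc = cfg["nc"]
        self.reg_max = cfg.get("reg_max", 16)
        width = cfg.get("width_multiple", 1.0)
        depth = cfg.get("depth_multiple", 1.0)
        max_ch = cfg.get("max_channels", float("inf"))

        rows = list(cfg["backbone"]) + list(cfg["head"])
        ch: list[int] = [3]
        self.layers = nn.ModuleList()
        self.froms: list = []
        save: set[int] = set()
        for i, (frm, n, name, args) in enumerate(rows):
            if name not in BLOCK_REGISTRY:
                raise KeyError(f"unknown block {name!r} at layer {i}")
            args = list(args)
            if name in _CHANNEL_ARG_BLOCKS and args:
                args[0] = make_divisible(min(args[0], max_ch) * width, 8)
            n_eff = max(round(n * depth), 1) if n > 1 else n
            if name in ("C3k2", "C2PSA", "MSEIExtractor"):
                args = [args[0], n_eff] + args[1:]
            def _ch(f: int) -> int:
                return ch[-1] if f == -1 else ch[f + 1]

            if isinstance(frm, list):
                cin = [_ch(f) for f in frm]
                save.update(f % len(rows) for f in frm if f != -1)
            else:
                cin = _ch(frm)
                if frm != -1:
                    save.add(frm % len(rows))
            module, cout = BLOCK_REGISTRY[name](cin, args, cfg)
            self.layers.append(module)
            self.froms.append(frm)
            ch.append(cout)
        self.save = sorted(save)
        self.strides = self.layers[-1].strides

    @property
    def detect(self):
        return self.layers[-1]

    def forward(self, x):
        if not isinstance(x, Tensor):
            x = Tensor(x)
        outputs: dict[int, Tensor] = {}
        y = x
        for i, (m, frm) in enumerate(zip(self.layers, self.froms)):
            if isinstance(frm, list):
                inp = [y if f == -1 else outputs[f] for f in frm]
            else:
                inp = y if frm == -1 else outputs[frm]
            y = m(inp)
            if i in self.save:
                outputs[i] = y
        return y  # list of per-level (B, 4*reg_max+nc, H, W)


def build_model(cfg: dict, num_classes: int | None = None, seed: int = 0,
                width_multiple: float | None = None) -> DetectionModel:
    cfg = copy.deepcopy(cfg)
    if num_classes is not None:
        if num_classes < 1:
            raise ValueError("num_classes must be >= 1")
        cfg["nc"] = num_classes
    if width_multiple is not None:
        cfg["width_multiple"] = width_multiple
    return DetectionModel(cfg, seed=seed)


def build_yolo11n_baseline(num_classes: int = 1, seed: int = 0,
                           width_multiple: float | None = None) -> DetectionModel:
    """The unmodified nano substrate (all replacement flags off)."""
    return build_model(BASE_CONFIG, num_classes, seed, width_multiple)
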