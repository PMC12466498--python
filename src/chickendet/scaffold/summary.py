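"""Model introspection: parameter counting and FLOPs profiling.

GFLOPs follow the multiply-accumulate-times-two convention on the fused
inference graph (normalization folded into the preceding convolution, so
it contributes no ops; activations, pooling and resampling are free, as
are the attention stage's functional matmuls).  The convention is
switchable for sensitivity checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .. import nn
from .model import DetectionModel, FeatureMapSpec

__all__ = ["ModelSummary", "count_params", "profile_flops", "summarize"]

CONVENTIONS = ("mac2", "mac2+bias", "unfused")


@dataclass
class ModelSummary:
    params_total: int
    gflops_640: float
    per_layer: list[tuple[str, int]] = field(default_factory=list)

    @property
    def params_millions(self) -> float:
        return round(self.params_total / 1e6, 2)

    def __post_init__(self):
        if self.per_layer and self.params_total != sum(p for _, p in self.per_layer):
            raise ValueError("per_layer params do not sum to params_total")


def count_params(model: nn.Module, fused: bool = False) -> int:
    """Number of trainable weights, each counted exactly once.

    With ``fused=True`` the count is taken on the inference graph where
    each batch norm is folded into its preceding convolution (the conv
    gains a bias, the norm's scale/shift disappear: net minus one weight
    per normalized channel).  Printed model-size tables use fused counts.
    """
    raw = model.num_params()
    if not fused:
        return raw
    folded = sum(m.ch for m in model.modules() if isinstance(m, nn.BatchNorm2d))
    return raw - folded


def _per_layer(model: nn.Module, fused: bool = False) -> list[tuple[str, int]]:
    if isinstance(model, DetectionModel):
        return [(f"{i}:{type(m).__name__}", count_params(m, fused))
                for i, m in enumerate(model.layers)]
    return [(type(model).__name__, count_params(model, fused))]


def profile_flops(model: nn.Module, input_spec: FeatureMapSpec | tuple = (1, 3, 640, 640),
                  convention: str = "mac2") -> float:
    """GFLOPs of one forward pass at the given input size."""
    if convention not in CONVENTIONS:
        raise ValueError(f"convention must be one of {CONVENTIONS}")
    if not isinstance(input_spec, FeatureMapSpec):
        input_spec = FeatureMapSpec(*input_spec)
    input_spec.require_stride(32)
    was_training = model.training
    model.eval()
    with nn.no_grad(), nn.profile_scope() as records:
        model(np.zeros(input_spec.shape, dtype=np.float32))
    model.train(was_training)
    flops = 0.0
    for kind, macs, extra in records:
        if kind in ("conv", "linear"):
            flops += 2.0 * macs
            if convention == "mac2+bias":
                flops += extra
        elif kind == "bn" and convention == "unfused":
            flops += extra
    return flops / 1e9


def summarize(model: DetectionModel, imgsz: int = 640, convention: str = "mac2",
              fused: bool = True) -> ModelSummary:
    """Table-style summary (fused counts by default, like printed budgets)."""
    return ModelSummary(
        params_total=count_params(model, fused),
        gflops_640=profile_flops(model, (1, 3, imgsz, imgsz), convention),
        per_layer=_per_layer(model, fused),
    )
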