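"""Variant assembly: baseline, single-module ablations, and the full model.

Replacement sites and block hyper-parameters live here as single frozen
constants, calibrated once against the printed parameter/GFLOPs budgets
and then never touched; every test reads them from this module.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

from . import cgdown, mseam, msei  # noqa: F401  (register blocks)
from .scaffold.model import BASE_CONFIG, DetectionModel, build_model
from .scaffold.summary import ModelSummary, summarize

__all__ = ["VariantFlags", "VARIANTS", "variant_config", "build_variant",
           "summarize_variants"]


@dataclass(frozen=True)
class VariantFlags:
    use_dhmseam: bool = False
    use_msei: bool = False
    use_cgdown: bool = False

    def name(self) -> str:
        return {v: k for k, v in VARIANTS.items()}.get(self, "custom")


VARIANTS: dict[str, VariantFlags] = {
    "baseline": VariantFlags(False, False, False),
    "model1": VariantFlags(True, False, False),
    "model2": VariantFlags(False, True, False),
    "model3": VariantFlags(False, False, True),
    "model4": VariantFlags(True, True, False),
    "model5": VariantFlags(True, False, True),
    "model6": VariantFlags(False, True, True),
    "chicken-yolo": VariantFlags(True, True, True),
}

# ---------------------------------------------------------------- calibration
# Backbone stages replaced by MSEIExtractor, with the per-site spatial-gate
# hidden width of the DSM (the budget-tuning free parameter).
# site -> (dsm spatial-gate hidden width, branch-projection groups,
# fuse-conv kernel, edge-enhancer shared across pyramid branches).
# Stage 8 is excluded so the largest pyramid level stays a true
# downsample at training sizes down to 224 px.
MSEI_SITES: dict[int, tuple[int, int, int, bool]] = {
    2: (64, 1, 1, True), 4: (16, 2, 1, False), 6: (16, 4, 1, True),
}

# Stride-2 convolutions replaced by CGDown: every backbone downsampler
# (stem included) and the two neck downsamplers; values are
# (reduction_ratio, context_groups, local_pointwise, local_kernel).
CGDOWN_SITES: dict[int, tuple[int, int, bool, int]] = {
    0: (16, 8, False, 3), 1: (16, 1, False, 5), 3: (16, 1, True, 3),
    5: (16, 1, True, 3), 7: (16, 2, False, 3),
    17: (16, 1, False, 3), 20: (16, 1, True, 3),
}

# Fully connected bottleneck ratio of every MultiSEAM in the head.
MSEAM_EXPANSION: float = 0.375


def variant_config(flags: VariantFlags) -> dict:
    cfg = copy.deepcopy(BASE_CONFIG)
    rows = cfg["backbone"] + cfg["head"]
    n_backbone = len(cfg["backbone"])
    if flags.use_msei:
        for site, (hidden, proj_groups, fuse_k, shared) in MSEI_SITES.items():
            frm, n, name, args = rows[site]
            if name != "C3k2":
                raise ValueError(f"MSEI site {site} is {name}, expected C3k2")
            c2 = args[0]
            e = args[2] if len(args) > 2 else 0.5
            rows[site] = [frm, n, "MSEIExtractor",
                          [c2, e, hidden, proj_groups, fuse_k, shared]]
    if flags.use_cgdown:
        for site, (reduction, groups, pointwise, local_k) in CGDOWN_SITES.items():
            frm, n, name, args = rows[site]
            if name != "Conv" or args[2] != 2:
                raise ValueError(f"CGDown site {site} is not a stride-2 Conv")
            rows[site] = [frm, n, "CGDown",
                          [args[0], reduction, groups, pointwise, local_k]]
    if flags.use_dhmseam:
        frm, n, name, args = rows[-1]
        if name != "Detect":
            raise ValueError("last layer is not the detect head")
        rows[-1] = [frm, n, "DHMSEAM", [MSEAM_EXPANSION]]
    cfg["backbone"] = rows[:n_backbone]
    cfg["head"] = rows[n_backbone:]
    return cfg


def build_variant(flags: VariantFlags | str, num_classes: int = 1, seed: int = 0,
                  width_multiple: float | None = None) -> DetectionModel:
    if isinstance(flags, str):
        try:
            flags = VARIANTS[flags]
        except KeyError:
            raise KeyError(f"unknown variant {flags!r}; "
                           f"choose from {sorted(VARIANTS)}") from None
    return build_model(variant_config(flags), num_classes, seed, width_multiple)


def summarize_variants(num_classes: int = 1, imgsz: int = 640,
                       seed: int = 0) -> dict[str, ModelSummary]:
    return {name: summarize(build_variant(flags, num_classes, seed), imgsz)
            for name, flags in VARIANTS.items()}
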