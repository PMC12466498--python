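"""Multi-stage image enhancement used as an annotation aid.

The four stages, applied in this fixed order:

1. directional saturation boost in HSV (stronger inside the red hue band
   covering combs, moderate elsewhere),
2. gamma brightening of global dark regions,
3. CLAHE on the luminance plane (chrominance untouched),
4. edge-aware (bilateral) denoising.

Enhanced images exist only to make annotation easier in dark scenes;
``transfer_labels`` pairs label files back to the untouched originals by
filename stem, and ``audit_manifest`` enforces that no enhanced image
ever enters a training/evaluation manifest.

No numeric constants for this pipeline are published; the defaults in
``EnhanceParams`` are repository policy.
"""

from __future__ import annotations

import shutil
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage import color, exposure, restoration

__all__ = ["EnhanceParams", "saturation_boost", "gamma_correct",
           "clahe_luminance", "edge_denoise", "enhance_pipeline",
           "transfer_labels", "TransferReport", "audit_manifest"]

IMAGE_SUFFIXES = (".png", ".jpg", ".jpeg")


@dataclass(frozen=True)
class EnhanceParams:
    red_hue_band: tuple[float, float] = (330.0, 30.0)  # degrees, wraps at 360
    sat_gain_red: float = 1.4
    sat_gain_global: float = 1.15
    gamma: float = 0.6
    clahe_clip: float = 2.0
    clahe_tiles: int = 8
    denoise_sigma_color: float = 0.08
    denoise_sigma_spatial: float = 2.0
    luminance_space: str = "lab"  # or "hsv-v"

    def __post_init__(self):
        if self.sat_gain_red < 1 or self.sat_gain_global < 1:
            raise ValueError("saturation gains must be >= 1")
        if not 0 < self.gamma <= 1:
            raise ValueError("gamma must lie in (0, 1]")
        if self.clahe_clip <= 0:
            raise ValueError("clahe_clip must be positive")
        if self.clahe_tiles < 2:
            raise ValueError("clahe_tiles must be >= 2")
        if self.luminance_space not in ("lab", "hsv-v"):
            raise ValueError("luminance_space must be 'lab' or 'hsv-v'")


def _check_rgb8(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3 or img.dtype != np.uint8:
        raise ValueError(f"expected 8-bit 3-channel image, got "
                         f"shape={img.shape} dtype={img.dtype}")
    return img


def _hue_mask(hue_deg: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    lo, hi = band
    if lo <= hi:
        return (hue_deg >= lo) & (hue_deg <= hi)
    return (hue_deg >= lo) | (hue_deg <= hi)  # band wraps through 0


def saturation_boost(img: np.ndarray, p: EnhanceParams) -> np.ndarray:
    """Multiply S inside/outside the red hue band; H and V untouched."""
    img = _check_rgb8(img)
    hsv = color.rgb2hsv(img / 255.0)
    gain = np.where(_hue_mask(hsv[..., 0] * 360.0, p.red_hue_band),
                    p.sat_gain_red, p.sat_gain_global)
    hsv[..., 1] = np.clip(hsv[..., 1] * gain, 0.0, 1.0)
    return np.clip(np.rint(color.hsv2rgb(hsv) * 255.0), 0, 255).astype(np.uint8)


def gamma_correct(img: np.ndarray, gamma: float) -> np.ndarray:
    """v -> 255 * (v/255)**gamma per channel; endpoints are fixed points."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    img = _check_rgb8(img)
    lut = np.clip(np.rint(255.0 * (np.arange(256) / 255.0) ** gamma),
                  0, 255).astype(np.uint8)
    return lut[img]


def clahe_luminance(img: np.ndarray, clip: float, tiles: int,
                    space: str = "lab") -> np.ndarray:
    """CLAHE on the luminance plane only; chrominance planes pass through."""
    img = _check_rgb8(img)
    if space == "lab":
        lab = color.rgb2lab(img / 255.0)
        lum = lab[..., 0] / 100.0
        eq = exposure.equalize_adapthist(lum, kernel_size=_tile_kernel(img, tiles),
                                         clip_limit=clip / 100.0)
        lab[..., 0] = eq * 100.0
        with warnings.catch_warnings():
            # slightly out-of-gamut Lab values are clipped on conversion
            warnings.simplefilter("ignore", UserWarning)
            out = color.lab2rgb(lab)
    else:
        hsv = color.rgb2hsv(img / 255.0)
        hsv[..., 2] = exposure.equalize_adapthist(
            hsv[..., 2], kernel_size=_tile_kernel(img, tiles),
            clip_limit=clip / 100.0)
        out = color.hsv2rgb(hsv)
    return np.clip(np.rint(out * 255.0), 0, 255).astype(np.uint8)


def _tile_kernel(img: np.ndarray, tiles: int) -> tuple[int, int]:
    return (max(img.shape[0] // tiles, 1), max(img.shape[1] // tiles, 1))


def edge_denoise(img: np.ndarray, p: EnhanceParams) -> np.ndarray:
    """Bilateral smoothing: kills flat-region noise, keeps step edges."""
    img = _check_rgb8(img)
    out = restoration.denoise_bilateral(
        img / 255.0, sigma_color=p.denoise_sigma_color,
        sigma_spatial=p.denoise_sigma_spatial, channel_axis=-1)
    return np.clip(np.rint(out * 255.0), 0, 255).astype(np.uint8)


def enhance_pipeline(img: np.ndarray, p: EnhanceParams | None = None) -> np.ndarray:
    """saturation -> gamma -> CLAHE -> denoise, in that order."""
    p = p or EnhanceParams()
    img = saturation_boost(img, p)
    img = gamma_correct(img, p.gamma)
    img = clahe_luminance(img, p.clahe_clip, p.clahe_tiles, p.luminance_space)
    return edge_denoise(img, p)


# ------------------------------------------------------------- label transfer

@dataclass
class TransferReport:
    pairs: list[tuple[str, str]] = field(default_factory=list)
    orphan_labels: list[str] = field(default_factory=list)
    orphan_images: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.orphan_labels and not self.orphan_images


def transfer_labels(enhanced_label_dir: str | Path, original_image_dir: str | Path,
                    out_dir: str | Path | None = None) -> TransferReport:
    """Pair label files (made on enhanced images) with the original images.

    Filenames are standardized, so a label matches the original with the
    same stem.  Geometry is copied verbatim — enhancement changed only
    visual quality, never positions.  Orphans on either side are reported.
    """
    label_dir, image_dir = Path(enhanced_label_dir), Path(original_image_dir)
    labels = {f.stem: f for f in sorted(label_dir.glob("*.txt"))}
    images = {f.stem: f for f in sorted(image_dir.iterdir())
              if f.suffix.lower() in IMAGE_SUFFIXES}
    report = TransferReport()
    for stem in sorted(set(labels) | set(images)):
        if stem in labels and stem in images:
            report.pairs.append((str(images[stem]), str(labels[stem])))
        elif stem in labels:
            report.orphan_labels.append(str(labels[stem]))
        else:
            report.orphan_images.append(str(images[stem]))
    if out_dir is not None and report.ok:
        out = Path(out_dir)
        (out / "images").mkdir(parents=True, exist_ok=True)
        (out / "labels").mkdir(parents=True, exist_ok=True)
        for img, lbl in report.pairs:
            shutil.copyfile(img, out / "images" / Path(img).name)
            shutil.copyfile(lbl, out / "labels" / Path(lbl).name)
    return report


def audit_manifest(manifest_rows: list[dict], enhanced_dir: str | Path) -> list[str]:
    """Return manifest image paths that live under the enhanced-image dir.

    Enhanced frames are annotation aids only and must never appear in a
    train/val/test manifest; a non-empty return is a policy violation.
    """
    enhanced = Path(enhanced_dir).resolve()
    bad = []
    for row in manifest_rows:
        path = Path(row["image"]).resolve()
        if enhanced in path.parents or path == enhanced:
            bad.append(row["image"])
    return bad
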