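"""Dataset loading (YOLO text-label layout) and online augmentation:
translation, scaling, horizontal flipping, Mosaic and Mixup.

Boxes are carried as absolute xyxy float arrays alongside HxWx3 float32
images in [0, 1]; augmentation parameters are repository defaults (the
source protocol names the transforms but no magnitudes).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from ..synth import BoxLabel

__all__ = ["Sample", "load_sample", "load_dataset", "AugmentParams", "augment_batch"]


@dataclass
class Sample:
    image: np.ndarray  # HxWx3 float32 in [0,1]
    boxes: np.ndarray  # (N,4) absolute xyxy

    @property
    def hw(self) -> tuple[int, int]:
        return self.image.shape[:2]


def load_sample(image_path: str | Path, label_path: str | Path | None = None,
                imgsz: int | None = None) -> Sample:
    img = Image.open(image_path).convert("RGB")
    if imgsz is not None and img.size != (imgsz, imgsz):
        img = img.resize((imgsz, imgsz), Image.BILINEAR)
    arr = np.asarray(img, dtype=np.float32) / 255.0
    h, w = arr.shape[:2]
    boxes = np.zeros((0, 4), dtype=np.float32)
    if label_path is not None and Path(label_path).exists():
        lines = Path(label_path).read_text().splitlines()
        if lines:
            boxes = np.array([BoxLabel.from_line(l).xyxy(w, h) for l in lines],
                             dtype=np.float32)
    return Sample(arr, boxes)


def load_dataset(manifest: list[dict], imgsz: int | None = None) -> list[Sample]:
    missing = [row["label"] for row in manifest
               if row.get("label") and not Path(row["label"]).exists()]
    if missing:
        raise FileNotFoundError(f"missing label files: {missing}")
    return [load_sample(row["image"], row.get("label"), imgsz) for row in manifest]


@dataclass(frozen=True)
class AugmentParams:
    translate: float = 0.1          # +/- fraction of image size
    scale_range: tuple[float, float] = (0.5, 1.5)
    flip_p: float = 0.5
    mosaic_p: float = 0.5
    mixup_p: float = 0.15
    mixup_beta: float = 8.0
    min_box: float = 2.0            # discard boxes collapsed below this (px)


def _clip_boxes(boxes: np.ndarray, h: int, w: int, min_box: float) -> np.ndarray:
    if not len(boxes):
        return boxes
    b = boxes.copy()
    b[:, [0, 2]] = b[:, [0, 2]].clip(0, w)
    b[:, [1, 3]] = b[:, [1, 3]].clip(0, h)
    keep = (b[:, 2] - b[:, 0] >= min_box) & (b[:, 3] - b[:, 1] >= min_box)
    return b[keep]


def _affine(s: Sample, rng: np.random.Generator, p: AugmentParams) -> Sample:
    """Scale + translate (nearest resample) + optional horizontal flip."""
    h, w = s.hw
    scale = rng.uniform(*p.scale_range)
    tx = rng.uniform(-p.translate, p.translate) * w
    ty = rng.uniform(-p.translate, p.translate) * h
    ys = ((np.arange(h) - ty) / scale).round().astype(int)
    xs = ((np.arange(w) - tx) / scale).round().astype(int)
    valid_y = (ys >= 0) & (ys < h)
    valid_x = (xs >= 0) & (xs < w)
    out = np.full_like(s.image, 0.45)
    out[np.ix_(valid_y, valid_x)] = s.image[np.ix_(ys[valid_y], xs[valid_x])]
    boxes = s.boxes * scale + np.array([tx, ty, tx, ty], dtype=np.float32)
    if rng.random() < p.flip_p:
        out = out[:, ::-1].copy()
        if len(boxes):
            boxes = boxes[:, [2, 1, 0, 3]] * np.array([-1, 1, -1, 1]) + \
                np.array([w, 0, w, 0], dtype=np.float32)
    return Sample(out, _clip_boxes(boxes, h, w, p.min_box))


def _mosaic(samples: list[Sample], rng: np.random.Generator,
            p: AugmentParams) -> Sample:
    """2x2 grid of four images, each quadrant nearest-resized to half."""
    h, w = samples[0].hw
    hh, hw = h // 2, w // 2
    out = np.empty((h, w, 3), dtype=np.float32)
    boxes = []
    corners = [(0, 0), (0, hw), (hh, 0), (hh, hw)]
    for s, (oy, ox) in zip(samples, corners):
        ys = (np.arange(hh) * 2).clip(0, s.hw[0] - 1)
        xs = (np.arange(hw) * 2).clip(0, s.hw[1] - 1)
        out[oy:oy + hh, ox:ox + hw] = s.image[np.ix_(ys, xs)]
        if len(s.boxes):
            b = s.boxes * 0.5 + np.array([ox, oy, ox, oy], dtype=np.float32)
            boxes.append(b)
    merged = np.concatenate(boxes) if boxes else np.zeros((0, 4), dtype=np.float32)
    return Sample(out, _clip_boxes(merged, h, w, p.min_box))


def _mixup(a: Sample, b: Sample, rng: np.random.Generator) -> Sample:
    lam = rng.beta(8.0, 8.0)
    img = lam * a.image + (1 - lam) * b.image
    boxes = np.concatenate([a.boxes, b.boxes]) if len(a.boxes) or len(b.boxes) \
        else np.zeros((0, 4), dtype=np.float32)
    return Sample(img.astype(np.float32), boxes)


def augment_batch(dataset: list[Sample], indices, rng: np.random.Generator,
                  p: AugmentParams | None = None) -> list[Sample]:
    """One augmented view per requested index."""
    p = p or AugmentParams()
    out = []
    for i in indices:
        if rng.random() < p.mosaic_p and len(dataset) >= 4:
            picks = [dataset[i]] + [dataset[rng.integers(len(dataset))]
                                    for _ in range(3)]
            s = _mosaic(picks, rng, p)
        else:
            s = _affine(dataset[i], rng, p)
        if rng.random() < p.mixup_p and len(dataset) >= 2:
            s = _mixup(s, _affine(dataset[rng.integers(len(dataset))], rng, p), rng)
        out.append(s)
    return out
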