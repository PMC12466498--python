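"""Procedural caged-bird scenes with YOLO-format head-neck labels.

Stands in for the (undeposited) farm imagery: multi-tier cages with a
strong illumination gradient (bright upper tier, dark lower tier and
cage depth), wire mesh, and three occluder types — water pipe, feed
trough, and conspecific crowding.  Every bird is rendered as a textured
body ellipse plus a head-neck capsule with a red comb patch; the label
box tightly encloses the rendered head-neck mask.  Fully deterministic
under (spec, seed).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = ["SceneSpec", "BoxLabel", "generate_scene", "generate_dataset",
           "split_dataset", "make_special_sets", "load_manifest",
           "VISIBILITY_THRESHOLD", "OCCLUDER_TYPES"]

# Birds whose head-neck region is more occluded than this are not labeled
# (annotation policy for near-total occlusion; the source protocol is
# qualitative, the number is repository policy).
VISIBILITY_THRESHOLD = 0.15

OCCLUDER_TYPES = ("pipe", "trough", "crowd")

POOR_LIGHT_MAX = 0.30  # illumination quantile boundary for the special set


@dataclass(frozen=True)
class SceneSpec:
    n_chickens: int = 4
    tier: str = "upper"
    illumination: float = 0.8
    occluders: tuple[str, ...] = ()
    depth_falloff: float = 0.5
    seed: int = 0
    size: int = 320

    def __post_init__(self):
        if self.n_chickens < 0:
            raise ValueError("n_chickens must be >= 0")
        if self.tier not in ("upper", "lower"):
            raise ValueError("tier must be 'upper' or 'lower'")
        if not 0.0 <= self.illumination <= 1.0:
            raise ValueError("illumination must lie in [0, 1]")
        for occ in self.occluders:
            if occ not in OCCLUDER_TYPES:
                raise ValueError(f"unknown occluder {occ!r}")
        if self.size <= 0:
            raise ValueError("scene must have positive area")


@dataclass(frozen=True)
class BoxLabel:
    class_id: int
    cx: float
    cy: float
    w: float
    h: float
    visibility_fraction: float = 1.0

    def __post_init__(self):
        for v in (self.cx, self.cy, self.w, self.h):
            if not 0.0 <= v <= 1.0:
                raise ValueError("box coordinates must be normalized to [0, 1]")

    def to_line(self) -> str:
        return (f"{self.class_id} {self.cx:.6f} {self.cy:.6f} "
                f"{self.w:.6f} {self.h:.6f}")

    @classmethod
    def from_line(cls, line: str) -> "BoxLabel":
        parts = line.split()
        return cls(int(parts[0]), *map(float, parts[1:5]))

    def xyxy(self, width: int, height: int) -> tuple[float, float, float, float]:
        return ((self.cx - self.w / 2) * width, (self.cy - self.h / 2) * height,
                (self.cx + self.w / 2) * width, (self.cy + self.h / 2) * height)


def _ellipse_mask(size: int, cy: float, cx: float, ry: float, rx: float,
                  angle: float = 0.0) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    dy, dx = yy - cy, xx - cx
    ca, sa = np.cos(angle), np.sin(angle)
    u = dx * ca + dy * sa
    v = -dx * sa + dy * ca
    return (u / rx) ** 2 + (v / ry) ** 2 <= 1.0


def _paint(canvas: np.ndarray, mask: np.ndarray, rgb, texture=None) -> None:
    canvas[mask] = rgb
    if texture is not None:
        canvas[mask] += texture[mask][:, None]
        np.clip(canvas, 0.0, 1.0, out=canvas)


def _render_bird(canvas, rng, size, feather_noise):
    """Draw one bird; returns (headneck_mask, body_mask)."""
    s = size
    cy = rng.uniform(0.35 * s, 0.85 * s)
    cx = rng.uniform(0.12 * s, 0.88 * s)
    body_ry = rng.uniform(0.055, 0.085) * s
    body_rx = body_ry * rng.uniform(1.3, 1.7)
    angle = rng.uniform(-0.4, 0.4)
    body = _ellipse_mask(s, cy, cx, body_ry, body_rx, angle)
    base = np.array([0.62, 0.48, 0.22]) * rng.uniform(0.85, 1.1)
    _paint(canvas, body, np.clip(base, 0, 1), feather_noise)

    # head-neck capsule: neck rectangle leaning out of the body + head disc
    side = rng.choice([-1.0, 1.0])
    head_r = body_ry * rng.uniform(0.38, 0.5)
    neck_len = body_ry * rng.uniform(1.2, 1.6)
    hx = cx + side * (body_rx * 0.8)
    hy = cy - neck_len
    neck = _ellipse_mask(s, (cy + hy) / 2, (cx * 0.25 + hx * 0.75),
                         neck_len * 0.65, head_r * 0.75, 0.15 * side)
    head = _ellipse_mask(s, hy, hx, head_r, head_r)
    headneck = neck | head
    _paint(canvas, headneck, np.clip(base * 1.08, 0, 1), feather_noise)
    comb = _ellipse_mask(s, hy - head_r * 0.9, hx, head_r * 0.45, head_r * 0.55)
    _paint(canvas, comb, np.array([0.75, 0.08, 0.06]))
    eye = _ellipse_mask(s, hy, hx + side * head_r * 0.4, head_r * 0.16,
                        head_r * 0.16)
    _paint(canvas, eye, np.array([0.05, 0.04, 0.03]))
    return headneck | comb, body | headneck | comb


def generate_scene(spec: SceneSpec) -> tuple[np.ndarray, list[BoxLabel]]:
    """Render one scene; returns (HxWx3 uint8 image, labels)."""
    rng = np.random.default_rng(spec.seed)
    s = spec.size
    canvas = np.empty((s, s, 3), dtype=np.float64)
    canvas[:] = np.array([0.45, 0.40, 0.33])  # cage interior
    canvas += rng.normal(0.0, 0.02, (s, s, 1))
    feather_noise = rng.normal(0.0, 0.045, (s, s))

    headnecks: list[np.ndarray] = []
    bodies: list[np.ndarray] = []
    for _ in range(spec.n_chickens):
        hn, body = _render_bird(canvas, rng, s, feather_noise)
        headnecks.append(hn)
        bodies.append(body)

    occ_mask = np.zeros((s, s), dtype=bool)
    if "crowd" in spec.occluders:
        for _ in range(rng.integers(2, 5)):
            _, body = _render_bird(canvas, rng, s, feather_noise)
            occ_mask |= body
    if "trough" in spec.occluders:
        top = int(rng.uniform(0.55, 0.75) * s)
        trough = np.zeros((s, s), dtype=bool)
        trough[top:, :] = True
        _paint(canvas, trough, np.array([0.30, 0.28, 0.26]))
        occ_mask |= trough
    if "pipe" in spec.occluders:
        y0 = int(rng.uniform(0.25, 0.6) * s)
        thick = max(int(0.035 * s), 3)
        pipe = np.zeros((s, s), dtype=bool)
        pipe[y0:y0 + thick, :] = True
        _paint(canvas, pipe, np.array([0.55, 0.55, 0.58]))
        occ_mask |= pipe

    # wire mesh
    step = max(s // 12, 8)
    mesh = np.zeros((s, s), dtype=bool)
    mesh[::step, :] = True
    mesh[:, ::step] = True
    canvas[mesh] *= 0.55

    # tier/depth illumination: rear (top of frame) darker, scaled globally
    depth = 1.0 - spec.depth_falloff * (1.0 - np.linspace(0, 1, s))[:, None, None]
    lum = 0.15 + 0.85 * spec.illumination
    canvas = np.clip(canvas * lum * depth, 0.0, 1.0)
    image = np.clip(np.rint(canvas * 255.0), 0, 255).astype(np.uint8)

    labels: list[BoxLabel] = []
    for i, hn in enumerate(headnecks):
        area = hn.sum()
        if area == 0:
            continue
        in_front = occ_mask.copy()
        for later in bodies[i + 1:]:
            in_front |= later
        visible = 1.0 - (hn & in_front).sum() / area
        if visible < VISIBILITY_THRESHOLD:
            continue
        ys, xs = np.nonzero(hn)
        x0, x1 = xs.min(), xs.max() + 1
        y0, y1 = ys.min(), ys.max() + 1
        labels.append(BoxLabel(0, (x0 + x1) / 2 / s, (y0 + y1) / 2 / s,
                               (x1 - x0) / s, (y1 - y0) / s,
                               visibility_fraction=float(visible)))
    return image, labels


# ------------------------------------------------------------------- datasets

def _sample_spec(rng: np.random.Generator, size: int,
                 tier: str | None = None,
                 illumination: tuple[float, float] | None = None,
                 min_occluders: int = 0) -> SceneSpec:
    tier = tier or ("upper" if rng.random() < 0.5 else "lower")
    if illumination is None:
        illumination = (0.55, 1.0) if tier == "upper" else (0.05, 0.5)
    n_occ = rng.integers(min_occluders, len(OCCLUDER_TYPES) + 1)
    occ = tuple(sorted(rng.choice(OCCLUDER_TYPES, size=n_occ, replace=False)))
    return SceneSpec(
        n_chickens=int(rng.integers(1, 7)),
        tier=tier,
        illumination=float(rng.uniform(*illumination)),
        occluders=occ,
        depth_falloff=float(rng.uniform(0.3, 0.7)),
        seed=int(rng.integers(0, 2 ** 31)),
        size=size,
    )


def _write_example(spec: SceneSpec, stem: str, out: Path) -> dict:
    image, labels = generate_scene(spec)
    img_path = out / "images" / f"{stem}.png"
    lbl_path = out / "labels" / f"{stem}.txt"
    Image.fromarray(image).save(img_path)
    lbl_path.write_text("".join(l.to_line() + "\n" for l in labels))
    spec_dict = asdict(spec)
    spec_dict["occluders"] = list(spec.occluders)  # JSON-stable form
    return {"image": str(img_path), "label": str(lbl_path),
            "n_boxes": len(labels), "spec": spec_dict}


def generate_dataset(n_images: int, out_dir: str | Path, seed: int = 0,
                     size: int = 320, force: bool = False,
                     spec_sampler=_sample_spec, prefix: str = "scene") -> list[dict]:
    """Write images/, labels/ and manifest.json in YOLO dataset layout."""
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} is not empty; pass force=True to overwrite")
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "labels").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    manifest = [_write_example(spec_sampler(rng, size), f"{prefix}_{i:05d}", out)
                for i in range(n_images)]
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def load_manifest(path: str | Path) -> list[dict]:
    path = Path(path)
    if path.is_dir():
        path = path / "manifest.json"
    return json.loads(path.read_text())


def split_dataset(manifest: list[dict], ratios: tuple[float, float, float] = (0.7, 0.2, 0.1),
                  seed: int = 0) -> tuple[list[dict], list[dict], list[dict]]:
    """Shuffled 7:2:1 partition: floor, floor, remainder.

    This floor/remainder rule reproduces the reference 3851 -> 2695/770/386
    split arithmetic exactly.
    """
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    n = len(manifest)
    if n < 10:
        raise ValueError("need at least 10 items to split")
    order = np.random.default_rng(seed).permutation(n)
    n_train = int(np.floor(ratios[0] * n))
    n_val = int(np.floor(ratios[1] * n))
    idx_train = order[:n_train]
    idx_val = order[n_train:n_train + n_val]
    idx_test = order[n_train + n_val:]
    pick = lambda idx: [manifest[i] for i in sorted(idx)]  # noqa: E731
    return pick(idx_train), pick(idx_val), pick(idx_test)


def make_special_sets(out_dir: str | Path, n_each: int = 100, seed: int = 0,
                      size: int = 320, force: bool = False) -> tuple[list[dict], list[dict]]:
    """Two dedicated 100-image test sets: poor illumination and multi-occlusion."""
    out = Path(out_dir)

    def poor_light(rng, sz):
        return _sample_spec(rng, sz, tier="lower",
                            illumination=(0.02, POOR_LIGHT_MAX))

    def multi_occ(rng, sz):
        return _sample_spec(rng, sz, min_occluders=2)

    poor = generate_dataset(n_each, out / "poor-light", seed=seed + 101, size=size,
                            force=force, spec_sampler=poor_light, prefix="poor")
    occ = generate_dataset(n_each, out / "multi-occ", seed=seed + 202, size=size,
                           force=force, spec_sampler=multi_occ, prefix="occ")
    return poor, occ
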