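"""Training loop, box decoding and evaluation for the detection models.

The loss follows the substrate family: complete-IoU box loss +
binary-cross-entropy classification + distribution-focal regression,
with a centre-inside-box static assignment (the reference assigner is
task-aligned; the simplification is documented and is sufficient for the
desk-scale fixtures this package trains on).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .. import nn
from ..nn.tensor import (Tensor, atan, bce_with_logits, concatenate, maximum,
                         minimum, softmax)
from ..scaffold.blocks import make_anchors
from ..scaffold.model import DetectionModel
from .data import AugmentParams, Sample, augment_batch, load_dataset
from .metrics import Detection, DetectionMetrics, iou_matrix, map_metrics

__all__ = ["TrainConfig", "TrainHistory", "train", "evaluate", "predict",
           "decode_predictions", "nms", "detection_loss", "SGD"]

AUGMENTATIONS = ("translation", "scaling", "flipping", "Mosaic", "Mixup")


@dataclass(frozen=True)
class TrainConfig:
    optimizer: str = "SGD"
    learning_rate: float = 0.01
    momentum: float = 0.937
    weight_decay: float = 0.0005
    batch_size: int = 32
    epochs: int = 400
    image_size: int = 640
    patience: int = 50
    augment: bool = True
    augmentations: tuple[str, ...] = AUGMENTATIONS
    conf_thr: float = 0.25
    iou_nms: float = 0.7
    box_weight: float = 7.5
    cls_weight: float = 0.5
    dfl_weight: float = 1.5
    seed: int = 0

    def __post_init__(self):
        if self.optimizer != "SGD":
            raise ValueError("only SGD is supported")
        for name in ("learning_rate", "momentum", "weight_decay", "batch_size",
                     "epochs", "image_size", "patience"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class TrainHistory:
    epochs: list[dict] = field(default_factory=list)
    stopped_early: bool = False
    best_epoch: int = -1
    best_map50: float = -1.0  # below any real score: first eval sets the bar

    def log(self, **kwargs) -> None:
        self.epochs.append(kwargs)


# ------------------------------------------------------------------- decoding

def _flatten_levels(outputs: list[Tensor], reg_max: int):
    """list of (B, C, H, W) -> (B, 4*reg_max, A), (B, nc, A), level shapes."""
    shapes = [tuple(o.shape[-2:]) for o in outputs]
    flat = concatenate([o.reshape(o.shape[0], o.shape[1], -1) for o in outputs],
                       axis=2)
    return flat[:, :4 * reg_max], flat[:, 4 * reg_max:], shapes


def _dfl_decode_np(box_logits: np.ndarray, reg_max: int) -> np.ndarray:
    b, _, a = box_logits.shape
    logits = box_logits.reshape(b, 4, reg_max, a)
    logits = logits - logits.max(axis=2, keepdims=True)
    e = np.exp(logits)
    probs = e / e.sum(axis=2, keepdims=True)
    return (probs * np.arange(reg_max).reshape(1, 1, reg_max, 1)).sum(axis=2)


def nms(boxes: np.ndarray, scores: np.ndarray, iou_thr: float = 0.7) -> np.ndarray:
    """Greedy non-maximum suppression; returns kept indices."""
    order = np.argsort(-scores, kind="stable")
    keep = []
    while order.size:
        i = order[0]
        keep.append(i)
        if order.size == 1:
            break
        rest = order[1:]
        ious = iou_matrix(boxes[i][None], boxes[rest])[0]
        order = rest[ious < iou_thr]
    return np.asarray(keep, dtype=int)


def decode_predictions(outputs: list[Tensor], reg_max: int, strides,
                       conf_thr: float = 0.25, iou_nms: float = 0.7,
                       ) -> list[list[Detection]]:
    """Raw level maps -> per-image NMS-filtered detections (pixel xyxy)."""
    box_t, cls_t, shapes = _flatten_levels(outputs, reg_max)
    box, cls = box_t.data, cls_t.data
    points, stride_arr = make_anchors(shapes, strides)
    ltrb = _dfl_decode_np(box, reg_max) * stride_arr[None, None]
    x1y1 = points.T[None] - ltrb[:, :2]
    x2y2 = points.T[None] + ltrb[:, 2:]
    xyxy = np.concatenate([x1y1, x2y2], axis=1)  # (B, 4, A)
    conf = 1.0 / (1.0 + np.exp(-np.clip(cls.max(axis=1), -60, 60)))
    results = []
    for bi in range(xyxy.shape[0]):
        mask = conf[bi] >= conf_thr
        boxes_i = xyxy[bi].T[mask]
        scores_i = conf[bi][mask]
        valid = (boxes_i[:, 2] > boxes_i[:, 0]) & (boxes_i[:, 3] > boxes_i[:, 1])
        boxes_i, scores_i = boxes_i[valid], scores_i[valid]
        keep = nms(boxes_i, scores_i, iou_nms) if len(boxes_i) else []
        results.append([Detection(tuple(boxes_i[k]), float(scores_i[k]))
                        for k in keep])
    return results


# ----------------------------------------------------------------------- loss

def _assign(points: np.ndarray, stride_arr: np.ndarray, gt: np.ndarray,
            reg_max: int) -> tuple[np.ndarray, np.ndarray]:
    """Centre-inside-box assignment: anchor -> smallest containing gt.

    Returns (pos_idx, gt_idx).  An anchor is a candidate for a box when its
    point lies inside and the box is representable at the anchor's stride
    (every side distance < reg_max cells).
    """
    if not len(gt):
        return np.zeros(0, dtype=int), np.zeros(0, dtype=int)
    px, py = points[:, 0][:, None], points[:, 1][:, None]
    l = px - gt[None, :, 0]
    t = py - gt[None, :, 1]
    r = gt[None, :, 2] - px
    b = gt[None, :, 3] - py
    ltrb = np.stack([l, t, r, b], axis=-1)
    inside = ltrb.min(axis=-1) > 0
    fits = (ltrb.max(axis=-1) / stride_arr[:, None]) < (reg_max - 1)
    cand = inside & fits
    areas = (gt[:, 2] - gt[:, 0]) * (gt[:, 3] - gt[:, 1])
    cost = np.where(cand, areas[None, :], np.inf)
    gt_idx = cost.argmin(axis=1)
    pos = cost.min(axis=1) < np.inf
    return np.nonzero(pos)[0], gt_idx[pos]


def _ciou(pred: Tensor, target: np.ndarray) -> Tensor:
    """Complete IoU between (N,4) predicted boxes and constant targets."""
    t = np.asarray(target, dtype=np.float32)
    ix = maximum(minimum(pred[:, 2], t[:, 2]) - maximum(pred[:, 0], t[:, 0]), 0.0)
    iy = maximum(minimum(pred[:, 3], t[:, 3]) - maximum(pred[:, 1], t[:, 1]), 0.0)
    inter = ix * iy
    wp = pred[:, 2] - pred[:, 0]
    hp = pred[:, 3] - pred[:, 1]
    wt, ht = t[:, 2] - t[:, 0], t[:, 3] - t[:, 1]
    union = wp * hp + wt * ht - inter + 1e-7
    iou_v = inter / union
    # enclosing box diagonal and centre distance
    cw = maximum(pred[:, 2], t[:, 2]) - minimum(pred[:, 0], t[:, 0])
    ch = maximum(pred[:, 3], t[:, 3]) - minimum(pred[:, 1], t[:, 1])
    c2 = cw * cw + ch * ch + 1e-7
    dx = (pred[:, 0] + pred[:, 2] - t[:, 0] - t[:, 2]) * 0.5
    dy = (pred[:, 1] + pred[:, 3] - t[:, 1] - t[:, 3]) * 0.5
    rho2 = dx * dx + dy * dy
    v = (4.0 / math.pi ** 2) * (atan(wt / ht) - atan(wp / (hp + 1e-7))) ** 2
    alpha = (v / ((1.0 + 1e-7) - iou_v + v)).detach()
    return iou_v - rho2 / c2 - Tensor(alpha.data) * v


def detection_loss(outputs: list[Tensor], targets: list[np.ndarray],
                   reg_max: int, strides, cfg: TrainConfig):
    """Composite loss over a batch; returns (total, parts dict)."""
    box_t, cls_t, shapes = _flatten_levels(outputs, reg_max)
    points, stride_arr = make_anchors(shapes, strides)
    bsz = box_t.shape[0]
    total_pos = 0
    box_loss = Tensor(0.0)
    dfl_loss = Tensor(0.0)
    cls_targets = np.zeros(cls_t.shape, dtype=np.float32)
    for bi, gt in enumerate(targets):
        gt = np.asarray(gt, dtype=np.float32).reshape(-1, 4)
        pos, gti = _assign(points, stride_arr, gt, reg_max)
        if not len(pos):
            continue
        total_pos += len(pos)
        cls_targets[bi, 0, pos] = 1.0
        s = stride_arr[pos][:, None]
        p = points[pos]
        tgt = gt[gti]
        # dfl: distances in stride cells, split into adjacent bins
        d = np.stack([p[:, 0] - tgt[:, 0], p[:, 1] - tgt[:, 1],
                      tgt[:, 2] - p[:, 0], tgt[:, 3] - p[:, 1]], axis=1) / s
        d = d.clip(0, reg_max - 1 - 1e-3)
        lo = np.floor(d).astype(int)
        hi = lo + 1
        w_hi = (d - lo).astype(np.float32)
        w_lo = 1.0 - w_hi
        logits = box_t[bi].reshape(4, reg_max, -1)[:, :, pos]  # (4, bins, P)
        logits = logits.transpose(0, 2, 1)                      # (4, P, bins)
        logp = (softmax(logits, axis=2) + 1e-9).log()
        ar4 = np.arange(4)[:, None]
        arp = np.arange(len(pos))[None, :]
        nll = -(logp[ar4, arp, lo.T] * Tensor(w_lo.T)
                + logp[ar4, arp, hi.T] * Tensor(w_hi.T))
        dfl_loss = dfl_loss + nll.mean() * len(pos)
        # box: decode expectation -> pixel boxes -> CIoU
        probs = softmax(logits, axis=2)
        exp_d = (probs * Tensor(np.arange(reg_max, dtype=np.float32))).sum(axis=2)
        exp_d = exp_d.transpose() * Tensor(s)                   # (P, 4) pixels
        px_, py_ = p[:, 0:1], p[:, 1:2]
        pred_box = concatenate([Tensor(px_) - exp_d[:, 0:1],
                                Tensor(py_) - exp_d[:, 1:2],
                                Tensor(px_) + exp_d[:, 2:3],
                                Tensor(py_) + exp_d[:, 3:4]], axis=1)
        box_loss = box_loss + (1.0 - _ciou(pred_box, tgt)).sum()
    denom = max(total_pos, 1)
    cls_loss = bce_with_logits(cls_t, cls_targets).sum() / denom
    box_loss = box_loss / denom
    dfl_loss = dfl_loss / denom
    total = (cfg.box_weight * box_loss + cfg.cls_weight * cls_loss
             + cfg.dfl_weight * dfl_loss)
    parts = {"box": float(box_loss.data), "cls": float(cls_loss.data),
             "dfl": float(dfl_loss.data), "n_pos": total_pos}
    return total, parts


# ------------------------------------------------------------------ optimizer

class SGD:
    def __init__(self, params, lr: float, momentum: float = 0.0,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr, self.momentum, self.weight_decay = lr, momentum, weight_decay
        self.velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        for p, v in zip(self.params, self.velocity):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


# ----------------------------------------------------------------- train/eval

def _batch_tensor(samples: list[Sample]) -> Tensor:
    arr = np.stack([s.image.transpose(2, 0, 1) for s in samples])
    return Tensor(np.ascontiguousarray(arr, dtype=np.float32))


def recalibrate_bn(model: DetectionModel, samples: list[Sample]) -> None:
    """Overwrite BN running statistics with exact stats of one batch.

    Short training runs leave the EMA (momentum 0.03) far from the true
    activation statistics, which wrecks eval-mode inference; a single
    momentum-1 pass over (a slice of) the training data fixes that.
    """
    bns = [m for m in model.modules() if isinstance(m, nn.BatchNorm2d)]
    saved = [b.momentum for b in bns]
    for b in bns:
        b.momentum = 1.0
    model.train()
    with nn.no_grad():
        model(_batch_tensor(samples))
    for b, mo in zip(bns, saved):
        b.momentum = mo


def predict(model: DetectionModel, samples: list[Sample], cfg: TrainConfig,
            batch: int = 8) -> list[list[Detection]]:
    model.eval()
    out: list[list[Detection]] = []
    with nn.no_grad():
        for i in range(0, len(samples), batch):
            chunk = samples[i:i + batch]
            raw = model(_batch_tensor(chunk))
            out.extend(decode_predictions(raw, model.reg_max, model.strides,
                                          cfg.conf_thr, cfg.iou_nms))
    return out


def evaluate(model: DetectionModel, manifest: list[dict],
             cfg: TrainConfig | None = None, imgsz: int | None = None,
             ) -> DetectionMetrics:
    """Run inference over a manifest and score it (errors on missing labels)."""
    cfg = cfg or TrainConfig()
    if not manifest:
        raise ValueError("empty evaluation manifest")
    samples = load_dataset(manifest, imgsz)
    preds = predict(model, samples, cfg)
    return map_metrics(preds, [s.boxes for s in samples])


def evaluate_predictions(predictions: list[list[Detection]],
                         manifest: list[dict], imgsz: int | None = None,
                         ) -> DetectionMetrics:
    """Score saved predictions against a manifest (deterministic)."""
    samples = load_dataset(manifest, imgsz)
    return map_metrics(predictions, [s.boxes for s in samples])


def train(model: DetectionModel, train_manifest: list[dict],
          val_manifest: list[dict] | None = None,
          cfg: TrainConfig | None = None, eval_every: int = 1,
          verbose: bool = False):
    """SGD training with early stopping on validation mAP50.

    Returns (best state_dict, TrainHistory).  Fully seeded via cfg.seed.
    """
    cfg = cfg or TrainConfig()
    if not train_manifest:
        raise ValueError("empty training manifest")
    rng = np.random.default_rng(cfg.seed)
    dataset = load_dataset(train_manifest, cfg.image_size)
    val = val_manifest if val_manifest is not None else train_manifest
    opt = SGD(model.parameters(), cfg.learning_rate, cfg.momentum,
              cfg.weight_decay)
    history = TrainHistory()
    best_state = model.state_dict()
    bad_epochs = 0
    aug = AugmentParams() if cfg.augment else None
    for epoch in range(cfg.epochs):
        model.train()
        order = rng.permutation(len(dataset))
        parts_sum = {"box": 0.0, "cls": 0.0, "dfl": 0.0}
        n_batches = 0
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            batch = (augment_batch(dataset, idx, rng, aug) if aug
                     else [dataset[j] for j in idx])
            raw = model(_batch_tensor(batch))
            loss, parts = detection_loss(raw, [s.boxes for s in batch],
                                         model.reg_max, model.strides, cfg)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}: {parts}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            for k in parts_sum:
                parts_sum[k] += parts[k]
            n_batches += 1
        record = {k: v / n_batches for k, v in parts_sum.items()}
        record["epoch"] = epoch
        if epoch % eval_every == 0 or epoch == cfg.epochs - 1:
            recalibrate_bn(model, dataset[:max(cfg.batch_size, 2)])
            metrics = evaluate(model, val, cfg, cfg.image_size)
            record.update(metrics.as_dict())
            if metrics.mAP50 > history.best_map50:
                history.best_map50 = metrics.mAP50
                history.best_epoch = epoch
                best_state = model.state_dict()
                bad_epochs = 0
            else:
                bad_epochs += eval_every
        history.log(**record)
        if verbose:
            print({k: round(v, 3) if isinstance(v, float) else v
                   for k, v in record.items()})
        if bad_epochs >= cfg.patience:
            history.stopped_early = True
            break
    return best_state, history
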