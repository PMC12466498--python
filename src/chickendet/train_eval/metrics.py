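"""Detection metrics: IoU matching, P/R/F1, AP and mAP, plus the
radar-chart normalization and polygon-area comparison.

All headline quantities are reported on the percentage scale.  AP uses
101-point interpolation by default (switchable to all-point).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["MatchCounts", "DetectionMetrics", "Detection", "iou",
           "match_detections", "precision_recall", "f1_score",
           "average_precision", "map_metrics", "normalize_metric",
           "radar_polygon_area", "IOU_THRESHOLDS_50_95"]

IOU_THRESHOLDS_50_95 = tuple(np.round(np.arange(0.50, 0.96, 0.05), 2))


@dataclass(frozen=True)
class Detection:
    """A scored predicted box, absolute xyxy pixels."""

    box: tuple[float, float, float, float]
    score: float
    class_id: int = 0


@dataclass(frozen=True)
class MatchCounts:
    TP: int
    FP: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.FP, self.FN) < 0:
            raise ValueError("match counts must be non-negative")


@dataclass
class DetectionMetrics:
    P: float
    R: float
    F1: float
    mAP50: float
    mAP50_95: float
    per_threshold_ap: dict[float, float] = field(default_factory=dict)
    N: int = 1  # classes averaged in the mean AP

    def as_dict(self) -> dict[str, float]:
        return {"P": self.P, "R": self.R, "F1": self.F1,
                "mAP50": self.mAP50, "mAP50_95": self.mAP50_95}


def _validate_box(box) -> np.ndarray:
    b = np.asarray(box, dtype=np.float64)
    if b.shape != (4,) or b[2] <= b[0] or b[3] <= b[1]:
        raise ValueError(f"degenerate box {box!r}: need x2>x1, y2>y1")
    return b


def iou(box_a, box_b) -> float:
    """Intersection-over-union of two xyxy boxes, in [0, 1]."""
    a, b = _validate_box(box_a), _validate_box(box_b)
    ix = max(0.0, min(a[2], b[2]) - max(a[0], b[0]))
    iy = max(0.0, min(a[3], b[3]) - max(a[1], b[1]))
    inter = ix * iy
    union = ((a[2] - a[0]) * (a[3] - a[1]) + (b[2] - b[0]) * (b[3] - b[1]) - inter)
    return float(inter / union) if union > 0 else 0.0


def iou_matrix(boxes_a: np.ndarray, boxes_b: np.ndarray) -> np.ndarray:
    """Pairwise IoU, (Na, Nb)."""
    a = np.asarray(boxes_a, dtype=np.float64).reshape(-1, 4)
    b = np.asarray(boxes_b, dtype=np.float64).reshape(-1, 4)
    ix = (np.minimum(a[:, None, 2], b[None, :, 2])
          - np.maximum(a[:, None, 0], b[None, :, 0])).clip(min=0)
    iy = (np.minimum(a[:, None, 3], b[None, :, 3])
          - np.maximum(a[:, None, 1], b[None, :, 1])).clip(min=0)
    inter = ix * iy
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    union = area_a[:, None] + area_b[None, :] - inter
    return np.where(union > 0, inter / union, 0.0)


def _match_flags(preds: list[Detection], gt_boxes, iou_thr: float) -> np.ndarray:
    """Greedy one-to-one matching in descending confidence.

    Returns TP flags aligned with the *original* prediction order.
    """
    order = np.argsort([-p.score for p in preds], kind="stable")
    gt = np.asarray(gt_boxes, dtype=np.float64).reshape(-1, 4)
    taken = np.zeros(len(gt), dtype=bool)
    flags = np.zeros(len(preds), dtype=bool)
    if len(gt) and len(preds):
        mat = iou_matrix([preds[i].box for i in order], gt)
        for r, row in enumerate(mat):
            row = np.where(taken, -1.0, row)
            j = int(np.argmax(row))
            if row[j] >= iou_thr:
                taken[j] = True
                flags[order[r]] = True
    return flags


def match_detections(preds: list[Detection], gt_boxes, iou_thr: float = 0.5) -> MatchCounts:
    flags = _match_flags(preds, gt_boxes, iou_thr)
    tp = int(flags.sum())
    n_gt = len(np.asarray(gt_boxes, dtype=np.float64).reshape(-1, 4))
    return MatchCounts(TP=tp, FP=len(preds) - tp, FN=n_gt - tp)


def precision_recall(c: MatchCounts) -> tuple[float, float]:
    """(P, R) as percentages; 0 when undefined."""
    p = 100.0 * c.TP / (c.TP + c.FP) if c.TP + c.FP else 0.0
    r = 100.0 * c.TP / (c.TP + c.FN) if c.TP + c.FN else 0.0
    return p, r


def f1_score(p: float, r: float) -> float:
    """Harmonic mean on the percentage scale (callers round to 1 decimal)."""
    return 2.0 * p * r / (p + r) if p + r > 0 else 0.0


def average_precision(tp_flags: np.ndarray, gt_count: int,
                      method: str = "101point") -> float:
    """Area under the P-R curve for confidence-ranked TP/FP flags, in [0, 1].

    ``101point``: mean of max-precision-to-the-right sampled at recalls
    0, 0.01, ..., 1.  ``allpoint``: exact area under the interpolated
    staircase.
    """
    if gt_count <= 0:
        raise ValueError("AP undefined for gt_count == 0; exclude the class")
    tp_flags = np.asarray(tp_flags, dtype=bool)
    if tp_flags.size == 0 or not tp_flags.any():
        return 0.0
    tp = np.cumsum(tp_flags)
    fp = np.cumsum(~tp_flags)
    recall = tp / gt_count
    precision = tp / (tp + fp)
    # envelope: best precision at any recall >= r
    env = np.maximum.accumulate(precision[::-1])[::-1]
    if method == "101point":
        samples = np.linspace(0.0, 1.0, 101)
        idx = np.searchsorted(recall, samples, side="left")
        vals = np.where(idx < len(env), env[np.minimum(idx, len(env) - 1)], 0.0)
        return float(vals.mean())
    if method == "allpoint":
        r_prev = np.concatenate([[0.0], recall])
        return float(np.sum((recall - r_prev[:-1]) * env))
    raise ValueError(f"unknown AP method {method!r}")


def map_metrics(predictions: list[list[Detection]], gt_boxes: list,
                thresholds=IOU_THRESHOLDS_50_95, method: str = "101point",
                ) -> DetectionMetrics:
    """Dataset-level metrics for a single class.

    ``predictions[i]`` / ``gt_boxes[i]`` belong to image i.  P/R/F1 are
    reported at the confidence cutoff that maximizes F1 at IoU 0.5.
    """
    if len(predictions) != len(gt_boxes):
        raise ValueError("predictions and ground truth differ in length")
    gt_count = sum(len(np.asarray(g, dtype=np.float64).reshape(-1, 4))
                   for g in gt_boxes)
    if gt_count == 0:
        raise ValueError("no ground-truth boxes in the evaluation set")

    per_thr: dict[float, float] = {}
    flat_scores = np.array([p.score for preds in predictions for p in preds])
    order = np.argsort(-flat_scores, kind="stable")
    for thr in thresholds:
        if flat_scores.size:
            flags_all = np.concatenate(
                [_match_flags(preds, gts, thr)
                 for preds, gts in zip(predictions, gt_boxes)])[order]
        else:
            flags_all = np.zeros(0, dtype=bool)
        per_thr[float(thr)] = average_precision(flags_all, gt_count, method)

    # P/R at the max-F1 cutoff of the IoU-0.5 ranked curve
    if flat_scores.size:
        flags50 = np.concatenate(
            [_match_flags(preds, gts, 0.5) for preds, gts in zip(predictions, gt_boxes)]
        )[order]
        tp = np.cumsum(flags50)
        fp = np.cumsum(~flags50)
        prec = 100.0 * tp / (tp + fp)
        rec = 100.0 * tp / gt_count
        with np.errstate(invalid="ignore"):
            f1s = np.where(prec + rec > 0, 2 * prec * rec / (prec + rec), 0.0)
        best = int(np.argmax(f1s))
        p, r, f1 = float(prec[best]), float(rec[best]), float(f1s[best])
    else:
        p = r = f1 = 0.0

    ap50 = per_thr[0.5]
    ap_mean = float(np.mean(list(per_thr.values())))
    return DetectionMetrics(P=p, R=r, F1=f1, mAP50=100.0 * ap50,
                            mAP50_95=100.0 * ap_mean, per_threshold_ap=per_thr)


def normalize_metric(values, direction: str = "positive") -> np.ndarray:
    """Radar-chart normalization to [0, 1]; larger is better afterwards.

    positive: (v - min) / (max - min).
    negative: log10 first, then reversed linear normalization.
    All-equal inputs map to all-ones (every model is equally best).
    """
    v = np.asarray(values, dtype=np.float64)
    if v.size < 2:
        raise ValueError("need at least two values to normalize")
    if direction == "negative":
        if (v <= 0).any():
            raise ValueError("negative-direction values must be positive")
        u = np.log10(v)
        lo, hi = u.min(), u.max()
        return np.ones_like(u) if hi == lo else (hi - u) / (hi - lo)
    if direction != "positive":
        raise ValueError("direction must be 'positive' or 'negative'")
    lo, hi = v.min(), v.max()
    return np.ones_like(v) if hi == lo else (v - lo) / (hi - lo)


def radar_polygon_area(values, k: int | None = None) -> float:
    """Area of the radar polygon with vertices at radius v_i on k axes."""
    v = np.asarray(values, dtype=np.float64)
    k = k or v.size
    if k < 3 or v.size != k:
        raise ValueError("radar polygon needs k >= 3 values")
    if (v < 0).any() or (v > 1).any():
        raise ValueError("normalized values must lie in [0, 1]")
    return float(0.5 * np.sin(2 * np.pi / k) * np.sum(v * np.roll(v, -1)))
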