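"""Metric stack: IoU, matching, P/R/F1, AP/mAP, normalization, radar area.

The mAP cross-check uses a second, independently coded brute-force
evaluator implemented inside this file.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chickendet.train_eval.metrics import (IOU_THRESHOLDS_50_95, Detection,
                                           MatchCounts, average_precision,
                                           f1_score, iou, map_metrics,
                                           match_detections, normalize_metric,
                                           precision_recall,
                                           radar_polygon_area)


class TestIoU:
    def test_identical(self):
        assert iou([0, 0, 2, 2], [0, 0, 2, 2]) == 1.0

    def test_disjoint(self):
        assert iou([0, 0, 1, 1], [5, 5, 6, 6]) == 0.0

    def test_third_overlap_oracle(self):
        assert iou([0, 0, 2, 2], [1, 0, 3, 2]) == pytest.approx(1 / 3)

    def test_rejects_degenerate(self):
        with pytest.raises(ValueError):
            iou([0, 0, 0, 2], [0, 0, 1, 1])


class TestMatching:
    def test_single_tp(self):
        preds = [Detection((0, 0, 10, 10), 0.9)]
        c = match_detections(preds, [[0, 0, 10, 14]], 0.5)  # IoU ~ 0.71
        assert (c.TP, c.FP, c.FN) == (1, 0, 0)

    def test_low_iou_is_fp_and_fn(self):
        preds = [Detection((0, 0, 10, 10), 0.9)]
        c = match_detections(preds, [[8, 8, 20, 20]], 0.5)
        assert (c.TP, c.FP, c.FN) == (0, 1, 1)

    def test_two_preds_one_gt(self):
        """Exhaustive small-case oracle: the higher-confidence prediction
        takes the ground truth; the other becomes a false positive."""
        gt = [[0, 0, 10, 10]]
        for conf_hi_first in (True, False):
            scores = (0.9, 0.5) if conf_hi_first else (0.5, 0.9)
            preds = [Detection((0, 0, 10, 10), scores[0]),
                     Detection((0, 0, 10, 11), scores[1])]
            c = match_detections(preds, gt, 0.5)
            assert (c.TP, c.FP, c.FN) == (1, 1, 0)

    def test_counts_validation(self):
        with pytest.raises(ValueError):
            MatchCounts(-1, 0, 0)


class TestPrecisionRecall:
    @pytest.mark.parametrize("tp,fp,fn,expected", [
        (1, 0, 0, (100.0, 100.0)),
        (0, 5, 5, (0.0, 0.0)),
        (3, 1, 2, (75.0, 60.0)),
    ])
    def test_cases(self, tp, fp, fn, expected):
        assert precision_recall(MatchCounts(tp, fp, fn)) == expected


class TestF1:
    def test_baseline_row(self):
        assert round(f1_score(89.3, 81.8), 1) == 85.4

    def test_full_model_row(self):
        assert round(f1_score(89.6, 82.8), 1) == 86.1

    @settings(max_examples=30, deadline=None)
    @given(x=st.floats(0.1, 100))
    def test_fixed_point(self, x):
        assert f1_score(x, x) == pytest.approx(x)

    def test_zero_denominator(self):
        assert f1_score(0.0, 0.0) == 0.0


class TestAveragePrecision:
    def test_perfect_ranking(self):
        assert average_precision(np.array([1, 1, 1], bool), 3) == 1.0

    def test_no_tp(self):
        assert average_precision(np.array([0, 0], bool), 2) == 0.0

    def test_staircase_oracle(self):
        """1 TP then 1 FP with 2 gts, built by hand: precision 1.0 at recall
        0.5, then 0 beyond.  101-point mean = 51/101; all-point area = 0.5."""
        flags = np.array([1, 0], bool)
        assert average_precision(flags, 2, "101point") == pytest.approx(51 / 101)
        assert average_precision(flags, 2, "allpoint") == pytest.approx(0.5)

    def test_undefined_for_no_gt(self):
        with pytest.raises(ValueError):
            average_precision(np.array([1], bool), 0)


def brute_force_map(predictions, gts, thr):
    """Independent reference evaluator: explicit sort, loop matching, and
    trapezoid area under the interpolated precision envelope."""
    scored = []
    for img, (preds, gt) in enumerate(zip(predictions, gts)):
        for p in preds:
            scored.append((p.score, img, p.box))
    scored.sort(key=lambda t: -t[0])
    used = [set() for _ in gts]
    flags = []
    for score, img, box in scored:
        gt = np.asarray(gts[img], dtype=float).reshape(-1, 4)
        best_j, best_iou = -1, thr
        for j in range(len(gt)):
            if j in used[img]:
                continue
            i = iou(box, gt[j])
            if i >= best_iou:
                best_iou, best_j = i, j
        if best_j >= 0:
            used[img].add(best_j)
            flags.append(1)
        else:
            flags.append(0)
    n_gt = sum(len(np.asarray(g, dtype=float).reshape(-1, 4)) for g in gts)
    if not flags or not any(flags):
        return 0.0
    tp = np.cumsum(flags)
    prec = tp / np.arange(1, len(flags) + 1)
    rec = tp / n_gt
    env = np.maximum.accumulate(prec[::-1])[::-1]
    area, prev_r = 0.0, 0.0
    for r, p in zip(rec, env):
        area += (r - prev_r) * p
        prev_r = r
    return area


def random_instance(rng, n_img=3, max_boxes=6):
    gts, preds = [], []
    for _ in range(n_img):
        n_gt = rng.integers(0, max_boxes)
        boxes = []
        for _ in range(n_gt):
            x, y = rng.uniform(0, 80, 2)
            w, h = rng.uniform(5, 20, 2)
            boxes.append([x, y, x + w, y + h])
        gts.append(np.array(boxes).reshape(-1, 4))
        n_pred = rng.integers(0, max_boxes)
        p = []
        for _ in range(n_pred):
            if len(boxes) and rng.random() < 0.7:
                bx = np.array(boxes[rng.integers(len(boxes))])
                bx = bx + rng.normal(0, 3, 4)
                bx[2] = max(bx[2], bx[0] + 1)
                bx[3] = max(bx[3], bx[1] + 1)
            else:
                x, y = rng.uniform(0, 80, 2)
                bx = np.array([x, y, x + rng.uniform(4, 20),
                               y + rng.uniform(4, 20)])
            p.append(Detection(tuple(bx), float(rng.random())))
        preds.append(p)
    return preds, gts


class TestMapMetrics:
    def test_perfect_predictions(self):
        gts = [np.array([[0, 0, 10, 10], [20, 20, 40, 40]])]
        preds = [[Detection((0, 0, 10, 10), 0.9),
                  Detection((20, 20, 40, 40), 0.8)]]
        m = map_metrics(preds, gts)
        assert m.mAP50 == 100.0 and m.mAP50_95 == 100.0
        assert m.P == 100.0 and m.R == 100.0

    def test_no_predictions(self):
        m = map_metrics([[]], [np.array([[0, 0, 10, 10]])])
        assert m.R == 0.0 and m.mAP50 == 0.0

    def test_ten_thresholds(self):
        assert len(IOU_THRESHOLDS_50_95) == 10
        assert IOU_THRESHOLDS_50_95[0] == 0.5 and IOU_THRESHOLDS_50_95[-1] == 0.95

    def test_jittered_boxes_strict_ordering(self, rng):
        gts = [np.array([[10, 10, 40, 40], [50, 50, 90, 80]])]
        preds = [[Detection((12, 11, 41, 43), 0.9),
                  Detection((53, 48, 88, 83), 0.8)]]
        m = map_metrics(preds, gts)
        assert m.mAP50_95 < m.mAP50

    def test_monotone_in_iou_threshold(self, rng):
        preds, gts = random_instance(rng)
        m = map_metrics(preds, gts) if any(len(g) for g in gts) else None
        if m is None:
            return
        aps = [m.per_threshold_ap[t] for t in sorted(m.per_threshold_ap)]
        assert all(a >= b - 1e-12 for a, b in zip(aps, aps[1:]))

    @pytest.mark.parametrize("seed", range(8))
    def test_agrees_with_independent_evaluator(self, seed):
        rng = np.random.default_rng(seed)
        preds, gts = random_instance(rng)
        if not any(len(g) for g in gts):
            return
        ours = map_metrics(preds, gts, thresholds=(0.5,), method="allpoint")
        ref = brute_force_map(preds, gts, 0.5)
        assert ours.mAP50 / 100.0 == pytest.approx(ref, abs=1e-9)
        ours101 = map_metrics(preds, gts, thresholds=(0.5,))
        assert abs(ours101.mAP50 / 100.0 - ref) < 0.02


class TestNormalization:
    def test_positive_max_is_one(self):
        out = normalize_metric([1.0, 3.0, 2.0], "positive")
        assert out[1] == 1.0 and out[0] == 0.0

    def test_negative_min_is_one(self):
        out = normalize_metric([2.0, 8.0, 4.0], "negative")
        assert out[0] == 1.0 and out[1] == 0.0

    def test_gflops_log_oracle(self):
        # (log10 21.3 - log10 9.0) / (log10 21.3 - log10 6.3) = 0.7072
        out = normalize_metric([6.3, 9.0, 21.3], "negative")
        assert out[1] == pytest.approx(0.70719, abs=1e-4)

    def test_all_equal_maps_to_ones(self):
        assert (normalize_metric([5.0, 5.0, 5.0], "negative") == 1.0).all()

    def test_rejects_nonpositive_negative_direction(self):
        with pytest.raises(ValueError):
            normalize_metric([0.0, 1.0], "negative")


class TestRadarArea:
    def test_zero_polygon(self):
        assert radar_polygon_area([0, 0, 0, 0, 0]) == 0.0

    def test_regular_pentagon_oracle(self):
        # (5/2) * sin(72 deg) = 2.37764
        assert radar_polygon_area([1] * 5) == pytest.approx(2.37764, abs=1e-4)

    def test_homogeneity(self, rng):
        v = rng.random(6)
        a1 = radar_polygon_area(v)
        a2 = radar_polygon_area(0.5 * v)
        assert a2 == pytest.approx(0.25 * a1)

    def test_rejects_small_k(self):
        with pytest.raises(ValueError):
            radar_polygon_area([0.5, 0.5])
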