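"""Training loop, decoding and evaluation."""

import numpy as np
import pytest

from chickendet.assembly import build_variant
from chickendet.nn.tensor import Tensor
from chickendet.train_eval import (AugmentParams, TrainConfig, augment_batch,
                                   evaluate, evaluate_predictions, load_dataset,
                                   nms, train)
from chickendet.train_eval.data import Sample
from chickendet.train_eval.metrics import Detection
from chickendet.train_eval.train import (_assign, decode_predictions,
                                         detection_loss, _batch_tensor)
from chickendet.scaffold.blocks import make_anchors


class TestTrainConfig:
    def test_defaults_lock_reference_hyperparameters(self):
        cfg = TrainConfig()
        assert cfg.optimizer == "SGD"
        assert cfg.learning_rate == 0.01
        assert cfg.momentum == 0.937
        assert cfg.weight_decay == 0.0005
        assert cfg.batch_size == 32
        assert cfg.epochs == 400
        assert cfg.image_size == 640
        assert cfg.patience == 50

    def test_augmentation_list(self):
        assert set(TrainConfig().augmentations) == {
            "translation", "scaling", "flipping", "Mosaic", "Mixup"}

    def test_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(optimizer="Adam")
        with pytest.raises(ValueError):
            TrainConfig(learning_rate=0)


class TestAssigner:
    def test_anchor_inside_box_is_positive(self):
        points, strides = make_anchors([(8, 8)], [8])
        gt = np.array([[8.0, 8.0, 40.0, 40.0]])
        pos, gti = _assign(points, strides, gt, 16)
        assert len(pos) == 16  # 4x4 cells strictly inside
        assert (gti == 0).all()

    def test_no_gt_no_positives(self):
        points, strides = make_anchors([(4, 4)], [8])
        pos, gti = _assign(points, strides, np.zeros((0, 4)), 16)
        assert len(pos) == 0


class TestDecode:
    def test_dfl_peak_decodes_to_bin(self):
        """Logits peaked at bin k decode to a box k*stride around the anchor."""
        reg_max, nc, h = 16, 1, 4
        raw = np.zeros((1, 4 * reg_max + nc, h, h), dtype=np.float32)
        k = 3
        for side in range(4):
            raw[0, side * reg_max + k] = 40.0  # hard peak
        raw[0, 4 * reg_max] = 10.0  # confident class
        dets = decode_predictions([Tensor(raw)], reg_max, [8], conf_thr=0.5,
                                  iou_nms=1.1)
        assert len(dets[0]) == h * h
        x1, y1, x2, y2 = dets[0][0].box
        assert x2 - x1 == pytest.approx(2 * k * 8, abs=1e-3)
        cx, cy = (x1 + x2) / 2, (y1 + y2) / 2
        assert (cx, cy) == (pytest.approx(4.0), pytest.approx(4.0))

    def test_nms_suppresses_duplicates(self):
        boxes = np.array([[0, 0, 10, 10], [1, 0, 11, 10], [30, 30, 40, 40]],
                         dtype=float)
        keep = nms(boxes, np.array([0.9, 0.8, 0.7]), iou_thr=0.5)
        assert list(keep) == [0, 2]


@pytest.fixture()
def loss_fixture(tiny_dataset):
    model = build_variant("baseline", width_multiple=0.0625, seed=3)
    samples = load_dataset(tiny_dataset[:2], imgsz=96)
    return model, samples


class TestLoss:
    def test_loss_parts_finite_and_positive(self, loss_fixture):
        model, samples = loss_fixture
        raw = model(_batch_tensor(samples))
        loss, parts = detection_loss(raw, [s.boxes for s in samples],
                                     model.reg_max, model.strides, TrainConfig())
        assert np.isfinite(loss.data)
        assert parts["n_pos"] > 0
        assert parts["box"] > 0 and parts["cls"] > 0 and parts["dfl"] > 0

    def test_loss_decreases_under_training(self, tiny_dataset):
        model = build_variant("baseline", width_multiple=0.0625, seed=3)
        cfg = TrainConfig(epochs=8, batch_size=2, image_size=96,
                          augment=False, patience=100, seed=0)
        _, hist = train(model, tiny_dataset[:2], cfg=cfg, eval_every=100)
        first, last = hist.epochs[0], hist.epochs[-1]
        assert last["cls"] < first["cls"]
        assert last["dfl"] <= first["dfl"] * 1.05

    def test_nan_weights_abort_with_diagnostics(self, tiny_dataset):
        model = build_variant("baseline", width_multiple=0.0625, seed=3)
        model.layers[0].conv.weight.data[:] = np.nan
        cfg = TrainConfig(epochs=1, batch_size=2, image_size=96, augment=False)
        with pytest.raises(RuntimeError, match="non-finite"):
            train(model, tiny_dataset[:2], cfg=cfg)

    def test_empty_manifest_rejected(self):
        model = build_variant("baseline", width_multiple=0.0625, seed=3)
        with pytest.raises(ValueError, match="empty"):
            train(model, [], cfg=TrainConfig(epochs=1))


class TestEarlyStopping:
    def test_stops_after_patience_without_improvement(self, tiny_dataset):
        # lr ~ 0 freezes the model, so validation mAP never improves
        model = build_variant("baseline", width_multiple=0.0625, seed=3)
        cfg = TrainConfig(epochs=30, batch_size=2, image_size=96,
                          learning_rate=1e-12, augment=False, patience=5, seed=0)
        _, hist = train(model, tiny_dataset[:2], cfg=cfg)
        assert hist.stopped_early
        assert len(hist.epochs) <= 8


class TestEvaluate:
    def test_ground_truth_predictions_score_100(self, tiny_dataset):
        samples = load_dataset(tiny_dataset, imgsz=96)
        preds = [[Detection(tuple(b), 0.99) for b in s.boxes] for s in samples]
        m = evaluate_predictions(preds, tiny_dataset, imgsz=96)
        assert m.mAP50 == 100.0 and m.mAP50_95 == 100.0
        assert m.P == 100.0 and m.R == 100.0

    def test_no_predictions_zero_recall(self, tiny_dataset):
        preds = [[] for _ in tiny_dataset]
        m = evaluate_predictions(preds, tiny_dataset, imgsz=96)
        assert m.R == 0.0 and m.mAP50 == 0.0

    def test_untrained_model_runs(self, tiny_dataset):
        model = build_variant("baseline", width_multiple=0.0625, seed=3)
        m = evaluate(model, tiny_dataset[:2], imgsz=96)
        assert 0.0 <= m.mAP50 <= 100.0

    def test_missing_labels_listed(self, tiny_dataset, tmp_path):
        rows = [dict(tiny_dataset[0])]
        rows[0]["label"] = str(tmp_path / "nope.txt")
        model = build_variant("baseline", width_multiple=0.0625, seed=3)
        with pytest.raises(FileNotFoundError, match="nope.txt"):
            evaluate(model, rows, imgsz=96)


class TestAugmentation:
    def _samples(self, rng, n=6):
        return [Sample(rng.random((64, 64, 3)).astype(np.float32),
                       np.array([[10, 10, 30, 30], [40, 8, 60, 28]],
                                dtype=np.float32))
                for _ in range(n)]

    def test_boxes_stay_in_bounds(self, rng):
        ds = self._samples(rng)
        out = augment_batch(ds, range(len(ds)), np.random.default_rng(0))
        for s in out:
            assert s.image.shape == (64, 64, 3)
            if len(s.boxes):
                assert s.boxes[:, [0, 2]].min() >= 0
                assert s.boxes[:, [1, 3]].max() <= 64
                assert (s.boxes[:, 2] > s.boxes[:, 0]).all()

    def test_deterministic_under_seed(self, rng):
        ds = self._samples(rng)
        a = augment_batch(ds, [0, 1], np.random.default_rng(7))
        b = augment_batch(ds, [0, 1], np.random.default_rng(7))
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.image, sb.image)
            assert np.array_equal(sa.boxes, sb.boxes)

    def test_flip_only_reflects_boxes(self, rng):
        ds = self._samples(rng, 1)
        p = AugmentParams(translate=0.0, scale_range=(1.0, 1.0), flip_p=1.0,
                          mosaic_p=0.0, mixup_p=0.0)
        out = augment_batch(ds, [0], np.random.default_rng(0), p)[0]
        expected = ds[0].boxes.copy()
        expected[:, [0, 2]] = 64 - ds[0].boxes[:, [2, 0]]
        assert np.allclose(np.sort(out.boxes, axis=0),
                           np.sort(expected, axis=0), atol=1e-4)
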