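"""Tests of assembly plumbing: profiling, decoding, NMS, evaluation, I/O."""

import numpy as np
import pytest

from yolodcpg.autograd import no_grad
from yolodcpg.box_losses import iou
from yolodcpg.dcpg_attention import DCPGAttention
from yolodcpg.detector import (DetectionSet, build_model, count_flops,
                               count_params, decode_and_nms, evaluate,
                               evaluate_model, load_model, nms, save_model,
                               train_toy)
from yolodcpg.nn import Conv2d, count_macs
from yolodcpg.synthetic_pestboard import SceneConfig, generate_dataset
from conftest import rasterized_iou


class TestProfiling:
    def test_single_conv_param_closed_form(self):
        conv = Conv2d(3, 16, 3, bias=True)
        assert conv.weight.size + conv.bias.size == 3 * 3 * 3 * 16 + 16 == 448

    def test_single_conv_mac_closed_form(self):
        conv = Conv2d(3, 16, 3, stride=1, bias=True)
        with no_grad(), count_macs() as c:
            conv(np.zeros((1, 3, 64, 64), dtype=np.float32))
        assert 2 * c[0] == 2 * (3 * 3 * 3) * 16 * 64 * 64  # ~3.54 MFLOPs

    def test_attention_adds_exactly_4c_params(self):
        base = count_params(build_model("yolo-dcpg-noattn"))
        full = count_params(build_model("yolo-dcpg"))
        c5 = build_model("yolo-dcpg").backbone.out_channels["P5"]
        assert full - base == 4 * c5
        assert sum(p.size for p in DCPGAttention(c5).parameters()) == 4 * c5

    def test_head_level_must_exist(self):
        from yolodcpg.detector import ModelConfig
        with pytest.raises(ValueError):
            build_model(ModelConfig(backbone="yolov8n", neck="v8pan",
                                    head_levels=("P2", "P3")))

    def test_forward_shape_contract(self):
        model = build_model("toy", num_classes=3)
        model.eval()
        with no_grad():
            raws = model(np.zeros((1, 3, 160, 160), dtype=np.float32))
        assert len(raws) == 3
        for raw, stride in zip(raws, model.strides):
            assert raw.shape == (1, 4 * model.cfg.reg_max + 3, 160 // stride, 160 // stride)


def brute_force_nms(boxes, scores, thr):
    """Independent NMS oracle using the rasterisation IoU."""
    alive = list(range(len(scores)))
    keep = []
    while alive:
        best = max(alive, key=lambda i: scores[i])
        keep.append(best)
        alive = [i for i in alive
                 if i != best and rasterized_iou(boxes[best], boxes[i]) < thr]
    return keep


class TestNMS:
    def test_duplicate_suppressed(self):
        boxes = np.array([[5, 5, 2, 2], [5, 5, 2, 2.0]])
        keep = nms(boxes, np.array([0.9, 0.8]), 0.5)
        assert keep == [0]

    def test_five_box_scene_matches_brute_force(self):
        boxes = np.array([
            [10, 10, 6, 6], [12, 10, 6, 6], [30, 30, 4, 4],
            [31, 31, 4, 4], [50, 10, 5, 8.0]])
        scores = np.array([0.9, 0.85, 0.7, 0.95, 0.6])
        for thr in (0.3, 0.5, 0.7):
            assert sorted(nms(boxes, scores, thr)) == sorted(
                brute_force_nms(boxes, scores, thr))

    def test_empty_raw_predictions_decode_to_empty(self):
        assert decode_and_nms([], [8], num_classes=2) == []

    def test_low_confidence_maps_give_empty_sets(self):
        raw = np.full((1, 4 * 8 + 2, 4, 4), -10.0, dtype=np.float32)
        out = decode_and_nms([raw], [8], num_classes=2, reg_max=8)
        assert len(out) == 1 and out[0].boxes.shape == (0, 4)


def _dets(entries):
    if not entries:
        return DetectionSet.empty()
    boxes = np.array([e[2] for e in entries], dtype=float)
    return DetectionSet(boxes, np.array([e[1] for e in entries]),
                        np.array([e[0] for e in entries]))


class TestEvaluate:
    def test_perfect_detections_score_100(self):
        gts = [[(0, (10, 10, 4, 4)), (1, (30, 30, 6, 6))],
               [(0, (15, 15, 5, 5))]]
        dets = [_dets([(0, 1.0, (10, 10, 4, 4)), (1, 1.0, (30, 30, 6, 6))]),
                _dets([(0, 1.0, (15, 15, 5, 5))])]
        rep = evaluate(dets, gts, num_classes=2)
        assert rep.precision == rep.recall == 100.0
        assert rep.map50 == pytest.approx(100.0)
        assert rep.map50_95 == pytest.approx(100.0)

    def test_no_detections(self):
        gts = [[(0, (10, 10, 4, 4))]]
        rep = evaluate([DetectionSet.empty()], gts, num_classes=1)
        assert rep.precision == 0.0 and rep.recall == 0.0 and rep.map50 == 0.0

    def test_hand_enumerated_confusion_counts(self):
        """10 gts over 2 classes; detector finds 8 (one low-score), misses 2,
        and adds 1 false positive."""
        gts = [[(0, (10 * k, 10, 4, 4)) for k in range(1, 6)],
               [(1, (10 * k, 30, 4, 4)) for k in range(1, 6)]]
        dets = [
            _dets([(0, 0.9, (10 * k, 10, 4, 4)) for k in range(1, 5)]
                  + [(0, 0.8, (90, 90, 4, 4))]),          # 4 TP + 1 FP, 1 miss
            _dets([(1, 0.7, (10 * k, 30, 4, 4)) for k in range(1, 5)]),  # 4 TP, 1 miss
        ]
        rep = evaluate(dets, gts, num_classes=2, iou_thresholds=0.5)
        assert rep.precision == pytest.approx(100 * 8 / 9)
        assert rep.recall == pytest.approx(100 * 8 / 10)
        # AP class 0: 4 TPs then one FP at lower score -> precision 1.0 up to
        # recall 0.8; AP = 81/101. class 1: 4/5 recall at precision 1 -> 81/101.
        assert rep.map50 == pytest.approx(100 * 81 / 101, abs=1e-6)

    def test_class_without_gt_excluded_with_warning(self):
        gts = [[(0, (10, 10, 4, 4))]]
        dets = [_dets([(0, 1.0, (10, 10, 4, 4))])]
        with pytest.warns(UserWarning, match="no ground truths"):
            rep = evaluate(dets, gts, num_classes=3)
        assert rep.map50 == pytest.approx(100.0)

    def test_map_50_95_never_exceeds_map50(self, rng):
        for _ in range(5):
            gts, dets = [], []
            for _ in range(3):
                g = [(int(rng.integers(2)),
                      tuple(np.r_[rng.uniform(10, 90, 2), rng.uniform(4, 12, 2)]))
                     for _ in range(6)]
                d = [(int(rng.integers(2)), float(rng.uniform(0.1, 1)),
                      tuple(np.r_[rng.uniform(10, 90, 2), rng.uniform(4, 12, 2)]))
                     for _ in range(8)]
                gts.append(g)
                dets.append(_dets(d))
            rep = evaluate(dets, gts, num_classes=2)
            assert rep.map50_95 <= rep.map50 + 1e-9


def reference_evaluator(dets, gts, num_classes, thr):
    """Brute-force per-class matcher + direct 101-point AP, written
    independently of the library implementation."""
    aps = []
    prec_tp = prec_fp = 0
    for c in range(num_classes):
        n_gt = sum(1 for g in gts for cc, _ in g if cc == c)
        if n_gt == 0:
            continue
        records = []
        for d, g in zip(dets, gts):
            gt_boxes = [b for cc, b in g if cc == c]
            taken = [False] * len(gt_boxes)
            idx = [i for i in range(len(d.scores)) if d.labels[i] == c]
            for i in sorted(idx, key=lambda i: -d.scores[i]):
                ious = [iou(tuple(d.boxes[i]), gt_boxes[k]) if not taken[k] else -1
                        for k in range(len(gt_boxes))]
                k = int(np.argmax(ious)) if ious else -1
                if k >= 0 and ious[k] >= thr:
                    taken[k] = True
                    records.append((d.scores[i], 1))
                else:
                    records.append((d.scores[i], 0))
        records.sort(key=lambda r: -r[0])
        tps = np.cumsum([r[1] for r in records]) if records else np.array([])
        fps = np.cumsum([1 - r[1] for r in records]) if records else np.array([])
        prec_tp += int(tps[-1]) if len(tps) else 0
        prec_fp += int(fps[-1]) if len(fps) else 0
        ap = 0.0
        for r in np.linspace(0, 1, 101):
            ps = [tp / (tp + fp) for tp, fp in zip(tps, fps) if n_gt and tp / n_gt >= r]
            ap += max(ps) if ps else 0.0
        aps.append(ap / 101)
    return float(np.mean(aps)) * 100 if aps else 0.0


class TestEvaluatorAgainstBruteForce:
    def test_randomized_scenes_match(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            gts, dets = [], []
            for _ in range(2):
                g = [(int(rng.integers(3)),
                      tuple(np.r_[rng.uniform(10, 90, 2), rng.uniform(5, 15, 2)]))
                     for _ in range(10)]
                entries = []
                for cc, b in g:
                    if rng.uniform() < 0.8:  # jittered true positives
                        jb = tuple(np.r_[np.array(b[:2]) + rng.normal(0, 2, 2),
                                         np.array(b[2:]) * rng.uniform(0.8, 1.2, 2)])
                        entries.append((cc, float(rng.uniform(0.3, 1)), jb))
                for _ in range(rng.integers(0, 4)):  # false positives
                    entries.append((int(rng.integers(3)), float(rng.uniform(0.1, 1)),
                                    tuple(np.r_[rng.uniform(10, 90, 2),
                                                rng.uniform(5, 15, 2)])))
                gts.append(g)
                dets.append(_dets(entries))
            rep = evaluate(dets, gts, num_classes=3, iou_thresholds=0.5)
            expected = reference_evaluator(dets, gts, 3, 0.5)
            assert rep.map50 == pytest.approx(expected, abs=1e-6)


@pytest.fixture(scope="module")
def tiny_scenes():
    cfg = SceneConfig(image_size=96, num_classes=2, objects_per_image=3,
                      target_size_range=(0.08, 0.2), occlusion_rate=0.1,
                      class_frequencies=(0.7, 0.3))
    return generate_dataset(cfg, 8, seed=5)


class TestTrainingAndIO:
    def test_one_epoch_smoke_finite_loss(self, tiny_scenes):
        model = build_model("toy", num_classes=2, seed=0)
        log = train_toy(model, tiny_scenes, epochs=1, seed=0, batch_size=4)
        assert len(log["epoch_loss"]) == 1
        assert np.isfinite(log["epoch_loss"][0])

    def test_same_seed_identical_loss_curves(self, tiny_scenes):
        logs = []
        for _ in range(2):
            model = build_model("toy", num_classes=2, seed=3)
            logs.append(train_toy(model, tiny_scenes, epochs=2, seed=3, batch_size=4))
        assert logs[0]["epoch_loss"] == logs[1]["epoch_loss"]

    def test_save_load_forward_parity(self, tmp_path, rng):
        model = build_model("toy", num_classes=2, seed=1)
        model.eval()
        path = tmp_path / "model.npz"
        save_model(model, path)
        clone = load_model(path)
        x = rng.normal(0, 1, (1, 3, 96, 96)).astype(np.float32)
        with no_grad():
            a = model(x)
            b = clone(x)
        for u, v in zip(a, b):
            np.testing.assert_allclose(u.data, v.data, atol=1e-4)
        assert count_params(clone) == count_params(model)
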