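"""CIoU loss and evaluation stack against independent oracles."""

import math

import numpy as np
import pytest

from srnetyolo.boxes import BBox, Detection, iou
from srnetyolo.losses_metrics import (average_precision, ciou_loss,
                                      ciou_loss_tensor, evaluate,
                                      match_detections, precision_recall_f1)
from srnetyolo.nn import Tensor


def ciou_formula_oracle(pred, gt):
    """Direct textbook evaluation, coded independently of the library."""
    ax1, ay1, ax2, ay2 = pred.x, pred.y, pred.x + pred.w, pred.y + pred.h
    bx1, by1, bx2, by2 = gt.x, gt.y, gt.x + gt.w, gt.y + gt.h
    iw = max(min(ax2, bx2) - max(ax1, bx1), 0.0)
    ih = max(min(ay2, by2) - max(ay1, by1), 0.0)
    inter = iw * ih
    union = pred.w * pred.h + gt.w * gt.h - inter
    i = inter / union
    rho2 = ((ax1 + ax2) / 2 - (bx1 + bx2) / 2) ** 2 + ((ay1 + ay2) / 2 - (by1 + by2) / 2) ** 2
    c2 = (max(ax2, bx2) - min(ax1, bx1)) ** 2 + (max(ay2, by2) - min(ay1, by1)) ** 2
    v = 4 / math.pi**2 * (math.atan(gt.w / gt.h) - math.atan(pred.w / pred.h)) ** 2
    alpha = 0.0 if v == 0 else v / (1 - i + v)
    return 1 - i + rho2 / c2 + alpha * v


class TestCIoU:
    def test_identical_boxes_zero_loss(self):
        b = BBox(0, 3, 4, 10, 12)
        out = ciou_loss(b, b)
        assert out.iou == 1.0 and out.center_dist_sq == 0.0 and out.v == 0.0
        assert out.loss == 0.0

    def test_worked_example(self):
        out = ciou_loss(BBox(0, 0, 0, 2, 2), BBox(0, 0, 0, 2, 4))
        assert out.iou == pytest.approx(0.5)
        assert out.center_dist_sq == pytest.approx(1.0)  # centres (1,1) vs (1,2)
        assert out.encl_diag_sq == pytest.approx(4 + 16)
        v = 4 / math.pi**2 * (math.atan(0.5) - math.atan(1.0)) ** 2
        assert out.v == pytest.approx(v)
        assert out.loss == pytest.approx(ciou_formula_oracle(
            BBox(0, 0, 0, 2, 2), BBox(0, 0, 0, 2, 4)), abs=1e-12)

    def test_ten_random_pairs_match_formula(self, rng):
        for _ in range(10):
            p = BBox(0, *rng.uniform(0, 50, 2), *rng.uniform(2, 40, 2))
            g = BBox(0, *rng.uniform(0, 50, 2), *rng.uniform(2, 40, 2))
            assert ciou_loss(p, g).loss == pytest.approx(
                ciou_formula_oracle(p, g), abs=1e-10)

    def test_monotone_approach(self):
        """Loss never increases as a disjoint box slides toward the target."""
        gt = BBox(0, 100, 100, 20, 20)
        losses = [ciou_loss(BBox(0, 100 - 80 + 7 * step, 100, 20, 20), gt).loss
                  for step in range(10)]
        assert all(l2 <= l1 + 1e-12 for l1, l2 in zip(losses, losses[1:]))

    def test_invariants(self, rng):
        for _ in range(50):
            p = BBox(0, *rng.uniform(0, 50, 2), *rng.uniform(2, 40, 2))
            g = BBox(0, *rng.uniform(0, 50, 2), *rng.uniform(2, 40, 2))
            out = ciou_loss(p, g)
            assert 0.0 <= out.iou <= 1.0
            assert out.center_dist_sq <= out.encl_diag_sq
            assert out.v >= 0 and out.loss >= 0
            assert out.alpha < 1.0

    def test_nonpositive_extent_rejected(self):
        with pytest.raises(ValueError):
            BBox(0, 0, 0, 0, 5)

    def test_tensor_version_matches_scalar(self, rng):
        pairs = [(BBox(0, *rng.uniform(0, 50, 2), *rng.uniform(2, 40, 2)),
                  BBox(0, *rng.uniform(0, 50, 2), *rng.uniform(2, 40, 2)))
                 for _ in range(8)]
        pred = Tensor(np.array([[p.x, p.y, p.x2, p.y2] for p, _ in pairs],
                               dtype=np.float64))
        gt = np.array([[g.x, g.y, g.x2, g.y2] for _, g in pairs])
        got = ciou_loss_tensor(pred, gt).data
        expect = [ciou_loss(p, g).loss for p, g in pairs]
        np.testing.assert_allclose(got, expect, atol=1e-6)

    def test_tensor_version_gradient_direction(self):
        """Gradient descent on the loss moves a nearby box onto the target."""
        gt = np.array([[10.0, 10.0, 30.0, 30.0]])
        pred = Tensor(np.array([[14.0, 12.0, 36.0, 28.0]]), requires_grad=True,
                      dtype=np.float64)
        for _ in range(400):
            loss = ciou_loss_tensor(pred, gt).sum()
            pred.grad = None
            loss.backward()
            pred.data = pred.data - 0.5 * pred.grad
        assert ciou_loss_tensor(pred, gt).data[0] < 0.01


class TestMatching:
    def test_perfect_detections(self):
        gts = [BBox(0, 0, 0, 10, 10), BBox(1, 50, 50, 8, 8)]
        dets = [Detection(g, 0.9) for g in gts]
        c = match_detections(dets, gts, 0.5)
        assert sum(c.tp.values()) == 2 and sum(c.fp.values()) == 0
        assert sum(c.fn.values()) == 0

    def test_no_detections(self):
        gts = [BBox(0, 0, 0, 10, 10)] * 3
        c = match_detections([], gts, 0.5)
        assert c.fn[0] == 3 and c.tp[0] == 0

    def test_tp_plus_fn_equals_ground_truth_count(self, rng):
        from conftest import random_boxes

        for trial in range(20):
            gts = random_boxes(rng, int(rng.integers(0, 10)), 200, 200)
            dets = [Detection(b, float(rng.uniform(0.1, 1)))
                    for b in random_boxes(rng, int(rng.integers(0, 10)), 200, 200)]
            c = match_detections(dets, gts, 0.5)
            for cls in {g.class_id for g in gts}:
                n_gt = sum(g.class_id == cls for g in gts)
                assert c.tp.get(cls, 0) + c.fn.get(cls, 0) == n_gt

    def test_crafted_overlap_scenario(self):
        """5 detections, 3 gts; greedy confidence-order assignment."""
        gts = [BBox(0, 0, 0, 10, 10), BBox(0, 8, 0, 10, 10), BBox(0, 40, 40, 10, 10)]
        dets = [
            Detection(BBox(0, 1, 0, 10, 10), 0.95),   # best IoU with gt0
            Detection(BBox(0, 0, 0, 10, 10), 0.90),   # gt0 taken -> gt1? IoU ~0.25 -> FP
            Detection(BBox(0, 8, 1, 10, 10), 0.85),   # matches gt1
            Detection(BBox(0, 41, 40, 10, 10), 0.80), # matches gt2
            Detection(BBox(0, 90, 90, 5, 5), 0.70),   # FP
        ]
        c = match_detections(dets, gts, 0.5)
        assert c.tp[0] == 3 and c.fp[0] == 2 and c.fn[0] == 0
        # exhaustive check: same counts as brute-force greedy with explicit order
        order = sorted(range(5), key=lambda i: -dets[i].confidence)
        taken, tp = set(), 0
        for i in order:
            cands = [(iou(dets[i].bbox, g), gi) for gi, g in enumerate(gts)
                     if gi not in taken and iou(dets[i].bbox, g) >= 0.5]
            if cands:
                best = max(cands)
                taken.add(best[1])
                tp += 1
        assert tp == c.tp[0]

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValueError):
            match_detections([], [], 0.0)


class TestPRF1:
    def test_simple_arithmetic(self):
        assert precision_recall_f1(3, 1, 1) == (0.75, 0.75, 0.75)

    def test_degenerate_zero_convention(self):
        p, r, f1 = precision_recall_f1(0, 0, 5)
        assert (p, r, f1) == (0.0, 0.0, 0.0)

    def test_f1_is_harmonic_mean(self, rng):
        for _ in range(100):
            tp, fp, fn = (int(v) for v in rng.integers(0, 30, 3))
            p, r, f1 = precision_recall_f1(tp, fp, fn)
            expect = 0.0 if p + r == 0 else 2 * p * r / (p + r)
            assert f1 == pytest.approx(expect, abs=1e-12)


def envelope_integration_oracle(confs, flags, n_gt):
    """Brute-force rectangle sum over the monotone PR envelope."""
    order = sorted(range(len(confs)), key=lambda i: -confs[i])
    tp = fp = 0
    pts = [(0.0, 1.0)]
    for i in order:
        tp += bool(flags[i]); fp += (not flags[i])
        pts.append((tp / n_gt, tp / (tp + fp)))
    # envelope: precision at recall r is max precision at any recall >= r
    area = 0.0
    recalls = sorted({r for r, _ in pts})
    prev_r = 0.0
    for r in recalls:
        if r == 0.0:
            continue
        env = max((p for rr, p in pts if rr >= r), default=0.0)
        area += (r - prev_r) * env
        prev_r = r
    return area


class TestAveragePrecision:
    def test_all_true_positives(self):
        assert average_precision([0.9, 0.8], [True, True], 2) == 1.0

    def test_single_false_positive(self):
        assert average_precision([0.9], [False], 1) == 0.0

    def test_worked_six_detection_case(self):
        confs = [0.9, 0.8, 0.7, 0.6, 0.5, 0.4]
        flags = [True, False, True, True, False, True]
        got = average_precision(confs, flags, 5)
        expect = envelope_integration_oracle(confs, flags, 5)
        assert got == pytest.approx(expect, abs=1e-12)

    def test_random_cases_match_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(1, 15))
            confs = rng.uniform(0, 1, n).round(2).tolist()
            n_gt = int(rng.integers(1, 10))
            flags = (rng.random(n) < 0.5).tolist()
            if sum(flags) > n_gt:
                flags = [f and i < n_gt for i, f in enumerate(flags)]
            got = average_precision(confs, flags, n_gt)
            assert got == pytest.approx(
                envelope_integration_oracle(confs, flags, n_gt), abs=1e-9)

    def test_tie_break_stability(self):
        confs = [0.5, 0.5, 0.5]
        a = average_precision(confs, [True, False, True], 2)
        b = average_precision(confs, [True, False, True], 2)
        assert a == b


def reference_map(dets_by_image, gts_by_image, iou_thresh=0.5):
    """Independent mAP@IoU implementation (pooled, all-point interpolation)."""
    classes = sorted({g.class_id for gts in gts_by_image.values() for g in gts})
    aps = []
    for c in classes:
        records = []  # (conf, is_tp)
        n_gt = 0
        for img in sorted(set(dets_by_image) | set(gts_by_image)):
            gts = [g for g in gts_by_image.get(img, []) if g.class_id == c]
            dets = sorted([d for d in dets_by_image.get(img, [])
                           if d.bbox.class_id == c], key=lambda d: -d.confidence)
            n_gt += len(gts)
            used = set()
            for d in dets:
                best, best_ov = None, iou_thresh
                for gi, g in enumerate(gts):
                    if gi in used:
                        continue
                    ov = iou(d.bbox, g)
                    if ov >= best_ov and (best is None or ov > best_ov):
                        best, best_ov = gi, ov
                if best is not None:
                    used.add(best)
                    records.append((d.confidence, True))
                else:
                    records.append((d.confidence, False))
        if n_gt == 0:
            continue
        records.sort(key=lambda t: -t[0])
        aps.append(envelope_integration_oracle(
            [r[0] for r in records], [r[1] for r in records], n_gt))
    return float(np.mean(aps)) if aps else float("nan")


class TestEvaluate:
    def test_identical_sets_map_one(self):
        gts = {f"im{i}": [BBox(0, 5, 5, 10, 10), BBox(1, 30, 30, 12, 12)]
               for i in range(3)}
        dets = {k: [Detection(b, 0.9) for b in v] for k, v in gts.items()}
        res = evaluate(dets, gts)
        assert res.map == pytest.approx(1.0)

    def test_half_perfect_classes(self):
        gts = {"a": [BBox(0, 5, 5, 10, 10), BBox(1, 40, 40, 10, 10)]}
        dets = {"a": [Detection(BBox(0, 5, 5, 10, 10), 0.9)]}
        res = evaluate(dets, gts)
        assert res.map == pytest.approx(0.5)

    def test_matches_independent_reference(self, rng):
        """Randomised 20-image evaluation agrees with the reference to 1e-6."""
        from conftest import random_boxes

        gts_by_image, dets_by_image = {}, {}
        for i in range(20):
            img = f"im{i:02d}"
            gts = random_boxes(rng, int(rng.integers(0, 8)), 320, 320)
            dets = []
            for g in gts:
                if rng.random() < 0.75:  # jittered true detection
                    dx, dy = rng.uniform(-3, 3, 2)
                    dets.append(Detection(
                        BBox(g.class_id,
                             min(max(g.x + dx, 0), 320 - g.w),
                             min(max(g.y + dy, 0), 320 - g.h), g.w, g.h),
                        float(rng.uniform(0.3, 1.0))))
            for b in random_boxes(rng, int(rng.integers(0, 4)), 320, 320):
                dets.append(Detection(b, float(rng.uniform(0.05, 0.9))))
            gts_by_image[img], dets_by_image[img] = gts, dets
        res = evaluate(dets_by_image, gts_by_image, 0.5)
        ref = reference_map(dets_by_image, gts_by_image, 0.5)
        assert res.map == pytest.approx(ref, abs=1e-6)

    def test_unknown_class_rejected(self):
        gts = {"a": [BBox(0, 5, 5, 10, 10)]}
        dets = {"a": [Detection(BBox(3, 5, 5, 10, 10), 0.9)]}
        with pytest.raises(ValueError, match="unknown class"):
            evaluate(dets, gts)

    def test_metric_ranges(self, rng):
        from conftest import random_boxes

        gts = {"a": random_boxes(rng, 5, 200, 200)}
        dets = {"a": [Detection(b, 0.5) for b in random_boxes(rng, 5, 200, 200)]}
        res = evaluate(dets, gts)
        for m in res.per_class.values():
            for key in ("precision", "recall", "f1"):
                assert 0.0 <= m[key] <= 1.0
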