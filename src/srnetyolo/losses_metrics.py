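"""CIoU bounding-box loss and the detection evaluation stack.

The complete-IoU loss augments 1 - IoU with a normalised centre-distance
term and an aspect-ratio consistency term:

    L = 1 - IoU + rho^2(b, b_gt) / c^2 + alpha * v

where rho is the distance between box centres, c the diagonal of the
smallest enclosing box, v = (4/pi^2) (arctan(w_gt/h_gt) - arctan(w/h))^2
and alpha = v / ((1 - IoU) + v).  Alpha is treated as a constant during
backpropagation.

Evaluation follows the YOLO-family convention: greedy confidence-ordered
matching at a fixed IoU threshold (0.5 by default), all-point
(monotone-envelope) precision-recall interpolation for AP, and mAP as the
unweighted mean over classes that have at least one ground truth.
Size-stratified evaluation restricts ground truths (and the detections
matched to them) to one pixel-size class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .boxes import BBox, Detection, iou
from .data.sizes import SizeClass, size_class
from .nn import Tensor

__all__ = [
    "CIoUBreakdown", "ciou_loss", "ciou_loss_tensor",
    "EvalCounts", "match_detections", "precision_recall_f1",
    "average_precision", "EvalResult", "evaluate",
]


# --------------------------------------------------------------------- CIoU
@dataclass(frozen=True)
class CIoUBreakdown:
    iou: float
    center_dist_sq: float
    encl_diag_sq: float
    v: float
    alpha: float
    loss: float


def ciou_loss(pred: BBox, gt: BBox) -> CIoUBreakdown:
    """Complete-IoU loss between two boxes, with its components."""
    if pred.w <= 0 or pred.h <= 0 or gt.w <= 0 or gt.h <= 0:
        raise ValueError("boxes must have positive extents")
    i = iou(pred, gt)
    (px, py), (gx, gy) = pred.center, gt.center
    rho2 = (px - gx) ** 2 + (py - gy) ** 2
    cw = max(pred.x2, gt.x2) - min(pred.x, gt.x)
    ch = max(pred.y2, gt.y2) - min(pred.y, gt.y)
    c2 = cw**2 + ch**2
    v = (4.0 / math.pi**2) * (math.atan(gt.w / gt.h) - math.atan(pred.w / pred.h)) ** 2
    alpha = 0.0 if v == 0.0 else v / ((1.0 - i) + v)
    loss = 1.0 - i + rho2 / c2 + alpha * v
    return CIoUBreakdown(iou=i, center_dist_sq=rho2, encl_diag_sq=c2,
                         v=v, alpha=alpha, loss=loss)


def ciou_loss_tensor(pred: Tensor, gt: np.ndarray) -> Tensor:
    """Differentiable CIoU loss for training.

    ``pred`` is an (N, 4) tensor of x1, y1, x2, y2 corners; ``gt`` a
    matching constant array.  Returns the (N,) per-box loss; alpha is
    computed from detached values (no gradient flows through it).
    """
    eps = 1e-9
    gt_t = Tensor(np.asarray(gt, dtype=pred.dtype))
    px1, py1, px2, py2 = (pred[:, i] for i in range(4))
    gx1, gy1, gx2, gy2 = (gt_t[:, i] for i in range(4))
    pw, ph = (px2 - px1).maximum(eps), (py2 - py1).maximum(eps)
    gw, gh = gx2 - gx1, gy2 - gy1
    inter_w = px2.minimum(gx2) - px1.maximum(gx1)
    inter_h = py2.minimum(gy2) - py1.maximum(gy1)
    inter = inter_w.maximum(0.0) * inter_h.maximum(0.0)
    union = pw * ph + gw * gh - inter
    i = inter / (union + eps)
    rho2 = ((px1 + px2 - gx1 - gx2) ** 2 + (py1 + py2 - gy1 - gy2) ** 2) * 0.25
    cw = px2.maximum(gx2) - px1.minimum(gx1)
    ch = py2.maximum(gy2) - py1.minimum(gy1)
    c2 = cw**2 + ch**2 + eps
    v = ((gw / gh).arctan() - (pw / ph).arctan()) ** 2 * (4.0 / math.pi**2)
    alpha = v.data / ((1.0 - i.data) + v.data + eps)  # constant wrt gradients
    return 1.0 - i + rho2 / c2 + Tensor(alpha) * v


# --------------------------------------------------------------- evaluation
@dataclass
class EvalCounts:
    """Per-class true/false positives and false negatives."""

    tp: dict = field(default_factory=dict)
    fp: dict = field(default_factory=dict)
    fn: dict = field(default_factory=dict)

    def classes(self):
        return sorted(set(self.tp) | set(self.fp) | set(self.fn))

    def add(self, other: "EvalCounts"):
        for d_self, d_other in ((self.tp, other.tp), (self.fp, other.fp), (self.fn, other.fn)):
            for c, n in d_other.items():
                d_self[c] = d_self.get(c, 0) + n


def _greedy_match(dets: list[Detection], gts: list[BBox], iou_thresh: float):
    """Confidence-ordered greedy matching within one image.

    Returns (order, matched_gt_index per det, iou per det) where order is
    the stable confidence-descending permutation of ``dets``.
    """
    order = sorted(range(len(dets)), key=lambda i: -dets[i].confidence)
    matched_gt = [-1] * len(dets)
    taken = [False] * len(gts)
    for rank, di in enumerate(order):
        det = dets[di]
        best, best_iou = -1, -1.0
        for gi, gt in enumerate(gts):
            if taken[gi] or gt.class_id != det.bbox.class_id:
                continue
            ov = iou(det.bbox, gt)
            if ov >= iou_thresh and ov > best_iou:
                best, best_iou = gi, ov
        if best >= 0:
            taken[best] = True
            matched_gt[di] = best
    return order, matched_gt, taken


def match_detections(dets: list[Detection], gts: list[BBox],
                     iou_thresh: float = 0.5) -> EvalCounts:
    """Greedy TP/FP/FN counting for one image."""
    if not 0.0 < iou_thresh < 1.0:
        raise ValueError("iou_thresh must lie in (0, 1)")
    _, matched_gt, taken = _greedy_match(dets, gts, iou_thresh)
    counts = EvalCounts()
    for c in {d.bbox.class_id for d in dets} | {g.class_id for g in gts}:
        counts.tp[c], counts.fp[c], counts.fn[c] = 0, 0, 0
    for det, m in zip(dets, matched_gt):
        c = det.bbox.class_id
        if m >= 0:
            counts.tp[c] += 1
        else:
            counts.fp[c] += 1
    for gi, gt in enumerate(gts):
        if not taken[gi]:
            counts.fn[gt.class_id] += 1
    return counts


def precision_recall_f1(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """Precision, recall and F1 = 2TP / (2TP + FN + FP); 0/0 defined as 0."""
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * tp / (2 * tp + fn + fp) if 2 * tp + fn + fp else 0.0
    return p, r, f1


def average_precision(confidences, tp_flags, n_gt: int) -> float:
    """Area under the monotone precision-recall envelope (all-point).

    Detections are ranked by descending confidence with a stable tie-break
    on input order.  Returns ``nan`` when there are no ground truths.
    """
    if n_gt < 0:
        raise ValueError("n_gt must be >= 0")
    if n_gt == 0:
        return float("nan")
    confidences = np.asarray(confidences, dtype=float)
    tp_flags = np.asarray(tp_flags, dtype=bool)
    if confidences.size == 0:
        return 0.0
    order = np.argsort(-confidences, kind="stable")
    tp = np.cumsum(tp_flags[order])
    fp = np.cumsum(~tp_flags[order])
    recall = tp / n_gt
    precision = tp / np.maximum(tp + fp, 1)
    # monotone envelope, integrated over recall
    mrec = np.concatenate(([0.0], recall, [1.0]))
    mpre = np.concatenate(([0.0], precision, [0.0]))
    mpre = np.maximum.accumulate(mpre[::-1])[::-1]
    idx = np.where(mrec[1:] != mrec[:-1])[0]
    return float(np.sum((mrec[idx + 1] - mrec[idx]) * mpre[idx + 1]))


@dataclass
class EvalResult:
    """Per-class precision/recall/F1/AP and their class-mean mAP."""

    per_class: dict
    map: float
    counts: EvalCounts

    def summary(self) -> str:
        lines = [f"{'class':>8} {'P':>7} {'R':>7} {'F1':>7} {'AP':>7}"]
        for c, m in sorted(self.per_class.items()):
            lines.append(
                f"{c:>8} {m['precision']:7.3f} {m['recall']:7.3f} "
                f"{m['f1']:7.3f} {m['ap']:7.3f}"
            )
        lines.append(f"mAP@0.5 = {self.map:.4f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "per_class": {str(c): m for c, m in self.per_class.items()},
            "map": self.map,
        }


def evaluate(dets_by_image: dict, gts_by_image: dict, iou_thresh: float = 0.5,
             size_filter: SizeClass | None = None) -> EvalResult:
    """Pooled evaluation over a set of images.

    ``dets_by_image`` / ``gts_by_image`` map an image id to its detections
    and ground-truth boxes.  With a ``size_filter``, ground truths outside
    the class are dropped; detections that matched a dropped ground truth
    are ignored, and unmatched detections count as FP in the stratum of
    their own predicted size.
    """
    ids = set(dets_by_image) | set(gts_by_image)
    known_classes = {g.class_id for gts in gts_by_image.values() for g in gts}
    per_class_scores: dict[int, list] = {}
    per_class_flags: dict[int, list] = {}
    n_gt: dict[int, int] = {}
    counts = EvalCounts()

    for img in sorted(ids):
        dets = list(dets_by_image.get(img, []))
        gts = list(gts_by_image.get(img, []))
        for d in dets:
            if known_classes and d.bbox.class_id not in known_classes:
                raise ValueError(f"unknown class id {d.bbox.class_id} in detections")
        order, matched_gt, taken = _greedy_match(dets, gts, iou_thresh)
        in_stratum = [size_filter is None or size_class(g) == size_filter for g in gts]
        for gi, gt in enumerate(gts):
            if not in_stratum[gi]:
                continue
            n_gt[gt.class_id] = n_gt.get(gt.class_id, 0) + 1
            if not taken[gi]:
                counts.fn[gt.class_id] = counts.fn.get(gt.class_id, 0) + 1
        for di, det in enumerate(dets):
            c = det.bbox.class_id
            m = matched_gt[di]
            if m >= 0:
                if not in_stratum[m]:
                    continue  # matched an out-of-stratum object: ignore
                counts.tp[c] = counts.tp.get(c, 0) + 1
                flag = True
            else:
                if size_filter is not None and size_class(det.bbox) != size_filter:
                    continue
                counts.fp[c] = counts.fp.get(c, 0) + 1
                flag = False
            per_class_scores.setdefault(c, []).append(det.confidence)
            per_class_flags.setdefault(c, []).append(flag)

    per_class = {}
    aps = []
    for c in sorted(known_classes | set(n_gt) | set(per_class_scores)):
        tp = counts.tp.get(c, 0)
        fp = counts.fp.get(c, 0)
        fn = counts.fn.get(c, 0)
        p, r, f1 = precision_recall_f1(tp, fp, fn)
        ap = average_precision(per_class_scores.get(c, []), per_class_flags.get(c, []),
                               n_gt.get(c, 0))
        per_class[c] = {"precision": p, "recall": r, "f1": f1,
                        "ap": ap, "n_gt": n_gt.get(c, 0)}
        if n_gt.get(c, 0) > 0:
            aps.append(ap)
    mean_ap = float(np.mean(aps)) if aps else float("nan")
    return EvalResult(per_class=per_class, map=mean_ap, counts=counts)
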