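"""End-to-end training of the detector with the detection loss only.

Positive assignment uses a centre prior: a grid cell is positive for the
ground-truth box that contains its centre (nearest box centre breaks
ties).  A box too small to contain any cell centre is assigned the cell
nearest its centre at the finest scale, so even 4-px objects receive a
learning signal.  The loss is binary cross-entropy over class logits on
every cell plus complete-IoU loss on positive cells, normalised by the
number of positives.

The default hyperparameters (1000 epochs, batch 32, 640-px images,
lr0 = 0.001 with cosine decay to lr0 * lrf, lrf = 0.01, SGD momentum
0.937, weight decay 5e-4) describe a full-scale run; desk-scale runs
override epochs, batch and image size explicitly.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .backbone_model import ModelConfig, RawPredictions, SRNetYOLO, decode_predictions
from .boxes import BBox
from .data.annotations import AnnotatedImage
from .losses_metrics import ciou_loss_tensor, evaluate
from .nn import SGD, Tensor, cosine_lr

__all__ = ["TrainConfig", "TrainResult", "detection_loss", "train",
           "images_to_batch", "evaluate_model"]


@dataclass
class TrainConfig:
    epochs: int = 1000
    batch_size: int = 32
    image_size: int = 640
    seed: int = 0
    lr0: float = 0.001
    lrf: float = 0.01
    momentum: float = 0.937
    weight_decay: float = 5e-4
    box_weight: float = 5.0
    cls_weight: float = 1.0
    hflip: bool = False
    warmup_steps: int = 0
    log_every: int = 10

    def validate(self):
        for name in ("epochs", "batch_size", "image_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.lr0 and 0 < self.lrf <= 1):
            raise ValueError("need lr0 > 0 and lrf in (0, 1]")
        return self


@dataclass
class TrainResult:
    loss_history: list = field(default_factory=list)   # per-step total loss
    epoch_losses: list = field(default_factory=list)
    val_map_history: list = field(default_factory=list)
    best_val_map: float = float("nan")
    best_state: dict | None = None
    wall_time_s: float = 0.0


def images_to_batch(imgs: list[AnnotatedImage]) -> tuple[Tensor, list[list[BBox]]]:
    """Stack RGB images into a normalised (B, 3, H, W) tensor."""
    arr = np.stack([im.pixels for im in imgs]).astype(np.float32) / 255.0
    return Tensor(arr.transpose(0, 3, 1, 2)), [list(im.boxes) for im in imgs]


def _assign_scale(gts: list[BBox], H: int, W: int, stride: int):
    """Centre-prior assignment on one grid: cell -> gt index or -1."""
    assign = -np.ones((H, W), dtype=np.int64)
    if not gts:
        return assign
    ii, jj = np.mgrid[0:H, 0:W]
    cx = (jj + 0.5) * stride
    cy = (ii + 0.5) * stride
    best_d2 = np.full((H, W), np.inf)
    for gi, g in enumerate(gts):
        inside = (cx >= g.x) & (cx < g.x2) & (cy >= g.y) & (cy < g.y2)
        gcx, gcy = g.center
        d2 = (cx - gcx) ** 2 + (cy - gcy) ** 2
        take = inside & (d2 < best_d2)
        assign[take] = gi
        best_d2 = np.where(take, d2, best_d2)
    return assign


def assign_targets(gt_lists: list[list[BBox]], shapes, strides):
    """Build per-scale class targets and positive-cell index lists.

    Returns, per scale: (cls_target (B, nc, H, W) is built by the caller
    from ``pos``) — here we return ``pos`` as a dict of arrays with keys
    b, i, j, cls, gt_xyxy.
    """
    out = []
    fallback_done = [set() for _ in gt_lists]
    finest = 0
    for si, ((H, W), stride) in enumerate(zip(shapes, strides)):
        b_idx, i_idx, j_idx, cls_idx, gt_boxes = [], [], [], [], []
        for b, gts in enumerate(gt_lists):
            assign = _assign_scale(gts, H, W, stride)
            covered = set(np.unique(assign[assign >= 0]).tolist())
            if si == finest:
                # fallback: tiny boxes with no covering cell centre
                for gi, g in enumerate(gts):
                    if gi in covered:
                        continue
                    gcx, gcy = g.center
                    j = min(max(int(gcx / stride), 0), W - 1)
                    i = min(max(int(gcy / stride), 0), H - 1)
                    if assign[i, j] < 0:
                        assign[i, j] = gi
                        fallback_done[b].add(gi)
            ii, jj = np.nonzero(assign >= 0)
            for i, j in zip(ii, jj):
                gi = assign[i, j]
                g = gts[gi]
                b_idx.append(b); i_idx.append(i); j_idx.append(j)
                cls_idx.append(g.class_id)
                gt_boxes.append([g.x, g.y, g.x2, g.y2])
        out.append({
            "b": np.asarray(b_idx, dtype=np.int64),
            "i": np.asarray(i_idx, dtype=np.int64),
            "j": np.asarray(j_idx, dtype=np.int64),
            "cls": np.asarray(cls_idx, dtype=np.int64),
            "gt_xyxy": np.asarray(gt_boxes, dtype=np.float32).reshape(-1, 4),
        })
    return out


def _bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Element-wise BCE from logits: softplus(x) - x * t (stable)."""
    t = Tensor(targets.astype(logits.dtype))
    return logits.softplus() - logits * t


def detection_loss(raw: RawPredictions, gt_lists: list[list[BBox]],
                   box_weight: float = 5.0, cls_weight: float = 1.0):
    """Composite detection loss; returns (total, components dict)."""
    shapes = [c.shape[2:] for c in raw.cls_logits]
    pos = assign_targets(gt_lists, shapes, raw.strides)
    B = raw.cls_logits[0].shape[0]
    nc = raw.cls_logits[0].shape[1]
    n_pos_total = max(sum(len(p["b"]) for p in pos), 1)

    cls_terms, box_terms = [], []
    for c_t, d_t, stride, p in zip(raw.cls_logits, raw.box_dists, raw.strides, pos):
        H, W = c_t.shape[2:]
        target = np.zeros((B, nc, H, W), dtype=np.float32)
        if len(p["b"]):
            target[p["b"], p["cls"], p["i"], p["j"]] = 1.0
        cls_terms.append(_bce_with_logits(c_t, target).sum())
        if len(p["b"]):
            dists = d_t[p["b"], :, p["i"], p["j"]]  # (N, 4) softplus'd
            cx = (p["j"].astype(np.float32) + 0.5) * stride
            cy = (p["i"].astype(np.float32) + 0.5) * stride
            cx_t, cy_t = Tensor(cx), Tensor(cy)
            x1 = cx_t - dists[:, 0] * float(stride)
            y1 = cy_t - dists[:, 1] * float(stride)
            x2 = cx_t + dists[:, 2] * float(stride)
            y2 = cy_t + dists[:, 3] * float(stride)
            pred = nn.stack([x1, y1, x2, y2], axis=1)
            box_terms.append(ciou_loss_tensor(pred, p["gt_xyxy"]).sum())

    cls_loss = sum(cls_terms[1:], cls_terms[0]) * (1.0 / n_pos_total)
    if box_terms:
        box_loss = sum(box_terms[1:], box_terms[0]) * (1.0 / n_pos_total)
    else:
        box_loss = Tensor(np.zeros(()))
    total = cls_weight * cls_loss + box_weight * box_loss
    return total, {"cls": float(cls_loss.data), "box": float(box_loss.data),
                   "total": float(total.data), "n_pos": n_pos_total}


def evaluate_model(model: SRNetYOLO, imgs: list[AnnotatedImage],
                   conf_thresh: float = 0.25, nms_iou: float = 0.5,
                   iou_thresh: float = 0.5, size_filter=None, batch_size: int = 8):
    """Run inference and compute pooled detection metrics."""
    model.eval()
    dets_by_image, gts_by_image = {}, {}
    for start in range(0, len(imgs), batch_size):
        chunk = imgs[start : start + batch_size]
        x, gt_lists = images_to_batch(chunk)
        raw = model(x)
        dets = decode_predictions(raw, conf_thresh, nms_iou,
                                  image_size=(chunk[0].width, chunk[0].height))
        for im, d, g in zip(chunk, dets, gt_lists):
            dets_by_image[im.image_id] = d
            gts_by_image[im.image_id] = g
    return evaluate(dets_by_image, gts_by_image, iou_thresh, size_filter)


def _maybe_flip(img: AnnotatedImage, rng) -> AnnotatedImage:
    if rng.random() < 0.5:
        return img
    flipped = img.pixels[:, ::-1].copy()
    boxes = [BBox(b.class_id, img.width - b.x - b.w, b.y, b.w, b.h) for b in img.boxes]
    return AnnotatedImage(image_id=img.image_id, width=img.width, height=img.height,
                          boxes=boxes, pixels=flipped, class_names=img.class_names)


def train(model: SRNetYOLO, train_imgs: list[AnnotatedImage],
          val_imgs: list[AnnotatedImage] | None, cfg: TrainConfig,
          progress: bool = False) -> TrainResult:
    """SGD training loop; deterministic for a fixed config and seed."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    opt = SGD(model.parameters(), lr=cfg.lr0, momentum=cfg.momentum,
              weight_decay=cfg.weight_decay)
    steps_per_epoch = max(math.ceil(len(train_imgs) / cfg.batch_size), 1)
    total_steps = steps_per_epoch * cfg.epochs
    result = TrainResult()
    t0 = time.time()
    step = 0
    best_map = -1.0
    model.train()
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(train_imgs))
        epoch_loss = 0.0
        for start in range(0, len(train_imgs), cfg.batch_size):
            batch_ids = order[start : start + cfg.batch_size]
            imgs = [train_imgs[i] for i in batch_ids]
            if cfg.hflip:
                imgs = [_maybe_flip(im, rng) for im in imgs]
            x, gt_lists = images_to_batch(imgs)
            raw = model(x)
            loss, comps = detection_loss(raw, gt_lists,
                                         cfg.box_weight, cfg.cls_weight)
            if not np.isfinite(comps["total"]):
                raise FloatingPointError(
                    f"non-finite loss at step {step}: {comps}")
            opt.zero_grad()
            loss.backward()
            opt.lr = cosine_lr(step, total_steps, cfg.lr0, cfg.lrf)
            if cfg.warmup_steps and step < cfg.warmup_steps:
                opt.lr *= (step + 1) / cfg.warmup_steps
            opt.step()
            result.loss_history.append(comps["total"])
            epoch_loss += comps["total"]
            step += 1
            if progress and step % cfg.log_every == 0:
                print(f"epoch {epoch + 1} step {step}: "
                      f"total {comps['total']:.4f} cls {comps['cls']:.4f} "
                      f"box {comps['box']:.4f} lr {opt.lr:.5f}", flush=True)
        result.epoch_losses.append(epoch_loss / steps_per_epoch)
        if val_imgs:
            res = evaluate_model(model, val_imgs)
            result.val_map_history.append(res.map)
            m = -1.0 if math.isnan(res.map) else res.map
            if m > best_map:
                best_map = m
                result.best_state = model.state_dict()
            model.train()
            if progress:
                print(f"epoch {epoch + 1}: mean loss "
                      f"{result.epoch_losses[-1]:.4f} val mAP {res.map:.4f}",
                      flush=True)
    if val_imgs and result.best_state is not None:
        result.best_val_map = best_map
        model.load_state_dict(result.best_state)
    model.eval()
    result.wall_time_s = time.time() - t0
    return result
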