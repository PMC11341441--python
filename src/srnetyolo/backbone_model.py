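"""The full tiny-pest detector and its plain-backbone baseline.

A CSP/C2f backbone extracts pyramid maps P3/P4/P5 at strides 8/16/32.
The super-resolving variant additionally reconstructs P5 to P3's spatial
size (FM-SR), fuses it with P3 through the gated routing-attention block
(BiFormerAF) to form NewP3, and re-runs the deeper stages from NewP3 to
obtain NewP4/NewP5, which replace the original P4/P5.  A PAN-style neck
aggregates the three scales and an anchor-free decoupled head predicts,
per cell, class probabilities (sigmoid) and left/top/right/bottom
distances to the box sides (softplus, in stride units).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .bra import AttentionConfig
from .biformer_af import BiFormerAF, C2f, FusionConfig
from .boxes import BBox, Detection, iou
from .fm_sr import FMSR, FMSRConfig
from .nn import Tensor, functional as F

__all__ = ["ModelConfig", "RawPredictions", "Backbone", "SRNetYOLO",
           "decode_predictions", "nms", "save_checkpoint", "load_checkpoint"]


@dataclass
class ModelConfig:
    input_size: int = 640
    num_classes: int = 2
    width_mult: float = 0.25
    depth_mult: float = 0.33
    strides: tuple = (8, 16, 32)
    use_sr_fusion: bool = True          # False -> plain baseline backbone
    attn_S: int = 8                     # regions per side at the P3 scale
    attn_k: int = 4
    attn_heads: int = 4
    n_res_blocks: int = 5
    c2f_depth_fusion: int = 1
    seed: int = 0                       # weight-initialisation seed

    def validate(self):
        if self.input_size % 32:
            raise ValueError("input_size must be divisible by 32")
        p3 = self.input_size // 8
        if self.use_sr_fusion and (p3 % self.attn_S):
            raise ValueError(
                f"attn_S={self.attn_S} must divide the P3 size {p3}"
            )
        return self

    def widths(self):
        base = (64, 128, 256, 512, 1024)
        w = [max(int(round(c * self.width_mult)), 8) for c in base]
        w[4] = min(w[4], w[3] * 2)
        return w

    def depth(self, n: int) -> int:
        return max(int(round(n * self.depth_mult)), 1)


@dataclass
class RawPredictions:
    """Per-scale class logits (B, nc, H, W) and box distances (B, 4, H, W)."""

    cls_logits: list
    box_dists: list
    strides: tuple


class Backbone(nn.Module):
    """CSP/C2f pyramid extractor: image -> (P3, P4, P5)."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.cfg = cfg.validate()
        c1, c2, c3, c4, c5 = cfg.widths()
        d = cfg.depth
        self.stem = nn.ConvBNSiLU(3, c1, 3, stride=2)
        self.down1 = nn.ConvBNSiLU(c1, c2, 3, stride=2)
        self.c2f1 = C2f(c2, c2, d(3))
        self.down2 = nn.ConvBNSiLU(c2, c3, 3, stride=2)
        self.c2f2 = C2f(c3, c3, d(6))
        self.down3 = nn.ConvBNSiLU(c3, c4, 3, stride=2)
        self.c2f3 = C2f(c4, c4, d(6))
        self.down4 = nn.ConvBNSiLU(c4, c5, 3, stride=2)
        self.c2f4 = C2f(c5, c5, d(3))

    def stage_p3(self, x: Tensor) -> Tensor:
        if x.shape[-1] % 32 or x.shape[-2] % 32:
            raise ValueError("input spatial dims must be divisible by 32")
        return self.c2f2(self.down2(self.c2f1(self.down1(self.stem(x)))))

    def stage_p4(self, p3: Tensor) -> Tensor:
        return self.c2f3(self.down3(p3))

    def stage_p5(self, p4: Tensor) -> Tensor:
        return self.c2f4(self.down4(p4))

    def forward(self, x: Tensor):
        p3 = self.stage_p3(x)
        p4 = self.stage_p4(p3)
        p5 = self.stage_p5(p4)
        return p3, p4, p5


class Neck(nn.Module):
    """PAN-style top-down + bottom-up aggregation with C2f blocks."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        _, _, c3, c4, c5 = cfg.widths()
        d = cfg.depth
        self.td4 = C2f(c5 + c4, c4, d(3), shortcut=False)
        self.td3 = C2f(c4 + c3, c3, d(3), shortcut=False)
        self.dn3 = nn.ConvBNSiLU(c3, c3, 3, stride=2)
        self.bu4 = C2f(c3 + c4, c4, d(3), shortcut=False)
        self.dn4 = nn.ConvBNSiLU(c4, c4, 3, stride=2)
        self.bu5 = C2f(c4 + c5, c5, d(3), shortcut=False)

    def forward(self, p3, p4, p5):
        t4 = self.td4(nn.concat([F.upsample_nearest2x(p5), p4], axis=1))
        t3 = self.td3(nn.concat([F.upsample_nearest2x(t4), p3], axis=1))
        b4 = self.bu4(nn.concat([self.dn3(t3), t4], axis=1))
        b5 = self.bu5(nn.concat([self.dn4(b4), p5], axis=1))
        return t3, b4, b5


class _ScaleHead(nn.Module):
    def __init__(self, ch: int, num_classes: int):
        super().__init__()
        self.cls_stem = nn.Sequential(nn.ConvBNSiLU(ch, ch, 3), nn.ConvBNSiLU(ch, ch, 3))
        self.cls_out = nn.Conv2d(ch, num_classes, 1)
        self.box_stem = nn.Sequential(nn.ConvBNSiLU(ch, ch, 3), nn.ConvBNSiLU(ch, ch, 3))
        self.box_out = nn.Conv2d(ch, 4, 1)
        # start with low objectness so early training is not swamped by FPs
        self.cls_out.bias.data[:] = -4.0

    def forward(self, x):
        return self.cls_out(self.cls_stem(x)), self.box_out(self.box_stem(x))


class DetectionHead(nn.Module):
    """Decoupled anchor-free head over the three pyramid scales."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        _, _, c3, c4, c5 = cfg.widths()
        self.cfg = cfg
        self.heads = nn.ModuleList([
            _ScaleHead(c, cfg.num_classes) for c in (c3, c4, c5)
        ])

    def forward(self, feats) -> RawPredictions:
        cls_logits, box_dists = [], []
        for head, f in zip(self.heads, feats):
            c, b = head(f)
            cls_logits.append(c)
            box_dists.append(b.softplus())  # distances >= 0, stride units
        return RawPredictions(cls_logits, box_dists, self.cfg.strides)


class SRNetYOLO(nn.Module):
    """Full detector; ``cfg.use_sr_fusion=False`` gives the plain baseline."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.cfg = cfg.validate()
        nn.seed_init(cfg.seed)
        rng = np.random.default_rng(cfg.seed)
        self.backbone = Backbone(cfg)
        _, _, c3, c4, c5 = cfg.widths()
        if cfg.use_sr_fusion:
            self.fm_sr = FMSR(c5, FMSRConfig(
                n_res_blocks=cfg.n_res_blocks, out_channels=c3))
            attn = AttentionConfig(S=cfg.attn_S, k=cfg.attn_k,
                                   num_heads=cfg.attn_heads)
            self.fusion = BiFormerAF(c3, FusionConfig(
                c2f_depth=cfg.c2f_depth_fusion, attn=attn), rng)
        self.neck = Neck(cfg)
        self.head = DetectionHead(cfg)

    def extract_pyramid(self, x: Tensor):
        """(NewP3, NewP4, NewP5) — or (P3, P4, P5) for the baseline."""
        p3 = self.backbone.stage_p3(x)
        if not self.cfg.use_sr_fusion:
            p4 = self.backbone.stage_p4(p3)
            return p3, p4, self.backbone.stage_p5(p4)
        p4 = self.backbone.stage_p4(p3)
        p5 = self.backbone.stage_p5(p4)
        srp5 = self.fm_sr(p5)
        new_p3 = self.fusion(p3, srp5)
        new_p4 = self.backbone.stage_p4(new_p3)
        new_p5 = self.backbone.stage_p5(new_p4)
        return new_p3, new_p4, new_p5

    def forward(self, x: Tensor) -> RawPredictions:
        feats = self.extract_pyramid(x)
        return self.head(self.neck(*feats))


# ----------------------------------------------------------------- decoding
def _decode_scale(cls_logits: np.ndarray, box_dists: np.ndarray, stride: int):
    """Decode one scale for one image -> (boxes_xyxy, scores, classes)."""
    nc, H, W = cls_logits.shape
    probs = 1.0 / (1.0 + np.exp(-cls_logits))
    cls = probs.argmax(axis=0)
    score = probs.max(axis=0)
    jj, ii = np.meshgrid(np.arange(W), np.arange(H))
    cx = (jj + 0.5) * stride
    cy = (ii + 0.5) * stride
    l, t, r, b = box_dists * stride
    boxes = np.stack([cx - l, cy - t, cx + r, cy + b], axis=-1)
    return boxes.reshape(-1, 4), score.reshape(-1), cls.reshape(-1)


def nms(boxes: np.ndarray, scores: np.ndarray, iou_thresh: float) -> list[int]:
    """Greedy IoU-based suppression; returns kept indices, best first."""
    order = np.argsort(-scores, kind="stable")
    keep = []
    x1, y1, x2, y2 = boxes.T
    areas = np.maximum(x2 - x1, 0) * np.maximum(y2 - y1, 0)
    suppressed = np.zeros(len(boxes), dtype=bool)
    for i in order:
        if suppressed[i]:
            continue
        keep.append(int(i))
        ix1 = np.maximum(x1[i], x1)
        iy1 = np.maximum(y1[i], y1)
        ix2 = np.minimum(x2[i], x2)
        iy2 = np.minimum(y2[i], y2)
        inter = np.maximum(ix2 - ix1, 0) * np.maximum(iy2 - iy1, 0)
        ov = inter / np.maximum(areas[i] + areas - inter, 1e-12)
        suppressed |= ov > iou_thresh
    return keep


def decode_predictions(raw: RawPredictions, conf_thresh: float = 0.25,
                       nms_iou: float = 0.5,
                       image_size: int | tuple | None = None) -> list[list[Detection]]:
    """Raw grids -> per-image detection lists (confidence filtered, NMS'd)."""
    if not (0.0 <= conf_thresh <= 1.0 and 0.0 <= nms_iou <= 1.0):
        raise ValueError("thresholds must lie in [0, 1]")
    B = raw.cls_logits[0].shape[0]
    if image_size is None:
        image_size = raw.cls_logits[0].shape[2] * raw.strides[0]
    iw, ih = (image_size, image_size) if np.isscalar(image_size) else image_size
    out = []
    for bi in range(B):
        all_boxes, all_scores, all_cls = [], [], []
        for c_t, b_t, s in zip(raw.cls_logits, raw.box_dists, raw.strides):
            bx, sc, cl = _decode_scale(c_t.data[bi], b_t.data[bi], s)
            m = sc >= conf_thresh
            all_boxes.append(bx[m]); all_scores.append(sc[m]); all_cls.append(cl[m])
        boxes = np.concatenate(all_boxes) if all_boxes else np.zeros((0, 4))
        scores = np.concatenate(all_scores)
        classes = np.concatenate(all_cls)
        boxes[:, [0, 2]] = boxes[:, [0, 2]].clip(0, iw)
        boxes[:, [1, 3]] = boxes[:, [1, 3]].clip(0, ih)
        dets = []
        for c in np.unique(classes):
            m = classes == c
            idx = np.flatnonzero(m)
            for k in nms(boxes[m], scores[m], nms_iou):
                x1, y1, x2, y2 = boxes[idx[k]]
                if x2 - x1 < 1e-3 or y2 - y1 < 1e-3:
                    continue
                dets.append(Detection(
                    BBox(int(c), float(x1), float(y1),
                         float(x2 - x1), float(y2 - y1)),
                    float(min(max(scores[idx[k]], 0.0), 1.0))))
        dets.sort(key=lambda d: -d.confidence)
        out.append(dets)
    return out


# ------------------------------------------------------------- checkpointing
def save_checkpoint(model: SRNetYOLO, path: str):
    """Single-file checkpoint: serialized weights plus the model config."""
    state = model.state_dict()
    cfg_json = json.dumps(asdict(model.cfg))
    np.savez(path, __config__=np.frombuffer(cfg_json.encode(), dtype=np.uint8),
             **state)


def load_checkpoint(path: str) -> SRNetYOLO:
    with np.load(path, allow_pickle=False) as data:
        cfg_dict = json.loads(bytes(data["__config__"].tobytes()).decode())
        for key in ("strides", "classes"):
            if key in cfg_dict and isinstance(cfg_dict[key], list):
                cfg_dict[key] = tuple(cfg_dict[key])
        cfg = ModelConfig(**cfg_dict)
        model = SRNetYOLO(cfg)
        state = {k: data[k] for k in data.files if k != "__config__"}
    model.load_state_dict(state)
    return model
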