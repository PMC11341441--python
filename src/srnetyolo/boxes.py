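"""Axis-aligned pixel-space boxes and detections.

Coordinates are continuous, 0-based, origin top-left, x to the right and
y down.  A box occupies the half-open extent [x, x+w) x [y, y+h).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["BBox", "Detection", "iou"]


@dataclass(frozen=True)
class BBox:
    class_id: int
    x: float
    y: float
    w: float
    h: float

    def __post_init__(self):
        if self.w <= 0 or self.h <= 0:
            raise ValueError(f"box extents must be positive, got w={self.w}, h={self.h}")

    @property
    def x2(self) -> float:
        return self.x + self.w

    @property
    def y2(self) -> float:
        return self.y + self.h

    @property
    def center(self) -> tuple[float, float]:
        return (self.x + self.w / 2.0, self.y + self.h / 2.0)

    @property
    def area(self) -> float:
        return self.w * self.h

    def shifted(self, dx: float, dy: float) -> "BBox":
        return BBox(self.class_id, self.x + dx, self.y + dy, self.w, self.h)

    def scaled(self, s: float) -> "BBox":
        return BBox(self.class_id, self.x * s, self.y * s, self.w * s, self.h * s)


@dataclass(frozen=True)
class Detection:
    bbox: BBox
    confidence: float

    def __post_init__(self):
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence must lie in [0, 1], got {self.confidence}")


def iou(a: BBox, b: BBox) -> float:
    """Intersection-over-union of two boxes."""
    ix = min(a.x2, b.x2) - max(a.x, b.x)
    iy = min(a.y2, b.y2) - max(a.y, b.y)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    return inter / (a.area + b.area - inter)
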