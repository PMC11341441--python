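"""Anti-aliased down-scaling of annotated images.

Pixels are resampled with an area-averaging (box) filter, which smooths
the result and avoids aliasing ("jagged") artefacts when shrinking; boxes
are scaled by the same factor and rounded outward, so e.g. a 130-px box
scaled by 31/130 becomes exactly 31 px.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
from PIL import Image

from ..boxes import BBox
from .annotations import AnnotatedImage

__all__ = ["downscale_image", "downscale_dataset"]


def downscale_image(img: AnnotatedImage, scale: float) -> AnnotatedImage:
    if not 0.0 < scale < 1.0:
        raise ValueError("scale must lie in (0, 1)")
    new_w = max(int(round(img.width * scale)), 1)
    new_h = max(int(round(img.height * scale)), 1)
    pixels = None
    if img.pixels is not None:
        pixels = np.asarray(
            Image.fromarray(img.pixels).resize((new_w, new_h), Image.Resampling.BOX)
        )
    boxes = []
    for b in img.boxes:
        x1 = math.floor(b.x * scale)
        y1 = math.floor(b.y * scale)
        x2 = math.ceil((b.x + b.w) * scale)
        y2 = math.ceil((b.y + b.h) * scale)
        w, h = x2 - x1, y2 - y1
        if w < 1 or h < 1:
            warnings.warn("box shrank below 1 px; clamping", stacklevel=2)
            w, h = max(w, 1), max(h, 1)
        x1 = min(max(x1, 0), new_w - w)
        y1 = min(max(y1, 0), new_h - h)
        boxes.append(BBox(b.class_id, x1, y1, w, h))
    return AnnotatedImage(
        image_id=f"{img.image_id}_s{scale:g}", width=new_w, height=new_h,
        boxes=boxes, pixels=pixels, class_names=img.class_names,
        source={"parent": img.image_id, "scale": scale},
    ).validate()


def downscale_dataset(imgs, scale: float) -> list:
    return [downscale_image(img, scale) for img in imgs]
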