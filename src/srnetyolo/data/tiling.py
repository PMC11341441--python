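"""Overlapping-tile dataset preparation.

Large trap photographs are cut into fixed-size tiles with a 40-px overlap
between neighbours; because no labelled pest exceeds 40 px per side, every
object appears whole in at least one tile.  Tile origins advance at stride
``tile_size - overlap`` and the last origin on each axis is clamped so the
final tile ends exactly at the image edge.  A box belongs to a tile iff it
is fully contained in it (straddling boxes are dropped from that tile, not
clipped); boxes falling in several overlapping tiles are kept in each.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from ..boxes import BBox
from .annotations import AnnotatedImage

__all__ = ["Tile", "tile_origins", "tile_image"]


@dataclass
class Tile:
    parent_id: str
    origin: tuple[int, int]          # (x0, y0) in parent pixels
    image: AnnotatedImage            # tile-frame pixels and remapped boxes

    @property
    def tile_id(self) -> str:
        return f"{self.parent_id}_x{self.origin[0]}_y{self.origin[1]}"


def tile_origins(size: int, tile: int, stride: int) -> list[int]:
    """Axis origins at the given stride, last one clamped to the edge."""
    if size <= tile:
        return [0]
    starts, pos = [], 0
    while pos + tile < size:
        starts.append(pos)
        pos += stride
    starts.append(size - tile)
    return starts


def tile_image(img: AnnotatedImage, tile_size: int = 640, overlap: int = 40) -> list[Tile]:
    """Cut an annotated image into overlapping tiles with remapped boxes."""
    if overlap >= tile_size:
        raise ValueError("overlap must be smaller than tile_size")
    img.validate()
    big = [b for b in img.boxes if b.w > overlap or b.h > overlap]
    if big:
        warnings.warn(
            f"{len(big)} box(es) exceed the {overlap}-px overlap; they may be "
            "lost at tile boundaries", stacklevel=2)
    if img.width < tile_size or img.height < tile_size:
        warnings.warn(
            f"image {img.width}x{img.height} smaller than tile {tile_size}; "
            "emitting a single clamped tile", stacklevel=2)
    stride = tile_size - overlap
    xs = tile_origins(img.width, tile_size, stride)
    ys = tile_origins(img.height, tile_size, stride)
    tiles = []
    for y0 in ys:
        for x0 in xs:
            tw = min(tile_size, img.width)
            th = min(tile_size, img.height)
            boxes = [
                b.shifted(-x0, -y0)
                for b in img.boxes
                if b.x >= x0 and b.y >= y0 and b.x + b.w <= x0 + tw and b.y + b.h <= y0 + th
            ]
            pixels = None
            if img.pixels is not None:
                pixels = img.pixels[y0 : y0 + th, x0 : x0 + tw]
            sub = AnnotatedImage(
                image_id=f"{img.image_id}_x{x0}_y{y0}",
                width=tw, height=th, boxes=boxes, pixels=pixels,
                class_names=img.class_names,
                source={"parent": img.image_id, "x0": x0, "y0": y0},
            ).validate()
            tiles.append(Tile(parent_id=img.image_id, origin=(x0, y0), image=sub))
    return tiles
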