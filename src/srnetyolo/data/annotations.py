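"""Annotated images and Pascal-VOC / YOLO annotation I/O.

Internally boxes are 0-based half-open pixel rectangles.  Pascal-VOC XML
uses 1-based inclusive corners (LabelImg convention); the conversion
happens only at the file boundary:

    x = xmin - 1,  w = xmax - xmin + 1        (read)
    xmin = x + 1,  xmax = x + w               (write)

YOLO text rows are ``class cx cy w h`` normalised to [0, 1] by the image
size.
"""

from __future__ import annotations

import os
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field

import numpy as np
from PIL import Image

from ..boxes import BBox

__all__ = ["AnnotatedImage", "read_voc_xml", "write_voc_xml",
           "read_yolo_txt", "write_yolo_txt", "ParseError"]


class ParseError(ValueError):
    """Malformed or inconsistent annotation file."""


@dataclass
class AnnotatedImage:
    image_id: str
    width: int
    height: int
    boxes: list = field(default_factory=list)
    pixels: np.ndarray | None = None  # (H, W, 3) uint8 RGB
    class_names: tuple = ("cotton_thrips", "myzus_persicae")
    source: dict = field(default_factory=dict)

    def validate(self):
        if self.pixels is not None and self.pixels.shape[:2] != (self.height, self.width):
            raise ValueError("pixel array inconsistent with declared size")
        for b in self.boxes:
            if b.x < 0 or b.y < 0 or b.x + b.w > self.width or b.y + b.h > self.height:
                raise ValueError(
                    f"box {b} outside image bounds {self.width}x{self.height}"
                )
            if not 0 <= b.class_id < len(self.class_names):
                raise ValueError(f"class id {b.class_id} outside label set")
        return self

    def save_image(self, path: str):
        if self.pixels is None:
            raise ValueError("no pixel data to save")
        Image.fromarray(self.pixels).save(path)


def _req(node, tag, path):
    child = node.find(tag)
    if child is None or child.text is None:
        raise ParseError(f"{path}: missing <{tag}> element")
    return child.text


def read_voc_xml(path: str, load_image: bool = True,
                 class_names: tuple | None = None) -> AnnotatedImage:
    """Read a LabelImg-style Pascal-VOC annotation file.

    ``class_names`` fixes the label vocabulary (unknown names are an
    error); when omitted the sorted set of names in the file is used.
    The image referenced by ``<filename>`` is loaded from the same
    directory when present and ``load_image`` is true.
    """
    try:
        tree = ET.parse(path)
    except ET.ParseError as e:
        raise ParseError(f"{path}: not well-formed XML ({e})") from e
    root = tree.getroot()
    size = root.find("size")
    if size is None:
        raise ParseError(f"{path}: missing <size> element")
    width = int(_req(size, "width", path))
    height = int(_req(size, "height", path))
    filename = root.findtext("filename", default="")
    image_id = os.path.splitext(filename or os.path.basename(path))[0]

    if class_names is not None:
        names = list(class_names)
    else:
        seen = {_req(obj, "name", path) for obj in root.iter("object")}
        names = sorted(seen)
    boxes = []
    for obj in root.iter("object"):
        name = _req(obj, "name", path)
        if name not in names:
            raise ParseError(f"{path}: label {name!r} not in class vocabulary {names}")
        bnd = obj.find("bndbox")
        if bnd is None:
            raise ParseError(f"{path}: object without <bndbox>")
        xmin = float(_req(bnd, "xmin", path))
        ymin = float(_req(bnd, "ymin", path))
        xmax = float(_req(bnd, "xmax", path))
        ymax = float(_req(bnd, "ymax", path))
        if xmax < xmin or ymax < ymin:
            raise ParseError(f"{path}: inverted box corners")
        if xmax > width or ymax > height or xmin < 1 or ymin < 1:
            raise ParseError(
                f"{path}: box ({xmin},{ymin},{xmax},{ymax}) outside image "
                f"{width}x{height}"
            )
        boxes.append(BBox(names.index(name), xmin - 1, ymin - 1,
                          xmax - xmin + 1, ymax - ymin + 1))

    pixels = None
    if load_image and filename:
        img_path = os.path.join(os.path.dirname(path), filename)
        if os.path.exists(img_path):
            pixels = np.asarray(Image.open(img_path).convert("RGB"))
    return AnnotatedImage(image_id=image_id, width=width, height=height,
                          boxes=boxes, pixels=pixels,
                          class_names=tuple(names) or ("cotton_thrips", "myzus_persicae"),
                          source={"xml": str(path)})


def write_voc_xml(img: AnnotatedImage, path: str, image_filename: str | None = None):
    """Write a Pascal-VOC XML annotation (lossless round trip)."""
    img.validate()
    root = ET.Element("annotation")
    ET.SubElement(root, "folder").text = os.path.basename(os.path.dirname(path)) or "."
    ET.SubElement(root, "filename").text = image_filename or f"{img.image_id}.png"
    size = ET.SubElement(root, "size")
    ET.SubElement(size, "width").text = str(img.width)
    ET.SubElement(size, "height").text = str(img.height)
    ET.SubElement(size, "depth").text = "3"
    for b in img.boxes:
        obj = ET.SubElement(root, "object")
        ET.SubElement(obj, "name").text = img.class_names[b.class_id]
        ET.SubElement(obj, "difficult").text = "0"
        bnd = ET.SubElement(obj, "bndbox")
        ET.SubElement(bnd, "xmin").text = str(int(round(b.x)) + 1)
        ET.SubElement(bnd, "ymin").text = str(int(round(b.y)) + 1)
        ET.SubElement(bnd, "xmax").text = str(int(round(b.x + b.w)))
        ET.SubElement(bnd, "ymax").text = str(int(round(b.y + b.h)))
    ET.indent(tree := ET.ElementTree(root))
    tree.write(path, encoding="unicode")


def write_yolo_txt(img: AnnotatedImage, path: str):
    """Write normalised ``class cx cy w h`` rows."""
    img.validate()
    lines = []
    for b in img.boxes:
        cx = (b.x + b.w / 2) / img.width
        cy = (b.y + b.h / 2) / img.height
        w, h = b.w / img.width, b.h / img.height
        for v in (cx, cy, w, h):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"normalised value {v} outside [0, 1]")
        lines.append(f"{b.class_id} {cx:.6f} {cy:.6f} {w:.6f} {h:.6f}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + ("\n" if lines else ""))


def read_yolo_txt(path: str, width: int, height: int) -> list:
    """Read YOLO rows back into pixel-space boxes."""
    boxes = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 5:
                raise ParseError(f"{path}:{ln}: expected 5 fields, got {len(parts)}")
            cid = int(parts[0])
            cx, cy, w, h = (float(v) for v in parts[1:])
            for v in (cx, cy, w, h):
                if not 0.0 <= v <= 1.0:
                    raise ParseError(f"{path}:{ln}: value {v} outside [0, 1]")
            boxes.append(BBox(cid, (cx - w / 2) * width, (cy - h / 2) * height,
                              w * width, h * height))
    return boxes
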