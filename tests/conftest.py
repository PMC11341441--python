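import numpy as np
import pytest

from srnetyolo.boxes import BBox
from srnetyolo.data.annotations import AnnotatedImage


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_annotated(width=1280, height=1280, boxes=(), image_id="fixture",
                   with_pixels=False, class_names=("cotton_thrips", "myzus_persicae")):
    pixels = None
    if with_pixels:
        r = np.random.default_rng(0)
        pixels = r.integers(0, 255, size=(height, width, 3), dtype=np.uint8)
    return AnnotatedImage(image_id=image_id, width=width, height=height,
                          boxes=list(boxes), pixels=pixels, class_names=class_names)


def random_boxes(rng, n, width, height, max_side=40, min_side=4, n_classes=2):
    out = []
    for _ in range(n):
        w = int(rng.integers(min_side, max_side + 1))
        h = int(rng.integers(min_side, max_side + 1))
        x = int(rng.integers(0, width - w + 1))
        y = int(rng.integers(0, height - h + 1))
        out.append(BBox(int(rng.integers(n_classes)), x, y, w, h))
    return out
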