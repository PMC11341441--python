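"""Size-stratified test-set construction.

From a pool of annotated tiles: test A keeps everything; test B keeps the
tiles whose every pest is tiny (both sides <= 32 px); test C keeps those
whose every pest is very tiny (both sides <= 16 px).  By construction
C is a subset of B is a subset of A.  Tiles without any pest are excluded
from B and C (they carry no size evidence).
"""

from __future__ import annotations

from .sizes import is_tiny, is_very_tiny

__all__ = ["build_size_testsets"]


def _images(tiles):
    # accept both Tile objects and bare AnnotatedImages
    return [(t, getattr(t, "image", t)) for t in tiles]


def build_size_testsets(tiles):
    """Return (test_a, test_b, test_c) tile lists."""
    test_a, test_b, test_c = [], [], []
    for tile, img in _images(tiles):
        test_a.append(tile)
        if img.boxes and all(is_tiny(b) for b in img.boxes):
            test_b.append(tile)
        if img.boxes and all(is_very_tiny(b) for b in img.boxes):
            test_c.append(tile)
    return test_a, test_b, test_c
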