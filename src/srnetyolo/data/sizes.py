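"""Pixel-size classes for pest objects.

A pest is *very tiny* when both box sides are at most 16 px, *tiny* when
both sides are at most 32 px (so every very-tiny pest is also tiny), and
*large* otherwise.  Boundaries are inclusive.  For stratified reporting
the three labels partition a box set: very_tiny, tiny-but-not-very-tiny,
large.
"""

from __future__ import annotations

import enum

from ..boxes import BBox

__all__ = ["SizeClass", "size_class", "VERY_TINY_MAX", "TINY_MAX"]

VERY_TINY_MAX = 16.0
TINY_MAX = 32.0


class SizeClass(enum.Enum):
    very_tiny = "very_tiny"
    tiny = "tiny"          # tiny but not very tiny (partition label)
    large = "large"


def size_class(box: BBox) -> SizeClass:
    """Classify a box by its pixel extents (both-sides rule, inclusive)."""
    if box.w <= VERY_TINY_MAX and box.h <= VERY_TINY_MAX:
        return SizeClass.very_tiny
    if box.w <= TINY_MAX and box.h <= TINY_MAX:
        return SizeClass.tiny
    return SizeClass.large


def is_tiny(box: BBox) -> bool:
    """Tiny in the inclusive sense: both sides <= 32 px (contains very tiny)."""
    return box.w <= TINY_MAX and box.h <= TINY_MAX


def is_very_tiny(box: BBox) -> bool:
    return box.w <= VERY_TINY_MAX and box.h <= VERY_TINY_MAX
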