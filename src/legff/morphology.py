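"""Flat-disk grayscale erosion and dilation.

These produce the local minimum and local maximum maps that serve as
guidance images for the extreme-map guided filter.  Borders are handled by
edge replication, which for flat structuring elements is equivalent to
taking the min/max over the in-bounds part of the footprint and avoids the
spurious border extrema that constant padding would introduce.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .core import StructuringElement, as_image


def make_disk(k: int) -> StructuringElement:
    """Closed-disk footprint of radius ``k``: (di, dj) in iff di^2+dj^2 <= k^2."""
    k = int(k)
    if k < 1:
        raise ValueError(f"disk radius must be >= 1, got {k}")
    coords = np.arange(-k, k + 1)
    dj, di = np.meshgrid(coords, coords)
    return StructuringElement(radius=k, footprint=(di * di + dj * dj) <= k * k)


def erode(img, se: StructuringElement) -> np.ndarray:
    """Local minimum map: per-pixel min over the disk footprint (replicated edges)."""
    img = as_image(img)
    return ndimage.grey_erosion(img, footprint=se.footprint, mode="nearest")


def dilate(img, se: StructuringElement) -> np.ndarray:
    """Local maximum map: per-pixel max over the disk footprint (replicated edges)."""
    img = as_image(img)
    return ndimage.grey_dilation(img, footprint=se.footprint, mode="nearest")
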