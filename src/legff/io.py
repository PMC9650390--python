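"""Image reading and writing (PNG/TIFF/JPEG in, PNG/TIFF out).

Everything is converted to float64 on the 0-255 scale at load: 8-bit data
is used as-is, 16-bit data is linearly rescaled by 255/65535 (with a
logged note), and color images keep their three channels.  Writing an
8-bit image back without processing is byte-identical.
"""

from __future__ import annotations

import logging
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .fusion import to_uint8

logger = logging.getLogger(__name__)


def load_image(path) -> np.ndarray:
    """Load an image as float64 on the 0-255 scale (2-D gray or H x W x 3 color)."""
    arr = iio.imread(Path(path))
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    if arr.ndim == 3 and arr.shape[2] == 1:
        arr = arr[:, :, 0]
    if arr.ndim not in (2, 3):
        raise ValueError(f"unsupported image dimensionality {arr.shape} in {path}")
    img = arr.astype(np.float64)
    if arr.dtype == np.uint16:
        logger.info("rescaling 16-bit image %s to the 0-255 scale", path)
        img *= 255.0 / 65535.0
    elif arr.dtype != np.uint8:
        # floats or exotic integer types: normalize only if out of range
        if img.max() > 255.0 or img.min() < 0.0:
            raise ValueError(f"cannot interpret intensity range of {path} (dtype {arr.dtype})")
    return img


def is_color(img: np.ndarray) -> bool:
    """True for an H x W x 3 image whose channels actually differ."""
    return img.ndim == 3


def save_image(path, img) -> None:
    """Clip/round to 8 bits and write PNG or TIFF based on the file suffix."""
    path = Path(path)
    if path.suffix.lower() not in (".png", ".tif", ".tiff"):
        raise ValueError(f"output format {path.suffix!r} not supported (use PNG or TIFF)")
    iio.imwrite(path, to_uint8(img))
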