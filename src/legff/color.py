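"""Color protocol for fusing a pseudo-color image with a grayscale one.

Functional modalities (PET/SPECT-like) are pseudo-colored; their anatomy
lives in the luminance channel while the color encodes activity.  The
protocol converts the color image to YCbCr, fuses its Y channel with the
grayscale image, and reassembles RGB from the fused luminance and the
*original* chroma channels, so the color coding is preserved untouched.

The conversion is full-range BT.601 (no 16-235 footroom/headroom), pinned
in one constant matrix and exactly invertible over [0, 255] up to
rounding.
"""

from __future__ import annotations

import numpy as np

from .core import FusionConfig, validate_pair
from .fusion import fuse_pair

# Full-range BT.601 luma coefficients and chroma scale factors.
_KR, _KG, _KB = 0.299, 0.587, 0.114
_CB_SCALE = 0.564  # = 0.5 / (1 - Kb)
_CR_SCALE = 0.713  # = 0.5 / (1 - Kr)


def _as_rgb(img) -> np.ndarray:
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected an H x W x 3 color image, got shape {arr.shape}")
    return arr


def rgb_to_ycbcr(img) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split an RGB image (0-255) into full-range BT.601 Y, Cb, Cr planes."""
    rgb = _as_rgb(img)
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    y = _KR * r + _KG * g + _KB * b
    cb = 128.0 + (b - y) * _CB_SCALE
    cr = 128.0 + (r - y) * _CR_SCALE
    return y, cb, cr


def ycbcr_to_rgb(y, cb, cr) -> np.ndarray:
    """Inverse BT.601 conversion; output clipped to [0, 255]."""
    y, cb = validate_pair(y, cb)
    y, cr = validate_pair(y, cr)
    r = y + (cr - 128.0) / _CR_SCALE
    b = y + (cb - 128.0) / _CB_SCALE
    g = (y - _KR * r - _KB * b) / _KG
    return np.clip(np.stack([r, g, b], axis=-1), 0.0, 255.0)


def fuse_color_gray(color_img, gray_img, cfg: FusionConfig | None = None) -> np.ndarray:
    """Fuse a pseudo-color image with a grayscale image via the luminance channel.

    Returns an H x W x 3 float image in [0, 255]; the chroma planes are the
    source color image's Cb/Cr bit-for-bit (before the final RGB transform).
    """
    y, cb, cr = rgb_to_ycbcr(color_img)
    y_fused = fuse_pair(y, gray_img, cfg)
    return ycbcr_to_rgb(np.clip(y_fused, 0.0, 255.0), cb, cr)
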