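"""He-style guided filter with an arbitrary guidance image.

Within every r x r window the filter fits a local linear model
q = a * I_g + b between the guidance I_g and the input p:

    a_k = cov(I_g, p)_k / (var(I_g)_k + eps)
    b_k = mean(p)_k - a_k * mean(I_g)_k

and the output at each pixel averages (a, b) over all windows covering it.
``r`` is the full window side length (an r x r window), so the schedule
[3, 5, 7, 9, 11] means 3x3 ... 11x11 windows.  Box means near the border
divide by the in-bounds pixel count, matching the original reference
implementation.  Intensities are divided by 255 before the fit so that
``eps`` lives on the conventional 0-1 scale; the output is returned on the
0-255 scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import correlate1d

from .core import as_image, validate_pair


@dataclass(frozen=True)
class GuidedFilterParams:
    """Window side length (odd, >= 3) and regularization of the guided filter."""

    window_size: int
    epsilon: float

    def __post_init__(self):
        if self.window_size < 3 or self.window_size % 2 == 0:
            raise ValueError(f"window size must be odd and >= 3, got {self.window_size}")
        if self.epsilon < 0:
            raise ValueError(f"epsilon must be nonnegative, got {self.epsilon}")


def _box_sum(img: np.ndarray, r: int) -> np.ndarray:
    """Sum over the r x r window centered at each pixel, zero outside the image."""
    w = np.ones(r)
    out = correlate1d(img, w, axis=0, mode="constant", cval=0.0)
    return correlate1d(out, w, axis=1, mode="constant", cval=0.0)


def _box_count(shape: tuple[int, int], r: int) -> np.ndarray:
    return _box_sum(np.ones(shape), r)


def box_mean(img, r: int) -> np.ndarray:
    """Border-aware box mean: average over the r x r window clipped to the image."""
    img = as_image(img)
    r = int(r)
    if r < 1 or r % 2 == 0:
        raise ValueError(f"box window size must be odd and positive, got {r}")
    return _box_sum(img, r) / _box_count(img.shape, r)


def guided_filter(input_p, guidance_i, params: GuidedFilterParams) -> np.ndarray:
    """Smooth ``input_p`` under the guidance of ``guidance_i``.

    Both images are on the 0-255 scale; so is the output.  Windows of
    exactly zero guidance variance with ``eps == 0`` fall back to the
    limit convention a = 0, b = window mean.
    """
    p, i = validate_pair(input_p, guidance_i)
    r, eps = params.window_size, params.epsilon

    p = p / 255.0
    i = i / 255.0
    n = _box_count(p.shape, r)

    mean_i = _box_sum(i, r) / n
    mean_p = _box_sum(p, r) / n
    corr_ip = _box_sum(i * p, r) / n
    corr_ii = _box_sum(i * i, r) / n

    var_i = corr_ii - mean_i * mean_i
    cov_ip = corr_ip - mean_i * mean_p

    denom = var_i + eps
    # 0/0 only occurs for eps == 0 on exactly constant windows; define a = 0 there.
    with np.errstate(divide="ignore", invalid="ignore"):
        a = np.where(denom != 0.0, cov_ip / np.where(denom != 0.0, denom, 1.0), 0.0)
    b = mean_p - a * mean_i

    mean_a = _box_sum(a, r) / n
    mean_b = _box_sum(b, r) / n

    return (mean_a * i + mean_b) * 255.0
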