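"""Shared domain types and validation.

All filtering operates on 2-D float64 arrays on the 0-255 intensity scale.
Images loaded from disk are normalized into [0, 255]; intermediate feature
maps are deliberately *not* clipped — dark feature maps are negative and
weighted detail sums may exceed 255.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class ShapeMismatchError(ValueError):
    """Two images that must be co-registered have different shapes."""


class NonFiniteValueError(ValueError):
    """An image contains NaN or infinite intensities."""


def as_image(arr, name: str = "image") -> np.ndarray:
    """Coerce ``arr`` to a validated 2-D float64 image.

    Raises ``ValueError`` for wrong dimensionality and
    ``NonFiniteValueError`` (with the first offending coordinate) for
    NaN/Inf pixels.
    """
    img = np.asarray(arr, dtype=np.float64)
    if img.ndim != 2 or img.shape[0] < 1 or img.shape[1] < 1:
        raise ValueError(f"{name} must be a 2-D array, got shape {img.shape}")
    finite = np.isfinite(img)
    if not finite.all():
        i, j = np.argwhere(~finite)[0]
        raise NonFiniteValueError(
            f"{name} contains a non-finite value at pixel ({i}, {j})"
        )
    return img


def validate_pair(a, b) -> tuple[np.ndarray, np.ndarray]:
    """Validate two co-registered single-channel images.

    Returns the pair as float64 arrays, unchanged otherwise.  Raises
    ``ShapeMismatchError`` naming both shapes when dimensions differ.
    """
    a = as_image(a, "first image")
    b = as_image(b, "second image")
    if a.shape != b.shape:
        raise ShapeMismatchError(
            f"images must have identical dimensions, got {a.shape} vs {b.shape}"
        )
    return a, b


@dataclass(frozen=True)
class StructuringElement:
    """Flat disk footprint used for the local min/max (erosion/dilation) maps.

    The footprint is the closed disk: cell (di, dj) is included iff
    di**2 + dj**2 <= radius**2, giving a (2k+1) x (2k+1) boolean mask that
    is symmetric under 180-degree rotation with a true center.
    """

    radius: int
    footprint: np.ndarray

    def __post_init__(self):
        if self.radius < 1:
            raise ValueError(f"structuring element radius must be >= 1, got {self.radius}")


def default_window_sizes(n_scales: int) -> list[int]:
    """Window-size schedule r_i = 2*i + 1 for i = 1..n (so n=5 -> [3,5,7,9,11])."""
    return [2 * i + 1 for i in range(1, n_scales + 1)]


@dataclass(frozen=True)
class FusionConfig:
    """Parameters of the multi-scale fusion pipeline.

    Attributes
    ----------
    n_scales:
        Number of filtering scales n (default 5).
    window_sizes:
        Guided-filter window side lengths r_1..r_n; default r_i = 2*i + 1.
    disk_radii:
        Structuring-element radii k_1..k_n; default k_i = r_i.
    gf_epsilon:
        Guided-filter regularization, applied on intensities divided
        by 255 (the usual 0-1 convention for He-style filters).
    entropy_bins:
        Histogram bins used by the entropy-based detail weights.
    enhance_weights:
        If False, all detail weights are forced to 1 (no enhancement);
        useful for ablations and exact self-fusion checks.
    """

    n_scales: int = 5
    window_sizes: tuple[int, ...] = None  # type: ignore[assignment]
    disk_radii: tuple[int, ...] = None  # type: ignore[assignment]
    gf_epsilon: float = 0.01
    entropy_bins: int = 256
    enhance_weights: bool = True

    def __post_init__(self):
        if self.n_scales < 1:
            raise ValueError("n_scales must be >= 1")
        if self.window_sizes is None:
            object.__setattr__(
                self, "window_sizes", tuple(default_window_sizes(self.n_scales))
            )
        else:
            object.__setattr__(self, "window_sizes", tuple(self.window_sizes))
        if self.disk_radii is None:
            object.__setattr__(self, "disk_radii", tuple(self.window_sizes))
        else:
            object.__setattr__(self, "disk_radii", tuple(self.disk_radii))
        if len(self.window_sizes) != self.n_scales or len(self.disk_radii) != self.n_scales:
            raise ValueError(
                "window_sizes and disk_radii must each list one value per scale "
                f"(n_scales={self.n_scales}, got {len(self.window_sizes)} window "
                f"sizes and {len(self.disk_radii)} disk radii)"
            )
        if any(r < 3 or r % 2 == 0 for r in self.window_sizes):
            raise ValueError(f"window sizes must be odd and >= 3, got {self.window_sizes}")
        if any(k < 1 for k in self.disk_radii):
            raise ValueError(f"disk radii must be >= 1, got {self.disk_radii}")
        if self.gf_epsilon < 0:
            raise ValueError("gf_epsilon must be nonnegative")
        if self.entropy_bins < 1:
            raise ValueError("entropy_bins must be >= 1")


@dataclass
class ScaleDecomposition:
    """Per-source multi-scale stack of detail layers plus the base image.

    ``bright_maps[i]`` is everywhere >= 0, ``dark_maps[i]`` everywhere <= 0,
    and at every pixel and scale at most one of the two is nonzero.  The
    stack telescopes: sum of all bright and dark maps plus ``base``
    reconstructs the input exactly (to float tolerance).
    """

    bright_maps: list[np.ndarray]
    dark_maps: list[np.ndarray]
    base: np.ndarray

    @property
    def n_scales(self) -> int:
        return len(self.bright_maps)

    def reconstruct(self) -> np.ndarray:
        """Sum all detail layers and the base back into the original image."""
        out = self.base.copy()
        for b, d in zip(self.bright_maps, self.dark_maps):
            out += b + d
        return out


@dataclass(frozen=True)
class MetricReport:
    """No-reference quality scores of a (fused) image.

    SF: spatial frequency; AbG: average absolute gradient; STD: population
    standard deviation; E: Shannon entropy in bits.  Keys for
    reference-based scores (PS, QCB, VIFF, Qabf, QGS, WSSIM, MSSIM) are
    reserved in the serialized schema for a future extension.
    """

    SF: float
    AbG: float
    STD: float
    E: float
    extras: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {"SF": self.SF, "AbG": self.AbG, "STD": self.STD, "E": self.E}
        d.update(self.extras)
        return d
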