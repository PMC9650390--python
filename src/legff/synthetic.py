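"""Seeded phantom-pair generators emulating multi-modal brain image pairs.

Every generator is deterministic under its seed and returns ground-truth
masks alongside the image, so downstream tests can make detector-style
assertions (e.g., "the fused image keeps the lesion that only the
MR-like source carries") without any external data.

The phantoms are stylized, not anatomical: a CT-like image is a bright
elliptical "skull" annulus around a flat dim interior, an MR-like image
is a textured soft-tissue interior with bright and dark lesions at known
loci inside a faint rim, and a PET-like image is a smooth pseudo-color
activity map.  Noise in the CT-like phantom is confined to the skull and
the exterior air: the soft-tissue interior is rendered flat, emulating
the featurelessness of brain parenchyma at a bone window, which also
gives tests an exact handle on what the CT contributes inside the skull
(nothing).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

MIN_SIZE = 32

#: Shared head geometry (fractions of the image size): ellipse semi-axes
#: and the inner edge of the skull annulus, so CT-like and MR-like
#: phantoms of the same size are co-registered by construction.
_RX, _RY, _INNER = 0.40, 0.45, 0.86


@dataclass
class Phantom:
    """A synthetic image plus its ground-truth region masks."""

    image: np.ndarray
    masks: dict[str, np.ndarray] = field(default_factory=dict)


def _check_size(size: int) -> int:
    size = int(size)
    if size < MIN_SIZE:
        raise ValueError(f"phantom size must be >= {MIN_SIZE}, got {size}")
    return size


def _head_geometry(size: int) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Radial coordinate of the head ellipse and the three head regions."""
    c = (size - 1) / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    f = np.sqrt(((xx - c) / (_RX * size)) ** 2 + ((yy - c) / (_RY * size)) ** 2)
    interior = f <= _INNER
    annulus = (f > _INNER) & (f <= 1.0)
    exterior = f > 1.0
    return f, interior, annulus, exterior


def _bounded_noise(rng: np.random.Generator, shape, sigma: float, bound: float) -> np.ndarray:
    return np.clip(rng.normal(0.0, sigma, size=shape), -bound, bound)


def make_ct_like(size: int = 256, seed: int = 0) -> Phantom:
    """CT-like phantom: bright skull annulus, flat dim interior, dark air.

    Annulus pixels stay >= 200 and the interior is uniform at 60; mild
    seeded noise is applied to the annulus and exterior only (see module
    docstring).
    """
    size = _check_size(size)
    rng = np.random.default_rng(seed)
    _, interior, annulus, exterior = _head_geometry(size)

    img = np.full((size, size), 60.0)
    img[exterior] = 5.0
    img[annulus] = 225.0
    noise = _bounded_noise(rng, (size, size), sigma=2.0, bound=6.0)
    img[~interior] += noise[~interior]
    np.clip(img, 0.0, 255.0, out=img)
    return Phantom(image=img, masks={"skull": annulus, "interior": interior, "exterior": exterior})


def _lesion_mask(size: int, centers: list[tuple[float, float]], radius: float) -> np.ndarray:
    c = (size - 1) / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    mask = np.zeros((size, size), dtype=bool)
    r = radius * size
    for dy, dx in centers:
        mask |= ((xx - (c + dx * size)) ** 2 + (yy - (c + dy * size)) ** 2) <= r * r
    return mask


# Lesion loci (offsets from center, fractions of size), kept well inside
# the skull so lesion neighborhoods are pure soft tissue.
_BRIGHT_LESIONS = [(-0.10, 0.08), (0.12, -0.05)]
_DARK_LESIONS = [(0.02, 0.16), (-0.14, -0.12)]
_LESION_RADIUS = 0.035
_LESION_CONTRAST = 60.0


def make_mr_like(size: int = 256, seed: int = 0) -> Phantom:
    """MR-like phantom: textured soft tissue, known lesions, faint rim.

    Bright (dark) lesion pixels sit 60 levels above (below) the local
    tissue field, so even after the bounded texture noise they differ
    from their immediate surroundings by well over 40 levels.
    """
    size = _check_size(size)
    rng = np.random.default_rng(seed)
    _, interior, annulus, exterior = _head_geometry(size)

    # Band-limited tissue texture: smoothed white noise plus broad blobs.
    blobs = gaussian_filter(rng.normal(0.0, 1.0, (size, size)), sigma=size / 16.0)
    blobs *= 12.0 / max(blobs.std(), 1e-12)
    texture = _bounded_noise(rng, (size, size), sigma=1.5, bound=4.0)

    img = np.full((size, size), 2.0)
    img[annulus] = 40.0  # faint rim where the skull sits
    img[interior] = 100.0 + np.clip(blobs[interior], -25.0, 25.0)

    bright = _lesion_mask(size, _BRIGHT_LESIONS, _LESION_RADIUS) & interior
    dark = _lesion_mask(size, _DARK_LESIONS, _LESION_RADIUS) & interior
    img[bright] += _LESION_CONTRAST
    img[dark] -= _LESION_CONTRAST
    img += texture
    np.clip(img, 0.0, 255.0, out=img)

    return Phantom(
        image=img,
        masks={
            "bright_lesions": bright,
            "dark_lesions": dark,
            "rim": annulus,
            "interior": interior,
        },
    )


# Blob centers are kept far enough apart (relative to their Gaussian
# widths) that one blob's tail cannot wash out the other's chroma.
_PET_BLOBS = [
    ((-0.10, -0.08), 0.09, (210.0, 70.0, 35.0)),
    ((0.14, 0.12), 0.07, (60.0, 90.0, 200.0)),
]


def make_pet_like(size: int = 256, seed: int = 0) -> Phantom:
    """PET-like phantom: smooth pseudo-color activity blobs on a neutral gray.

    The background noise is shared across channels, so chroma is exactly
    neutral off the blobs and strongly non-neutral (|Cb-128| or |Cr-128|
    >= 20) on the blob masks.
    """
    size = _check_size(size)
    rng = np.random.default_rng(seed)
    c = (size - 1) / 2.0
    yy, xx = np.mgrid[0:size, 0:size]

    gray = 45.0 + _bounded_noise(rng, (size, size), sigma=1.5, bound=4.0)
    img = np.repeat(gray[:, :, None], 3, axis=2)
    blob_mask = np.zeros((size, size), dtype=bool)
    for (dy, dx), sig, color in _PET_BLOBS:
        d2 = (xx - (c + dx * size)) ** 2 + (yy - (c + dy * size)) ** 2
        w = np.exp(-d2 / (2.0 * (sig * size) ** 2))
        img = img * (1.0 - w[:, :, None]) + w[:, :, None] * np.asarray(color)
        blob_mask |= w > 0.5
    return Phantom(image=np.clip(img, 0.0, 255.0), masks={"blobs": blob_mask})


def random_image(size: int, seed: int, low: float = 0.0, high: float = 255.0) -> np.ndarray:
    """Uniform random test image on [low, high]; handy for oracle comparisons."""
    rng = np.random.default_rng(seed)
    return rng.uniform(low, high, size=(size, size))
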