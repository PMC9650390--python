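"""Fusion of two multi-scale decompositions into a single image.

Per scale, bright feature maps are fused by the elementwise maximum and
dark feature maps by the elementwise minimum — high-magnitude detail wins.
The fused per-scale maps are then combined into one bright and one dark
map by an entropy-weighted sum: each scale's weight is its entropy divided
by the smallest entropy across scales, so the least informative scale gets
weight 1 and every other scale is enhanced in proportion to its
information content.  Base images fuse by the elementwise maximum, and the
final image is bright + dark + base.
"""

from __future__ import annotations

import logging

import numpy as np

from .core import FusionConfig, ScaleDecomposition, validate_pair
from .decompose import decompose

logger = logging.getLogger(__name__)


def fuse_feature_scale(b1, b2, d1, d2) -> tuple[np.ndarray, np.ndarray]:
    """Fuse one scale of detail: elementwise max of bright, min of dark maps."""
    b1, b2 = validate_pair(b1, b2)
    d1, d2 = validate_pair(d1, d2)
    return np.maximum(b1, b2), np.minimum(d1, d2)


def shannon_entropy(img, bins: int = 256) -> float:
    """Shannon entropy (bits) of ``img`` quantized to equal-width bins over [0, 255].

    Values above 255 are clipped into the top bin for histogram purposes.
    Negative intensities are rejected; callers negate dark feature maps
    before measuring their entropy.
    """
    img = np.asarray(img, dtype=np.float64)
    if img.min() < 0:
        raise ValueError("entropy is defined on nonnegative maps; negate dark maps first")
    hist, _ = np.histogram(np.minimum(img, 255.0), bins=int(bins), range=(0.0, 255.0))
    p = hist / hist.sum()
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def compute_weights(fused_maps, polarity: str, bins: int = 256) -> list[float]:
    """Entropy-proportional enhancement weights, normalized so min(w) == 1.

    ``polarity`` is "bright" or "dark"; dark maps are negated before the
    entropy is measured.  If the least informative scale has zero entropy
    (blank feature maps) the weights degenerate to all ones.
    """
    if polarity not in ("bright", "dark"):
        raise ValueError(f"polarity must be 'bright' or 'dark', got {polarity!r}")
    sign = -1.0 if polarity == "dark" else 1.0
    entropies = [shannon_entropy(sign * np.asarray(m, dtype=np.float64), bins) for m in fused_maps]
    e_min = min(entropies)
    if e_min == 0.0:
        logger.warning(
            "zero minimum entropy among %s feature maps; enhancement disabled (all weights 1)",
            polarity,
        )
        return [1.0] * len(entropies)
    return [e / e_min for e in entropies]


def integrate_features(fused_maps, weights) -> np.ndarray:
    """Weighted elementwise sum of per-scale fused feature maps."""
    if len(fused_maps) != len(weights):
        raise ValueError(
            f"got {len(fused_maps)} maps but {len(weights)} weights"
        )
    out = np.zeros_like(np.asarray(fused_maps[0], dtype=np.float64))
    for m, w in zip(fused_maps, weights):
        out += float(w) * np.asarray(m, dtype=np.float64)
    return out


def fuse_base(base1, base2) -> np.ndarray:
    """Fuse the low-frequency base images by the elementwise maximum."""
    base1, base2 = validate_pair(base1, base2)
    return np.maximum(base1, base2)


def fuse_decompositions(
    dec1: ScaleDecomposition, dec2: ScaleDecomposition, cfg: FusionConfig
) -> dict:
    """Fuse two decompositions; returns the internals alongside the result.

    The returned dict has keys ``fused`` (unclipped float image),
    ``bright``, ``dark``, ``base`` (the integrated fused components),
    ``bright_maps``/``dark_maps`` (per-scale fused maps) and
    ``bright_weights``/``dark_weights``.
    """
    if dec1.n_scales != dec2.n_scales:
        raise ValueError("decompositions have different scale counts")
    bright_maps, dark_maps = [], []
    for b1, b2, d1, d2 in zip(dec1.bright_maps, dec2.bright_maps, dec1.dark_maps, dec2.dark_maps):
        bf, df = fuse_feature_scale(b1, b2, d1, d2)
        bright_maps.append(bf)
        dark_maps.append(df)

    if cfg.enhance_weights:
        wb = compute_weights(bright_maps, "bright", cfg.entropy_bins)
        wd = compute_weights(dark_maps, "dark", cfg.entropy_bins)
    else:
        wb = [1.0] * len(bright_maps)
        wd = [1.0] * len(dark_maps)

    bright = integrate_features(bright_maps, wb)
    dark = integrate_features(dark_maps, wd)
    base = fuse_base(dec1.base, dec2.base)
    return {
        "fused": bright + dark + base,
        "bright": bright,
        "dark": dark,
        "base": base,
        "bright_maps": bright_maps,
        "dark_maps": dark_maps,
        "bright_weights": wb,
        "dark_weights": wd,
    }


def fuse_pair(img1, img2, cfg: FusionConfig | None = None) -> np.ndarray:
    """Fuse two co-registered grayscale images; returns the unclipped float image.

    Use :func:`to_uint8` to export the result on the 8-bit range.
    """
    img1, img2 = validate_pair(img1, img2)
    cfg = cfg or FusionConfig()
    dec1 = decompose(img1, cfg)
    dec2 = decompose(img2, cfg)
    return fuse_decompositions(dec1, dec2, cfg)["fused"]


def to_uint8(img) -> np.ndarray:
    """Clip to [0, 255] and round half-to-even for 8-bit export."""
    return np.rint(np.clip(np.asarray(img, dtype=np.float64), 0.0, 255.0)).astype(np.uint8)
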