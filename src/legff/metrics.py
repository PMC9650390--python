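"""No-reference image quality scores: SF, AbG, STD and entropy.

These quantify the amount of detail (SF, AbG, STD) and the richness of
the intensity distribution (E) of a fused image; larger is better.  For
color images the scores are evaluated on the luminance channel.

The average-gradient formula varies across the fusion literature; here it
is the mean over interior pixels of sqrt((dx^2 + dy^2) / 2) with forward
differences, which makes scores comparable within this package but not
necessarily to other codebases.
"""

from __future__ import annotations

import json

import numpy as np

from .core import MetricReport, as_image
from .fusion import shannon_entropy

#: Reference-based metric keys reserved in the report schema (not computed).
RESERVED_METRICS = ("PS", "QCB", "VIFF", "Qabf", "QGS", "WSSIM", "MSSIM")


def _require_2x2(img: np.ndarray) -> None:
    if img.shape[0] < 2 or img.shape[1] < 2:
        raise ValueError(f"metric needs an image of at least 2x2 pixels, got {img.shape}")


def spatial_frequency(img) -> float:
    """SF = sqrt(RF^2 + CF^2): RMS horizontal and vertical first differences."""
    img = as_image(img)
    _require_2x2(img)
    rf2 = np.mean(np.diff(img, axis=1) ** 2)
    cf2 = np.mean(np.diff(img, axis=0) ** 2)
    return float(np.sqrt(rf2 + cf2))


def average_gradient(img) -> float:
    """Mean over interior pixels of sqrt((dx^2 + dy^2) / 2), forward differences."""
    img = as_image(img)
    _require_2x2(img)
    dx = img[:-1, 1:] - img[:-1, :-1]
    dy = img[1:, :-1] - img[:-1, :-1]
    return float(np.mean(np.sqrt((dx * dx + dy * dy) / 2.0)))


def std_metric(img) -> float:
    """Population standard deviation of the intensities."""
    return float(np.std(as_image(img)))


def entropy_metric(img, bins: int = 256) -> float:
    """Shannon entropy (bits) of the intensities clipped to [0, 255], 256 bins."""
    img = np.clip(as_image(img), 0.0, 255.0)
    return shannon_entropy(img, bins)


def metric_report(img) -> MetricReport:
    """All four no-reference scores of one grayscale image."""
    img = as_image(img)
    return MetricReport(
        SF=spatial_frequency(img),
        AbG=average_gradient(img),
        STD=std_metric(img),
        E=entropy_metric(img),
    )


def report_to_json(report: MetricReport) -> str:
    d = report.as_dict()
    for key in RESERVED_METRICS:
        d.setdefault(key, None)
    return json.dumps(d, indent=2)


def report_to_tsv(report: MetricReport) -> str:
    d = report.as_dict()
    return "\n".join(f"{k}\t{v:.6f}" for k, v in d.items()) + "\n"
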