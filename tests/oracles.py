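"""Independent brute-force reference implementations used only by tests.

Everything here is written as literal per-pixel loops over window
definitions, deliberately sharing no code with the package internals.
"""

from __future__ import annotations

import numpy as np


def disk_cells(k: int) -> list[tuple[int, int]]:
    """All (di, dj) offsets inside the closed disk of radius k, by enumeration."""
    return [
        (di, dj)
        for di in range(-k, k + 1)
        for dj in range(-k, k + 1)
        if di * di + dj * dj <= k * k
    ]


def sliding_extremum(img: np.ndarray, k: int, kind: str) -> np.ndarray:
    """Per-pixel min/max over the disk footprint with edge replication."""
    h, w = img.shape
    fn = np.min if kind == "min" else np.max
    out = np.empty_like(img, dtype=np.float64)
    cells = disk_cells(k)
    for i in range(h):
        for j in range(w):
            vals = [
                img[min(max(i + di, 0), h - 1), min(max(j + dj, 0), w - 1)]
                for di, dj in cells
            ]
            out[i, j] = fn(vals)
    return out


def _window(i: int, j: int, half: int, h: int, w: int) -> tuple[slice, slice]:
    return (
        slice(max(0, i - half), min(h, i + half + 1)),
        slice(max(0, j - half), min(w, j + half + 1)),
    )


def naive_box_mean(img: np.ndarray, r: int) -> np.ndarray:
    """Mean over the r x r window intersected with the image, per-pixel loop."""
    h, w = img.shape
    half = (r - 1) // 2
    out = np.empty((h, w))
    for i in range(h):
        for j in range(w):
            out[i, j] = img[_window(i, j, half, h, w)].mean()
    return out


def naive_guided_filter(p: np.ndarray, g: np.ndarray, r: int, eps: float) -> np.ndarray:
    """Literal windowed least-squares guided filter (0-255 in and out).

    For every window center a linear model q = a*g + b is fitted, then
    each output pixel averages the models of all windows covering it.
    """
    p = np.asarray(p, dtype=np.float64) / 255.0
    g = np.asarray(g, dtype=np.float64) / 255.0
    h, w = p.shape
    half = (r - 1) // 2
    a = np.empty((h, w))
    b = np.empty((h, w))
    for i in range(h):
        for j in range(w):
            win = _window(i, j, half, h, w)
            gw, pw = g[win], p[win]
            mg, mp = gw.mean(), pw.mean()
            cov = (gw * pw).mean() - mg * mp
            var = (gw * gw).mean() - mg * mg
            denom = var + eps
            if denom == 0.0:
                a[i, j] = 0.0
                b[i, j] = mp
            else:
                a[i, j] = cov / denom
                b[i, j] = mp - a[i, j] * mg
    q = np.empty((h, w))
    for i in range(h):
        for j in range(w):
            win = _window(i, j, half, h, w)
            q[i, j] = (a[win] * g[i, j] + b[win]).mean()
    return q * 255.0
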