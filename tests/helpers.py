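"""Shared phantom builders for the test suite."""

from __future__ import annotations

import numpy as np
from scipy.ndimage import distance_transform_edt


def thick_curve(fy, half_len: int, half_width: int, pad: int | None = None) -> np.ndarray:
    """Binary band of half-width ``half_width`` around the curve y = fy(x),
    sampled at integer x in [-half_len, half_len]."""
    pad = pad if pad is not None else half_width + 10
    xs = np.arange(-half_len, half_len + 1)
    ys = fy(xs.astype(float))
    ys = ys - ys.min()
    height = int(np.ceil(ys.max())) + 2 * pad
    width = 2 * half_len + 2 * pad + 1
    center_line = np.zeros((height, width), bool)
    center_line[np.rint(ys).astype(int) + pad, xs + half_len + pad] = True
    return distance_transform_edt(~center_line) <= half_width


def rect_mask(height: int = 41, width: int = 100, pad: int = 10) -> np.ndarray:
    mask = np.zeros((height + 2 * pad, width + 2 * pad), bool)
    mask[pad : pad + height, pad : pad + width] = True
    return mask


def disk_mask(radius: int = 50, pad: int = 5) -> np.ndarray:
    size = 2 * (radius + pad) + 1
    y, x = np.ogrid[:size, :size]
    c = radius + pad
    return (x - c) ** 2 + (y - c) ** 2 <= radius**2


def arc_mask(radius_of_curvature: float = 1000.0, half_len: int = 160, half_width: int = 15) -> np.ndarray:
    """Band around a circular arc of constant curvature 1/radius_of_curvature."""
    r = radius_of_curvature
    return thick_curve(lambda x: r - np.sqrt(r * r - x * x), half_len, half_width)


def random_blob(seed: int, size: int = 120) -> np.ndarray:
    """Connected random blob mask (largest component of smoothed noise)."""
    from scipy import ndimage

    rng = np.random.default_rng(seed)
    field = ndimage.gaussian_filter(rng.standard_normal((size, size)), 8)
    mask = field > np.quantile(field, 0.8)
    labels, n = ndimage.label(mask)
    if n == 0:
        mask[size // 2, size // 2] = True
        return mask
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == int(np.argmax(counts))
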