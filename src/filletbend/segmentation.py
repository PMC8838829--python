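"""Sideview fillet segmentation and region analysis.

The segmentation pipeline applies, in this fixed order:

1. global intensity thresholding,
2. hole filling,
3. median filtering,
4. morphological opening,
5. object size filtering (small isolated objects removed).

If several objects survive, the largest connected component is kept.  The
order matters (filling a holed object before opening is not the same as the
reverse) and is deliberately fixed.

Region properties follow a pixel-as-unit-square convention: a component
spanning rows ``r0..r1`` inclusive has height ``r1 - r0 + 1``, and the
top/bottom box edges sit half a pixel outside the extreme pixel centers, so
that the exact identity ``h = ht + hb`` holds for the centroid split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.measure import perimeter_crofton

from .errors import NoObjectError

#: 4-connected structuring element used for hole filling.
_FILL_STRUCTURE = ndimage.generate_binary_structure(2, 1)
#: 8-connectivity used for labeling.
_LABEL_STRUCTURE = ndimage.generate_binary_structure(2, 2)


@dataclass(frozen=True)
class SegParams:
    global_threshold: int = 60
    median_kernel: int = 3
    opening_radius: int = 2
    min_object_area: int = 500

    def __post_init__(self) -> None:
        if self.median_kernel < 1 or self.median_kernel % 2 == 0:
            raise ValueError("median_kernel must be odd and >= 1")
        if self.min_object_area < 0:
            raise ValueError("min_object_area must be >= 0")


@dataclass
class FilletSegment:
    """Binary mask of one fillet with derived region properties.

    ``bbox`` is (top, left, bottom, right) with exclusive bottom/right, so
    ``bottom - top`` equals the pixel-row extent (= ``max_height``).
    """

    mask: np.ndarray = field(repr=False)
    centroid: tuple[float, float]
    area: int
    perimeter: float
    bbox: tuple[int, int, int, int]
    major_axis_angle: float
    max_height: int
    avg_height: float
    length: int


def _disk(radius: int) -> np.ndarray:
    if radius < 1:
        return np.ones((1, 1), bool)
    y, x = np.ogrid[-radius : radius + 1, -radius : radius + 1]
    return x * x + y * y <= radius * radius


# -- individual pipeline stages (exposed so order sensitivity can be probed) --

def threshold_stage(frame: np.ndarray, threshold: int) -> np.ndarray:
    return np.asarray(frame) > threshold


def fill_holes_stage(mask: np.ndarray) -> np.ndarray:
    return ndimage.binary_fill_holes(mask, structure=_FILL_STRUCTURE)


def median_stage(mask: np.ndarray, kernel: int) -> np.ndarray:
    if kernel <= 1:
        return mask
    return ndimage.median_filter(mask.astype(np.uint8), size=kernel).astype(bool)


def opening_stage(mask: np.ndarray, radius: int) -> np.ndarray:
    if radius < 1:
        return mask
    return ndimage.binary_opening(mask, structure=_disk(radius))


def size_filter_stage(mask: np.ndarray, min_area: int) -> np.ndarray:
    labels, n = ndimage.label(mask, structure=_LABEL_STRUCTURE)
    if n == 0:
        return mask
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    keep = counts >= min_area
    return keep[labels]


def largest_object(mask: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(mask, structure=_LABEL_STRUCTURE)
    if n == 0:
        raise NoObjectError("empty mask after filtering")
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == int(np.argmax(counts))


def segment_mask(frame: np.ndarray, params: SegParams = SegParams()) -> np.ndarray:
    """Run the five-stage pipeline and return the largest surviving object.

    The post-threshold stages are local operators, so they run on a padded
    crop around the thresholded foreground and are embedded back afterwards;
    the result is identical to running them on the full frame.
    """
    mask = threshold_stage(frame, params.global_threshold)
    rows = np.flatnonzero(mask.any(axis=1))
    if rows.size == 0:
        raise NoObjectError("empty mask after filtering")
    cols = np.flatnonzero(mask.any(axis=0))
    margin = params.median_kernel + 2 * params.opening_radius + 2
    r0 = max(0, rows[0] - margin)
    r1 = min(mask.shape[0], rows[-1] + 1 + margin)
    c0 = max(0, cols[0] - margin)
    c1 = min(mask.shape[1], cols[-1] + 1 + margin)
    sub = mask[r0:r1, c0:c1]
    sub = fill_holes_stage(sub)
    sub = median_stage(sub, params.median_kernel)
    sub = opening_stage(sub, params.opening_radius)
    sub = size_filter_stage(sub, params.min_object_area)
    out = np.zeros_like(mask)
    out[r0:r1, c0:c1] = largest_object(sub)
    return out


def segment_fillet(frame: np.ndarray, params: SegParams = SegParams()) -> FilletSegment:
    """Segment one frame and compute region properties of the fillet."""
    return region_properties(segment_mask(frame, params))


def major_axis_angle(mask: np.ndarray) -> float:
    """Angle (radians, row-down image coordinates) of the major axis of the
    foreground pixel cloud relative to the +column axis, in (-pi/2, pi/2]."""
    rows, cols = np.nonzero(mask)
    x = cols - cols.mean()
    y = rows - rows.mean()
    mu20 = float(np.mean(x * x))
    mu02 = float(np.mean(y * y))
    mu11 = float(np.mean(x * y))
    angle = 0.5 * np.arctan2(2.0 * mu11, mu20 - mu02)
    if angle <= -np.pi / 2:
        angle += np.pi
    elif angle > np.pi / 2:
        angle -= np.pi
    return angle


def region_properties(mask: np.ndarray) -> FilletSegment:
    """Region properties of a binary mask (largest assumed to be the fillet).

    Centroid is the mean of foreground pixel coordinates; perimeter uses the
    Crofton 4-direction estimator (near-unbiased on smooth shapes); the major
    axis comes from second central moments.
    """
    mask = np.asarray(mask, bool)
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise NoObjectError("empty mask")
    top, bottom = int(rows.min()), int(rows.max()) + 1
    left, right = int(cols.min()), int(cols.max()) + 1
    area = int(rows.size)
    col_counts = np.bincount(cols - left)
    occupied = col_counts[col_counts > 0]
    sub = np.pad(mask[top:bottom, left:right], 1)  # crofton is local: crop for speed
    return FilletSegment(
        mask=mask,
        centroid=(float(rows.mean()), float(cols.mean())),
        area=area,
        perimeter=float(perimeter_crofton(sub, directions=4)),
        bbox=(top, left, bottom, right),
        major_axis_angle=major_axis_angle(mask),
        max_height=bottom - top,
        avg_height=float(occupied.mean()),
        length=right - left,
    )


def height_features(mask: np.ndarray, belt_row: int | None = None) -> tuple[float, float, float]:
    """First-frame height split (h, ht, hb).

    ``h`` is the bounding-box height; ``ht`` the distance from the box top
    down to the centroid and ``hb`` from the centroid down to the box bottom
    (the belt surface on a flat frame), measured with pixel-center geometry so
    that ``h = ht + hb`` holds exactly.  If ``belt_row`` is given it replaces
    the box bottom (useful when the mask does not quite touch the belt).
    """
    seg = mask if isinstance(mask, FilletSegment) else region_properties(mask)
    top, _, bottom, _ = seg.bbox
    if belt_row is not None:
        bottom = int(belt_row)
    crow = seg.centroid[0]
    ht = crow - (top - 0.5)
    hb = (bottom - 0.5) - crow
    return (float(bottom - top), float(ht), float(hb))
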