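"""Scale-invariant bending energy of a segmented fillet.

For a fillet segment with contour perimeter P, a skeleton curve of length
proxy L, and curvature samples C(k) along that curve, the bending energy is

    BE = (P**2 / L) * sum_k C(k)**2

The P**2 and 1/L normalization makes BE dimensionless and (approximately)
scale-invariant.  The curve is obtained by (1) rotating the segment about its
centroid so the major axis is horizontal, (2) taking the medial-axis skeleton
of the rotated mask, and (3) regressing the skeleton points with a
second-degree polynomial.  Curvature is the analytic curvature of the fitted
quadratic, C(x) = |y''| / (1 + y'**2)**1.5, sampled at the integer columns
spanned by the skeleton; L is the number of those columns.

A rigid (wooden-breast-like) fillet barely bends over the discharge edge, so
its maximum bending energy over a pass is small; a flexible normal fillet
bends strongly and scores high.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skimage.morphology import medial_axis

from .errors import DegenerateShapeError, NoObjectError
from .segmentation import FilletSegment, major_axis_angle, region_properties

log = logging.getLogger(__name__)


@dataclass
class SkeletonCurve:
    raw_points: np.ndarray = field(repr=False)  # (n, 2) array of (row, col)
    fit_coeffs: tuple[float, float, float]  # (a, b, c) of row = a*col^2 + b*col + c
    x_range: tuple[int, int]
    n_samples: int


@dataclass
class BendingEnergyValue:
    BE: float
    P: float
    L: int
    curvature_samples: np.ndarray = field(repr=False)


@dataclass
class BendingTrace:
    """Per-frame bending-energy series over a tracking window."""

    values: list[float]  # NaN where the frame was degenerate/empty
    MBE: float
    argmax_frame: int


def _rotate_binary(sub: np.ndarray, crow: float, ccol: float, angle: float) -> np.ndarray:
    """Nearest-neighbor rotation of a binary raster by ``-angle`` about
    (crow, ccol), on a canvas just containing the rotated shape.

    Rotating the pixel cloud by the negative of its major-axis angle makes
    the major axis horizontal.
    """
    h, w = sub.shape
    ca, sa = np.cos(angle), np.sin(angle)
    corners = np.array([[0.0, 0.0], [0.0, w], [h, 0.0], [h, w]])
    rel = corners - [crow, ccol]
    # forward map (row, col) -> (row*ca - col*sa, row*sa + col*ca) is rotation
    # by -angle in x/y convention; it zeroes the measured moment angle.
    fr = rel[:, 0] * ca - rel[:, 1] * sa
    fc = rel[:, 0] * sa + rel[:, 1] * ca
    margin = 2
    r_lo, r_hi = np.floor(fr.min()) - margin, np.ceil(fr.max()) + margin
    c_lo, c_hi = np.floor(fc.min()) - margin, np.ceil(fc.max()) + margin
    out_h = int(r_hi - r_lo) + 1
    out_w = int(c_hi - c_lo) + 1
    rr, cc = np.mgrid[0:out_h, 0:out_w]
    orow = rr + r_lo
    ocol = cc + c_lo
    # inverse map back into the input raster
    ir = orow * ca + ocol * sa + crow
    ic = -orow * sa + ocol * ca + ccol
    iri = np.rint(ir).astype(int)
    ici = np.rint(ic).astype(int)
    valid = (iri >= 0) & (iri < h) & (ici >= 0) & (ici < w)
    out = np.zeros((out_h, out_w), bool)
    out[valid] = sub[iri[valid], ici[valid]]
    return out


def rotate_to_major_axis(segment: FilletSegment | np.ndarray) -> np.ndarray:
    """Return the segment mask rotated about its centroid so that the major
    axis is horizontal (within ~1 degree), on a tight canvas."""
    seg = segment if isinstance(segment, FilletSegment) else region_properties(segment)
    top, left, bottom, right = seg.bbox
    sub = seg.mask[top:bottom, left:right]
    if sub.size <= 1 or seg.area < 2:
        raise DegenerateShapeError("mask too small to rotate")
    crow = seg.centroid[0] - top
    ccol = seg.centroid[1] - left
    return _rotate_binary(sub, crow, ccol, seg.major_axis_angle)


#: Fraction of skeleton columns dropped at each end before the quadratic fit.
#: The medial axis of a blunt-ended shape grows diagonal branch spurs at its
#: extremities; trimming the outermost columns keeps them out of the fit while
#: the curve extent (and hence L) still spans the full skeleton.
END_TRIM_FRACTION = 0.05


def skeletonize_and_fit(rotated_mask: np.ndarray) -> SkeletonCurve:
    """Medial-axis skeleton of a horizontal mask, regressed with a quadratic.

    The skeleton point cloud is reduced to one representative row per column
    (the median, robust to branch spurs), the outermost columns are trimmed
    (see END_TRIM_FRACTION), and a second-degree polynomial is fitted to the
    remainder.  ``x_range`` and ``n_samples`` always cover the untrimmed
    column span.
    """
    skel = medial_axis(np.asarray(rotated_mask, bool))
    rows, cols = np.nonzero(skel)
    xs = np.unique(cols)
    if rows.size < 3 or xs.size < 3:
        raise DegenerateShapeError("fewer than three skeleton points for the quadratic fit")
    med = np.array([np.median(rows[cols == x]) for x in xs])
    k = int(round(END_TRIM_FRACTION * xs.size))
    if xs.size - 2 * k >= 3:
        fit_x, fit_y = xs[k : xs.size - k], med[k : xs.size - k]
    else:
        fit_x, fit_y = xs, med
    coeffs = np.polyfit(fit_x.astype(float), fit_y, 2)
    x_min, x_max = int(xs[0]), int(xs[-1])
    return SkeletonCurve(
        raw_points=np.column_stack([rows, cols]),
        fit_coeffs=(float(coeffs[0]), float(coeffs[1]), float(coeffs[2])),
        x_range=(x_min, x_max),
        n_samples=x_max - x_min + 1,
    )


def quadratic_curvature(coeffs: tuple[float, float, float], x: np.ndarray) -> np.ndarray:
    """Analytic curvature |y''| / (1 + y'^2)^(3/2) of y = a x^2 + b x + c."""
    a, b, _ = coeffs
    slope = 2.0 * a * x + b
    return np.abs(2.0 * a) / (1.0 + slope**2) ** 1.5


def compute_bending_energy(segment: FilletSegment | np.ndarray) -> BendingEnergyValue:
    """Bending energy of one segment: de-rotate, skeletonize, fit, integrate."""
    seg = segment if isinstance(segment, FilletSegment) else region_properties(segment)
    rotated = rotate_to_major_axis(seg)
    curve = skeletonize_and_fit(rotated)
    x = np.arange(curve.x_range[0], curve.x_range[1] + 1, dtype=float)
    c = quadratic_curvature(curve.fit_coeffs, x)
    L = curve.n_samples
    P = seg.perimeter
    be = float(P**2 / L * np.sum(c**2))
    return BendingEnergyValue(BE=be, P=float(P), L=L, curvature_samples=c)


def bending_energy_trace(segments: list[FilletSegment | None]) -> BendingTrace:
    """Per-frame BE over a window; degenerate/missing frames are skipped."""
    values: list[float] = []
    best = -np.inf
    best_frame = -1
    for i, seg in enumerate(segments):
        if seg is None:
            values.append(float("nan"))
            continue
        try:
            be = compute_bending_energy(seg).BE
        except (DegenerateShapeError, NoObjectError) as exc:
            log.warning("frame %d skipped in bending-energy trace: %s", i, exc)
            values.append(float("nan"))
            continue
        values.append(be)
        if be > best:  # strict: first occurrence of the maximum wins
            best = be
            best_frame = i
    if best_frame < 0:
        raise NoObjectError("no valid frame in the tracking window")
    return BendingTrace(values=values, MBE=float(best), argmax_frame=best_frame)


def max_bending_energy(segments: list[FilletSegment | None]) -> float:
    """Maximum per-frame bending energy over the tracking window (MBE)."""
    return bending_energy_trace(segments).MBE
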