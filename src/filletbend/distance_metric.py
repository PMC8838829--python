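"""Centroid-to-axle distance descriptor.

For each tracked frame i the raw distance is the Euclidean distance from the
fillet centroid to the fixed reference point at the roller axle center,

    d_i = sqrt((x_c - x_r)**2 + (y_c - y_r)**2)   [px].

Because a flexible fillet wraps around the discharge edge, its centroid dips
closer to the axle, so the minimum of d_i over a pass (MDM) is smaller for
normal fillets than for rigid wooden-breast fillets.  To remove the size
dependence, d_i is divided by a per-fillet scale factor measured on the first
(flat) frame,

    H = ht + R,

where ht is the centroid-to-top height split of the first frame and R the
roller radius; the minimum of d_i / H is the normalized minimum distance
measure (NMDM, unitless).  The alternative scale factor H' = hb + R is also
exported (feature names HTR and HBR).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import NoObjectError
from .segmentation import FilletSegment, height_features


@dataclass
class DistanceTrace:
    d_raw: list[float]  # NaN where the frame had no segment
    d_norm: list[float]
    H: float
    R: float
    reference_point: tuple[float, float]
    MDM: float
    NMDM: float
    argmin_frame: int


def distance_i(centroid: tuple[float, float], reference: tuple[float, float]) -> float:
    """Euclidean pixel distance between centroid and reference, both (row, col)."""
    return float(np.hypot(centroid[0] - reference[0], centroid[1] - reference[1]))


def scale_factor_H(first_segment: FilletSegment, R: float, belt_row: int | None = None) -> float:
    """Scale factor H = ht + R from the first (flat) frame of the window."""
    _, ht, _ = height_features(first_segment, belt_row=belt_row)
    return float(ht + R)


def alt_scale_factors(
    first_segment: FilletSegment, R: float, belt_row: int | None = None
) -> tuple[float, float]:
    """(HTR, HBR) = (ht + R, hb + R) from the first frame."""
    _, ht, hb = height_features(first_segment, belt_row=belt_row)
    return (float(ht + R), float(hb + R))


def run_distance_trace(
    window_segments: list[FilletSegment | None],
    geom,
) -> DistanceTrace:
    """Distance trace over a tracking window.

    The first entry must be a valid (flat-frame) segment, since it defines H.
    Frames where segmentation failed (None) are skipped, not interpolated.
    Ties in the minimum resolve to the first occurrence.
    """
    if not window_segments:
        raise NoObjectError("empty tracking window")
    first = window_segments[0]
    if first is None:
        raise NoObjectError("first window frame has no segment; cannot compute H")
    reference = geom.reference_point
    R = float(geom.roller_radius)
    H = scale_factor_H(first, R)
    d_raw: list[float] = []
    d_norm: list[float] = []
    best = np.inf
    best_frame = -1
    for i, seg in enumerate(window_segments):
        if seg is None:
            d_raw.append(float("nan"))
            d_norm.append(float("nan"))
            continue
        d = distance_i(seg.centroid, reference)
        d_raw.append(d)
        d_norm.append(d / H)
        if d < best:
            best = d
            best_frame = i
    if best_frame < 0:
        raise NoObjectError("no valid frame in the tracking window")
    return DistanceTrace(
        d_raw=d_raw,
        d_norm=d_norm,
        H=H,
        R=R,
        reference_point=reference,
        MDM=float(best),
        NMDM=float(best / H),
        argmin_frame=best_frame,
    )
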