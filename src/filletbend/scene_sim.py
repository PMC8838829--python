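"""Synthetic conveyor-scene generator.

Renders sideview frame sequences of single broiler breast fillets riding a
conveyor belt, bending over the discharge-roller edge, and falling out of the
field of view.  The generator provides exact per-frame ground-truth masks and
event frames so that the motion sensor, the segmentation stages and the two
bending descriptors can all be validated without recorded video.

Conventions: row 0 is the top of the image, row indices increase downward,
all indices are 0-based.  The belt surface is the horizontal line at
``belt_row``; a flat fillet occupies rows ``belt_row - t .. belt_row - 1``
where ``t`` is its local thickness.  The roller axle center (the reference
point of the distance descriptor) sits exactly one roller radius below the
belt surface at the discharge-edge column.

The bending model is deliberately simple: once part of the fillet overhangs
the edge column, each overhanging column sags vertically by a cantilever-like
quadratic law ``delta(x) = x**2 / (2 * rigidity)`` (capped), where ``x`` is
the overhang length in pixels.  Rigid (wooden-breast-like) fillets have high
rigidity and barely sag; normal fillets sag strongly.  When the centroid
passes the edge the fillet detaches with its deformation frozen and falls
with constant downward acceleration.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .errors import FilletBendError
from .frame_io import FrameSequence

LABELS = ("normal", "moderate", "severe")

#: Class-conditional presets for fillet geometry, (mean, sd) in pixels.
#: Length and maximum thickness follow the published sideview measurements of
#: graded fillets; rigidity presets are dimensionless stiffness values chosen
#: so that the two bending descriptors reproduce the published severity
#: orderings (normal fillets bend most, severe wooden-breast fillets least).
CLASS_PRESETS: dict[str, dict[str, float]] = {
    "normal": {"length": 319.0, "length_sd": 12.0, "thickness": 73.0, "thickness_sd": 8.0, "rigidity": 40.0},
    "moderate": {"length": 322.0, "length_sd": 18.0, "thickness": 80.0, "thickness_sd": 7.0, "rigidity": 160.0},
    "severe": {"length": 323.0, "length_sd": 15.0, "thickness": 85.0, "thickness_sd": 7.0, "rigidity": 240.0},
}


@dataclass(frozen=True)
class SceneGeometry:
    """Fixed scene layout of the sideview imaging station, in pixels.

    ``reference_point`` (the roller axle center) is derived: it lies exactly
    ``roller_radius`` below the belt surface at the edge column.
    """

    image_w: int = 960
    image_h: int = 696
    belt_row: int = 320
    edge_col: int = 620
    roller_radius: float = 49.0
    arrival_col: int = 420
    departure_row: int = 600
    line_speed_px_per_frame: float = 6.0
    frame_rate_fps: float = 200.0

    def __post_init__(self) -> None:
        if not (0 <= self.arrival_col < self.edge_col < self.image_w):
            raise ValueError("need 0 <= arrival_col < edge_col < image_w")
        if not (self.belt_row < self.departure_row < self.image_h):
            raise ValueError("need belt_row < departure_row < image_h")
        if self.roller_radius <= 0 or self.line_speed_px_per_frame <= 0:
            raise ValueError("roller_radius and line speed must be positive")

    @property
    def reference_point(self) -> tuple[float, float]:
        """(row, col) of the roller axle center."""
        return (self.belt_row + self.roller_radius, float(self.edge_col))

    def replace(self, **kw) -> "SceneGeometry":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class FilletProfile:
    """Sideview outline of one fillet in local coordinates.

    ``heights[j]`` is the rasterized thickness (in rows) of column ``j``,
    ``j = 0`` being the tail (thinner, leading end) and
    ``j = length_px - 1`` the head.  ``outline`` is the corresponding closed
    polygon (x, y) with y measured upward from the belt.
    """

    length_px: int
    max_thickness_px: int
    taper: float
    rigidity: float
    heights: np.ndarray = field(repr=False)
    outline: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.length_px < 4 or self.max_thickness_px < 2:
            raise ValueError("profile too small to rasterize")
        if not (0.0 <= self.taper <= 1.0):
            raise ValueError("taper must lie in [0, 1]")
        if not self.rigidity > 0:
            raise ValueError("rigidity must be positive")


@dataclass
class SimulatedPass:
    """One simulated fillet transit with exact ground truth."""

    frames: FrameSequence
    truth_masks: list[np.ndarray]
    truth_arrival_frame: int
    truth_departure_frame: int
    label: str
    rigidity_used: float
    seed: int


def _height_profile(length: int, max_thickness: int, taper: float) -> np.ndarray:
    """Tapered half-elliptical thickness profile, tail (j=0) thinner."""
    u = np.linspace(0.0, 1.0, length)
    envelope = np.sqrt(np.clip(1.0 - (2.0 * u - 1.0) ** 2, 0.0, None))
    shape = envelope * (1.0 - taper * (1.0 - u))
    shape = shape / shape.max() * max_thickness
    heights = np.maximum(np.rint(shape).astype(int), 2)
    return heights


def make_fillet_profile(
    class_label: str,
    rng_seed: int,
    presets: dict[str, dict[str, float]] | None = None,
    taper: float = 0.3,
) -> FilletProfile:
    """Draw a class-conditional fillet profile.

    Length and maximum thickness are drawn from the class preset Gaussians
    (clamped to sane minima); rigidity is drawn log-normally around the class
    preset with 15 % relative spread.  Deterministic given ``rng_seed``.
    """
    presets = presets if presets is not None else CLASS_PRESETS
    if class_label not in presets:
        raise ValueError(f"unknown class label: {class_label!r}")
    p = presets[class_label]
    rng = np.random.default_rng(rng_seed)
    length = int(max(20, round(rng.normal(p["length"], p["length_sd"]))))
    thickness = int(max(6, round(rng.normal(p["thickness"], p["thickness_sd"]))))
    rigidity = float(p["rigidity"] * np.exp(rng.normal(0.0, 0.15)))
    heights = _height_profile(length, thickness, taper)
    xs = np.arange(length, dtype=float)
    top = np.column_stack([xs, heights.astype(float)])
    bottom = np.column_stack([xs[::-1], np.zeros(length)])
    outline = np.vstack([bottom, top])
    return FilletProfile(
        length_px=length,
        max_thickness_px=int(heights.max()),
        taper=taper,
        rigidity=rigidity,
        heights=heights,
        outline=outline,
    )


def _column_sag(overhang: np.ndarray, rigidity: float, max_sag: float) -> np.ndarray:
    """Vertical deflection per column for given overhang lengths (px)."""
    sag = np.where(overhang > 0, overhang.astype(float) ** 2 / (2.0 * rigidity), 0.0)
    return np.minimum(sag, max_sag)


def simulate_pass(
    profile: FilletProfile,
    geom: SceneGeometry,
    rng_seed: int,
    *,
    label: str = "",
    noise_sigma: float = 4.0,
    background_intensity: int = 10,
    fillet_intensity: int = 200,
    gravity_px_per_frame2: float = 3.0,
    detach_kick_px_per_frame: float = 6.0,
    max_sag_px: float = 180.0,
    lead_in_frames: int = 3,
    max_frames: int = 400,
) -> SimulatedPass:
    """Render one fillet transit: flat travel, edge bending, detachment, fall.

    The fillet enters tail-first with its head ``lead_in_frames`` line-speed
    steps short of the arrival trigger column.  Frames are 8-bit grayscale
    with optional additive Gaussian noise; truth masks are exact.

    ``detach_kick_px_per_frame`` is an extra forward velocity gained at
    detachment: tipping over the edge accelerates the center of mass forward
    before release, which carries the falling fillet clear of the roller.
    """
    L = profile.length_px
    if L >= geom.image_w:
        raise ValueError("profile wider than the image")
    speed = geom.line_speed_px_per_frame
    head0 = geom.arrival_col - lead_in_frames * speed
    if head0 - L < 0:
        raise ValueError("profile does not fit left of the arrival column")

    rng = np.random.default_rng(rng_seed)
    rows_grid = np.arange(geom.image_h, dtype=float)[:, None]

    frames: list[np.ndarray] = []
    masks: list[np.ndarray] = []
    truth_arrival = -1
    truth_departure = -1
    detached = False
    frozen_sag: np.ndarray | None = None
    fall_offset = 0.0
    fall_velocity = 0.0
    fall_dx = 0.0
    heights = profile.heights.astype(float)

    for i in range(max_frames):
        tail = head0 - L + i * speed + fall_dx
        cols = tail + np.arange(L)  # real-valued column of each profile column
        if detached:
            assert frozen_sag is not None
            fall_velocity += gravity_px_per_frame2
            fall_offset += fall_velocity
            fall_dx += detach_kick_px_per_frame
            sag = frozen_sag + fall_offset
        else:
            overhang = cols - geom.edge_col
            sag = _column_sag(overhang, profile.rigidity, max_sag_px)

        col_idx = np.rint(cols).astype(int)
        bottoms = geom.belt_row + sag  # exclusive lower row bound per column
        tops = bottoms - heights
        inside = (col_idx >= 0) & (col_idx < geom.image_w)
        mask = np.zeros((geom.image_h, geom.image_w), dtype=bool)
        if inside.any():
            sub = (rows_grid >= tops[None, inside]) & (rows_grid < bottoms[None, inside])
            mask[:, col_idx[inside]] = sub
        if not mask.any() and i > 0:
            break

        if truth_arrival < 0 and mask[:, geom.arrival_col].any():
            truth_arrival = i
        if truth_departure < 0 and mask[geom.departure_row, :].any():
            truth_departure = i

        frame = np.full(mask.shape, np.float32(background_intensity))
        frame[mask] = fillet_intensity
        if noise_sigma > 0:
            frame += rng.standard_normal(frame.shape, dtype=np.float32) * np.float32(noise_sigma)
        frames.append(np.clip(np.rint(frame), 0, 255).astype(np.uint8))
        masks.append(mask)

        if not detached:
            fg = mask.sum()
            if fg:
                centroid_col = mask.sum(axis=0).dot(np.arange(geom.image_w)) / fg
                if centroid_col > geom.edge_col:
                    detached = True
                    frozen_sag = sag.copy()

        # stop once the fillet has fully left through the bottom or right edge
        if truth_departure >= 0 and not mask[: geom.departure_row + 1, :].any():
            break

    if truth_arrival < 0:
        truth_arrival = 0
    if truth_departure < 0:
        truth_departure = len(frames) - 1

    seq = FrameSequence(
        frames=frames,
        frame_rate_fps=geom.frame_rate_fps,
        source_id=f"sim-{label or 'pass'}-{rng_seed}",
    )
    return SimulatedPass(
        frames=seq,
        truth_masks=masks,
        truth_arrival_frame=truth_arrival,
        truth_departure_frame=truth_departure,
        label=label,
        rigidity_used=profile.rigidity,
        seed=rng_seed,
    )


def cohort_seeds(n_per_class: int, master_seed: int) -> list[tuple[str, int, int]]:
    """Reproducible (label, profile_seed, render_seed) triples for a cohort."""
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(master_seed)
    out = []
    for lab in LABELS:
        seeds = rng.integers(0, 2**31 - 1, size=(n_per_class, 2))
        for k in range(n_per_class):
            out.append((lab, int(seeds[k, 0]), int(seeds[k, 1])))
    return out


def iter_cohort(
    n_per_class: int,
    geom: SceneGeometry,
    master_seed: int,
    **sim_kwargs,
):
    """Yield a balanced labeled cohort one pass at a time (memory-friendly)."""
    for lab, pseed, rseed in cohort_seeds(n_per_class, master_seed):
        profile = make_fillet_profile(lab, pseed)
        yield simulate_pass(profile, geom, rseed, label=lab, **sim_kwargs)


def generate_cohort(
    n_per_class: int,
    geom: SceneGeometry,
    master_seed: int,
    **sim_kwargs,
) -> list[SimulatedPass]:
    """Balanced labeled cohort as a list.

    Note: a full-resolution pass holds ~100 MB of frames and masks; for large
    cohorts prefer :func:`iter_cohort` and process passes one at a time.
    """
    return list(iter_cohort(n_per_class, geom, master_seed, **sim_kwargs))
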