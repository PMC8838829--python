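"""Per-fillet feature assembly and cohort batch processing.

For each pass the tracking window is delimited by the software motion sensor,
every window frame is segmented, and eleven features are assembled:

* size/shape features from the first (flat) window frame:
  MAXH, AVGH, MAXL, AREA, PERIM, HTR, HBR;
* bending descriptors over the whole window: MDM, NMDM (distance metric) and
  MBE (bending energy);
* an ordinal class label (0 normal, 1 moderate, 2 severe) when known.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .bending_energy import max_bending_energy
from .distance_metric import alt_scale_factors, run_distance_trace
from .errors import FilletBendError, NoObjectError
from .frame_io import FEATURE_COLUMNS, FrameSequence
from .motion_sensor import TriggerConfig, delimit_window
from .scene_sim import LABELS, SceneGeometry, SimulatedPass, iter_cohort
from .segmentation import FilletSegment, SegParams, segment_fillet

log = logging.getLogger(__name__)

LABEL_TO_ORDINAL = {lab: i for i, lab in enumerate(LABELS)}


@dataclass
class FilletFeatures:
    NMDM: float
    MDM: float
    MBE: float
    MAXH: float
    AVGH: float
    MAXL: float
    AREA: float
    PERIM: float
    HTR: float
    HBR: float
    label: int | None = None

    def as_row(self) -> dict:
        return asdict(self)


def _segment_window(
    seq: FrameSequence, window, seg_params: SegParams
) -> list[FilletSegment | None]:
    segments: list[FilletSegment | None] = []
    for i in range(window.start_frame, window.end_frame + 1):
        try:
            segments.append(segment_fillet(seq.frames[i], seg_params))
        except NoObjectError:
            segments.append(None)
    return segments


def extract_features(
    seq: FrameSequence,
    geom: SceneGeometry,
    seg_params: SegParams = SegParams(),
    trigger_cfg: TriggerConfig | None = None,
    label: int | None = None,
) -> FilletFeatures:
    """Extract the eleven-feature vector from one single-fillet sequence."""
    cfg = trigger_cfg or TriggerConfig.from_geometry(geom)
    window = delimit_window(seq, cfg)
    segments = _segment_window(seq, window, seg_params)
    first = segments[0]
    if first is None:
        raise NoObjectError("no fillet segment on the first window frame")

    trace = run_distance_trace(segments, geom)
    mbe = max_bending_energy(segments)
    htr, hbr = alt_scale_factors(first, geom.roller_radius)
    return FilletFeatures(
        NMDM=trace.NMDM,
        MDM=trace.MDM,
        MBE=mbe,
        MAXH=float(first.max_height),
        AVGH=float(first.avg_height),
        MAXL=float(first.length),
        AREA=float(first.area),
        PERIM=float(first.perimeter),
        HTR=htr,
        HBR=hbr,
        label=label,
    )


def features_from_pass(
    sim_pass: SimulatedPass,
    geom: SceneGeometry,
    seg_params: SegParams = SegParams(),
    trigger_cfg: TriggerConfig | None = None,
) -> FilletFeatures:
    """Extract features from a simulated pass, attaching its true label."""
    label = LABEL_TO_ORDINAL.get(sim_pass.label)
    return extract_features(sim_pass.frames, geom, seg_params, trigger_cfg, label=label)


def process_cohort(
    passes,
    geom: SceneGeometry,
    seg_params: SegParams = SegParams(),
    trigger_cfg: TriggerConfig | None = None,
    labels: list[int | None] | None = None,
) -> pd.DataFrame:
    """One feature row per pass; failures are logged and reported, not dropped.

    ``passes`` may hold FrameSequence or SimulatedPass objects.  Failed rows
    appear as NaN features so the caller can see exactly which passes failed.
    """
    passes = list(passes)
    if not passes:
        raise ValueError("process_cohort needs at least one pass")
    rows = []
    failures = 0
    for k, item in enumerate(passes):
        lab = labels[k] if labels is not None else None
        try:
            if isinstance(item, SimulatedPass):
                feats = features_from_pass(item, geom, seg_params, trigger_cfg)
            else:
                feats = extract_features(item, geom, seg_params, trigger_cfg, label=lab)
            rows.append(feats.as_row())
        except FilletBendError as exc:
            log.warning("pass %d failed feature extraction: %s", k, exc)
            failures += 1
            rows.append({c: (lab if c == "label" else np.nan) for c in FEATURE_COLUMNS})
    if failures == len(passes):
        raise NoObjectError("feature extraction failed for every pass")
    df = pd.DataFrame(rows, columns=FEATURE_COLUMNS)
    df.index.name = "fillet_id"
    return df


def simulated_cohort_features(
    n_per_class: int,
    geom: SceneGeometry,
    master_seed: int,
    seg_params: SegParams = SegParams(),
    **sim_kwargs,
) -> pd.DataFrame:
    """Simulate a balanced cohort and extract features pass-by-pass.

    Streams one pass at a time so full-resolution cohorts stay within a
    modest memory footprint.  Deterministic given ``master_seed``.
    """
    rows = []
    for sim_pass in iter_cohort(n_per_class, geom, master_seed, **sim_kwargs):
        feats = features_from_pass(sim_pass, geom, seg_params)
        rows.append(feats.as_row())
    df = pd.DataFrame(rows, columns=FEATURE_COLUMNS)
    df.index.name = "fillet_id"
    return df
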