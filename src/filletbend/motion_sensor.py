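"""Software motion sensing via two single-pixel trigger lines.

A vertical trigger line (one image column, upstream of the discharge edge)
signals the arrival of a fillet; a horizontal trigger line (one image row,
below the belt) signals the fillet leaving the field of view after its fall.
A line fires when enough of its pixels exceed an intensity threshold, and the
state must hold for a short debounce run of consecutive frames to reject
single-frame noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import NoObjectError
from .frame_io import FrameSequence


@dataclass(frozen=True)
class TriggerConfig:
    arrival_col: int
    departure_row: int
    intensity_threshold: int = 60
    min_active_pixels: int = 5
    debounce_frames: int = 2

    def __post_init__(self) -> None:
        if self.min_active_pixels < 1:
            raise ValueError("min_active_pixels must be >= 1")
        if self.debounce_frames < 1:
            raise ValueError("debounce_frames must be >= 1")

    @classmethod
    def from_geometry(cls, geom, **overrides) -> "TriggerConfig":
        return cls(
            arrival_col=geom.arrival_col,
            departure_row=geom.departure_row,
            **overrides,
        )


@dataclass(frozen=True)
class TrackingWindow:
    start_frame: int
    end_frame: int
    sequence_id: str = ""

    def __post_init__(self) -> None:
        if self.start_frame >= self.end_frame:
            raise ValueError("start_frame must precede end_frame")


def _line_active(values: np.ndarray, cfg: TriggerConfig) -> bool:
    return int(np.count_nonzero(values > cfg.intensity_threshold)) >= cfg.min_active_pixels


def arrival_triggered(frame: np.ndarray, cfg: TriggerConfig) -> bool:
    """True iff enough pixels in the arrival column exceed the threshold."""
    if not (0 <= cfg.arrival_col < frame.shape[1]):
        raise ValueError(f"arrival_col {cfg.arrival_col} outside frame width {frame.shape[1]}")
    return _line_active(frame[:, cfg.arrival_col], cfg)


def departure_triggered(frame: np.ndarray, cfg: TriggerConfig) -> bool:
    """True iff enough pixels in the departure row exceed the threshold."""
    if not (0 <= cfg.departure_row < frame.shape[0]):
        raise ValueError(f"departure_row {cfg.departure_row} outside frame height {frame.shape[0]}")
    return _line_active(frame[cfg.departure_row, :], cfg)


def _first_debounced(flags: list[bool], debounce: int, start: int = 0) -> int:
    """Index of the first frame opening a run of ``debounce`` True flags, or -1."""
    run = 0
    for i in range(start, len(flags)):
        run = run + 1 if flags[i] else 0
        if run >= debounce:
            return i - debounce + 1
    return -1


def delimit_window(seq: FrameSequence, cfg: TriggerConfig) -> TrackingWindow:
    """Locate the single tracking window of a one-fillet sequence.

    The window starts at the first (debounced) arrival trigger and ends at
    the first (debounced) departure trigger after it.  If the departure line
    never fires, the window ends at the last frame still showing the object.
    """
    if len(seq) == 0:
        raise NoObjectError("empty sequence")
    arrivals = [arrival_triggered(f, cfg) for f in seq.frames]
    start = _first_debounced(arrivals, cfg.debounce_frames)
    if start < 0:
        raise NoObjectError("no arrival trigger fired in the sequence")
    departures = [departure_triggered(f, cfg) for f in seq.frames]
    end = _first_debounced(departures, cfg.debounce_frames, start=start + 1)
    if end < 0 or end <= start:
        # fall back: last frame with any above-threshold content
        nonempty = [
            int(np.count_nonzero(f > cfg.intensity_threshold)) >= cfg.min_active_pixels
            for f in seq.frames
        ]
        end = max((i for i, ok in enumerate(nonempty) if ok), default=start)
        if end <= start:
            end = min(start + 1, len(seq) - 1)
    if end <= start:
        raise NoObjectError("could not delimit a tracking window")
    return TrackingWindow(start_frame=start, end_frame=end, sequence_id=seq.source_id)
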