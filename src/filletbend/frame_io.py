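"""Reading and writing frame sequences, masks, geometry configs and
per-fillet feature tables.

Frames are exchanged as zero-padded numbered 8-bit grayscale PNG stacks (or a
single multi-page TIFF); feature tables as comma-separated UTF-8 CSV with a
fixed header; scene geometry as YAML.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .errors import FormatError

#: Fixed column order of the per-fillet feature table.
FEATURE_COLUMNS = [
    "NMDM",
    "MDM",
    "MBE",
    "MAXH",
    "AVGH",
    "MAXL",
    "AREA",
    "PERIM",
    "HTR",
    "HBR",
    "label",
]

#: ITU-R BT.601 luminance weights used for RGB -> grayscale conversion.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)


@dataclass
class FrameSequence:
    """Ordered grayscale rasters for one fillet pass."""

    frames: list[np.ndarray]
    frame_rate_fps: float = 200.0
    source_id: str = ""

    def __post_init__(self) -> None:
        if self.frame_rate_fps <= 0:
            raise ValueError("frame_rate_fps must be positive")
        shapes = {f.shape for f in self.frames}
        if len(shapes) > 1:
            raise FormatError(f"frames have mixed dimensions: {sorted(shapes)}")

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i):
        return self.frames[i]

    def subsequence(self, start: int, stop: int) -> "FrameSequence":
        return FrameSequence(
            frames=self.frames[start:stop],
            frame_rate_fps=self.frame_rate_fps,
            source_id=f"{self.source_id}[{start}:{stop}]",
        )


def to_grayscale(frame: np.ndarray) -> np.ndarray:
    """Convert an RGB(A) raster to 8-bit grayscale with BT.601 weights;
    grayscale input passes through unchanged."""
    if frame.ndim == 2:
        return frame.astype(np.uint8, copy=False)
    if frame.ndim == 3 and frame.shape[2] in (3, 4):
        rgb = frame[..., :3].astype(float)
        gray = rgb @ np.asarray(LUMA_WEIGHTS)
        return np.clip(np.rint(gray), 0, 255).astype(np.uint8)
    raise FormatError(f"unsupported frame shape {frame.shape}")


def write_sequence(seq: FrameSequence, directory: str | Path, prefix: str = "frame") -> list[Path]:
    """Write a sequence as zero-padded numbered grayscale PNGs."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    width = max(4, len(str(len(seq.frames) - 1)))
    paths = []
    for i, frame in enumerate(seq.frames):
        p = directory / f"{prefix}_{i:0{width}d}.png"
        iio.imwrite(p, np.asarray(frame, dtype=np.uint8))
        paths.append(p)
    return paths


def read_sequence(path: str | Path, frame_rate_fps: float = 200.0) -> FrameSequence:
    """Read a numbered PNG stack (directory) or a multi-page TIFF file.

    Frames are ordered by filename (directory) or page index (TIFF); RGB
    inputs are converted to grayscale.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() == ".png")
        if not files:
            raise FileNotFoundError(f"no PNG frames found in {path}")
        frames = [to_grayscale(iio.imread(p)) for p in files]
    elif path.is_file() and path.suffix.lower() in (".tif", ".tiff"):
        stack = iio.imread(path)
        if stack.ndim == 2:
            stack = stack[None]
        frames = [to_grayscale(f) for f in stack]
    else:
        raise FileNotFoundError(f"no frame stack at {path}")
    shapes = {f.shape for f in frames}
    if len(shapes) > 1:
        raise FormatError(f"frames in {path} have mixed dimensions: {sorted(shapes)}")
    return FrameSequence(frames=frames, frame_rate_fps=frame_rate_fps, source_id=str(path))


def write_mask_stack(masks: list[np.ndarray], directory: str | Path, prefix: str = "mask") -> list[Path]:
    """Write binary masks as 0/255 grayscale PNGs parallel to the frames."""
    arr = [np.where(np.asarray(m, bool), 255, 0).astype(np.uint8) for m in masks]
    return write_sequence(FrameSequence(frames=arr), directory, prefix=prefix)


def read_mask_stack(directory: str | Path, prefix: str = "mask") -> list[np.ndarray]:
    directory = Path(directory)
    files = sorted(p for p in directory.iterdir() if p.name.startswith(prefix) and p.suffix == ".png")
    if not files:
        raise FileNotFoundError(f"no mask PNGs with prefix {prefix!r} in {directory}")
    return [iio.imread(p) > 127 for p in files]


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a per-fillet feature table as CSV with the fixed header.

    The index is written as a ``fillet_id`` column; numeric round-trip is
    good to well beyond 6 significant digits.
    """
    if table.empty:
        raise ValueError("refusing to write an empty feature table")
    unknown = [c for c in table.columns if c not in FEATURE_COLUMNS]
    if unknown:
        raise FormatError(f"unknown feature columns: {unknown}")
    out = table.copy()
    out.index.name = "fillet_id"
    out.to_csv(path, float_format="%.10g")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a feature-table CSV, validating the header."""
    df = pd.read_csv(path, index_col="fillet_id")
    unknown = [c for c in df.columns if c not in FEATURE_COLUMNS]
    if unknown:
        raise FormatError(f"unknown feature columns in {path}: {unknown}")
    if df.empty:
        warnings.warn(f"feature table {path} contains no rows", stacklevel=2)
    feature_cols = [c for c in df.columns if c != "label"]
    df[feature_cols] = df[feature_cols].astype(float)
    if "label" in df.columns and not df.empty:
        df["label"] = df["label"].astype(int)
    return df


def write_geometry(geom, path: str | Path) -> None:
    """Serialize a SceneGeometry (and optional trigger settings) to YAML."""
    from dataclasses import asdict

    with open(path, "w") as fh:
        yaml.safe_dump({"scene_geometry": asdict(geom)}, fh, sort_keys=True)


def read_geometry(path: str | Path):
    from .scene_sim import SceneGeometry

    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "scene_geometry" not in doc:
        raise FormatError(f"{path} does not contain a scene_geometry block")
    return SceneGeometry(**doc["scene_geometry"])


def write_pass_metadata(sim_pass, path: str | Path) -> None:
    """Sidecar YAML with label, seeds and ground-truth event frames."""
    meta = {
        "label": sim_pass.label,
        "seed": int(sim_pass.seed),
        "rigidity_used": float(sim_pass.rigidity_used),
        "truth_arrival_frame": int(sim_pass.truth_arrival_frame),
        "truth_departure_frame": int(sim_pass.truth_departure_frame),
        "n_frames": len(sim_pass.frames),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)


def read_pass_metadata(path: str | Path) -> dict:
    with open(path) as fh:
        meta = yaml.safe_load(fh)
    if not isinstance(meta, dict):
        raise FormatError(f"{path} is not a metadata mapping")
    return meta
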