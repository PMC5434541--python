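"""Image-sequence and table I/O, plus physical-calibration metadata.

All positional data follow one raster convention: ``x`` is the column index
increasing rightward, ``y`` the row index increasing downward, origin at the
centre of the top-left pixel, positions in pixel units with subpixel
precision.  Calibration (``pixel_size_um``, ``frame_interval_s``) is always
supplied explicitly — it is experimental metadata, never inferred from TIFF
tags.

Detections and tracks travel as tidy :class:`pandas.DataFrame` tables
(one row per detection, or per (track, frame) observation) and are stored
as plain CSV with a single header row and full-precision floats.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "ImageSequence",
    "RunConfig",
    "read_sequence",
    "write_sequence",
    "DETECTION_COLUMNS",
    "TRACK_COLUMNS",
    "write_detections",
    "read_detections",
    "write_tracks",
    "read_tracks",
]

#: Required columns of a detection table, in storage order.
DETECTION_COLUMNS = ["frame_index", "x_px", "y_px", "area_px2", "contrast"]

#: Required columns of a track table, in storage order.
TRACK_COLUMNS = ["track_id", "frame_index", "x_px", "y_px"]


@dataclass
class ImageSequence:
    """An ordered stack of equally shaped grayscale frames with calibration.

    Parameters
    ----------
    frames
        List of 2D arrays (row-major), all of identical shape. Bit depth is
        whatever the source provided; intensities are treated numerically.
    pixel_size_um
        Effective pixel size in micrometres (> 0).
    frame_interval_s
        Time between consecutive frame starts in seconds (> 0).
    id
        Free-text run label.
    """

    frames: list[np.ndarray]
    pixel_size_um: float
    frame_interval_s: float
    id: str = ""

    def __post_init__(self) -> None:
        if len(self.frames) < 1:
            raise ValueError("ImageSequence needs at least one frame")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be > 0")
        shape0 = self.frames[0].shape
        for i, f in enumerate(self.frames):
            if f.ndim != 2:
                raise ValueError(f"frame {i} is not 2D (shape {f.shape})")
            if f.shape != shape0:
                raise ValueError(
                    f"frame {i} has shape {f.shape}, expected {shape0}"
                )

    @property
    def shape(self) -> tuple[int, int]:
        """(height, width) of every frame."""
        return self.frames[0].shape

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i: int) -> np.ndarray:
        return self.frames[i]

    def __iter__(self) -> Iterator[np.ndarray]:
        return iter(self.frames)

    def times_s(self) -> np.ndarray:
        """Start time of each frame in seconds (frame 0 at t = 0)."""
        return np.arange(len(self.frames)) * self.frame_interval_s


@dataclass
class RunConfig:
    """Parameters of one analysis run.

    The linking gate defaults to the 15 px maximum displacement used for
    tracked airway particles; together with the calibration it fixes the
    maximum measurable transport rate (see :func:`mcttrack.link.max_trackable_speed`).
    """

    pixel_size_um: float = 16.0
    frame_interval_s: float = 2.4
    gate_px: float = 15.0
    max_gap_frames: int = 2
    drift_threshold_px: float = 5.0
    # detection
    smooth_sigma_px: float = 1.5
    threshold_k: float = 5.0
    threshold_abs: float | None = None
    bead_diameter_um: float = 103.0
    min_circularity: float = 0.4
    # summaries
    heatmap_bin_mm_min: float = 0.25
    heatmap_extent_mm_min: float = 6.0
    time_bin_s: float = 60.0
    treatment_start_s: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gate_px <= 0:
            raise ValueError("gate_px must be > 0")
        if self.max_gap_frames < 0:
            raise ValueError("max_gap_frames must be >= 0")
        if self.drift_threshold_px <= 0:
            raise ValueError("drift_threshold_px must be > 0")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load a config from YAML or JSON (by extension)."""
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError(f"config {path} did not parse to a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        data = {k: getattr(self, k) for k in self.__dataclass_fields__}
        if path.suffix.lower() == ".json":
            path.write_text(json.dumps(data, indent=2))
        else:
            path.write_text(yaml.safe_dump(data, sort_keys=False))


def _read_tiff_pages(path: Path) -> list[np.ndarray]:
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        return [arr]
    if arr.ndim == 3:
        return [arr[i] for i in range(arr.shape[0])]
    raise ValueError(f"{path}: unsupported TIFF dimensionality {arr.ndim}")


def read_sequence(
    path: str | Path,
    pixel_size_um: float,
    frame_interval_s: float,
    id: str | None = None,
) -> ImageSequence:
    """Read a multi-page TIFF, or a directory of TIFF frames, as a sequence.

    Directory frames are taken in lexicographic filename order, which is the
    acquisition order for zero-padded frame numbering. Frames of mismatched
    shape raise a ``ValueError`` naming the offending file/page.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff")
        )
        if not files:
            raise FileNotFoundError(f"no TIFF frames in directory {path}")
        frames: list[np.ndarray] = []
        names: list[str] = []
        for p in files:
            pages = _read_tiff_pages(p)
            frames.extend(pages)
            names.extend([p.name] * len(pages))
        shape0 = frames[0].shape
        for name, f in zip(names, frames):
            if f.shape != shape0:
                raise ValueError(
                    f"frame {name} has shape {f.shape}, expected {shape0}"
                )
    else:
        if not path.exists():
            raise FileNotFoundError(str(path))
        frames = _read_tiff_pages(path)
    return ImageSequence(
        frames=frames,
        pixel_size_um=pixel_size_um,
        frame_interval_s=frame_interval_s,
        id=id if id is not None else path.stem,
    )


def write_sequence(
    seq: ImageSequence | Sequence[np.ndarray],
    path: str | Path,
    as_uint16: bool = False,
    uint16_range: tuple[float, float] = (0.0, 1.2),
) -> None:
    """Write frames as a multi-page TIFF.

    With ``as_uint16`` the (float) intensities are linearly mapped from
    ``uint16_range`` onto the full 16-bit range, emulating a 16-bit camera.
    """
    frames = list(seq.frames) if isinstance(seq, ImageSequence) else list(seq)
    stack = np.stack(frames) if len(frames) > 1 else np.asarray(frames[0])
    if as_uint16:
        lo, hi = uint16_range
        stack = np.clip((stack - lo) / (hi - lo), 0.0, 1.0)
        stack = np.round(stack * 65535).astype(np.uint16)
    tifffile.imwrite(str(path), stack, photometric="minisblack")


def _write_table(df: pd.DataFrame, columns: list[str], path: str | Path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"table missing required columns: {missing}")
    extra = [c for c in df.columns if c not in columns]
    df.to_csv(path, index=False, columns=columns + extra)


def _read_table(path: str | Path, columns: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.ParserError as exc:  # surface the row number
        raise ValueError(f"malformed table {path}: {exc}") from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"table {path} missing required columns: {missing}")
    return df


def write_detections(detections: pd.DataFrame, path: str | Path) -> None:
    """Write a detection table as CSV (full float precision, round-trips)."""
    _write_table(detections, DETECTION_COLUMNS, path)


def read_detections(path: str | Path) -> pd.DataFrame:
    """Read a detection table written by :func:`write_detections`."""
    df = _read_table(path, DETECTION_COLUMNS)
    if len(df):
        df["frame_index"] = df["frame_index"].astype(int)
    else:
        df = df.astype({"frame_index": int})
    return df


def write_tracks(tracks: pd.DataFrame, path: str | Path) -> None:
    """Write a track table: one row per (track, frame) observation.

    Duplicate (track_id, frame_index) rows are rejected — a track cannot be
    observed twice in one frame.
    """
    if len(tracks) and tracks.duplicated(["track_id", "frame_index"]).any():
        dup = tracks[tracks.duplicated(["track_id", "frame_index"])].iloc[0]
        raise ValueError(
            "duplicate observation for track "
            f"{int(dup['track_id'])} at frame {int(dup['frame_index'])}"
        )
    _write_table(tracks, TRACK_COLUMNS, path)


def read_tracks(path: str | Path) -> pd.DataFrame:
    """Read a track table; rejects duplicate (track_id, frame_index) rows."""
    df = _read_table(path, TRACK_COLUMNS)
    if len(df):
        if df.duplicated(["track_id", "frame_index"]).any():
            dup = df[df.duplicated(["track_id", "frame_index"])].iloc[0]
            raise ValueError(
                f"{path}: duplicate observation for track "
                f"{int(dup['track_id'])} at frame {int(dup['frame_index'])}"
            )
        df["track_id"] = df["track_id"].astype(int)
        df["frame_index"] = df["frame_index"].astype(int)
    else:
        df = df.astype({"track_id": int, "frame_index": int})
    return df
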