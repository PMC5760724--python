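"""Image-stack and table I/O, kymographs, and configuration files.

File formats: multi-page grayscale TIFF (8/16-bit integer or float) for
movies; CSV for track tables, MSD tables, decision scripts and intervention
logs (gap frames serialize coordinates as the literal token ``NaN``); flat
YAML for tracking configuration; TIFF or PNG for kymographs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .core import TrackingConfig
from .tracker import InterventionRecord, Track, TrackPoint

__all__ = [
    "ImageStack",
    "read_stack",
    "write_stack",
    "tracks_to_dataframe",
    "dataframe_to_tracks",
    "write_tracks",
    "read_tracks",
    "make_kymograph",
    "read_config",
    "write_config",
    "interventions_to_dataframe",
    "write_interventions",
]

TRACK_COLUMNS = ["track_id", "frame", "x", "y", "intensity", "status"]


@dataclass
class ImageStack:
    """Frames x rows x cols intensity array plus optional frame interval."""

    data: np.ndarray
    frame_interval: Optional[float] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or self.data.shape[0] < 1:
            raise ValueError(f"stack must be (frames, rows, cols); got {self.data.shape}")
        if np.issubdtype(self.data.dtype, np.floating) and not np.isfinite(self.data).all():
            raise ValueError("stack contains non-finite intensities")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self):
        return self.data.shape


def read_stack(path) -> ImageStack:
    """Load a multi-page grayscale TIFF, frame-major; single-page files
    become a 1-frame stack. RGB data is rejected."""
    try:
        with tifffile.TiffFile(path) as tif:
            series = tif.series[0]
            axes = series.axes
            data = series.asarray()
    except FileNotFoundError:
        raise
    except Exception as exc:  # corrupt / non-TIFF
        raise ValueError(f"cannot read {path} as a TIFF stack: {exc}") from exc
    if "S" in axes or (data.ndim == 3 and axes in ("YXS", "SYX")) or data.ndim > 3:
        raise ValueError(f"{path} holds RGB/multi-sample data; grayscale is required")
    if data.ndim == 2:
        data = data[None, :, :]
    if data.ndim != 3:
        raise ValueError(f"{path}: unexpected TIFF layout with axes {axes!r}")
    return ImageStack(data=data)


def write_stack(path, stack: "ImageStack | np.ndarray") -> None:
    data = stack.data if isinstance(stack, ImageStack) else np.asarray(stack)
    if data.ndim == 2:
        data = data[None]
    tifffile.imwrite(path, data.astype(np.float32))


def tracks_to_dataframe(tracks: Sequence[Track]) -> pd.DataFrame:
    rows = [
        {
            "track_id": t.track_id,
            "frame": p.frame,
            "x": p.x,
            "y": p.y,
            "intensity": p.intensity,
            "status": p.status,
        }
        for t in tracks
        for p in t.points
    ]
    return pd.DataFrame(rows, columns=TRACK_COLUMNS)


def dataframe_to_tracks(df: pd.DataFrame) -> List[Track]:
    tracks: List[Track] = []
    for tid, group in df.groupby("track_id", sort=True):
        group = group.sort_values("frame")
        t = Track(track_id=int(tid))
        for row in group.itertuples(index=False):
            t.points.append(
                TrackPoint(
                    frame=int(row.frame),
                    x=float(row.x),
                    y=float(row.y),
                    intensity=float(row.intensity),
                    status=str(row.status),
                )
            )
        tracks.append(t)
    return tracks


def write_tracks(tracks: Sequence[Track], path) -> None:
    """One CSV row per track point; gaps serialize x/y/intensity as ``NaN``."""
    tracks_to_dataframe(tracks).to_csv(path, index=False, na_rep="NaN")


def read_tracks(path) -> List[Track]:
    """Inverse of :func:`write_tracks`; validates the table invariants and
    reports offending CSV line numbers (header = line 1)."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ValueError(f"cannot parse track table {path}: {exc}") from exc
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    dup = df.duplicated(subset=["track_id", "frame"], keep="first")
    if dup.any():
        line = int(df.index[dup][0]) + 2
        raise ValueError(f"{path}, line {line}: duplicate (track_id, frame) pair")
    for tid, group in df.groupby("track_id"):
        frames = group.sort_values("frame")["frame"].to_numpy()
        if frames[0] != 0 or np.any(np.diff(frames) != 1):
            first_bad = int(group.index[0]) + 2
            raise ValueError(
                f"{path}, line {first_bad}: track {tid} frames are not "
                "consecutive integers starting at 0"
            )
    return dataframe_to_tracks(df)


def make_kymograph(stack: "ImageStack | np.ndarray") -> np.ndarray:
    """x-t image: row t is the maximum-intensity projection of frame t along
    the row (y) axis, so moving particles appear as slanted paths."""
    data = stack.data if isinstance(stack, ImageStack) else np.asarray(stack)
    if data.ndim != 3:
        raise ValueError("kymograph needs a (frames, rows, cols) stack")
    return data.max(axis=1)


def read_config(path, **overrides) -> TrackingConfig:
    """Flat YAML key/value file mirroring TrackingConfig; keyword overrides
    (e.g. CLI flags) take precedence over file values."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a flat mapping")
    raw.update({k: v for k, v in overrides.items() if v is not None})
    return TrackingConfig(**raw)


def write_config(config: TrackingConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {
                "scan_rows": config.scan_rows,
                "scan_cols": config.scan_cols,
                "window_size": config.window_size,
                "localization_method": config.localization_method,
                "brightness_k": config.brightness_k,
                "min_separation": config.min_separation,
                "frame_interval": config.frame_interval,
                "pixel_size": config.pixel_size,
            },
            fh,
            sort_keys=False,
        )


def interventions_to_dataframe(records: Sequence[InterventionRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        d = rec.decision
        x, y = d.manual_position if d.manual_position is not None else (math.nan, math.nan)
        rows.append(
            {
                "frame": rec.request.frame,
                "track_id": rec.request.track_id,
                "kind": rec.request.kind,
                "n_candidates": len(rec.request.candidates),
                "action": d.action,
                "x": x,
                "y": y,
                "candidate_index": d.candidate_index if d.candidate_index is not None else np.nan,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["frame", "track_id", "kind", "n_candidates", "action", "x", "y", "candidate_index"],
    )


def write_interventions(records: Sequence[InterventionRecord], path) -> None:
    """Audit trail: every intervention request and the decision applied."""
    interventions_to_dataframe(records).to_csv(path, index=False, na_rep="NaN")
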