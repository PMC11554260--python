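"""Reading, validating and structuring tag-detection tables.

A *detection* is one fiducial-tag read-out: trial, frame index, timestamp,
ant identity, tag-center pixel coordinates and the tag's front direction.
Coordinates follow the image convention (origin top-left, y increasing
downward); angles are measured counterclockwise from the +x axis in that same
frame and normalised to [0, 2*pi).

The head of an ant is estimated from the tag's directionality: the tag center
displaced by a configurable offset along the tag's front direction.  The
default offset is 0 px (head proxy = tag reference point) because the
proximity threshold used downstream is calibrated empirically and already
absorbs a constant offset.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import (
    DuplicateDetectionError,
    InsufficientFramesError,
    MissingColumnError,
    NonFiniteCoordinateError,
)

logger = logging.getLogger(__name__)

TWO_PI = 2.0 * math.pi

#: canonical column order of a detection table
DETECTION_COLUMNS = ("trial_id", "frame", "time_s", "ant_id", "x_px", "y_px", "theta_rad")


@dataclass(frozen=True)
class DetectionDialect:
    """Schema descriptor mapping canonical detection columns to file columns.

    ``origin``/``y_down`` document the coordinate convention of the source
    images; they are carried as provenance, not used to transform data.
    """

    trial_id: str = "trial_id"
    frame: str = "frame"
    time_s: str = "time_s"
    ant_id: str = "ant_id"
    x_px: str = "x_px"
    y_px: str = "y_px"
    theta_rad: str = "theta_rad"
    origin: str = "upper-left"
    y_down: bool = True

    def rename_map(self) -> dict[str, str]:
        return {getattr(self, c): c for c in DETECTION_COLUMNS}


DEFAULT_DIALECT = DetectionDialect()


@dataclass(frozen=True)
class TrialMetadata:
    """Treatment metadata for one trial.

    ``group_id`` identifies the (re-usable) group of tagged ants;
    ``pixel_scale_mm`` is millimetres per pixel (0.04 for the reference
    imaging setup); ``mean_frame_rate_ips`` is the trial-average imaging rate
    in images per second.
    """

    trial_id: str
    group_id: str
    group_size: int
    food_type: str
    food_availability: str
    pixel_scale_mm: float = 0.04
    mean_frame_rate_ips: float = 1.0

    def __post_init__(self):
        if self.group_size < 2:
            raise ValueError(f"group_size must be >= 2, got {self.group_size}")
        if not self.pixel_scale_mm > 0:
            raise ValueError("pixel_scale_mm must be > 0")
        if not self.mean_frame_rate_ips > 0:
            raise ValueError("mean_frame_rate_ips must be > 0")
        if self.food_type not in ("carbohydrate", "protein"):
            raise ValueError(f"unknown food_type {self.food_type!r}")
        if self.food_availability not in ("limited", "unlimited"):
            raise ValueError(f"unknown food_availability {self.food_availability!r}")


class DetectionTable:
    """Validated per-trial detection table.

    Rows are sorted by (frame, ant_id); (frame, ant_id) is unique; coordinates
    are finite and angles normalised to [0, 2*pi).
    """

    def __init__(self, df: pd.DataFrame, trial_id: str | None = None):
        self.df = df.reset_index(drop=True)
        if trial_id is None and len(df):
            trial_id = str(df["trial_id"].iloc[0])
        self.trial_id = trial_id

    @property
    def ants(self) -> list[str]:
        return sorted(self.df["ant_id"].unique().tolist())

    @property
    def n_ants(self) -> int:
        return self.df["ant_id"].nunique()

    @property
    def n_frames(self) -> int:
        return self.df["frame"].nunique()

    def __len__(self) -> int:
        return len(self.df)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"DetectionTable(trial={self.trial_id!r}, n_ants={self.n_ants}, "
            f"n_frames={self.n_frames}, n_rows={len(self)})"
        )


def validate_detections(df: pd.DataFrame, trial_id: str | None = None) -> DetectionTable:
    """Validate an already-canonical detection DataFrame."""
    if len(df):
        dup = df.duplicated(subset=["frame", "ant_id"])
        if dup.any():
            row = df.loc[dup.idxmax()]
            raise DuplicateDetectionError(
                f"ant {row['ant_id']!r} detected twice in frame {row['frame']}"
            )
        coords = df[["x_px", "y_px", "theta_rad", "time_s"]].to_numpy(dtype=float)
        if not np.isfinite(coords).all():
            raise NonFiniteCoordinateError("non-finite coordinate, angle or timestamp")
        df = df.copy()
        df["theta_rad"] = np.mod(df["theta_rad"].to_numpy(dtype=float), TWO_PI)
        df = df.sort_values(["frame", "ant_id"], kind="mergesort")
    return DetectionTable(df, trial_id=trial_id)


def read_detections(
    path: str | Path,
    dialect: DetectionDialect = DEFAULT_DIALECT,
    nominal_rate_ips: float | None = None,
) -> DetectionTable:
    """Read and validate one trial's detection CSV.

    Raises :class:`MissingColumnError` if a required column is absent (a
    missing timestamp column is tolerated when ``nominal_rate_ips`` is given:
    timestamps are then reconstructed as ``frame / nominal_rate_ips`` and the
    reconstruction is logged).
    """
    path = Path(path)
    raw = pd.read_csv(path)
    rename = dialect.rename_map()
    missing = [src for src in rename if src not in raw.columns]
    reconstruct_time = False
    if dialect.time_s in missing and nominal_rate_ips is not None:
        missing.remove(dialect.time_s)
        reconstruct_time = True
    if missing:
        raise MissingColumnError(f"{path.name}: missing required column(s) {missing}")
    df = raw.rename(columns={s: d for s, d in rename.items() if s in raw.columns})
    if reconstruct_time:
        df["time_s"] = df["frame"].astype(float) / float(nominal_rate_ips)
        logger.warning(
            "%s: no %r column; reconstructed time_s from frame index at %.3f images/s",
            path.name, dialect.time_s, nominal_rate_ips,
        )
    df = df[list(DETECTION_COLUMNS)]
    df["trial_id"] = df["trial_id"].astype(str)
    df["ant_id"] = df["ant_id"].astype(str)
    df["frame"] = df["frame"].astype(int)
    if len(df) and (df["frame"] < 0).any():
        raise NonFiniteCoordinateError("negative frame index")
    table = validate_detections(df, trial_id=path.stem if not len(df) else None)
    logger.info("%s: %d detections, %d ants, %d frames", path.name, len(table), table.n_ants, table.n_frames)
    return table


def write_detections(table: DetectionTable, path: str | Path,
                     dialect: DetectionDialect = DEFAULT_DIALECT) -> Path:
    path = Path(path)
    inverse = {c: getattr(dialect, c) for c in DETECTION_COLUMNS}
    table.df[list(DETECTION_COLUMNS)].rename(columns=inverse).to_csv(path, index=False)
    return path


def head_position(x_px, y_px, theta_rad, head_offset_px: float = 0.0):
    """Head point: tag center displaced along the tag's front direction.

    Accepts scalars or arrays; returns ``(head_x, head_y)``.
    """
    off = float(head_offset_px)
    if not math.isfinite(off) or off < 0:
        raise ValueError("head_offset_px must be finite and non-negative")
    x = np.asarray(x_px, dtype=float)
    y = np.asarray(y_px, dtype=float)
    th = np.asarray(theta_rad, dtype=float)
    hx = x + off * np.cos(th)
    hy = y + off * np.sin(th)
    if hx.ndim == 0:
        return float(hx), float(hy)
    return hx, hy


@dataclass
class Trajectory:
    """One ant's ordered detections with head points and recorded frame gaps."""

    ant_id: str
    frames: np.ndarray          # (n,) int, strictly increasing
    times: np.ndarray           # (n,) float seconds
    xy: np.ndarray              # (n, 2) tag-center pixels
    head: np.ndarray            # (n, 2) head-point pixels
    gap_after: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    # frames after which the next detection skips >= 1 recorded frame index

    def __len__(self) -> int:
        return len(self.frames)


class TrajectorySet:
    """Per-ant trajectories for one trial, plus a per-frame head-position view."""

    def __init__(self, trajectories: Mapping[str, Trajectory], trial_id: str | None = None,
                 head_offset_px: float = 0.0):
        self.trajectories = dict(trajectories)
        self.trial_id = trial_id
        self.head_offset_px = head_offset_px

    @property
    def ants(self) -> list[str]:
        return sorted(self.trajectories)

    def __getitem__(self, ant_id: str) -> Trajectory:
        return self.trajectories[ant_id]

    def __len__(self) -> int:
        return len(self.trajectories)

    def head_panel(self) -> tuple[np.ndarray, list[str], np.ndarray]:
        """Dense (frame x ant) view of head positions.

        Returns ``(frames, ants, heads)`` where ``heads`` has shape
        ``(n_frames, n_ants, 2)`` and is NaN where an ant was not detected.
        Used by interaction detection, which requires co-detection.
        """
        ants = self.ants
        all_frames = np.unique(
            np.concatenate([t.frames for t in self.trajectories.values()])
            if self.trajectories else np.empty(0, int)
        )
        heads = np.full((len(all_frames), len(ants), 2), np.nan)
        pos = {f: i for i, f in enumerate(all_frames)}
        for j, a in enumerate(ants):
            t = self.trajectories[a]
            idx = np.array([pos[f] for f in t.frames], dtype=int)
            heads[idx, j, :] = t.head
        return all_frames, ants, heads


def build_trajectories(table: DetectionTable, head_offset_px: float = 0.0) -> TrajectorySet:
    """Split a detection table into per-ant trajectories.

    Frame gaps are recorded but never interpolated: downstream distances and
    interactions are computed only over frames where detections exist.
    """
    trajs: dict[str, Trajectory] = {}
    if len(table):
        for ant_id, sub in table.df.groupby("ant_id", sort=True):
            sub = sub.sort_values("frame")
            frames = sub["frame"].to_numpy(int)
            xy = sub[["x_px", "y_px"]].to_numpy(float)
            hx, hy = head_position(sub["x_px"], sub["y_px"], sub["theta_rad"], head_offset_px)
            head = np.column_stack([np.atleast_1d(hx), np.atleast_1d(hy)])
            gap_after = frames[:-1][np.diff(frames) > 1] if len(frames) > 1 else np.empty(0, int)
            trajs[str(ant_id)] = Trajectory(
                ant_id=str(ant_id), frames=frames,
                times=sub["time_s"].to_numpy(float), xy=xy, head=head,
                gap_after=gap_after,
            )
    return TrajectorySet(trajs, trial_id=table.trial_id, head_offset_px=head_offset_px)


@dataclass(frozen=True)
class FrameRateSummary:
    mean_ips: float
    min_ips: float
    max_ips: float
    window_rates: np.ndarray  # images/s per fixed-duration window
    window_s: float


def frame_rate_summary(table: DetectionTable, window_s: float = 60.0) -> FrameRateSummary:
    """Trial frame-rate summary.

    Mean rate is ``(n_frames - 1) / (t_last - t_first)`` over distinct frames;
    window rates count distinct frames in fixed-duration bins.
    """
    if not len(table):
        raise InsufficientFramesError("empty detection table")
    per_frame = table.df.groupby("frame")["time_s"].first()
    times = per_frame.to_numpy(float)
    if len(times) < 2 or times[-1] <= times[0]:
        raise InsufficientFramesError("need >= 2 distinct timestamps")
    mean = (len(times) - 1) / (times[-1] - times[0])
    edges = np.arange(times[0], times[-1] + window_s, window_s)
    counts, _ = np.histogram(times, bins=edges)
    widths = np.minimum(edges[1:], times[-1]) - edges[:-1]
    valid = widths > 0
    rates = counts[valid] / widths[valid]
    return FrameRateSummary(
        mean_ips=float(mean),
        min_ips=float(rates.min()) if len(rates) else float(mean),
        max_ips=float(rates.max()) if len(rates) else float(mean),
        window_rates=rates,
        window_s=window_s,
    )


# --- trial metadata IO -------------------------------------------------------

METADATA_COLUMNS = ("trial_id", "group_id", "group_size", "food_type",
                    "food_availability", "pixel_scale_mm", "mean_frame_rate_ips")


def read_metadata(path: str | Path) -> list[TrialMetadata]:
    df = pd.read_csv(path)
    required = [c for c in METADATA_COLUMNS if c not in ("pixel_scale_mm", "mean_frame_rate_ips")]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise MissingColumnError(f"metadata: missing column(s) {missing}")
    out = []
    for _, row in df.iterrows():
        out.append(TrialMetadata(
            trial_id=str(row["trial_id"]), group_id=str(row["group_id"]),
            group_size=int(row["group_size"]), food_type=str(row["food_type"]),
            food_availability=str(row["food_availability"]),
            pixel_scale_mm=float(row.get("pixel_scale_mm", 0.04)),
            mean_frame_rate_ips=float(row.get("mean_frame_rate_ips", 1.0)),
        ))
    return out


def write_metadata(meta: Iterable[TrialMetadata], path: str | Path) -> Path:
    path = Path(path)
    rows = [{f.name: getattr(m, f.name) for f in fields(TrialMetadata)} for m in meta]
    pd.DataFrame(rows, columns=list(METADATA_COLUMNS)).to_csv(path, index=False)
    return path
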