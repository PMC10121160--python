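"""Session readers/writers: CSV position/quaternion logs, activity arrays,
grayscale AVI, and timestamp-based stream alignment.

Acquisition conventions: timestamps in milliseconds, positions in cm,
0-based frame indexing.  Multi-file recordings are concatenated in the order
given.  Streams are aligned by nearest timestamp within half a frame period.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .avi import read_gray_avi, write_gray_avi
from .behavior import PathSegmentation, Trajectory, Traversal, compute_speed
from .config import AnalysisConfig
from .core import ActivityMatrix, AlignmentError, PlacecellError
from .orientation import QuaternionStream, read_quaternion_csv


@dataclass
class SessionBundle:
    """Aligned activity + trajectory (+ orientation) for one session."""

    activity: ActivityMatrix
    trajectory: Trajectory
    orientation: QuaternionStream | None = None
    metadata: dict | None = None

    def __post_init__(self):
        if self.activity.n_frames != len(self.trajectory):
            raise AlignmentError(
                f"activity has {self.activity.n_frames} frames, "
                f"trajectory {len(self.trajectory)}"
            )


# ---------------------------------------------------------------------------
# CSV / array containers


def write_position_csv(path: str | Path, trajectory: Trajectory) -> None:
    df = pd.DataFrame(
        {
            "frame": np.arange(len(trajectory)),
            "time_ms": np.round(trajectory.t * 1000.0, 6),
            "x_cm": trajectory.x_cm,
            "y_cm": trajectory.y_cm,
        }
    )
    df.to_csv(path, index=False, float_format="%.9g")


def read_position_csv(paths, frame_rate_hz: float) -> Trajectory:
    """Read (and concatenate) position CSVs with columns frame,time_ms,x_cm,y_cm."""
    if isinstance(paths, (str, Path)):
        paths = [paths]
    parts = [pd.read_csv(p) for p in paths]
    for p, df in zip(paths, parts):
        missing = {"time_ms", "x_cm", "y_cm"} - set(df.columns)
        if missing:
            raise PlacecellError(f"{p}: position CSV missing columns {sorted(missing)}")
    if len(parts) > 1:
        # later parts continue the clock of earlier ones
        offset = 0.0
        frames = []
        for df in parts:
            t = df["time_ms"].to_numpy(dtype=float) + offset
            frames.append(df.assign(time_ms=t))
            offset = t[-1] + float(np.median(np.diff(t))) if len(t) > 1 else t[-1]
        df = pd.concat(frames, ignore_index=True)
    else:
        df = parts[0]
    t = df["time_ms"].to_numpy(dtype=float) / 1000.0
    if np.any(np.diff(t) <= 0):
        raise PlacecellError("non-monotone timestamps in position CSV")
    return Trajectory(
        t=t,
        x_cm=df["x_cm"].to_numpy(dtype=float),
        y_cm=df["y_cm"].to_numpy(dtype=float),
        frame_rate_hz=frame_rate_hz,
    )


def write_quaternion_csv(path: str | Path, stream: QuaternionStream) -> None:
    df = pd.DataFrame(
        {
            "frame": np.arange(len(stream)),
            "time_ms": np.round(stream.t * 1000.0, 6),
            "qw": stream.qw,
            "qx": stream.qx,
            "qy": stream.qy,
            "qz": stream.qz,
        }
    )
    df.to_csv(path, index=False, float_format="%.12g")


def write_activity_npz(path: str | Path, activity: ActivityMatrix) -> None:
    np.savez(
        path,
        activity=activity.values,
        frame_rate_hz=activity.frame_rate_hz,
        cell_ids=activity.cell_ids,
    )


def read_activity_npz(path: str | Path) -> ActivityMatrix:
    with np.load(path) as z:
        return ActivityMatrix(
            values=z["activity"],
            frame_rate_hz=float(z["frame_rate_hz"]),
            cell_ids=z["cell_ids"] if "cell_ids" in z else None,
        )


def write_segmentation_csv(path: str | Path, seg: PathSegmentation) -> None:
    from .behavior import segmentation_to_frame

    segmentation_to_frame(seg).to_csv(path, index=False)


def read_segmentation_csv(path: str | Path) -> PathSegmentation:
    df = pd.read_csv(path)
    return PathSegmentation(
        traversals=[
            Traversal(
                path_id=int(r.path_id), arm=int(r.arm), direction=int(r.direction),
                start_frame=int(r.start_frame), end_frame=int(r.end_frame),
            )
            for r in df.itertuples()
        ]
    )


write_behavior_avi = write_gray_avi
read_behavior_avi = read_gray_avi


# ---------------------------------------------------------------------------
# Session assembly


def align_streams(t_ref_s: np.ndarray, t_other_s: np.ndarray, frame_rate_hz: float
                  ) -> np.ndarray:
    """Index into the other stream nearest each reference timestamp.

    Raises if any nearest match is farther than half a frame period.
    """
    t_ref_s = np.asarray(t_ref_s, dtype=float)
    t_other_s = np.asarray(t_other_s, dtype=float)
    pos = np.searchsorted(t_other_s, t_ref_s)
    pos = np.clip(pos, 1, len(t_other_s) - 1)
    left = t_other_s[pos - 1]
    right = t_other_s[pos]
    idx = np.where(np.abs(t_ref_s - left) <= np.abs(right - t_ref_s), pos - 1, pos)
    err = np.abs(t_other_s[idx] - t_ref_s)
    tol = 0.5 / frame_rate_hz
    bad = err > tol
    if np.any(bad):
        frames = np.flatnonzero(bad)[:10].tolist()
        raise AlignmentError(
            f"{bad.sum()} frames misaligned beyond {tol * 1000:.1f} ms "
            f"(first: {frames})"
        )
    return idx


def read_session(
    activity_path: str | Path,
    position_paths,
    config: AnalysisConfig,
    frame_rate_hz: float,
    quaternion_path: str | Path | None = None,
) -> SessionBundle:
    """Assemble a session bundle from on-disk streams.

    The activity clock is the reference: position (and orientation) samples
    are matched to activity frames by nearest timestamp within half a frame
    period.  Here both streams are frame-indexed on the same clock, so this
    reduces to a frame-count check unless timestamps drift.
    """
    activity = read_activity_npz(activity_path)
    trajectory = read_position_csv(position_paths, frame_rate_hz)
    if activity.n_frames != len(trajectory):
        if activity.n_frames < len(trajectory):
            t_act = np.arange(activity.n_frames) / frame_rate_hz
            idx = align_streams(t_act, trajectory.t, frame_rate_hz)
            trajectory = Trajectory(
                t=t_act,
                x_cm=trajectory.x_cm[idx],
                y_cm=trajectory.y_cm[idx],
                frame_rate_hz=frame_rate_hz,
            )
        else:
            raise AlignmentError(
                f"activity has {activity.n_frames} frames but position only "
                f"{len(trajectory)}"
            )
    trajectory = compute_speed(trajectory, config.speed_smoothing_window_s)
    orientation = read_quaternion_csv(quaternion_path) if quaternion_path else None
    return SessionBundle(
        activity=activity,
        trajectory=trajectory,
        orientation=orientation,
        metadata={"frame_rate_hz": frame_rate_hz, "mode": config.mode},
    )


def write_manifest(path: str | Path, entries: dict) -> None:
    """Deterministic run manifest (sorted keys, no timestamps)."""
    Path(path).write_text(json.dumps(entries, indent=2, sort_keys=True) + "\n")
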