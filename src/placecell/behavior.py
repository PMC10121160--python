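"""Animal position from behavior video and track-path serialization.

Position is the bright tracking LED on the head-mounted scope, extracted from
8-bit grayscale overhead video as the intensity-weighted centroid of the
connected pixel region containing the frame's global maximum.  Pixel
positions are undistorted (even-order radial polynomial) and affinely mapped
to world centimeters.  On the rectangular track, running is serialized into
the eight directed paths (four arms x two directions).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .arena import ArenaSpec, TrackGeometry, path_id
from .core import ConfigurationError, PlacecellError, UntrackableSessionError


@dataclass
class Trajectory:
    """Timestamped 2-D positions with derived speeds and a validity mask.

    ``valid`` marks frames that are tracked and, once a speed threshold has
    been applied, moving fast enough to enter spatial analyses.
    """

    t: np.ndarray
    x_cm: np.ndarray
    y_cm: np.ndarray
    frame_rate_hz: float
    speed_cm_s: np.ndarray | None = None
    valid: np.ndarray | None = None

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.x_cm = np.asarray(self.x_cm, dtype=float)
        self.y_cm = np.asarray(self.y_cm, dtype=float)
        n = len(self.t)
        if len(self.x_cm) != n or len(self.y_cm) != n:
            raise ValueError("t, x_cm, y_cm must share length")
        if n == 0:
            raise ValueError("empty trajectory")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        if self.valid is None:
            self.valid = np.isfinite(self.x_cm) & np.isfinite(self.y_cm)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if len(self.valid) != n:
                raise ValueError("valid mask length mismatch")

    def __len__(self) -> int:
        return len(self.t)

    def copy(self) -> "Trajectory":
        return Trajectory(
            t=self.t.copy(),
            x_cm=self.x_cm.copy(),
            y_cm=self.y_cm.copy(),
            frame_rate_hz=self.frame_rate_hz,
            speed_cm_s=None if self.speed_cm_s is None else self.speed_cm_s.copy(),
            valid=self.valid.copy(),
        )


@dataclass(frozen=True)
class Traversal:
    """One directed run along a single arm: entered at one end, exited the other."""

    path_id: int
    arm: int
    direction: int  # +1 along increasing perimeter arclength
    start_frame: int
    end_frame: int  # inclusive


@dataclass
class PathSegmentation:
    """Ordered, non-overlapping arm traversals of a track session."""

    traversals: list[Traversal]

    def __len__(self) -> int:
        return len(self.traversals)

    def frames_of_path(self, pid: int, n_frames: int) -> np.ndarray:
        """Boolean frame mask for all traversals of one directed path."""
        mask = np.zeros(n_frames, dtype=bool)
        for tr in self.traversals:
            if tr.path_id == pid:
                mask[tr.start_frame : tr.end_frame + 1] = True
        return mask


# ---------------------------------------------------------------------------
# LED tracking


@dataclass
class LedTrack:
    """Per-frame LED pixel position (x=column, y=row) and tracking flags."""

    x_px: np.ndarray
    y_px: np.ndarray
    tracked: np.ndarray  # frame passed the contrast check (not interpolated)
    valid: np.ndarray  # tracked or interpolated within the allowed gap


def track_led_position(
    frames: np.ndarray,
    spot_min_contrast: float = 20.0,
    region_fraction: float = 0.5,
    max_gap_s: float = 0.5,
    frame_rate_hz: float = 30.0,
) -> LedTrack:
    """Locate the LED in each grayscale frame.

    Per frame the pixels at or above ``region_fraction`` of the global
    maximum are thresholded, the 8-connected component containing the
    maximum is kept, and its intensity-weighted centroid is the LED
    position.  Frames whose maximum exceeds the frame median by less than
    ``spot_min_contrast`` are flagged and later filled by linear
    interpolation across gaps of at most ``max_gap_s`` seconds; longer gaps
    stay invalid.
    """
    frames = np.asarray(frames)
    if frames.ndim != 3 or frames.shape[0] == 0:
        raise ValueError("frames must be a nonempty (n, h, w) array")
    n = frames.shape[0]
    x = np.full(n, np.nan)
    y = np.full(n, np.nan)
    tracked = np.zeros(n, dtype=bool)
    structure = np.ones((3, 3), dtype=bool)  # 8-connectivity
    for i in range(n):
        f = frames[i].astype(float)
        peak = f.max()
        if peak - np.median(f) < spot_min_contrast:
            continue
        mask = f >= region_fraction * peak
        labels, _ = ndimage.label(mask, structure=structure)
        peak_label = labels[np.unravel_index(np.argmax(f), f.shape)]
        region = labels == peak_label
        w = f[region]
        rows, cols = np.nonzero(region)
        total = w.sum()
        y[i] = float((rows * w).sum() / total)
        x[i] = float((cols * w).sum() / total)
        tracked[i] = True
    if not tracked.any():
        raise UntrackableSessionError("no frame passed the LED contrast check")

    valid = tracked.copy()
    max_gap = int(round(max_gap_s * frame_rate_hz))
    good = np.flatnonzero(tracked)
    # linear interpolation of interior gaps no longer than max_gap frames
    for a, b in zip(good[:-1], good[1:]):
        gap = b - a - 1
        if 0 < gap <= max_gap:
            frac = np.arange(1, gap + 1) / (gap + 1)
            x[a + 1 : b] = x[a] + frac * (x[b] - x[a])
            y[a + 1 : b] = y[a] + frac * (y[b] - y[a])
            valid[a + 1 : b] = True
    return LedTrack(x_px=x, y_px=y, tracked=tracked, valid=valid)


# ---------------------------------------------------------------------------
# Pixel -> world calibration


@dataclass
class CameraCalibration:
    """Radial undistortion plus affine pixel->world map.

    The forward distortion model is
    ``p_d = c + (p_u - c) * (1 + k1 r^2 + k2 r^4)`` with ``r`` the
    undistorted radius from the principal point ``c`` (pixels); correction
    inverts it by fixed-point iteration.  The affine map then converts
    undistorted pixels to world centimeters.
    """

    affine: np.ndarray  # 2x2
    offset: np.ndarray  # (2,)
    k1: float = 0.0
    k2: float = 0.0
    principal_point: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        self.affine = np.asarray(self.affine, dtype=float).reshape(2, 2)
        self.offset = np.asarray(self.offset, dtype=float).reshape(2)

    @classmethod
    def identity(cls) -> "CameraCalibration":
        return cls(affine=np.eye(2), offset=np.zeros(2))

    @classmethod
    def scale(cls, cm_per_px: float) -> "CameraCalibration":
        return cls(affine=np.eye(2) * cm_per_px, offset=np.zeros(2))


def distort_pixels(points_px: np.ndarray, calib: CameraCalibration) -> np.ndarray:
    """Apply the forward radial model (used to synthesize test data)."""
    p = np.asarray(points_px, dtype=float)
    c = np.asarray(calib.principal_point, dtype=float)
    d = p - c
    r2 = np.sum(d * d, axis=-1, keepdims=True)
    return c + d * (1 + calib.k1 * r2 + calib.k2 * r2**2)


def pixels_to_world(
    points_px: np.ndarray,
    calibration: CameraCalibration | None,
    n_iter: int = 25,
) -> np.ndarray:
    """Undistort pixel positions and map them to world centimeters."""
    if calibration is None:
        raise ConfigurationError("camera calibration is required")
    p = np.asarray(points_px, dtype=float)
    c = np.asarray(calibration.principal_point, dtype=float)
    d = p - c
    u = d.copy()
    for _ in range(n_iter):
        r2 = np.sum(u * u, axis=-1, keepdims=True)
        u = d / (1 + calibration.k1 * r2 + calibration.k2 * r2**2)
    undist = c + u
    return undist @ calibration.affine.T + calibration.offset


# ---------------------------------------------------------------------------
# Speed


def compute_speed(trajectory: Trajectory, smoothing_window_s: float = 0.25) -> Trajectory:
    """Central-difference speed, boxcar-smoothed; endpoints one-sided."""
    n = len(trajectory)
    if n < 2:
        raise ValueError("speed needs at least two frames")
    vx = np.gradient(trajectory.x_cm, trajectory.t)
    vy = np.gradient(trajectory.y_cm, trajectory.t)
    speed = np.hypot(vx, vy)
    win = int(round(smoothing_window_s * trajectory.frame_rate_hz))
    if win > 1:
        speed = ndimage.uniform_filter1d(speed, size=win, mode="nearest")
    out = trajectory.copy()
    out.speed_cm_s = speed
    return out


def apply_speed_threshold(trajectory: Trajectory, threshold_cm_s: float) -> Trajectory:
    """Keep only frames strictly faster than the threshold."""
    if trajectory.speed_cm_s is None:
        raise PlacecellError("compute_speed must run before speed thresholding")
    out = trajectory.copy()
    out.valid = trajectory.valid & (trajectory.speed_cm_s > threshold_cm_s)
    return out


# ---------------------------------------------------------------------------
# Track serialization


def serialize_track_paths(
    trajectory: Trajectory,
    track: ArenaSpec,
    corner_inset_cm: float = 14.0,
) -> PathSegmentation:
    """Serialize track running into directed arm traversals.

    Frames are projected onto the perimeter centerline.  Perimeter locations
    within ``corner_inset_cm`` of a corner belong to that corner's
    feeder/turn zone; the rest of each arm is its interior.  A traversal is
    a maximal interior run on one arm whose flanking zones are the arm's two
    different end corners; runs entered and exited at the same end are
    discarded.
    """
    geom = TrackGeometry(track)  # raises ConfigurationError for circle arenas
    if corner_inset_cm <= 0 or 2 * corner_inset_cm >= geom.arm_lengths.min():
        raise ConfigurationError("corner inset must be positive and leave arm interiors")
    s = geom.xy_to_arclength(trajectory.x_cm, trajectory.y_cm)
    d_corner, corner_idx = geom.distance_to_nearest_corner(s)
    in_corner = d_corner < corner_inset_cm
    arm = geom.arm_of_arclength(s)

    traversals: list[Traversal] = []
    last_corner: int | None = None
    run_start: int | None = None
    run_arm = 0
    entry_corner: int | None = None

    def close_run(end: int, exit_corner: int | None):
        nonlocal run_start
        if run_start is None:
            return
        a = run_arm
        start_c, end_c = a - 1, a % 4  # corners bounding arm a
        if (
            entry_corner is not None
            and exit_corner is not None
            and {entry_corner, exit_corner} == {start_c, end_c}
            and entry_corner != exit_corner
        ):
            direction = 1 if entry_corner == start_c else -1
            traversals.append(
                Traversal(
                    path_id=path_id(a, direction),
                    arm=a,
                    direction=direction,
                    start_frame=run_start,
                    end_frame=end,
                )
            )
        run_start = None

    for i in range(len(trajectory)):
        if in_corner[i]:
            close_run(i - 1, int(corner_idx[i]))
            last_corner = int(corner_idx[i])
        else:
            if run_start is None:
                run_start = i
                run_arm = int(arm[i])
                entry_corner = last_corner
            elif int(arm[i]) != run_arm:
                # crossed into another arm without touching the corner zone:
                # treat the shared corner as implicitly visited
                shared = run_arm % 4 if int(arm[i]) == run_arm % 4 + 1 else run_arm - 1
                close_run(i - 1, shared)
                last_corner = shared
                run_start = i
                run_arm = int(arm[i])
                entry_corner = shared
    close_run(len(trajectory) - 1, None)  # unterminated run: discarded
    return PathSegmentation(traversals=traversals)


def segmentation_to_frame(seg: PathSegmentation):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "traversal": i,
                "path_id": tr.path_id,
                "arm": tr.arm,
                "direction": tr.direction,
                "start_frame": tr.start_frame,
                "end_frame": tr.end_frame,
            }
            for i, tr in enumerate(seg.traversals)
        ]
    )
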