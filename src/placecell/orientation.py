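"""Quaternion head-orientation logs to Euler angles (roll, pitch, yaw).

The on-board absolute orientation sensor reports unit quaternions
(q_w, q_x, q_y, q_z) once per acquired frame.  They are converted offline via
the direction-cosine matrix

    r11 = 1 - 2 q_y^2 - 2 q_z^2   r12 = 2 q_x q_y + 2 q_w q_z   r13 = 2 q_x q_z - 2 q_w q_y
    r21 = 2 q_x q_y - 2 q_w q_z   r22 = 1 - 2 q_x^2 - 2 q_z^2   r23 = 2 q_y q_z + 2 q_w q_x
    r31 = 2 q_x q_z + 2 q_w q_y   r32 = 2 q_y q_z - 2 q_w q_x   r33 = 1 - 2 q_x^2 - 2 q_y^2

and the angle extraction

    roll  = atan2(r23, r33)
    pitch = atan2(sqrt(r11^2 + r12^2), -r13)
    yaw   = atan2(sin(roll) r31 - cos(roll) r21, cos(roll) r22 - sin(roll) r32)

All arctangents are the quadrant-aware two-argument form (a single-argument
arctan cannot represent yaw beyond +/-90 deg).  Under this pitch convention a
level orientation maps to pitch = 90 deg; the convention is preserved rather
than shifted.  Angles are returned in degrees by default; roll and yaw lie in
(-180, 180], pitch in [0, 180].
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import PlacecellError

GIMBAL_EPS = 1e-9


class QuaternionNormError(PlacecellError):
    """Quaternion norm is zero or too far from 1 to renormalize."""


@dataclass
class QuaternionStream:
    """Per-frame unit quaternions with timestamps (seconds)."""

    t: np.ndarray
    qw: np.ndarray
    qx: np.ndarray
    qy: np.ndarray
    qz: np.ndarray

    def __post_init__(self):
        for name in ("t", "qw", "qx", "qy", "qz"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.t)
        if any(len(getattr(self, k)) != n for k in ("qw", "qx", "qy", "qz")):
            raise ValueError("quaternion stream columns must share length")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def wxyz(self) -> np.ndarray:
        return np.stack([self.qw, self.qx, self.qy, self.qz], axis=-1)


@dataclass
class EulerAngles:
    """Euler-angle sequence (degrees unless noted) with gimbal-lock flags."""

    t: np.ndarray
    roll: np.ndarray
    pitch: np.ndarray
    yaw: np.ndarray
    gimbal: np.ndarray
    degrees: bool = True

    def __len__(self) -> int:
        return len(self.t)


def _normalized(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    norm = np.linalg.norm(q, axis=-1, keepdims=True)
    if np.any(norm == 0):
        raise QuaternionNormError("zero-norm quaternion")
    return q / norm


def quaternion_to_matrix(q: np.ndarray) -> np.ndarray:
    """Direction-cosine matrix from quaternion(s) (..., 4) in w,x,y,z order.

    The input is renormalized; a zero-norm quaternion raises
    :class:`QuaternionNormError`.
    """
    q = _normalized(q)
    w, x, y, z = q[..., 0], q[..., 1], q[..., 2], q[..., 3]
    R = np.empty(q.shape[:-1] + (3, 3))
    R[..., 0, 0] = 1 - 2 * y * y - 2 * z * z
    R[..., 0, 1] = 2 * x * y + 2 * w * z
    R[..., 0, 2] = 2 * x * z - 2 * w * y
    R[..., 1, 0] = 2 * x * y - 2 * w * z
    R[..., 1, 1] = 1 - 2 * x * x - 2 * z * z
    R[..., 1, 2] = 2 * y * z + 2 * w * x
    R[..., 2, 0] = 2 * x * z + 2 * w * y
    R[..., 2, 1] = 2 * y * z - 2 * w * x
    R[..., 2, 2] = 1 - 2 * x * x - 2 * y * y
    return R


def matrix_to_euler(R: np.ndarray, degrees: bool = True):
    """Extract (roll, pitch, yaw) and a gimbal-lock flag from DCM(s).

    Returns ``(roll, pitch, yaw, gimbal)``.  Near gimbal lock (|r33| and
    |r23| both below 1e-9) roll is indeterminate; the flag is set and roll
    falls back to atan2(0, 0) = 0 without raising.
    """
    R = np.asarray(R, dtype=float)
    r11, r12, r13 = R[..., 0, 0], R[..., 0, 1], R[..., 0, 2]
    r21, r22 = R[..., 1, 0], R[..., 1, 1]
    r23, r31 = R[..., 1, 2], R[..., 2, 0]
    r32, r33 = R[..., 2, 1], R[..., 2, 2]
    gimbal = (np.abs(r33) < GIMBAL_EPS) & (np.abs(r23) < GIMBAL_EPS)
    roll = np.arctan2(r23, r33)
    pitch = np.arctan2(np.sqrt(r11**2 + r12**2), -r13)
    yaw = np.arctan2(
        np.sin(roll) * r31 - np.cos(roll) * r21,
        np.cos(roll) * r22 - np.sin(roll) * r32,
    )
    if degrees:
        roll, pitch, yaw = np.degrees(roll), np.degrees(pitch), np.degrees(yaw)
    return roll, pitch, yaw, gimbal


def euler_to_matrix(roll, pitch, yaw, degrees: bool = True) -> np.ndarray:
    """Recompose the DCM from angles in this module's convention.

    Inverse of :func:`matrix_to_euler` away from gimbal lock; used for
    round-trip verification.
    """
    roll = np.asarray(roll, dtype=float)
    pitch = np.asarray(pitch, dtype=float)
    yaw = np.asarray(yaw, dtype=float)
    if degrees:
        roll, pitch, yaw = map(np.radians, (roll, pitch, yaw))
    # the printed pitch is 90 deg minus the aerospace elevation angle
    theta = np.pi / 2 - pitch
    cphi, sphi = np.cos(roll), np.sin(roll)
    cth, sth = np.cos(theta), np.sin(theta)
    cpsi, spsi = np.cos(yaw), np.sin(yaw)
    R = np.empty(np.broadcast(roll, pitch, yaw).shape + (3, 3))
    R[..., 0, 0] = cth * cpsi
    R[..., 0, 1] = cth * spsi
    R[..., 0, 2] = -sth
    R[..., 1, 0] = sphi * sth * cpsi - cphi * spsi
    R[..., 1, 1] = sphi * sth * spsi + cphi * cpsi
    R[..., 1, 2] = sphi * cth
    R[..., 2, 0] = cphi * sth * cpsi + sphi * spsi
    R[..., 2, 1] = cphi * sth * spsi - sphi * cpsi
    R[..., 2, 2] = cphi * cth
    return R


def convert_orientation_stream(
    stream: QuaternionStream,
    mounting_correction: np.ndarray | None = None,
    degrees: bool = True,
) -> EulerAngles:
    """Convert a quaternion stream to Euler angles.

    ``mounting_correction`` is a fixed 3x3 rotation accounting for how the
    sensor is mounted on the head; it pre-multiplies each sample's DCM
    before angle extraction (identity by default).
    """
    if len(stream) == 0:
        raise ValueError("empty quaternion stream")
    R = quaternion_to_matrix(stream.wxyz)
    if mounting_correction is not None:
        C = np.asarray(mounting_correction, dtype=float)
        if C.shape != (3, 3):
            raise ValueError("mounting correction must be a 3x3 rotation")
        R = C @ R
    roll, pitch, yaw, gimbal = matrix_to_euler(R, degrees=degrees)
    return EulerAngles(t=stream.t, roll=roll, pitch=pitch, yaw=yaw,
                       gimbal=gimbal, degrees=degrees)


# ---------------------------------------------------------------------------
# CSV I/O (acquisition-software column layout)


def read_quaternion_csv(path: str | Path) -> QuaternionStream:
    """Read a quaternion log CSV with columns frame,time_ms,qw,qx,qy,qz.

    Rows whose quaternion norm deviates from 1 by more than 1e-6 are
    renormalized; rows with non-finite entries raise with the row index.
    """
    df = pd.read_csv(path)
    required = ["time_ms", "qw", "qx", "qy", "qz"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise PlacecellError(f"quaternion CSV missing columns: {missing}")
    vals = df[["qw", "qx", "qy", "qz"]].to_numpy(dtype=float)
    bad = ~np.all(np.isfinite(vals), axis=1)
    if np.any(bad):
        rows = np.flatnonzero(bad)[:10].tolist()
        raise PlacecellError(f"malformed quaternion rows at indices {rows}")
    norm = np.linalg.norm(vals, axis=1)
    if np.any(norm == 0):
        rows = np.flatnonzero(norm == 0)[:10].tolist()
        raise PlacecellError(f"zero-norm quaternion rows at indices {rows}")
    vals = vals / norm[:, None]
    return QuaternionStream(
        t=df["time_ms"].to_numpy(dtype=float) / 1000.0,
        qw=vals[:, 0], qx=vals[:, 1], qy=vals[:, 2], qz=vals[:, 3],
    )


def write_euler_csv(path: str | Path, angles: EulerAngles) -> None:
    df = pd.DataFrame(
        {
            "frame": np.arange(len(angles)),
            "time_ms": np.round(angles.t * 1000.0, 6),
            "roll_deg": angles.roll,
            "pitch_deg": angles.pitch,
            "yaw_deg": angles.yaw,
            "gimbal_flag": angles.gimbal.astype(int),
        }
    )
    df.to_csv(path, index=False, float_format="%.9g")
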