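"""Arena geometry: circular open field and rectangular linear track.

The open field is an 80-cm-diameter circle (centered at the origin).  The
track is the perimeter of a 2.5 m x 1.25 m rectangle whose four arms are run
in two directions each, giving eight directed paths.  Reward feeders sit at
the two corners of one long side, so one arm (the 2.5-m "short path")
directly connects them while the remaining three arms form the "long path".

Conventions
-----------
* Track corners are numbered 0..3 counterclockwise starting at the feeder
  corner at the coordinate origin: c0=(0,0), c1=(L,0), c2=(L,W), c3=(0,W).
* Arm ``a`` (1..4) runs from corner ``a-1`` to corner ``a % 4``; arm 1 is the
  direct feeder-to-feeder arm.
* Perimeter arclength ``s`` increases counterclockwise from c0 over the
  range [0, 2(L+W)).
* A directed path id in 1..8 is ``2*(arm-1) + 1`` for travel in the
  direction of increasing arclength and ``2*(arm-1) + 2`` for the reverse.
"""
from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .core import ConfigurationError


class ArenaShape(str, Enum):
    CIRCLE = "circle"
    RECTANGLE_TRACK = "rectangle_track"


@dataclass(frozen=True)
class ArenaSpec:
    """Geometry of the behavioral environment.

    For ``circle``, only ``diameter_cm`` is used.  For ``rectangle_track``,
    ``track_outer_cm`` gives the (long, short) outer extents and
    ``path_width_cm`` the walkable arm width.
    """

    shape: ArenaShape
    diameter_cm: float | None = None
    track_outer_cm: tuple[float, float] | None = None
    path_width_cm: float = 10.0

    def __post_init__(self):
        shape = ArenaShape(self.shape)
        object.__setattr__(self, "shape", shape)
        if shape is ArenaShape.CIRCLE:
            if self.diameter_cm is None or self.diameter_cm <= 0:
                raise ValueError("circle arena requires diameter_cm > 0")
        else:
            if self.track_outer_cm is None:
                raise ValueError("track arena requires track_outer_cm")
            L, W = self.track_outer_cm
            if L <= 0 or W <= 0:
                raise ValueError("track extents must be positive")
            if self.path_width_cm <= 0:
                raise ValueError("path_width_cm must be positive")

    @property
    def radius_cm(self) -> float:
        if self.shape is not ArenaShape.CIRCLE:
            raise ConfigurationError("radius_cm is defined for circle arenas only")
        return self.diameter_cm / 2.0


def open_field_arena(diameter_cm: float = 80.0) -> ArenaSpec:
    return ArenaSpec(shape=ArenaShape.CIRCLE, diameter_cm=diameter_cm)


def rectangular_track_arena(
    long_cm: float = 250.0, short_cm: float = 125.0, path_width_cm: float = 10.0
) -> ArenaSpec:
    return ArenaSpec(
        shape=ArenaShape.RECTANGLE_TRACK,
        track_outer_cm=(long_cm, short_cm),
        path_width_cm=path_width_cm,
    )


# ---------------------------------------------------------------------------
# Track perimeter parameterization


class TrackGeometry:
    """Arclength parameterization of the rectangular track perimeter."""

    def __init__(self, arena: ArenaSpec):
        if arena.shape is not ArenaShape.RECTANGLE_TRACK:
            raise ConfigurationError("TrackGeometry requires a rectangle_track arena")
        self.arena = arena
        L, W = arena.track_outer_cm
        self.L, self.W = L, W
        self.corners = np.array([[0.0, 0.0], [L, 0.0], [L, W], [0.0, W]])
        # cumulative arclength of corners 0..4 (corner 4 wraps to corner 0)
        self.s_corners = np.array([0.0, L, L + W, 2 * L + W, 2 * (L + W)])
        self.perimeter = 2 * (L + W)

    @property
    def arm_lengths(self) -> np.ndarray:
        return np.diff(self.s_corners)

    def arclength_to_xy(self, s: np.ndarray) -> np.ndarray:
        """Map perimeter arclength(s) to (x, y) centerline positions."""
        s = np.mod(np.asarray(s, dtype=float), self.perimeter)
        out = np.empty(s.shape + (2,))
        for arm in range(4):
            lo, hi = self.s_corners[arm], self.s_corners[arm + 1]
            sel = (s >= lo) & (s < hi)
            if not np.any(sel):
                continue
            frac = (s[sel] - lo) / (hi - lo)
            p0 = self.corners[arm]
            p1 = self.corners[(arm + 1) % 4]
            out[sel] = p0 + frac[:, None] * (p1 - p0)
        return out

    def xy_to_arclength(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Project positions onto the perimeter centerline (nearest point)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        p = np.stack([x, y], axis=-1)
        best_d2 = np.full(x.shape, np.inf)
        best_s = np.zeros(x.shape)
        for arm in range(4):
            p0 = self.corners[arm]
            p1 = self.corners[(arm + 1) % 4]
            seg = p1 - p0
            seglen2 = seg @ seg
            t = np.clip(((p - p0) @ seg) / seglen2, 0.0, 1.0)
            proj = p0 + t[..., None] * seg
            d2 = np.sum((p - proj) ** 2, axis=-1)
            s_here = self.s_corners[arm] + t * np.sqrt(seglen2)
            better = d2 < best_d2
            best_d2 = np.where(better, d2, best_d2)
            best_s = np.where(better, s_here, best_s)
        return np.mod(best_s, self.perimeter)

    def arm_of_arclength(self, s: np.ndarray) -> np.ndarray:
        """Arm index 1..4 containing each arclength."""
        s = np.mod(np.asarray(s, dtype=float), self.perimeter)
        return np.clip(np.searchsorted(self.s_corners, s, side="right"), 1, 4)

    def distance_to_nearest_corner(self, s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Along-perimeter distance to the nearest corner and its index 0..3."""
        s = np.mod(np.asarray(s, dtype=float), self.perimeter)
        d = np.abs(s[..., None] - self.s_corners[None, :])
        d = np.minimum(d, self.perimeter - d)
        idx = np.argmin(d, axis=-1) % 4
        return np.min(d, axis=-1), idx


def path_id(arm: int, direction: int) -> int:
    """Directed path id in 1..8 for arm in 1..4, direction +1/-1."""
    if arm not in (1, 2, 3, 4) or direction not in (1, -1):
        raise ValueError("arm must be 1..4 and direction +1 or -1")
    return 2 * (arm - 1) + (1 if direction == 1 else 2)


def path_arm_direction(pid: int) -> tuple[int, int]:
    """Inverse of :func:`path_id`."""
    if not 1 <= pid <= 8:
        raise ValueError("path id must be in 1..8")
    arm = (pid - 1) // 2 + 1
    direction = 1 if pid % 2 == 1 else -1
    return arm, direction
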