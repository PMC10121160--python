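"""Occupancy and spatial neural activity rate maps.

Occupancy (seconds per bin) and summed activity are histogrammed on a grid
of half-open square bins (2 cm default), smoothed with a truncated Gaussian
kernel, and divided:

    lambda_i = smooth(binned activity)_i / smooth(binned occupancy)_i

Smoothing is mask-aware: the kernel is truncated at 3 sigma and renormalized
per output bin over valid bins, so rates near the wall of a circular arena
are not attenuated by out-of-arena zeros.  Because the same renormalization
is applied to numerator and denominator it cancels exactly in the rate, but
it matters when a single field (e.g. occupancy for p_i) is smoothed alone.

Only frames passing the trajectory's validity mask (tracked and above the
speed threshold) contribute; each contributes 1/frame_rate seconds.  In the
open field, bins occupied for less than a minimum time (100 ms) are excluded
from all subsequent analysis.  Track maps are one-dimensional in arclength
along each of the eight directed paths, with 2-cm arclength bins.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .arena import ArenaSpec, TrackGeometry, path_arm_direction
from .behavior import PathSegmentation, Trajectory
from .core import AlignmentError, DegenerateMapError, OutOfBoundsError


@dataclass
class BinGrid:
    """Square-bin grid with half-open bins [edge, edge + size).

    ``origin`` is the world position of the (0, 0) bin corner; maps are
    stored as (n_y, n_x) arrays indexed [iy, ix] with y increasing upward.
    ``arena_mask`` marks bins inside the arena.
    """

    bin_size_cm: float
    origin: tuple[float, float]
    n_x: int
    n_y: int
    arena_mask: np.ndarray

    def __post_init__(self):
        if self.bin_size_cm <= 0:
            raise ValueError("bin_size_cm must be positive")
        self.arena_mask = np.asarray(self.arena_mask, dtype=bool)
        if self.arena_mask.shape != (self.n_y, self.n_x):
            raise ValueError("arena_mask shape must be (n_y, n_x)")

    @classmethod
    def for_circle(cls, arena: ArenaSpec, bin_size_cm: float = 2.0) -> "BinGrid":
        """Grid covering the circle's bounding box, centered on the arena.

        A bin is in-arena when its center lies within the radius minus half
        a bin, i.e. it overlaps the reachable interior substantially.
        """
        R = arena.radius_cm
        n = int(np.ceil(2 * R / bin_size_cm))
        origin = (-n * bin_size_cm / 2, -n * bin_size_cm / 2)
        cx = origin[0] + (np.arange(n) + 0.5) * bin_size_cm
        cy = origin[1] + (np.arange(n) + 0.5) * bin_size_cm
        dist = np.hypot(cx[None, :], cy[:, None])
        mask = dist <= R - bin_size_cm / 2
        return cls(bin_size_cm=bin_size_cm, origin=origin, n_x=n, n_y=n, arena_mask=mask)

    @classmethod
    def for_rectangle(
        cls, width_cm: float, height_cm: float, bin_size_cm: float = 2.0,
        origin: tuple[float, float] = (0.0, 0.0),
    ) -> "BinGrid":
        nx = int(np.ceil(width_cm / bin_size_cm))
        ny = int(np.ceil(height_cm / bin_size_cm))
        return cls(bin_size_cm=bin_size_cm, origin=origin, n_x=nx, n_y=ny,
                   arena_mask=np.ones((ny, nx), dtype=bool))

    def bin_indices(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        ix = np.floor((np.asarray(x) - self.origin[0]) / self.bin_size_cm).astype(int)
        iy = np.floor((np.asarray(y) - self.origin[1]) / self.bin_size_cm).astype(int)
        return ix, iy

    def bin_centers(self) -> tuple[np.ndarray, np.ndarray]:
        cx = self.origin[0] + (np.arange(self.n_x) + 0.5) * self.bin_size_cm
        cy = self.origin[1] + (np.arange(self.n_y) + 0.5) * self.bin_size_cm
        return cx, cy


@dataclass
class OccupancyMap:
    """Seconds per bin plus the post-threshold valid-bin mask."""

    grid: BinGrid
    t: np.ndarray  # raw (unsmoothed) seconds per bin, (n_y, n_x)
    valid: np.ndarray
    frame_rate_hz: float
    n_valid_frames: int

    @property
    def total_time_s(self) -> float:
        return float(self.t.sum())


@dataclass
class RateMap:
    """Occupancy-normalized rate map (activity units / s per bin)."""

    grid: BinGrid
    rate: np.ndarray  # lambda_i on valid bins, 0 elsewhere
    occupancy_s: np.ndarray  # smoothed occupancy backing the division
    valid: np.ndarray

    @property
    def p(self) -> np.ndarray:
        """Occupancy probability per bin, renormalized over valid bins."""
        t = np.where(self.valid, self.occupancy_s, 0.0)
        total = t.sum()
        if total == 0:
            raise DegenerateMapError("no occupied valid bins")
        return t / total

    @property
    def mean_rate(self) -> float:
        """Occupancy-weighted mean rate (lambda-bar)."""
        return float(np.sum(self.p * np.where(self.valid, self.rate, 0.0)))


# ---------------------------------------------------------------------------


def frame_bin_flat_index(trajectory: Trajectory, grid: BinGrid) -> np.ndarray:
    """Flat bin index per frame (-1 for invalid frames); bounds-checked."""
    idx = np.full(len(trajectory), -1, dtype=np.int64)
    v = trajectory.valid
    ix, iy = grid.bin_indices(trajectory.x_cm[v], trajectory.y_cm[v])
    oob = (ix < 0) | (ix >= grid.n_x) | (iy < 0) | (iy >= grid.n_y)
    if np.any(oob):
        frames = np.flatnonzero(v)[oob]
        raise OutOfBoundsError(
            f"{oob.sum()} frames fall outside the grid (first: {frames[:10].tolist()})",
            frames=frames,
        )
    idx[v] = iy * grid.n_x + ix
    return idx


def compute_occupancy(
    trajectory: Trajectory,
    grid: BinGrid,
    min_occupancy_s: float | None = None,
) -> OccupancyMap:
    """Histogram valid-frame time onto the grid and apply the occupancy mask.

    Conservation holds exactly: the map sums to
    (number of valid frames) / frame_rate.
    """
    idx = frame_bin_flat_index(trajectory, grid)
    v = idx >= 0
    counts = np.bincount(idx[v], minlength=grid.n_x * grid.n_y)
    t = counts.reshape(grid.n_y, grid.n_x) / trajectory.frame_rate_hz
    valid = grid.arena_mask.copy()
    if min_occupancy_s is not None:
        valid &= t >= min_occupancy_s
    return OccupancyMap(
        grid=grid, t=t, valid=valid,
        frame_rate_hz=trajectory.frame_rate_hz, n_valid_frames=int(v.sum()),
    )


def gaussian_kernel_1d(sigma_bins: float) -> np.ndarray:
    """Normalized 1-D Gaussian kernel truncated at 3 sigma."""
    radius = int(np.ceil(3 * sigma_bins))
    x = np.arange(-radius, radius + 1)
    k = np.exp(-(x**2) / (2 * sigma_bins**2))
    return k / k.sum()


def smooth_map(
    values: np.ndarray,
    sigma_cm: float,
    bin_size_cm: float,
    valid: np.ndarray | None = None,
    renormalize: bool = True,
) -> np.ndarray:
    """Mask-aware Gaussian smoothing of a 1-D or 2-D binned map.

    The kernel (truncated at 3 sigma) is renormalized per output bin over
    the valid mask, so values never leak across or get diluted by invalid
    bins.  With ``sigma_cm <= bin_size_cm / 10`` the input is returned
    unchanged (limiting case).  Output is zero on invalid bins.
    """
    if sigma_cm <= 0:
        raise ValueError("sigma_cm must be positive")
    values = np.asarray(values, dtype=float)
    if valid is None:
        valid = np.ones_like(values, dtype=bool)
    valid = np.asarray(valid, dtype=bool)
    if not valid.any():
        raise DegenerateMapError("all bins invalid")
    if sigma_cm <= bin_size_cm / 10:
        return np.where(valid, values, 0.0)
    kernel = gaussian_kernel_1d(sigma_cm / bin_size_cm)

    def conv(a: np.ndarray) -> np.ndarray:
        out = a
        for axis in range(a.ndim):
            out = ndimage.convolve1d(out, kernel, axis=axis, mode="constant", cval=0.0)
        return out

    num = conv(np.where(valid, values, 0.0))
    if not renormalize:
        return np.where(valid, num, 0.0)
    den = conv(valid.astype(float))
    out = np.zeros_like(values)
    out[valid] = num[valid] / den[valid]
    return out


def compute_rate_map(
    activity_row: np.ndarray,
    trajectory: Trajectory,
    grid: BinGrid,
    sigma_cm: float = 3.0,
    min_occupancy_s: float | None = 0.1,
) -> RateMap:
    """Occupancy-normalized, smoothed rate map for one cell."""
    activity_row = np.asarray(activity_row, dtype=float)
    if len(activity_row) != len(trajectory):
        raise AlignmentError(
            f"activity has {len(activity_row)} frames, trajectory {len(trajectory)}"
        )
    occ = compute_occupancy(trajectory, grid, min_occupancy_s=min_occupancy_s)
    idx = frame_bin_flat_index(trajectory, grid)
    v = idx >= 0
    act = np.bincount(idx[v], weights=activity_row[v], minlength=grid.n_x * grid.n_y)
    act = act.reshape(grid.n_y, grid.n_x)
    return _divide_smoothed(act, occ, sigma_cm)


def _divide_smoothed(act_map: np.ndarray, occ: OccupancyMap, sigma_cm: float) -> RateMap:
    grid = occ.grid
    valid = occ.valid
    sm_act = smooth_map(act_map, sigma_cm, grid.bin_size_cm, valid)
    sm_occ = smooth_map(occ.t, sigma_cm, grid.bin_size_cm, valid)
    rate = np.zeros_like(sm_act)
    occupied = valid & (sm_occ > 0)
    rate[occupied] = sm_act[occupied] / sm_occ[occupied]
    return RateMap(grid=grid, rate=rate, occupancy_s=np.where(occupied, sm_occ, 0.0),
                   valid=occupied)


# ---------------------------------------------------------------------------
# 1-D per-path maps (track)


@dataclass
class PathRateMap:
    """1-D rate map along one directed path's arclength."""

    path_id: int
    bin_size_cm: float
    rate: np.ndarray
    occupancy_s: np.ndarray  # smoothed
    raw_occupancy_s: np.ndarray
    valid: np.ndarray
    empty: bool = False


@dataclass
class PathRateMaps:
    """Rate maps for the eight directed paths of a track session."""

    maps: dict[int, PathRateMap]

    def concatenated(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(occupancy_s, rate, valid) concatenated over paths 1..8."""
        occ, rate, valid = [], [], []
        for pid in sorted(self.maps):
            m = self.maps[pid]
            occ.append(m.occupancy_s)
            rate.append(m.rate)
            valid.append(m.valid)
        return np.concatenate(occ), np.concatenate(rate), np.concatenate(valid)

    @property
    def mean_rate(self) -> float:
        occ, rate, valid = self.concatenated()
        t = np.where(valid, occ, 0.0)
        total = t.sum()
        if total == 0:
            return 0.0
        return float(np.sum(t / total * np.where(valid, rate, 0.0)))


def _path_arclength(trajectory: Trajectory, geom: TrackGeometry, frames: np.ndarray,
                    arm: int) -> np.ndarray:
    """Along-arm arclength (from the arm's low-s corner) for given frames."""
    s = geom.xy_to_arclength(trajectory.x_cm[frames], trajectory.y_cm[frames])
    rel = s - geom.s_corners[arm - 1]
    # wrap-around safety for arm 4 projections that land at s ~ 0
    rel = np.mod(rel, geom.perimeter)
    return np.clip(rel, 0.0, geom.arm_lengths[arm - 1] - 1e-9)


def compute_path_rate_maps(
    activity_row: np.ndarray,
    trajectory: Trajectory,
    segmentation: PathSegmentation,
    track: ArenaSpec,
    bin_size_cm: float = 2.0,
    sigma_cm: float = 5.0,
) -> PathRateMaps:
    """Per-path 1-D binning, smoothing, and occupancy normalization.

    Uses each path's traversal frames that also pass the trajectory's
    validity mask.  Paths with no traversals yield an all-invalid map
    flagged ``empty``.  No minimum-occupancy mask is applied on the track.
    """
    activity_row = np.asarray(activity_row, dtype=float)
    if len(activity_row) != len(trajectory):
        raise AlignmentError("activity/trajectory frame mismatch")
    if len(segmentation) == 0:
        raise ValueError("segmentation has no traversals")
    geom = TrackGeometry(track)
    fr = trajectory.frame_rate_hz
    maps: dict[int, PathRateMap] = {}
    for pid in range(1, 9):
        arm, _ = path_arm_direction(pid)
        n_bins = int(np.ceil(geom.arm_lengths[arm - 1] / bin_size_cm))
        frame_mask = segmentation.frames_of_path(pid, len(trajectory)) & trajectory.valid
        frames = np.flatnonzero(frame_mask)
        if len(frames) == 0:
            maps[pid] = PathRateMap(
                path_id=pid, bin_size_cm=bin_size_cm,
                rate=np.zeros(n_bins), occupancy_s=np.zeros(n_bins),
                raw_occupancy_s=np.zeros(n_bins),
                valid=np.zeros(n_bins, dtype=bool), empty=True,
            )
            continue
        pos = _path_arclength(trajectory, geom, frames, arm)
        b = np.minimum((pos / bin_size_cm).astype(int), n_bins - 1)
        occ = np.bincount(b, minlength=n_bins) / fr
        act = np.bincount(b, weights=activity_row[frames], minlength=n_bins)
        valid = np.ones(n_bins, dtype=bool)
        sm_occ = smooth_map(occ, sigma_cm, bin_size_cm, valid)
        sm_act = smooth_map(act, sigma_cm, bin_size_cm, valid)
        rate = np.zeros(n_bins)
        occupied = sm_occ > 0
        rate[occupied] = sm_act[occupied] / sm_occ[occupied]
        maps[pid] = PathRateMap(
            path_id=pid, bin_size_cm=bin_size_cm, rate=rate,
            occupancy_s=np.where(occupied, sm_occ, 0.0), raw_occupancy_s=occ,
            valid=occupied,
        )
    return PathRateMaps(maps=maps)
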