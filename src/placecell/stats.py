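"""Spatial information content, circular-shuffle nulls, and classification.

The spatial information of a rate map (in bits) is

    I = sum_i p_i (lambda_i / lambda_bar) log2(lambda_i / lambda_bar)

with p_i = t_i / sum t_i the occupancy distribution over valid bins,
lambda_i the rate in bin i, and lambda_bar = sum_i p_i lambda_i.  Bins with
lambda_i = 0 contribute 0 (x log x -> 0).  I is the KL divergence between
the activity-weighted spatial distribution and the occupancy distribution,
hence nonnegative and invariant to rescaling the activity trace — the
unknown per-cell deconvolution constant cancels.

Chance level is set by circular shuffles that preserve the activity trace's
autocorrelation while destroying its coupling to position:

* ``position_time_shift`` (open field): the entire position sequence is
  time-shifted by a uniform random interval between 10 s and the recording
  length minus 10 s, wrapping to the beginning.
* ``session_frame_shift`` (track): the speed-thresholded activity sequence
  along the eight paths is frame-shifted circularly.
* ``trialwise_frame_shift`` (track): activity is frame-shifted circularly
  within each trial (arm traversal) independently.

Each of 500 shuffles recomputes the identical map + information pipeline.
A cell is a place cell when its true information exceeds at least 95% of
the shuffled values (strictly; ties count against significance, so a
constant-activity cell whose nulls all tie lands at percentile 0).
"""
from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .arena import ArenaSpec
from .behavior import PathSegmentation, Trajectory
from .core import AlignmentError, PlacecellError
from .maps import (
    BinGrid,
    OccupancyMap,
    PathRateMaps,
    RateMap,
    compute_occupancy,
    compute_path_rate_maps,
    frame_bin_flat_index,
    gaussian_kernel_1d,
    smooth_map,
)


class ShuffleMode(str, Enum):
    TRIALWISE_FRAME_SHIFT = "trialwise_frame_shift"
    SESSION_FRAME_SHIFT = "session_frame_shift"
    POSITION_TIME_SHIFT = "position_time_shift"


@dataclass(frozen=True)
class ShuffleSpec:
    mode: ShuffleMode
    n_shuffles: int = 500
    margin_s: float = 10.0  # position mode only
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "mode", ShuffleMode(self.mode))
        if self.n_shuffles < 1:
            raise ValueError("n_shuffles must be >= 1")


@dataclass
class SpatialInfoResult:
    """Information content, its null distribution, and the classification."""

    information_bits: float
    null_bits: np.ndarray
    percentile: float
    is_place_cell: bool
    undefined: bool = False  # silent cell: lambda_bar = 0, not classified


# ---------------------------------------------------------------------------
# Information


def skaggs_information(occupancy_s: np.ndarray, rate: np.ndarray) -> float:
    """Information (bits) from per-bin occupancy time and rate arrays.

    Returns NaN for a silent map (lambda_bar = 0).
    """
    t = np.asarray(occupancy_s, dtype=float).ravel()
    lam = np.asarray(rate, dtype=float).ravel()
    total = t.sum()
    if total <= 0:
        raise PlacecellError("occupancy is empty")
    p = t / total
    lam_bar = float(np.sum(p * lam))
    if lam_bar == 0:
        return np.nan
    ratio = lam / lam_bar
    pos = ratio > 0
    return float(np.sum(p[pos] * ratio[pos] * np.log2(ratio[pos])))


def spatial_information(rate_map: RateMap, occupancy: OccupancyMap | None = None) -> float:
    """Information of a 2-D rate map (bits).

    By default uses the smoothed occupancy stored in the rate map (the same
    field that normalized the rate); pass an :class:`OccupancyMap` to weight
    by raw occupancy instead.  p_i is renormalized over valid bins.
    """
    if occupancy is not None:
        if occupancy.t.shape != rate_map.rate.shape:
            raise AlignmentError("rate map and occupancy grids differ")
        t = np.where(rate_map.valid, occupancy.t, 0.0)
    else:
        t = np.where(rate_map.valid, rate_map.occupancy_s, 0.0)
    return skaggs_information(t, np.where(rate_map.valid, rate_map.rate, 0.0))


def path_maps_information(maps: PathRateMaps) -> float:
    """Information over the concatenated eight path maps (occupancy-weighted)."""
    occ, rate, valid = maps.concatenated()
    return skaggs_information(np.where(valid, occ, 0.0), np.where(valid, rate, 0.0))


# ---------------------------------------------------------------------------
# Fast open-field shuffle engine


class OpenFieldShuffler:
    """Precomputed state for position time-shift nulls of one session.

    Shifting the whole position sequence by k frames against a fixed
    activity trace is equivalent to shifting activity by -k against fixed
    positions, and a circular shift permutes frames, so the occupancy map
    (a histogram over frames) is invariant.  Only the activity histogram
    must be recomputed per shuffle, which keeps 500 shuffles per cell cheap.
    """

    def __init__(
        self,
        trajectory: Trajectory,
        grid: BinGrid,
        sigma_cm: float = 3.0,
        min_occupancy_s: float | None = 0.1,
    ):
        self.grid = grid
        self.sigma_cm = sigma_cm
        self.n_frames = len(trajectory)
        self.frame_rate = trajectory.frame_rate_hz
        self.occ = compute_occupancy(trajectory, grid, min_occupancy_s=min_occupancy_s)
        self.valid = self.occ.valid
        self.idx = frame_bin_flat_index(trajectory, grid)
        self.frame_sel = self.idx >= 0
        self.idx_sel = self.idx[self.frame_sel]
        self.kernel = gaussian_kernel_1d(sigma_cm / grid.bin_size_cm)
        sm_occ = smooth_map(self.occ.t, sigma_cm, grid.bin_size_cm, self.valid)
        self.occupied = self.valid & (sm_occ > 0)
        self.sm_occ = np.where(self.occupied, sm_occ, 0.0)
        self.p = self.sm_occ / self.sm_occ.sum()
        # valid-mask smoothing denominator, reused for every activity map
        from scipy import ndimage

        den = self.valid.astype(float)
        for axis in (0, 1):
            den = ndimage.convolve1d(den, self.kernel, axis=axis, mode="constant")
        self.den = den

    def rate_map_for(self, activity_row: np.ndarray) -> np.ndarray:
        """Smoothed occupancy-normalized rate map for an activity trace."""
        from scipy import ndimage

        act = np.bincount(
            self.idx_sel,
            weights=activity_row[self.frame_sel],
            minlength=self.grid.n_x * self.grid.n_y,
        ).reshape(self.grid.n_y, self.grid.n_x)
        act = np.where(self.valid, act, 0.0)
        for axis in (0, 1):
            act = ndimage.convolve1d(act, self.kernel, axis=axis, mode="constant")
        rate = np.zeros_like(act)
        rate[self.occupied] = act[self.occupied] / self.den[self.occupied] / self.sm_occ[self.occupied]
        return rate

    def information_for(self, activity_row: np.ndarray) -> float:
        rate = self.rate_map_for(activity_row)
        lam_bar = float(np.sum(self.p * rate))
        if lam_bar == 0:
            return np.nan
        ratio = rate[self.occupied] / lam_bar
        p = self.p[self.occupied]
        pos = ratio > 0
        return float(np.sum(p[pos] * ratio[pos] * np.log2(ratio[pos])))

    def null_informations(
        self,
        activity_row: np.ndarray,
        spec: ShuffleSpec,
        rng: np.random.Generator,
        collect_maps: bool = False,
    ) -> tuple[np.ndarray, np.ndarray | None]:
        lo = int(round(spec.margin_s * self.frame_rate))
        hi = self.n_frames - lo
        if hi <= lo:
            raise ValueError("recording shorter than twice the shuffle margin")
        shifts = rng.integers(lo, hi + 1, size=spec.n_shuffles)
        nulls = np.empty(spec.n_shuffles)
        null_maps = (
            np.empty((spec.n_shuffles,) + self.valid.shape) if collect_maps else None
        )
        for j, k in enumerate(shifts):
            shifted = np.roll(activity_row, -int(k))
            if collect_maps:
                rate = self.rate_map_for(shifted)
                null_maps[j] = rate
                lam_bar = float(np.sum(self.p * rate))
                if lam_bar == 0:
                    nulls[j] = np.nan
                    continue
                ratio = rate[self.occupied] / lam_bar
                p = self.p[self.occupied]
                pos = ratio > 0
                nulls[j] = float(np.sum(p[pos] * ratio[pos] * np.log2(ratio[pos])))
            else:
                nulls[j] = self.information_for(shifted)
        return nulls, null_maps


# ---------------------------------------------------------------------------
# Track shuffles


def _track_null_informations(
    activity_row: np.ndarray,
    trajectory: Trajectory,
    segmentation: PathSegmentation,
    track: ArenaSpec,
    spec: ShuffleSpec,
    rng: np.random.Generator,
    bin_size_cm: float,
    sigma_cm: float,
) -> np.ndarray:
    """Nulls by circularly shifting activity within speed-thresholded trials
    (trialwise mode) or along the whole eight-path sequence (session mode)."""
    n = len(trajectory)
    trial_frames = [
        np.flatnonzero(
            segmentation.frames_of_path(tr.path_id, n)
            & trajectory.valid
            & (np.arange(n) >= tr.start_frame)
            & (np.arange(n) <= tr.end_frame)
        )
        for tr in segmentation.traversals
    ]
    trial_frames = [f for f in trial_frames if len(f) > 0]
    all_frames = np.concatenate(trial_frames) if trial_frames else np.array([], int)
    nulls = np.empty(spec.n_shuffles)
    shuffled = activity_row.copy()
    for j in range(spec.n_shuffles):
        shuffled[:] = activity_row
        if spec.mode is ShuffleMode.TRIALWISE_FRAME_SHIFT:
            for f in trial_frames:
                k = int(rng.integers(0, len(f) + 1))
                shuffled[f] = np.roll(activity_row[f], k)
        else:
            k = int(rng.integers(0, len(all_frames) + 1))
            shuffled[all_frames] = np.roll(activity_row[all_frames], k)
        maps = compute_path_rate_maps(
            shuffled, trajectory, segmentation, track,
            bin_size_cm=bin_size_cm, sigma_cm=sigma_cm,
        )
        nulls[j] = path_maps_information(maps)
    return nulls


# ---------------------------------------------------------------------------
# Public shuffle / classification API


def shuffle_null(
    activity_row: np.ndarray,
    trajectory: Trajectory,
    spec: ShuffleSpec,
    grid: BinGrid | None = None,
    segmentation: PathSegmentation | None = None,
    track: ArenaSpec | None = None,
    sigma_cm: float | None = None,
    bin_size_cm: float = 2.0,
    min_occupancy_s: float | None = 0.1,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Null information sample under the requested circular-shuffle mode.

    Every permutation runs through the identical map + information pipeline
    as the true statistic.  Seeded via ``spec.seed`` unless an explicit
    ``rng`` is passed.
    """
    activity_row = np.asarray(activity_row, dtype=float)
    if len(activity_row) != len(trajectory):
        raise AlignmentError("activity/trajectory frame mismatch")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    if spec.mode is ShuffleMode.POSITION_TIME_SHIFT:
        if grid is None:
            raise ValueError("position mode requires a grid")
        sig = 3.0 if sigma_cm is None else sigma_cm
        eng = OpenFieldShuffler(trajectory, grid, sigma_cm=sig,
                                min_occupancy_s=min_occupancy_s)
        nulls, _ = eng.null_informations(activity_row, spec, rng)
        return nulls
    if segmentation is None or track is None:
        raise ValueError("track shuffle modes require segmentation and track geometry")
    sig = 5.0 if sigma_cm is None else sigma_cm
    return _track_null_informations(
        activity_row, trajectory, segmentation, track, spec, rng,
        bin_size_cm=bin_size_cm, sigma_cm=sig,
    )


def classify_place_cell(
    true_information: float,
    null_bits: np.ndarray,
    significance: float = 0.95,
) -> SpatialInfoResult:
    """Percentile of the true information in its null; place cell iff >= 0.95.

    The percentile counts nulls strictly below the true value, so ties count
    against significance.  An undefined (NaN) information leaves the cell
    unclassified.
    """
    null_bits = np.asarray(null_bits, dtype=float)
    if null_bits.size == 0:
        raise ValueError("empty null sample")
    if np.isnan(true_information):
        return SpatialInfoResult(
            information_bits=np.nan, null_bits=null_bits, percentile=np.nan,
            is_place_cell=False, undefined=True,
        )
    finite_nulls = null_bits[~np.isnan(null_bits)]
    pct = float(np.sum(finite_nulls < true_information) / null_bits.size)
    return SpatialInfoResult(
        information_bits=float(true_information), null_bits=null_bits,
        percentile=pct, is_place_cell=pct >= significance,
    )
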