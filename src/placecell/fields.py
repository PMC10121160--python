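"""Place-field detection by shuffle-threshold seeding and region growing.

A field is seeded by a connected component (4-connectivity by default) of at
least five bins whose rate exceeds the per-bin 95th percentile of shuffled
rate maps, then grown to all connected bins with rate at least 5% of the
grown component's peak rate.  Overlapping grown regions are merged.  The
field outline is the staircase polyline along bin edges, which is exactly
reproducible (no subpixel smoothing).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import AlignmentError
from .maps import BinGrid, RateMap


@dataclass
class ShuffleThresholdMap:
    """Per-bin 95th-percentile rate of the shuffled (null) rate maps."""

    q95: np.ndarray
    grid: BinGrid | None = None


@dataclass
class PlaceField:
    """A detected field: bin set, peak, and boundary contour(s) in cm."""

    mask: np.ndarray  # boolean (n_y, n_x)
    peak_bin: tuple[int, int]  # (iy, ix)
    peak_rate: float
    contours: list[np.ndarray]  # closed polylines, each (k, 2) of (x_cm, y_cm)

    @property
    def n_bins(self) -> int:
        return int(self.mask.sum())


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 4:
        return ndimage.generate_binary_structure(2, 1)
    if connectivity == 8:
        return ndimage.generate_binary_structure(2, 2)
    raise ValueError("connectivity must be 4 or 8")


def shuffle_bin_threshold(
    null_rate_maps: np.ndarray,
    grid: BinGrid | None = None,
    quantile: float = 0.95,
    min_nulls: int = 20,
) -> ShuffleThresholdMap:
    """Per-bin empirical quantile (linear interpolation) across null maps."""
    maps = np.asarray(null_rate_maps, dtype=float)
    if maps.ndim != 3:
        raise AlignmentError("null maps must be stacked (n, n_y, n_x)")
    if maps.shape[0] < min_nulls:
        raise ValueError(f"need at least {min_nulls} null maps, got {maps.shape[0]}")
    if grid is not None and maps.shape[1:] != grid.arena_mask.shape:
        raise AlignmentError("null map shape does not match the grid")
    q = np.quantile(maps, quantile, axis=0, method="linear")
    return ShuffleThresholdMap(q95=q, grid=grid)


def detect_place_fields(
    rate_map: RateMap,
    threshold: ShuffleThresholdMap,
    min_seed_bins: int = 5,
    peak_fraction: float = 0.05,
    connectivity: int = 4,
) -> list[PlaceField]:
    """Detect place fields in a rate map.

    Seeds are connected components of {rate > q95} with at least
    ``min_seed_bins`` bins.  Each seed is grown across connected valid bins
    with rate >= ``peak_fraction`` of the seed component's own peak (growth
    stops at unoccupied/invalid bins); the seed itself is always retained.
    Overlapping grown regions are merged into one field.  An empty list is a
    valid result.
    """
    if threshold.q95.shape != rate_map.rate.shape:
        raise AlignmentError("threshold map shape does not match the rate map")
    rate = np.where(rate_map.valid, rate_map.rate, 0.0)
    structure = _structure(connectivity)

    supra = rate_map.valid & (rate > threshold.q95)
    seed_labels, n_seeds = ndimage.label(supra, structure=structure)
    masks: list[np.ndarray] = []
    for lab in range(1, n_seeds + 1):
        seed = seed_labels == lab
        if seed.sum() < min_seed_bins:
            continue
        peak = rate[seed].max()
        superlevel = rate_map.valid & (rate >= peak_fraction * peak)
        grow_labels, _ = ndimage.label(superlevel, structure=structure)
        touched = np.unique(grow_labels[seed])
        touched = touched[touched > 0]
        grown = seed | np.isin(grow_labels, touched)
        masks.append(grown)

    # merge overlapping grown regions
    merged: list[np.ndarray] = []
    for m in masks:
        absorbed = m
        keep = []
        for other in merged:
            if np.any(absorbed & other):
                absorbed = absorbed | other
            else:
                keep.append(other)
        keep.append(absorbed)
        merged = keep

    fields = []
    for m in merged:
        flat = np.where(m, rate, -np.inf)
        iy, ix = np.unravel_index(np.argmax(flat), flat.shape)
        fields.append(
            PlaceField(
                mask=m,
                peak_bin=(int(iy), int(ix)),
                peak_rate=float(rate[iy, ix]),
                contours=field_contours(m, rate_map.grid),
            )
        )
    fields.sort(key=lambda f: -f.peak_rate)
    return fields


def field_contours(mask: np.ndarray, grid: BinGrid) -> list[np.ndarray]:
    """Staircase boundary polylines of a bin set, in world cm.

    Boundary edges are oriented with the field interior on the left and
    chained into closed loops (one per boundary component, holes included).
    """
    mask = np.asarray(mask, dtype=bool)
    ny, nx = mask.shape
    padded = np.zeros((ny + 2, nx + 2), dtype=bool)
    padded[1:-1, 1:-1] = mask
    # directed edges between lattice vertices (ix, iy) in bin units
    edges: dict[tuple[int, int], list[tuple[int, int]]] = {}

    def add(a: tuple[int, int], b: tuple[int, int]):
        edges.setdefault(a, []).append(b)

    for iy in range(ny):
        for ix in range(nx):
            if not mask[iy, ix]:
                continue
            if not padded[iy, ix + 1]:  # south neighbor empty: edge west->east
                add((ix, iy), (ix + 1, iy))
            if not padded[iy + 2, ix + 1]:  # north: east->west
                add((ix + 1, iy + 1), (ix, iy + 1))
            if not padded[iy + 1, ix]:  # west: north->south
                add((ix, iy + 1), (ix, iy))
            if not padded[iy + 1, ix + 2]:  # east: south->north
                add((ix + 1, iy), (ix + 1, iy + 1))

    loops: list[np.ndarray] = []
    while edges:
        start = min(edges)
        path = [start]
        cur = start
        prev = None
        while True:
            nxts = edges[cur]
            if len(nxts) == 1:
                nxt = nxts.pop()
                del edges[cur]
            else:
                # ambiguous vertex (diagonal touch): prefer turning left
                # relative to the incoming direction for a consistent walk
                dx, dy = (cur[0] - prev[0], cur[1] - prev[1]) if prev else (1, 0)
                left = (-dy, dx)
                pref = (cur[0] + left[0], cur[1] + left[1])
                nxt = pref if pref in nxts else nxts[0]
                nxts.remove(nxt)
                if not nxts:
                    del edges[cur]
            path.append(nxt)
            prev, cur = cur, nxt
            if cur == start:
                break
        pts = np.asarray(path, dtype=float)
        pts[:, 0] = grid.origin[0] + pts[:, 0] * grid.bin_size_cm
        pts[:, 1] = grid.origin[1] + pts[:, 1] * grid.bin_size_cm
        loops.append(pts)
    return loops
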