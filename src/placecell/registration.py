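"""Cross-session cell-footprint registration and sub-FOV cell counting.

Footprints (nonnegative weight images from source extraction) are
max-normalized and thresholded at 0.5 to give compact binary contours.
After a manual/configured session alignment (translation plus radial scale),
cell pairs within a 24-um centroid gate are scored by centroid distance and
Pearson correlation of the aligned normalized footprints over their union
support; pairs with distance < 6 um and correlation > 0.8 are accepted
greedily (ascending distance, one-to-one).  A probabilistic mixture model is
deliberately not used — the deterministic thresholds are the operative rule.

Also provides the random sub-field-of-view counting procedure: the number of
cell centroids inside each of 500 random 1-mm-diameter circles placed
uniformly inside the full field of view.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import PlacecellError


@dataclass
class CellContour:
    """One cell's normalized footprint, binary mask, and centroid (um)."""

    cell_id: int
    footprint: np.ndarray  # max-normalized, max = 1
    binary_mask: np.ndarray  # footprint >= 0.5
    centroid_um: np.ndarray  # (x, y)


@dataclass
class SessionAlignment:
    """Rigid translation plus radial scaling about a center (all in um)."""

    translation_um: tuple[float, float] = (0.0, 0.0)
    radial_scale: float = 1.0
    center_um: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        if self.radial_scale <= 0:
            raise ValueError("radial_scale must be positive")

    def apply(self, points_um: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points_um, dtype=float))
        c = np.asarray(self.center_um, dtype=float)
        t = np.asarray(self.translation_um, dtype=float)
        return c + self.radial_scale * (p - c) + t


@dataclass
class CellMatch:
    id_a: int
    id_b: int
    distance_um: float
    correlation: float


@dataclass
class MatchResult:
    matches: list[CellMatch]

    def __len__(self) -> int:
        return len(self.matches)

    @property
    def pairs(self) -> set[tuple[int, int]]:
        return {(m.id_a, m.id_b) for m in self.matches}

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {"id_a": m.id_a, "id_b": m.id_b,
                 "dist_um": m.distance_um, "correlation": m.correlation}
                for m in self.matches
            ]
        )


def preprocess_contours(
    footprints: np.ndarray, pixel_size_um: float, cell_ids: np.ndarray | None = None
) -> list[CellContour]:
    """Max-normalize, binarize at 0.5, and compute weighted centroids.

    ``footprints`` is (n_cells, h, w) nonnegative.  All-zero footprints are
    rejected with their cell ids.
    """
    fp = np.asarray(footprints, dtype=float)
    if fp.ndim != 3:
        raise ValueError("footprints must be stacked (n, h, w)")
    if np.any(fp < 0):
        raise ValueError("footprints must be nonnegative")
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    ids = np.arange(fp.shape[0]) if cell_ids is None else np.asarray(cell_ids)
    zero = fp.reshape(fp.shape[0], -1).max(axis=1) == 0
    if np.any(zero):
        raise PlacecellError(f"all-zero footprints for cells {ids[zero].tolist()}")
    out = []
    for i in range(fp.shape[0]):
        norm = fp[i] / fp[i].max()
        rows, cols = np.nonzero(norm)
        w = norm[rows, cols]
        cx = float((cols * w).sum() / w.sum()) * pixel_size_um
        cy = float((rows * w).sum() / w.sum()) * pixel_size_um
        out.append(
            CellContour(
                cell_id=int(ids[i]),
                footprint=norm,
                binary_mask=norm >= 0.5,
                centroid_um=np.array([cx, cy]),
            )
        )
    return out


def _footprint_correlation(
    a: np.ndarray, b: np.ndarray, shift_px: np.ndarray
) -> float:
    """Pearson correlation over the union support after shifting b by shift_px.

    ``shift_px`` is the (x, y) displacement that maps session-B pixels into
    session-A's frame (bilinear interpolation).
    """
    b_aligned = ndimage.shift(b, shift=(shift_px[1], shift_px[0]), order=1,
                              mode="constant", cval=0.0)
    support = (a > 0) | (b_aligned > 0)
    if support.sum() < 2:
        return 0.0
    va = a[support]
    vb = b_aligned[support]
    sa, sb = va.std(), vb.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.corrcoef(va, vb)[0, 1])


def match_cells(
    session_a: list[CellContour],
    session_b: list[CellContour],
    alignment: SessionAlignment | None = None,
    pixel_size_um: float = 1.0,
    gate_um: float = 24.0,
    max_distance_um: float = 6.0,
    min_correlation: float = 0.8,
) -> MatchResult:
    """One-to-one cell matching between two sessions.

    The alignment is applied to session B centroids/footprints first.
    Candidates are gated at ``gate_um`` centroid distance; a pair is
    acceptable when distance < ``max_distance_um`` AND correlation >
    ``min_correlation``; acceptance is greedy by ascending distance, each
    cell used at most once.  Empty sessions yield an empty match set.
    """
    if alignment is None:
        alignment = SessionAlignment()
    if not session_a or not session_b:
        return MatchResult(matches=[])
    ca = np.array([c.centroid_um for c in session_a])
    cb_raw = np.array([c.centroid_um for c in session_b])
    cb = alignment.apply(cb_raw)
    d = np.linalg.norm(ca[:, None, :] - cb[None, :, :], axis=2)
    cand = np.argwhere(d < gate_um)
    scored: list[tuple[float, int, int, float]] = []
    for i, j in cand:
        dist = float(d[i, j])
        # displacement of B's footprint in A's pixel frame
        shift_px = (cb[j] - cb_raw[j]) / pixel_size_um
        corr = _footprint_correlation(
            session_a[i].footprint, session_b[j].footprint, shift_px
        )
        if dist < max_distance_um and corr > min_correlation:
            scored.append((dist, int(i), int(j), corr))
    scored.sort(key=lambda s: (s[0], s[1], s[2]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    matches = []
    for dist, i, j, corr in scored:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        matches.append(
            CellMatch(
                id_a=session_a[i].cell_id, id_b=session_b[j].cell_id,
                distance_um=dist, correlation=corr,
            )
        )
    return MatchResult(matches=matches)


def estimate_alignment(
    session_a: list[CellContour],
    session_b: list[CellContour],
    translation_range_um: float = 20.0,
    translation_step_um: float = 2.0,
    scales: tuple[float, ...] = (0.98, 0.99, 1.0, 1.01, 1.02),
    match_radius_um: float = 6.0,
) -> SessionAlignment:
    """Coarse grid search for the session alignment.

    Maximizes the number of centroid pairs within ``match_radius_um``
    (ties broken by the summed residual distance).  Intended as a starting
    point for, not a replacement of, careful manual alignment.
    """
    ca = np.array([c.centroid_um for c in session_a])
    cb = np.array([c.centroid_um for c in session_b])
    center = cb.mean(axis=0)
    steps = np.arange(-translation_range_um, translation_range_um + 1e-9,
                      translation_step_um)
    best = (-1, np.inf, SessionAlignment())
    for s in scales:
        for tx in steps:
            for ty in steps:
                al = SessionAlignment(translation_um=(tx, ty), radial_scale=s,
                                      center_um=tuple(center))
                moved = al.apply(cb)
                d = np.linalg.norm(ca[:, None, :] - moved[None, :, :], axis=2)
                nn = d.min(axis=1)
                hits = int((nn < match_radius_um).sum())
                resid = float(nn[nn < match_radius_um].sum())
                if hits > best[0] or (hits == best[0] and resid < best[1]):
                    best = (hits, resid, al)
    return best[2]


@dataclass
class FovCountResult:
    counts: np.ndarray
    mean: float
    sd: float


def count_cells_in_random_fovs(
    centroids_um: np.ndarray,
    fov_extent_um: tuple[float, float],
    circle_diameter_um: float = 1000.0,
    n_samples: int = 500,
    seed: int = 0,
) -> FovCountResult:
    """Cell counts inside random circular sub-fields of view.

    Circle centers are uniform over positions keeping the circle fully
    inside the rectangular field of view; each sample counts the centroids
    within the circle.  The mean and SD (ddof=1) summarize the distribution.
    """
    centroids = np.atleast_2d(np.asarray(centroids_um, dtype=float))
    W, H = fov_extent_um
    r = circle_diameter_um / 2.0
    if W < circle_diameter_um or H < circle_diameter_um:
        raise ValueError("field of view smaller than the sampling circle")
    rng = np.random.default_rng(seed)
    cx = rng.uniform(r, W - r, size=n_samples)
    cy = rng.uniform(r, H - r, size=n_samples)
    if centroids.size == 0:
        counts = np.zeros(n_samples, dtype=int)
    else:
        d2 = (centroids[None, :, 0] - cx[:, None]) ** 2 + (
            centroids[None, :, 1] - cy[:, None]
        ) ** 2
        counts = (d2 <= r * r).sum(axis=1)
    sd = float(np.std(counts, ddof=1)) if n_samples > 1 else 0.0
    return FovCountResult(counts=counts, mean=float(np.mean(counts)), sd=sd)
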