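"""Occupancy binning, mask-aware smoothing, and rate-map normalization."""
import numpy as np
import pytest

import placecell as pc
from placecell.behavior import Trajectory, apply_speed_threshold
from placecell.core import AlignmentError, DegenerateMapError, OutOfBoundsError
from placecell.maps import (
    BinGrid,
    compute_occupancy,
    compute_path_rate_maps,
    compute_rate_map,
    smooth_map,
)
from placecell.synthetic import TuningSpec, tuning_rate


def square_grid(n=10, bs=2.0):
    return BinGrid(bin_size_cm=bs, origin=(0.0, 0.0), n_x=n, n_y=n,
                   arena_mask=np.ones((n, n), bool))


def still_traj(n, x, y, fr=20.0):
    return Trajectory(t=np.arange(n) / fr, x_cm=np.full(n, float(x)),
                      y_cm=np.full(n, float(y)), frame_rate_hz=fr)


# ---------------------------------------------------------------------------
# Occupancy


def test_single_bin_occupancy_seconds():
    occ = compute_occupancy(still_traj(100, 5.0, 5.0, fr=20.0), square_grid())
    assert occ.t[2, 2] == pytest.approx(5.0)
    assert occ.t.sum() == pytest.approx(5.0)


def test_minimum_occupancy_threshold_excludes_bin():
    # 80 ms in one bin at 100 fps < the 100-ms minimum
    traj = still_traj(8, 5.0, 5.0, fr=100.0)
    occ = compute_occupancy(traj, square_grid(), min_occupancy_s=0.1)
    assert occ.t[2, 2] == pytest.approx(0.08)
    assert not occ.valid[2, 2]
    occ2 = compute_occupancy(still_traj(10, 5.0, 5.0, fr=100.0), square_grid(),
                             min_occupancy_s=0.1)
    assert occ2.valid[2, 2]


@pytest.mark.parametrize("seed", range(5))
def test_occupancy_conservation_exact(seed, grid, open_arena):
    traj = pc.simulate_open_field_trajectory(open_arena, duration_s=30,
                                             frame_rate_hz=15, seed=seed)
    traj = apply_speed_threshold(traj, 5.0)
    occ = compute_occupancy(traj, grid)
    assert occ.t.sum() == pytest.approx(occ.n_valid_frames / traj.frame_rate_hz,
                                        abs=1e-9)


def test_out_of_bounds_frames_reported():
    with pytest.raises(OutOfBoundsError) as exc:
        compute_occupancy(still_traj(5, 100.0, 5.0), square_grid())
    assert exc.value.frames is not None


def test_half_open_bins():
    g = square_grid()
    ix, iy = g.bin_indices(np.array([0.0, 2.0 - 1e-12, 2.0]), np.zeros(3))
    assert list(ix) == [0, 0, 1]


# ---------------------------------------------------------------------------
# Smoothing


def test_uniform_field_unchanged_by_smoothing():
    v = np.full((20, 20), 3.7)
    out = smooth_map(v, sigma_cm=5.0, bin_size_cm=2.0)
    assert np.allclose(out, 3.7, atol=1e-9)


def test_delta_smoothing_matches_direct_convolution_and_conserves_sum():
    v = np.zeros((41, 41))
    v[20, 20] = 10.0
    out = smooth_map(v, sigma_cm=4.0, bin_size_cm=2.0)
    # direct oracle: outer product of the truncated normalized kernel
    from placecell.maps import gaussian_kernel_1d

    k = gaussian_kernel_1d(2.0)
    oracle = 10.0 * np.outer(k, k)
    r = len(k) // 2
    assert np.allclose(out[20 - r : 20 + r + 1, 20 - r : 20 + r + 1], oracle,
                       atol=1e-12)
    assert out.sum() == pytest.approx(10.0, abs=1e-9)


def test_tiny_sigma_is_identity():
    rng = np.random.default_rng(0)
    v = rng.uniform(size=(8, 8))
    out = smooth_map(v, sigma_cm=0.1, bin_size_cm=2.0)
    assert np.array_equal(out, v)


def test_all_invalid_mask_rejected():
    with pytest.raises(DegenerateMapError):
        smooth_map(np.ones((4, 4)), 3.0, 2.0, valid=np.zeros((4, 4), bool))


def test_mask_renormalization_keeps_uniform_at_edges():
    v = np.full((15, 15), 2.0)
    mask = np.zeros((15, 15), bool)
    mask[4:11, 4:11] = True
    out = smooth_map(v, sigma_cm=4.0, bin_size_cm=2.0, valid=mask)
    assert np.allclose(out[mask], 2.0, atol=1e-9)
    assert np.all(out[~mask] == 0)


# ---------------------------------------------------------------------------
# Rate maps


def test_constant_activity_gives_uniform_rate(grid, short_trajectory):
    traj = apply_speed_threshold(short_trajectory, 5.0)
    a = np.full(len(traj), 0.2)
    rm = compute_rate_map(a, traj, grid, sigma_cm=3.0, min_occupancy_s=None)
    fr = traj.frame_rate_hz
    assert np.allclose(rm.rate[rm.valid], 0.2 * fr, atol=1e-9)


def test_zero_activity_gives_zero_map(grid, short_trajectory):
    rm = compute_rate_map(np.zeros(len(short_trajectory)), short_trajectory, grid)
    assert np.all(rm.rate == 0)


def test_frame_mismatch_is_alignment_error(grid, short_trajectory):
    with pytest.raises(AlignmentError):
        compute_rate_map(np.zeros(10), short_trajectory, grid)


def test_mean_rate_identity(grid, short_trajectory):
    """On a full mask, lambda-bar equals total thresholded activity divided
    by total thresholded time (smoothing conserves both sums)."""
    traj = apply_speed_threshold(short_trajectory, 5.0)
    rng = np.random.default_rng(3)
    a = rng.gamma(2.0, 0.1, size=len(traj))
    # full-mask grid with >= 3 sigma of clearance around the arena
    full = BinGrid(bin_size_cm=2.0, origin=(-60.0, -60.0), n_x=60, n_y=60,
                   arena_mask=np.ones((60, 60), bool))
    rm = compute_rate_map(a, traj, full, sigma_cm=3.0, min_occupancy_s=None)
    total_t = traj.valid.sum() / traj.frame_rate_hz
    assert rm.mean_rate == pytest.approx(a[traj.valid].sum() / total_t, rel=1e-6)
    # internal consistency of the stored decomposition (arena-masked grid)
    rm2 = compute_rate_map(a, traj, grid, sigma_cm=3.0, min_occupancy_s=None)
    assert rm2.mean_rate == pytest.approx(np.sum(rm2.p * rm2.rate), abs=1e-9)


def test_noiseless_tuned_cell_recovers_center(grid, open_arena, full_trajectory):
    traj = apply_speed_threshold(full_trajectory, 5.0)
    spec = TuningSpec(center_cm=(10.0, -8.0), sigma_cm=10.0, peak_rate=5.0,
                      baseline_rate=1.0)
    act = pc.simulate_place_cell_activity(traj, [spec], noise=None)
    rm = compute_rate_map(act.values[0], traj, grid, sigma_cm=3.0,
                          min_occupancy_s=0.1)
    iy, ix = np.unravel_index(np.argmax(np.where(rm.valid, rm.rate, -np.inf)),
                              rm.rate.shape)
    cx, cy = rm.grid.bin_centers()
    assert abs(cx[ix] - 10.0) <= 2.0 and abs(cy[iy] + 8.0) <= 2.0
    true = tuning_rate(spec, *np.meshgrid(cx, cy))
    sel = rm.valid
    corr = np.corrcoef(rm.rate[sel], true[sel])[0, 1]
    assert corr > 0.95


# ---------------------------------------------------------------------------
# Path maps


def test_path_restricted_activity_maps_to_one_path(track_arena, track_session):
    traj, seg = track_session
    cell = TuningSpec(center_cm=(125.0, 0.0), sigma_cm=15.0, peak_rate=5.0,
                      baseline_rate=0.0, directional_path_ids=frozenset({1}))
    act = pc.simulate_place_cell_activity(traj, [cell], noise=None,
                                          segmentation=seg)
    traj_v = apply_speed_threshold(traj, 20.0)
    maps = compute_path_rate_maps(act.values[0], traj_v, seg, track_arena)
    assert maps.maps[1].rate.max() > 0
    for pid in range(2, 9):
        assert maps.maps[pid].rate.max() == pytest.approx(0.0, abs=1e-9)


def test_constant_activity_uniform_on_visited_paths(track_arena, track_session):
    traj, seg = track_session
    traj_v = apply_speed_threshold(traj, 20.0)
    a = np.full(len(traj), 0.5)
    maps = compute_path_rate_maps(a, traj_v, seg, track_arena)
    fr = traj.frame_rate_hz
    for pid, m in maps.maps.items():
        if m.empty:
            continue
        assert np.allclose(m.rate[m.valid], 0.5 * fr, atol=1e-9)


def test_unvisited_path_flagged_empty(track_arena):
    traj, seg = pc.simulate_track_trajectory(track_arena, n_traversals=1,
                                             short_path_prob=1.0, seed=2)
    traj_v = apply_speed_threshold(traj, 20.0)
    maps = compute_path_rate_maps(np.ones(len(traj)), traj_v, seg, track_arena)
    assert not maps.maps[1].empty
    assert maps.maps[3].empty and not maps.maps[3].valid.any()
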