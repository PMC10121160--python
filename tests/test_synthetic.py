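"""Generator contracts: determinism, arena containment, activity expectation
law, unit-quaternion streams, and LED frame rendering."""
import numpy as np
import pytest

import placecell as pc
from placecell.synthetic import (
    ActivityNoise,
    AngularMotion,
    TuningSpec,
    tuning_rate,
)


def test_zero_duration_rejected(open_arena):
    with pytest.raises(ValueError):
        pc.simulate_open_field_trajectory(open_arena, duration_s=0.0)
    with pytest.raises(ValueError):
        pc.simulate_open_field_trajectory(open_arena, frame_rate_hz=-1.0)


def test_trajectory_deterministic_under_seed(open_arena):
    a = pc.simulate_open_field_trajectory(open_arena, duration_s=20, seed=9)
    b = pc.simulate_open_field_trajectory(open_arena, duration_s=20, seed=9)
    assert np.array_equal(a.x_cm, b.x_cm) and np.array_equal(a.y_cm, b.y_cm)


def test_positions_inside_arena(open_arena, full_trajectory):
    r = np.hypot(full_trajectory.x_cm, full_trajectory.y_cm)
    assert r.max() <= open_arena.radius_cm


def test_open_field_coverage_contract(open_arena, grid, full_trajectory):
    """Default motion params visit >= 90% of in-arena bins for >= 100 ms."""
    occ = pc.compute_occupancy(full_trajectory, grid, min_occupancy_s=0.1)
    coverage = (occ.t[grid.arena_mask] >= 0.1).mean()
    assert coverage >= 0.9


def test_track_requires_track_arena(open_arena):
    with pytest.raises(ValueError):
        pc.simulate_track_trajectory(open_arena)


def test_track_positions_on_arms(track_arena, track_session):
    traj, _ = track_session
    from placecell.arena import TrackGeometry

    geom = TrackGeometry(track_arena)
    s = geom.xy_to_arclength(traj.x_cm, traj.y_cm)
    center = geom.arclength_to_xy(s)
    off = np.hypot(traj.x_cm - center[:, 0], traj.y_cm - center[:, 1])
    assert off.max() <= track_arena.path_width_cm / 2 + 1e-9


# ---------------------------------------------------------------------------
# Activity


def test_far_field_cell_silent():
    traj = pc.Trajectory(t=np.arange(100) / 15, x_cm=np.zeros(100),
                         y_cm=np.zeros(100), frame_rate_hz=15.0)
    cell = TuningSpec(center_cm=(200.0, 0.0), sigma_cm=5.0, peak_rate=4.0,
                      baseline_rate=0.0)
    act = pc.simulate_place_cell_activity(traj, [cell], noise=None)
    # trajectory is 40 sigma from the center: exp(-800) underflows to 0
    assert np.all(act.values == 0)


def test_stationary_at_center_noiseless_equals_peak_over_frame_rate():
    fr = 15.0
    traj = pc.Trajectory(t=np.arange(50) / fr, x_cm=np.zeros(50),
                         y_cm=np.zeros(50), frame_rate_hz=fr)
    cell = TuningSpec(center_cm=(0.0, 0.0), sigma_cm=5.0, peak_rate=4.0,
                      baseline_rate=1.0)
    act = pc.simulate_place_cell_activity(traj, [cell], noise=None)
    assert np.allclose(act.values, 4.0 / fr)


def test_negative_sigma_rejected():
    with pytest.raises(ValueError):
        TuningSpec(center_cm=(0, 0), sigma_cm=0.0, peak_rate=1.0)


def test_activity_nonnegative_and_deterministic(short_trajectory):
    cells, _ = pc.synthetic.default_open_field_cells(n_tuned=3, n_untuned=2, seed=1)
    a = pc.simulate_place_cell_activity(short_trajectory, cells, seed=5)
    b = pc.simulate_place_cell_activity(short_trajectory, cells, seed=5)
    assert np.array_equal(a.values, b.values)
    assert np.all(a.values >= 0)


def test_expectation_law_monte_carlo():
    """Mean activity at a fixed position converges to rate/frame_rate."""
    fr = 15.0
    n = 10_000
    traj = pc.Trajectory(t=np.arange(n) / fr, x_cm=np.full(n, 6.0),
                         y_cm=np.zeros(n), frame_rate_hz=fr)
    cell = TuningSpec(center_cm=(0.0, 0.0), sigma_cm=10.0, peak_rate=5.0,
                      baseline_rate=1.0)
    act = pc.simulate_place_cell_activity(traj, [cell], noise=ActivityNoise(),
                                          seed=8)
    expected = tuning_rate(cell, np.array([6.0]), np.array([0.0]))[0] / fr
    # Poisson x gamma(3): per-frame CV ~ sqrt((1 + 4/3 mu)/mu); SE ~ 1.2%
    assert act.values.mean() == pytest.approx(expected, rel=0.05)


def test_center_bin_mean_activity_tracks_peak_rate(full_trajectory):
    """Across tuned cells, mean activity in the frames nearest each cell's
    center matches peak_rate / frame_rate (Monte-Carlo, pooled)."""
    cells, mask = pc.synthetic.default_open_field_cells(n_tuned=50, n_untuned=0,
                                                        seed=2)
    act = pc.simulate_place_cell_activity(full_trajectory, cells, seed=3)
    fr = full_trajectory.frame_rate_hz
    ratios = []
    for row, spec in zip(act.values, cells):
        d = np.hypot(full_trajectory.x_cm - spec.center_cm[0],
                     full_trajectory.y_cm - spec.center_cm[1])
        near = d <= 2.0
        if near.sum() < 5:
            continue
        expected = tuning_rate(spec, full_trajectory.x_cm[near],
                               full_trajectory.y_cm[near]).mean() / fr
        ratios.append(row[near].mean() / expected)
    ratios = np.asarray(ratios)
    assert len(ratios) >= 30
    # pooled over cells the Monte-Carlo mean is tight even though single
    # cells fluctuate (few frames fall within 2 cm of a center)
    assert ratios.mean() == pytest.approx(1.0, abs=0.15)


def test_directional_cell_needs_segmentation(short_trajectory):
    cell = TuningSpec(center_cm=(0, 0), sigma_cm=5.0, peak_rate=2.0,
                      directional_path_ids=frozenset({1}))
    with pytest.raises(ValueError):
        pc.simulate_place_cell_activity(short_trajectory, [cell])


# ---------------------------------------------------------------------------
# Orientation stream


def test_orientation_stream_constant_without_motion():
    s = pc.simulate_orientation_stream(10, motion=None)
    assert np.all(s.wxyz == s.wxyz[0])


def test_orientation_stream_unit_norm():
    s = pc.simulate_orientation_stream(500, motion=AngularMotion(), seed=4)
    assert np.abs(np.linalg.norm(s.wxyz, axis=1) - 1.0).max() < 1e-9


def test_orientation_stream_yaw_integration():
    # 90 deg about z over 1 s
    s = pc.simulate_orientation_stream(
        16, frame_rate_hz=15.0, angular_velocity_dps=np.array([0, 0, 90.0])
    )
    ang = pc.convert_orientation_stream(s)
    assert ang.yaw[-1] - ang.yaw[0] == pytest.approx(90.0, abs=1e-6)


def test_orientation_stream_needs_frames():
    with pytest.raises(ValueError):
        pc.simulate_orientation_stream(0)


# ---------------------------------------------------------------------------
# LED rendering


def test_noiseless_frame_argmax_at_mapped_position():
    traj = pc.Trajectory(t=[0.0], x_cm=[10.0], y_cm=[20.0], frame_rate_hz=15.0)
    frames, flagged = pc.render_led_frames(
        traj, (64, 64), np.eye(2), background_level=0.0,
        background_noise_sd=0.0, seed=0,
    )
    assert not flagged[0]
    iy, ix = np.unravel_index(np.argmax(frames[0]), frames[0].shape)
    assert (ix, iy) == (10, 20)


def test_spot_outside_image_flagged():
    traj = pc.Trajectory(t=[0.0], x_cm=[500.0], y_cm=[20.0], frame_rate_hz=15.0)
    frames, flagged = pc.render_led_frames(traj, (64, 64), np.eye(2), seed=0)
    assert flagged[0]


def test_zero_contrast_spot_flagged():
    from placecell.synthetic import LedSpot

    traj = pc.Trajectory(t=[0.0], x_cm=[10.0], y_cm=[10.0], frame_rate_hz=15.0)
    _, flagged = pc.render_led_frames(
        traj, (32, 32), np.eye(2), spot=LedSpot(amplitude=0.0), seed=0
    )
    assert flagged[0]
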