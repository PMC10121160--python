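"""Synthetic sessions with the statistical structure the analysis assumes.

Every downstream stage (LED tracking, rate maps, information, shuffles,
field detection, registration) is tested against sessions from this module,
so its models are deliberately simple and fully parameterized:

* Open-field trajectories: a waypoint-seeking random walk.  A new goal is
  drawn uniformly in the arena whenever the current one is reached or a
  renewal timer (default 20 s, emulating pellets thrown at random locations
  every 20 s) expires; heading relaxes toward the goal with angular noise
  and speed follows an Ornstein-Uhlenbeck process.  This yields near-uniform
  arena sampling without claiming to match real rat gait statistics.
* Track trajectories: feeder-to-feeder journeys along the rectangle
  perimeter, alternating ends, choosing the direct 2.5-m arm or the 5-m
  three-arm detour with configurable probability, with ground-truth arm
  traversal labels.
* Activity: deconvolved-style nonnegative values whose per-frame expectation
  is ``(baseline + (peak-baseline) * exp(-||x-c||^2 / 2 sigma^2)) / frame_rate``,
  optionally Poisson-sampled with gamma multiplicative noise (deconvolved
  activity is scaled by an unknown per-cell constant, so only relative
  scale matters downstream).
* Orientation: unit-quaternion streams integrated from smoothly varying
  angular velocity.
* Behavior video: Gaussian LED spots on noisy 8-bit background frames.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .arena import ArenaShape, ArenaSpec, TrackGeometry, path_id
from .behavior import PathSegmentation, Trajectory, Traversal, compute_speed
from .core import ActivityMatrix
from .orientation import QuaternionStream


@dataclass(frozen=True)
class TuningSpec:
    """Gaussian spatial tuning of one simulated cell.

    Rates are in activity units per second.  ``directional_path_ids``
    restricts tuning to frames inside traversals of the listed directed
    paths (track mode), emulating direction-modulated place cells.
    """

    center_cm: tuple[float, float]
    sigma_cm: float
    peak_rate: float
    baseline_rate: float = 0.0
    directional_path_ids: frozenset[int] | None = None

    def __post_init__(self):
        if self.sigma_cm <= 0:
            raise ValueError("sigma_cm must be positive")
        if not (self.peak_rate >= self.baseline_rate >= 0):
            raise ValueError("need peak_rate >= baseline_rate >= 0")


@dataclass(frozen=True)
class OpenFieldMotion:
    """Bounded-random-walk parameters for the open-field walker."""

    mean_speed_cm_s: float = 22.0
    speed_sd_cm_s: float = 8.0
    speed_tau_s: float = 1.0
    min_speed_cm_s: float = 3.0
    max_speed_cm_s: float = 45.0
    turn_gain_per_s: float = 4.0
    heading_noise_rad_sqrt_s: float = 0.6
    waypoint_interval_s: float = 20.0
    waypoint_capture_cm: float = 4.0
    # waypoint radius ~ R * u^exponent: exponents below 0.5 oversample the
    # wall region, matching the edge-heavy coverage of real open-field rats
    waypoint_radius_exponent: float = 0.35
    wall_margin_cm: float = 1.0


@dataclass(frozen=True)
class TrackMotion:
    """Running-speed and dwell parameters for track journeys."""

    run_speed_cm_s: float = 45.0
    speed_sd_cm_s: float = 8.0
    min_speed_cm_s: float = 25.0
    feeder_dwell_s: float = 1.5
    lateral_sd_cm: float = 1.0


@dataclass(frozen=True)
class ActivityNoise:
    """Noise model for deconvolved activity.

    ``poisson`` draws per-frame counts at the rate-derived mean;
    ``gamma_shape`` (if set) multiplies by unit-mean gamma noise, giving the
    continuous nonnegative values typical of deconvolution output.
    """

    poisson: bool = True
    gamma_shape: float | None = 3.0

    @classmethod
    def none(cls) -> "ActivityNoise":
        return cls(poisson=False, gamma_shape=None)


@dataclass(frozen=True)
class AngularMotion:
    """Ornstein-Uhlenbeck angular-velocity parameters (deg/s per axis)."""

    rate_sd_dps: tuple[float, float, float] = (30.0, 30.0, 90.0)
    tau_s: float = 0.5


@dataclass(frozen=True)
class LedSpot:
    amplitude: float = 180.0
    sigma_px: float = 2.0


@dataclass
class SyntheticSession:
    """A complete simulated recording with ground truth."""

    trajectory: Trajectory
    activity: ActivityMatrix
    orientation: QuaternionStream | None
    ground_truth: list[TuningSpec]
    seed: int
    segmentation: PathSegmentation | None = None
    tuned_mask: np.ndarray | None = None


# ---------------------------------------------------------------------------
# Trajectories


def _uniform_in_disk(rng: np.random.Generator, radius: float) -> np.ndarray:
    r = radius * np.sqrt(rng.uniform())
    phi = rng.uniform(0, 2 * np.pi)
    return np.array([r * np.cos(phi), r * np.sin(phi)])


def simulate_open_field_trajectory(
    arena: ArenaSpec,
    duration_s: float = 840.0,
    frame_rate_hz: float = 15.0,
    motion: OpenFieldMotion = OpenFieldMotion(),
    seed: int = 0,
) -> Trajectory:
    """Simulate near-uniform exploration of a circular arena.

    With default parameters a 14-min run at 15 Hz occupies >= 90% of the
    in-arena 2-cm bins for at least 100 ms.
    """
    if arena.shape is not ArenaShape.CIRCLE:
        raise ValueError("open-field simulation requires a circle arena")
    if duration_s <= 0 or frame_rate_hz <= 0:
        raise ValueError("duration_s and frame_rate_hz must be positive")
    n = int(round(duration_s * frame_rate_hz))
    if n == 0:
        raise ValueError("requested duration yields zero frames")
    rng = np.random.default_rng(seed)
    dt = 1.0 / frame_rate_hz
    R = arena.radius_cm - motion.wall_margin_cm

    def draw_goal() -> np.ndarray:
        r = R * rng.uniform() ** motion.waypoint_radius_exponent
        phi = rng.uniform(0, 2 * np.pi)
        return np.array([r * np.cos(phi), r * np.sin(phi)])

    pos = _uniform_in_disk(rng, 0.8 * R)
    goal = draw_goal()
    heading = rng.uniform(0, 2 * np.pi)
    speed = motion.mean_speed_cm_s
    t_goal = 0.0

    xs = np.empty(n)
    ys = np.empty(n)
    for i in range(n):
        t_goal += dt
        if t_goal >= motion.waypoint_interval_s or np.hypot(*(goal - pos)) < motion.waypoint_capture_cm:
            goal = draw_goal()
            t_goal = 0.0
        desired = np.arctan2(goal[1] - pos[1], goal[0] - pos[0])
        err = (desired - heading + np.pi) % (2 * np.pi) - np.pi
        heading += motion.turn_gain_per_s * err * dt
        heading += motion.heading_noise_rad_sqrt_s * np.sqrt(dt) * rng.standard_normal()
        speed += (motion.mean_speed_cm_s - speed) * dt / motion.speed_tau_s
        speed += motion.speed_sd_cm_s * np.sqrt(dt) * rng.standard_normal()
        speed = float(np.clip(speed, motion.min_speed_cm_s, motion.max_speed_cm_s))
        pos = pos + speed * dt * np.array([np.cos(heading), np.sin(heading)])
        r = np.hypot(*pos)
        if r > R:  # clamp to the wall and steer back inside
            pos = pos * (R / r)
            heading = np.arctan2(goal[1] - pos[1], goal[0] - pos[0])
        xs[i] = pos[0]
        ys[i] = pos[1]
    traj = Trajectory(
        t=np.arange(n) / frame_rate_hz,
        x_cm=xs,
        y_cm=ys,
        frame_rate_hz=frame_rate_hz,
    )
    return compute_speed(traj)


def simulate_track_trajectory(
    arena: ArenaSpec,
    n_traversals: int = 32,
    short_path_prob: float = 0.7,
    frame_rate_hz: float = 23.0,
    motion: TrackMotion = TrackMotion(),
    seed: int = 0,
) -> tuple[Trajectory, PathSegmentation]:
    """Simulate alternating feeder-to-feeder journeys on the track.

    Returns the trajectory and the ground-truth segmentation of exactly
    ``n_traversals`` directed arm traversals (a long journey contributes
    three arm traversals; generation stops once the count is reached).
    """
    if arena.shape is not ArenaShape.RECTANGLE_TRACK:
        raise ValueError("track simulation requires a rectangle_track arena")
    if n_traversals < 1:
        raise ValueError("n_traversals must be >= 1")
    geom = TrackGeometry(arena)
    rng = np.random.default_rng(seed)
    dt = 1.0 / frame_rate_hz

    # plan the sequence of (arm, direction) traversals
    plan: list[tuple[int, int]] = []
    at_corner = 0  # feeders at corners 0 and 1
    while len(plan) < n_traversals:
        short = rng.uniform() < short_path_prob
        if at_corner == 0:
            legs = [(1, 1)] if short else [(4, -1), (3, -1), (2, -1)]
            at_corner = 1
        else:
            legs = [(1, -1)] if short else [(2, 1), (3, 1), (4, 1)]
            at_corner = 0
        plan.extend(legs)
    plan = plan[:n_traversals]

    xs: list[float] = []
    ys: list[float] = []
    labels: list[tuple[int, int, int, int]] = []  # arm, direction, start, end

    def dwell(s_pos: float, duration: float):
        n_dwell = max(1, int(round(duration / dt)))
        p = geom.arclength_to_xy(np.full(n_dwell, s_pos))
        jit = rng.normal(0, 0.3, size=(n_dwell, 2))
        xs.extend(p[:, 0] + jit[:, 0])
        ys.extend(p[:, 1] + jit[:, 1])

    dwell(geom.s_corners[0], motion.feeder_dwell_s)
    for arm, direction in plan:
        s_from = geom.s_corners[arm - 1 if direction == 1 else arm % 4]
        length = geom.arm_lengths[arm - 1]
        start_frame = len(xs)
        s_rel = 0.0
        while s_rel < length:
            v = rng.normal(motion.run_speed_cm_s, motion.speed_sd_cm_s)
            v = max(v, motion.min_speed_cm_s)
            s_rel += v * dt
            s_abs = s_from + direction * min(s_rel, length - 1e-9)
            p = geom.arclength_to_xy(np.array([s_abs]))[0]
            # lateral jitter perpendicular to the arm, clipped to the path
            lat = float(np.clip(rng.normal(0, motion.lateral_sd_cm),
                                -arena.path_width_cm / 2, arena.path_width_cm / 2))
            if arm in (1, 3):
                ys.append(p[1] + lat)
                xs.append(p[0])
            else:
                xs.append(p[0] + lat)
                ys.append(p[1])
        labels.append((arm, direction, start_frame, len(xs) - 1))
        end_corner_s = geom.s_corners[arm % 4 if direction == 1 else arm - 1]
        dwell(end_corner_s, motion.feeder_dwell_s * rng.uniform(0.7, 1.3))

    traj = Trajectory(
        t=np.arange(len(xs)) * dt,
        x_cm=np.asarray(xs),
        y_cm=np.asarray(ys),
        frame_rate_hz=frame_rate_hz,
    )
    seg = PathSegmentation(
        traversals=[
            Traversal(path_id=path_id(a, d), arm=a, direction=d,
                      start_frame=s, end_frame=e)
            for a, d, s, e in labels
        ]
    )
    return compute_speed(traj), seg


# ---------------------------------------------------------------------------
# Activity


def tuning_rate(spec: TuningSpec, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Expected rate (activity units / s) of a tuned cell at positions."""
    d2 = (x - spec.center_cm[0]) ** 2 + (y - spec.center_cm[1]) ** 2
    return spec.baseline_rate + (spec.peak_rate - spec.baseline_rate) * np.exp(
        -d2 / (2 * spec.sigma_cm**2)
    )


def simulate_place_cell_activity(
    trajectory: Trajectory,
    cells: list[TuningSpec],
    noise: ActivityNoise | None = ActivityNoise(),
    seed: int = 0,
    segmentation: PathSegmentation | None = None,
) -> ActivityMatrix:
    """Draw nonnegative activity whose expectation follows each cell's tuning.

    With ``noise=None`` (or :meth:`ActivityNoise.none`) the activity equals
    its expectation exactly.  Directionally tuned cells need the track
    ``segmentation`` to know which frames belong to which directed path;
    outside their paths they emit baseline only.
    """
    n = len(trajectory)
    if n == 0:
        raise ValueError("trajectory is empty")
    rng = np.random.default_rng(seed)
    if noise is None:
        noise = ActivityNoise.none()
    fr = trajectory.frame_rate_hz
    values = np.empty((len(cells), n))
    for c, spec in enumerate(cells):
        rate = tuning_rate(spec, trajectory.x_cm, trajectory.y_cm)
        if spec.directional_path_ids is not None:
            if segmentation is None:
                raise ValueError("directional tuning requires a track segmentation")
            on = np.zeros(n, dtype=bool)
            for pid in spec.directional_path_ids:
                on |= segmentation.frames_of_path(pid, n)
            rate = np.where(on, rate, spec.baseline_rate)
        mu = rate / fr
        if noise.poisson:
            a = rng.poisson(mu).astype(float)
        else:
            a = mu.copy()
        if noise.gamma_shape is not None:
            k = noise.gamma_shape
            a = a * rng.gamma(k, 1.0 / k, size=n)
        values[c] = a
    return ActivityMatrix(values=values, frame_rate_hz=fr)


# ---------------------------------------------------------------------------
# Orientation


def _quat_multiply(q1: np.ndarray, q2: np.ndarray) -> np.ndarray:
    w1, x1, y1, z1 = q1
    w2, x2, y2, z2 = q2
    return np.array(
        [
            w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
            w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
            w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
            w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
        ]
    )


def _axis_angle_quat(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    half = angle_rad / 2.0
    return np.concatenate([[np.cos(half)], np.sin(half) * axis])


def simulate_orientation_stream(
    n_frames: int,
    motion: AngularMotion | None = AngularMotion(),
    frame_rate_hz: float = 15.0,
    initial: np.ndarray | None = None,
    seed: int = 0,
    angular_velocity_dps: np.ndarray | None = None,
) -> QuaternionStream:
    """Integrate a unit-quaternion stream from smooth angular velocity.

    ``motion=None`` holds the initial quaternion constant.  A fixed
    ``angular_velocity_dps`` (3,) overrides the random process (used for
    controlled sweeps, e.g. a pure yaw rotation).
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    dt = 1.0 / frame_rate_hz
    q = np.array([1.0, 0.0, 0.0, 0.0]) if initial is None else _normalize4(initial)
    quats = np.empty((n_frames, 4))
    quats[0] = q
    omega = np.zeros(3)
    for i in range(1, n_frames):
        if angular_velocity_dps is not None:
            omega = np.asarray(angular_velocity_dps, dtype=float)
        elif motion is not None:
            sd = np.asarray(motion.rate_sd_dps)
            omega += (-omega) * dt / motion.tau_s
            omega += sd * np.sqrt(2 * dt / motion.tau_s) * rng.standard_normal(3)
        w_rad = np.radians(omega)
        angle = np.linalg.norm(w_rad) * dt
        if angle > 0:
            axis = w_rad / np.linalg.norm(w_rad)
            q = _quat_multiply(_axis_angle_quat(axis, angle), q)
            q = _normalize4(q)
        quats[i] = q
    return QuaternionStream(
        t=np.arange(n_frames) * dt,
        qw=quats[:, 0], qx=quats[:, 1], qy=quats[:, 2], qz=quats[:, 3],
    )


def _normalize4(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    return q / np.linalg.norm(q)


# ---------------------------------------------------------------------------
# Behavior video


def render_led_frames(
    trajectory: Trajectory,
    image_size: tuple[int, int],
    world_to_pixel: np.ndarray,
    pixel_offset: np.ndarray | None = None,
    spot: LedSpot = LedSpot(),
    background_level: float = 12.0,
    background_noise_sd: float = 2.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Render 8-bit grayscale frames with a Gaussian LED spot per frame.

    ``world_to_pixel`` is a 2x2 affine (plus optional offset) mapping
    (x_cm, y_cm) to (x_px, y_px).  Returns ``(frames, flagged)`` where
    flagged frames have the spot mapped outside the image or contrast below
    five background noise SDs; such frames contain background only.
    """
    h, w = image_size
    A = np.asarray(world_to_pixel, dtype=float).reshape(2, 2)
    b = np.zeros(2) if pixel_offset is None else np.asarray(pixel_offset, dtype=float)
    rng = np.random.default_rng(seed)
    n = len(trajectory)
    px = np.stack([trajectory.x_cm, trajectory.y_cm], axis=1) @ A.T + b
    frames = np.empty((n, h, w), dtype=np.uint8)
    flagged = np.zeros(n, dtype=bool)
    yy, xx = np.mgrid[0:h, 0:w]
    for i in range(n):
        bg = background_level + background_noise_sd * rng.standard_normal((h, w))
        cx, cy = px[i]
        outside = not (0 <= cx <= w - 1 and 0 <= cy <= h - 1)
        low_contrast = spot.amplitude < 5 * max(background_noise_sd, 1e-12)
        if outside or low_contrast:
            flagged[i] = True
            frame = bg
        else:
            d2 = (xx - cx) ** 2 + (yy - cy) ** 2
            frame = bg + spot.amplitude * np.exp(-d2 / (2 * spot.sigma_px**2))
        frames[i] = np.clip(np.round(frame), 0, 255).astype(np.uint8)
    return frames, flagged


# ---------------------------------------------------------------------------
# Convenience sessions


def default_open_field_cells(
    n_tuned: int = 30,
    n_untuned: int = 30,
    arena: ArenaSpec | None = None,
    sigma_cm: float = 10.0,
    peak_rate: float = 5.0,
    baseline_rate: float = 1.0,
    seed: int = 0,
) -> tuple[list[TuningSpec], np.ndarray]:
    """Tuned cells at random arena locations plus untuned baseline cells.

    Untuned cells carry the same mean rate (the baseline) everywhere, so
    classification cannot key on overall activity level.  Returns the specs
    and a boolean tuned mask.
    """
    from .arena import open_field_arena

    arena = arena or open_field_arena()
    rng = np.random.default_rng(seed)
    R = arena.radius_cm - sigma_cm / 2
    cells: list[TuningSpec] = []
    for _ in range(n_tuned):
        c = _uniform_in_disk(rng, R)
        cells.append(TuningSpec(center_cm=(c[0], c[1]), sigma_cm=sigma_cm,
                                peak_rate=peak_rate, baseline_rate=baseline_rate))
    for _ in range(n_untuned):
        cells.append(TuningSpec(center_cm=(0.0, 0.0), sigma_cm=sigma_cm,
                                peak_rate=baseline_rate, baseline_rate=baseline_rate))
    mask = np.zeros(len(cells), dtype=bool)
    mask[:n_tuned] = True
    return cells, mask


def make_open_field_session(
    n_tuned: int = 30,
    n_untuned: int = 30,
    duration_s: float = 840.0,
    frame_rate_hz: float = 15.0,
    seed: int = 0,
    with_orientation: bool = False,
    **cell_kwargs,
) -> SyntheticSession:
    """Full open-field session: trajectory + tuned/untuned cells (+ orientation)."""
    from .arena import open_field_arena

    arena = open_field_arena()
    traj = simulate_open_field_trajectory(
        arena, duration_s=duration_s, frame_rate_hz=frame_rate_hz, seed=seed
    )
    cells, tuned = default_open_field_cells(
        n_tuned=n_tuned, n_untuned=n_untuned, arena=arena, seed=seed + 1, **cell_kwargs
    )
    activity = simulate_place_cell_activity(traj, cells, seed=seed + 2)
    orientation = (
        simulate_orientation_stream(len(traj), frame_rate_hz=frame_rate_hz, seed=seed + 3)
        if with_orientation
        else None
    )
    return SyntheticSession(
        trajectory=traj,
        activity=activity,
        orientation=orientation,
        ground_truth=cells,
        seed=seed,
        tuned_mask=tuned,
    )
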