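"""Synthetic lunar-observation scenes with exact ground truth.

Generates 8-bit grayscale video of a bright, near-circular moon disk
drifting across a dark sky while small dark silhouettes (migrating birds)
cross the disk.  Every stage downstream — tracking, timestamp
reconstruction, transit detection, traffic-rate estimation — is testable
against the machine-readable truth this module emits.

The stated world
----------------
Transits are sampled from a physical flux model: horizontally flying
birds at an assumed altitude pass through the viewing cone toward the
moon.  The cone's cross-section at flight altitude ``H`` for a moon at
elevation ``theta`` is an ellipse with cross-azimuth semi-axis
``a = (delta/2) * H / sin(theta)`` and along-azimuth semi-axis
``b = a / sin(theta)`` (``delta`` = lunar angular diameter).  A bird with
ground-track bearing ``beta`` sees a gate of width
``2*sqrt(a^2 cos^2 psi + b^2 sin^2 psi)`` (``psi = beta - moon azimuth``)
perpendicular to its path, so a migration density of ``F`` birds per km
of front per hour yields ``F * E[gate] * duration`` expected transits —
the known flux that traffic-rate recovery tests check against.

Defaults model the validation regime of a spring full-moon session:
passerine ground speeds 5–25 m/s (mean 13), body lengths 0.08–0.25 m
(the 10–100 g passerine assumption), flight altitude 500 m, moon
~0.52 deg wide filling ~70% of the frame height.  Silhouettes are filled
3:1 ellipses — real silhouettes are irregular, but any compact dark blob
exercises the detector.  Drift is uniform and linear in the image plane;
frame timing jitter is optional uniform ±20% of the nominal period.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Callable, Sequence

import numpy as np

from . import geometry
from .timing import TimestampLog, append_checkpoint
from .tracking import MountState, MoonLossError

__all__ = [
    "SceneConfig",
    "TransitSpec",
    "TransitTruth",
    "GroundTruthLog",
    "gate_width_m",
    "mean_gate_width_m",
    "sample_transit_schedule",
    "render_frame",
    "simulate_session",
    "SessionResult",
]


@dataclass(frozen=True)
class SceneConfig:
    """Geometry, photometry and timing of a synthetic session."""

    frame_width_px: int = 800
    frame_height_px: int = 600
    field_of_view_deg: float = 1.0  # degrees spanned by the frame width
    moon_angular_diameter_deg: float = 0.52
    moon_brightness: int = 230
    sky_brightness: int = 8
    drift_rate_deg_per_min: float = 0.25
    drift_direction_deg: float = 25.0  # image-plane heading, atan2(dy,dx) convention
    fps_nominal: float = 30.0
    fog_attenuation: float = 1.0
    rng_seed: int = 0
    # viewing geometry used to map compass bearings into the image plane
    moon_azimuth_deg: float = 180.0
    moon_altitude_deg: float = 50.0
    camera_roll_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.frame_width_px <= 0 or self.frame_height_px <= 0:
            raise ValueError("frame dimensions must be positive")
        if self.moon_brightness <= self.sky_brightness:
            raise ValueError("moon must be brighter than the sky")
        if not (0.0 <= self.fog_attenuation <= 1.0):
            raise ValueError("fog_attenuation must lie in [0, 1]")
        if self.moon_diameter_px >= min(self.frame_width_px, self.frame_height_px):
            raise ValueError("moon disk must fit inside the frame")

    @property
    def px_per_deg(self) -> float:
        return self.frame_width_px / self.field_of_view_deg

    @property
    def moon_diameter_px(self) -> float:
        return self.moon_angular_diameter_deg * self.px_per_deg

    @property
    def moon_radius_px(self) -> float:
        return self.moon_diameter_px / 2.0

    @property
    def frame_center(self) -> tuple[float, float]:
        return (self.frame_width_px / 2.0, self.frame_height_px / 2.0)

    @property
    def drift_velocity_px_s(self) -> tuple[float, float]:
        rate = self.drift_rate_deg_per_min / 60.0 * self.px_per_deg
        ang = math.radians(self.drift_direction_deg)
        return (rate * math.cos(ang), rate * math.sin(ang))


@dataclass(frozen=True)
class TransitSpec:
    """One scheduled silhouette crossing."""

    start_time_s: float
    ground_track_bearing_deg: float  # compass bearing of flight
    body_orientation_deg: float  # compass bearing of the tail-to-beak axis
    angular_speed_deg_per_s: float  # image-plane angular speed
    silhouette_length_px: float
    silhouette_darkness: int = 30
    entry_chord_offset: float = 0.0  # fraction of disk radius, in [-1, 1]

    def __post_init__(self) -> None:
        if self.silhouette_length_px < 1:
            raise ValueError("silhouette_length_px must be >= 1")
        if self.angular_speed_deg_per_s <= 0:
            raise ValueError("angular speed must be positive")
        if abs(self.entry_chord_offset) > 1:
            raise ValueError("entry_chord_offset must lie in [-1, 1]")


def _transit_image_kinematics(spec: TransitSpec, scene: SceneConfig):
    """Entry point (relative to the moon center, px) and velocity (px/s).

    The silhouette starts one half-length outside the rim on the upstream
    side of its chord so it slides onto the disk after ``start_time_s``.
    """
    ang = math.radians(
        geometry.bearing_to_image_angle(
            spec.ground_track_bearing_deg,
            scene.moon_azimuth_deg,
            scene.moon_altitude_deg,
            scene.camera_roll_deg,
        )
    )
    d = np.array([math.cos(ang), math.sin(ang)])
    n = np.array([-d[1], d[0]])
    r = scene.moon_radius_px
    c = spec.entry_chord_offset
    half_chord = math.sqrt(max(r * r - (c * r) ** 2, 0.0))
    entry = c * r * n - (half_chord + spec.silhouette_length_px / 2.0) * d
    speed = spec.angular_speed_deg_per_s * scene.px_per_deg
    body_ang = math.radians(
        geometry.bearing_to_image_angle(
            spec.body_orientation_deg,
            scene.moon_azimuth_deg,
            scene.moon_altitude_deg,
            scene.camera_roll_deg,
        )
    )
    return entry, speed * d, body_ang


def _transit_window(spec: TransitSpec, scene: SceneConfig) -> tuple[float, float]:
    """(t_enter, t_exit): interval during which any part of the silhouette
    can overlap the disk."""
    entry, vel, _ = _transit_image_kinematics(spec, scene)
    r = scene.moon_radius_px
    c = spec.entry_chord_offset
    half_chord = math.sqrt(max(r * r - (c * r) ** 2, 0.0))
    speed = float(np.hypot(*vel))
    travel = 2.0 * half_chord + spec.silhouette_length_px
    return spec.start_time_s, spec.start_time_s + travel / speed


# -------------------------------------------------------------- flux sampling

def gate_width_m(
    bearing_deg, moon_azimuth_deg: float, moon_altitude_deg: float,
    moon_angular_diameter_deg: float, flight_altitude_m: float,
):
    """Width of the viewing-cone cross-section at flight altitude,
    perpendicular to the given ground-track bearing (meters)."""
    theta = math.radians(moon_altitude_deg)
    if math.sin(theta) <= 1e-6:
        raise ValueError("gate width unbounded: moon at the horizon")
    delta = math.radians(moon_angular_diameter_deg)
    slant = flight_altitude_m / math.sin(theta)
    a = 0.5 * delta * slant  # cross-azimuth semi-axis
    b = a / math.sin(theta)  # along-azimuth semi-axis
    psi = np.deg2rad(np.asarray(bearing_deg) - moon_azimuth_deg)
    return 2.0 * np.sqrt(a**2 * np.cos(psi) ** 2 + b**2 * np.sin(psi) ** 2)


def mean_gate_width_m(
    direction_distribution, moon_azimuth_deg, moon_altitude_deg,
    moon_angular_diameter_deg, flight_altitude_m, n_grid: int = 720,
) -> float:
    """Expectation of the gate width over a bearing distribution."""
    beta = np.linspace(0.0, 360.0, n_grid, endpoint=False)
    w = _direction_pdf(direction_distribution, beta)
    g = gate_width_m(
        beta, moon_azimuth_deg, moon_altitude_deg,
        moon_angular_diameter_deg, flight_altitude_m,
    )
    return float(np.sum(w * g) / np.sum(w))


def _direction_pdf(dist, beta_deg):
    kind = dist[0] if isinstance(dist, (tuple, list)) else dist.get("kind")
    if kind == "uniform":
        return np.ones_like(np.asarray(beta_deg, dtype=float))
    if kind == "vonmises":
        mu, kappa = (dist[1], dist[2]) if isinstance(dist, (tuple, list)) else (
            dist["mu_deg"], dist["kappa"])
        return np.exp(kappa * np.cos(np.deg2rad(np.asarray(beta_deg) - mu)))
    raise ValueError(f"unknown direction distribution {dist!r}")


def _sample_directions(dist, n, rng):
    kind = dist[0] if isinstance(dist, (tuple, list)) else dist.get("kind")
    if kind == "uniform":
        return rng.uniform(0.0, 360.0, n)
    if kind == "vonmises":
        mu, kappa = (dist[1], dist[2]) if isinstance(dist, (tuple, list)) else (
            dist["mu_deg"], dist["kappa"])
        return (np.rad2deg(rng.vonmises(math.radians(mu), kappa, n))) % 360.0
    raise ValueError(f"unknown direction distribution {dist!r}")


def sample_transit_schedule(
    density_per_km_h: float,
    flight_altitude_m: float,
    direction_distribution,
    duration_s: float,
    scene: SceneConfig,
    seed: int,
    ground_speed_mean_ms: float = 13.0,
    ground_speed_sd_ms: float = 3.0,
    ground_speed_range_ms: tuple[float, float] = (5.0, 25.0),
    body_length_range_m: tuple[float, float] = (0.08, 0.25),
    darkness_range: tuple[int, int] = (10, 80),
    orientation_offset_deg: float = 0.0,
) -> list[TransitSpec]:
    """Sample a transit schedule realizing a known horizontal flux.

    Birds form a uniform horizontal flux of ``density_per_km_h`` birds per
    km of front per hour at ``flight_altitude_m``; expected transit count
    is ``density * E[gate width] * duration``.  Chord offsets are uniform
    across the gate, which maps linearly to a uniform offset across the
    disk.  ``orientation_offset_deg`` sets the body-axis heading relative
    to the ground track (wind-drift scenarios).  Reproducible under a
    fixed seed.
    """
    if density_per_km_h < 0 or duration_s <= 0:
        raise ValueError("density must be >= 0 and duration positive")
    if scene.moon_altitude_deg <= 5.0:
        raise ValueError(
            f"degenerate geometry: moon altitude {scene.moon_altitude_deg} deg "
            "is at/near the horizon for the configured session"
        )
    if density_per_km_h == 0:
        return []
    rng = np.random.default_rng(seed)
    theta = math.radians(scene.moon_altitude_deg)
    slant_m = flight_altitude_m / math.sin(theta)
    gate_km = mean_gate_width_m(
        direction_distribution, scene.moon_azimuth_deg, scene.moon_altitude_deg,
        scene.moon_angular_diameter_deg, flight_altitude_m,
    ) / 1000.0
    expected = density_per_km_h * gate_km * duration_s / 3600.0
    n = rng.poisson(expected)
    if n == 0:
        return []

    # transiting birds carry bearing density p(beta) * gate(beta): rejection-sample
    g_max = gate_width_m(
        np.linspace(0, 360, 720, endpoint=False), scene.moon_azimuth_deg,
        scene.moon_altitude_deg, scene.moon_angular_diameter_deg, flight_altitude_m,
    ).max()
    keep_rounds = 0
    accepted = []
    while len(accepted) < n and keep_rounds < 1000:
        cand = _sample_directions(direction_distribution, n, rng)
        gc = gate_width_m(
            cand, scene.moon_azimuth_deg, scene.moon_altitude_deg,
            scene.moon_angular_diameter_deg, flight_altitude_m,
        )
        u = rng.uniform(0, g_max, n)
        accepted.extend(cand[u < gc].tolist())
        keep_rounds += 1
    bearings = np.array(accepted[:n])

    speeds = np.clip(
        rng.normal(ground_speed_mean_ms, ground_speed_sd_ms, n), *ground_speed_range_ms
    )
    factors = geometry.apparent_speed_factor(
        bearings, scene.moon_azimuth_deg, scene.moon_altitude_deg
    )
    ang_speed = np.rad2deg(speeds / slant_m * factors)  # deg/s in the image
    lengths_m = rng.uniform(*body_length_range_m, n)
    lengths_px = np.maximum(
        np.rad2deg(lengths_m / slant_m) * scene.px_per_deg, 1.0
    )
    specs = [
        TransitSpec(
            start_time_s=float(t0),
            ground_track_bearing_deg=float(b),
            # drift angle = bearing - orientation: the body heads upwind of
            # the realized ground track by the requested offset
            body_orientation_deg=float((b - orientation_offset_deg) % 360.0),
            angular_speed_deg_per_s=float(w),
            silhouette_length_px=float(L),
            silhouette_darkness=int(dk),
            entry_chord_offset=float(c),
        )
        for t0, b, w, L, dk, c in zip(
            rng.uniform(0.0, duration_s, n),
            bearings,
            ang_speed,
            lengths_px,
            rng.integers(darkness_range[0], darkness_range[1] + 1, n),
            rng.uniform(-1.0, 1.0, n),
        )
    ]
    specs.sort(key=lambda s: s.start_time_s)
    return specs


# ------------------------------------------------------------------ rendering

_GRID_CACHE: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}


def _grids(h: int, w: int) -> tuple[np.ndarray, np.ndarray]:
    if (h, w) not in _GRID_CACHE:
        _GRID_CACHE[(h, w)] = tuple(np.mgrid[0:h, 0:w].astype(np.float32))
    return _GRID_CACHE[(h, w)]


def _disk_coverage(scene: SceneConfig, center: tuple[float, float]) -> np.ndarray:
    yy, xx = _grids(scene.frame_height_px, scene.frame_width_px)
    dist = np.hypot(xx - center[0], yy - center[1])
    return np.clip(scene.moon_radius_px + 0.5 - dist, 0.0, 1.0)


def _silhouette_alpha(
    scene: SceneConfig, center: tuple[float, float], length_px: float, angle_rad: float
) -> tuple[np.ndarray, tuple[slice, slice]]:
    """Anti-aliased coverage of a 3:1 filled ellipse, within its bbox."""
    a = max(length_px / 2.0, 0.5)
    b = max(length_px / 6.0, 0.5)
    pad = a + 2.0
    x0 = max(int(center[0] - pad), 0)
    x1 = min(int(center[0] + pad) + 2, scene.frame_width_px)
    y0 = max(int(center[1] - pad), 0)
    y1 = min(int(center[1] + pad) + 2, scene.frame_height_px)
    if x0 >= x1 or y0 >= y1:
        return np.zeros((0, 0)), (slice(0, 0), slice(0, 0))
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dx, dy = xx - center[0], yy - center[1]
    ca, sa = math.cos(angle_rad), math.sin(angle_rad)
    u = dx * ca + dy * sa
    v = -dx * sa + dy * ca
    q = np.sqrt((u / a) ** 2 + (v / b) ** 2)
    alpha = np.clip((1.0 - q) * b + 0.5, 0.0, 1.0)
    return alpha, (slice(y0, y1), slice(x0, x1))


def render_frame(
    scene: SceneConfig,
    moon_center_px: tuple[float, float],
    active_transits: Sequence[TransitSpec],
    t: float,
    fog: float | None = None,
    _return_overlaps: bool = False,
):
    """Render one frame: anti-aliased bright disk plus dark silhouettes.

    Silhouettes are visible only where they overlap the disk (a bird
    against the night sky is below the exposure floor).  ``fog``
    multiplies the disk brightness.  An off-frame moon yields an all-sky
    frame, which is valid input for loss tests.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    fog = scene.fog_attenuation if fog is None else fog
    disk = _disk_coverage(scene, moon_center_px)
    moon_level = scene.sky_brightness + (scene.moon_brightness * fog - scene.sky_brightness)
    img = scene.sky_brightness + (max(moon_level, scene.sky_brightness) - scene.sky_brightness) * disk
    overlaps = []
    for spec in active_transits:
        entry, vel, body_ang = _transit_image_kinematics(spec, scene)
        rel = entry + vel * (t - spec.start_time_s)
        center = (moon_center_px[0] + rel[0], moon_center_px[1] + rel[1])
        alpha, box = _silhouette_alpha(scene, center, spec.silhouette_length_px, body_ang)
        if alpha.size == 0:
            overlaps.append(0.0)
            continue
        alpha_eff = alpha * disk[box]
        img[box] = img[box] * (1.0 - alpha_eff) + spec.silhouette_darkness * alpha_eff
        overlaps.append(float(alpha_eff.sum()))
    frame = np.clip(np.round(img), 0, 255).astype(np.uint8)
    if _return_overlaps:
        return frame, overlaps
    return frame


# ------------------------------------------------------------------- sessions

@dataclass
class TransitTruth:
    """Ground truth for one transit: its TransitSpec plus realized per-frame data."""

    spec: TransitSpec
    entry_frame: int = -1
    exit_frame: int = -1
    frames: list[int] = field(default_factory=list)
    centroids_px: list[tuple[float, float]] = field(default_factory=list)
    visible: list[bool] = field(default_factory=list)

    @property
    def n_visible(self) -> int:
        return int(sum(self.visible))


@dataclass
class GroundTruthLog:
    transits: list[TransitTruth] = field(default_factory=list)
    moon_centers_px: list[tuple[float, float]] = field(default_factory=list)
    frame_times_s: list[float] = field(default_factory=list)
    terminated_by_loss: bool = False

    def visible_transits(self, min_frames: int = 1) -> list[TransitTruth]:
        return [t for t in self.transits if t.n_visible >= min_frames]

    def to_jsonl(self, path) -> None:
        with open(path, "w") as fh:
            for tr in self.transits:
                rec = {
                    "spec": asdict(tr.spec),
                    "entry_frame": tr.entry_frame,
                    "exit_frame": tr.exit_frame,
                    "frames": tr.frames,
                    "centroids_px": [[round(x, 2), round(y, 2)] for x, y in tr.centroids_px],
                    "visible": tr.visible,
                }
                fh.write(json.dumps(rec) + "\n")

    @classmethod
    def from_jsonl(cls, path) -> "GroundTruthLog":
        log = cls()
        with open(path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                rec = json.loads(line)
                log.transits.append(
                    TransitTruth(
                        spec=TransitSpec(**rec["spec"]),
                        entry_frame=rec["entry_frame"],
                        exit_frame=rec["exit_frame"],
                        frames=rec["frames"],
                        centroids_px=[tuple(c) for c in rec["centroids_px"]],
                        visible=rec["visible"],
                    )
                )
        return log


@dataclass
class SessionResult:
    ground_truth: GroundTruthLog
    timestamp_log: TimestampLog
    n_frames: int
    terminated_by_loss: bool = False
    frames: list[np.ndarray] | None = None
    motor_events: list[tuple[float, str, int, float]] = field(default_factory=list)


def simulate_session(
    scene: SceneConfig,
    schedule: Sequence[TransitSpec],
    duration_s: float,
    controller=None,
    plant: MountState | None = None,
    timing_jitter: float = 0.0,
    fog_schedule: Callable[[float], float] | None = None,
    frame_sink: Callable[[np.ndarray], None] | None = None,
    collect_frames: bool = False,
    checkpoint_interval_s: float = 1.0,
    moon_start_px: tuple[float, float] | None = None,
    visible_min_overlap_px: float = 1.0,
) -> SessionResult:
    """Run a full synthetic session.

    Frames are emitted at the nominal rate (with optional uniform
    ±``timing_jitter`` fractional period jitter); the moon drifts linearly
    between controller corrections.  When a ``controller`` is supplied its
    motor commands are applied to the mount ``plant`` and shift the
    rendered moon.  The ground-truth log and timestamp log cover every
    frame; a controller loss error terminates the session cleanly and
    flags both logs.

    A transit's per-frame ``visible`` flag is true exactly when its
    rendered silhouette covers at least ``visible_min_overlap_px`` pixels
    of the disk, so truth and rendering cannot disagree.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    rng = np.random.default_rng(scene.rng_seed ^ 0x5EED)
    plant = plant or MountState()
    period = 1.0 / scene.fps_nominal
    moon0 = np.array(moon_start_px if moon_start_px is not None else scene.frame_center)
    drift = np.array(scene.drift_velocity_px_s)
    pointing_px = np.zeros(2)  # mount pointing offset, image px

    windows = [_transit_window(s, scene) for s in schedule]
    truths = [TransitTruth(spec=s) for s in schedule]
    truth_log = GroundTruthLog()
    ts_log = TimestampLog()
    frames_out: list[np.ndarray] | None = [] if collect_frames else None
    motor_events: list[tuple[float, str, int, float]] = []
    px_per_deg = scene.px_per_deg

    t = 0.0
    k = 0
    next_checkpoint = 0.0
    terminated = False
    n_nominal = int(round(duration_s * scene.fps_nominal))  # jitter-free frame count
    while (t < duration_s) if timing_jitter else (k < n_nominal):
        moon_center = tuple(moon0 + drift * t - pointing_px)
        active = [
            (i, s) for i, (s, (t0, t1)) in enumerate(zip(schedule, windows))
            if t0 - period <= t <= t1 + period
        ]
        fog = fog_schedule(t) if fog_schedule is not None else scene.fog_attenuation
        frame, overlaps = render_frame(
            scene, moon_center, [s for _, s in active], t, fog=fog, _return_overlaps=True
        )
        truth_log.moon_centers_px.append(moon_center)
        truth_log.frame_times_s.append(t)
        if k == 0 or t >= next_checkpoint:
            append_checkpoint(ts_log, t, k)
            next_checkpoint = t + checkpoint_interval_s

        for (i, spec), overlap in zip(active, overlaps):
            entry, vel, _ = _transit_image_kinematics(spec, scene)
            rel = entry + vel * (t - spec.start_time_s)
            pos = (moon_center[0] + rel[0], moon_center[1] + rel[1])
            vis = overlap >= visible_min_overlap_px
            tr = truths[i]
            tr.frames.append(k)
            tr.centroids_px.append((float(pos[0]), float(pos[1])))
            tr.visible.append(bool(vis))
            if vis:
                if tr.entry_frame < 0:
                    tr.entry_frame = k
                tr.exit_frame = k

        if frame_sink is not None:
            frame_sink(frame)
        if frames_out is not None:
            frames_out.append(frame)

        if controller is not None:
            try:
                for cmd in controller.on_frame(t, frame, k):
                    dx_deg, dy_deg = plant.apply(cmd)
                    pointing_px += np.array([dx_deg, dy_deg]) * px_per_deg
                    motor_events.append((t, cmd.axis, cmd.direction, cmd.pulse_duration_s))
            except MoonLossError:
                terminated = True
                k += 1
                break

        jitter = rng.uniform(-timing_jitter, timing_jitter) if timing_jitter else 0.0
        t += period * (1.0 + jitter)
        k += 1

    if ts_log.frame_counts and ts_log.frame_counts[-1] != k - 1 and k >= 2:
        append_checkpoint(ts_log, truth_log.frame_times_s[-1], k - 1)

    truth_log.transits = [tr for tr in truths if tr.frames]
    truth_log.terminated_by_loss = terminated
    return SessionResult(
        ground_truth=truth_log,
        timestamp_log=ts_log,
        n_frames=k,
        terminated_by_loss=terminated,
        frames=frames_out,
        motor_events=motor_events,
    )
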