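"""Closed-loop moon tracking.

The tracker works on a low-resolution copy of each frame: threshold to
separate the bright disk from the sky, take the binary-mask centroid as
the moon's position, and — only when that centroid wanders outside a
deadband around a reference point near frame center — emit timed motor
pulses that nudge a two-axis alt-azimuth mount to walk the image back.
Between corrections the mount is motionless and the moon drifts freely,
which keeps the recorded video steady.

Control law: a single proportional-duration pulse per axis
(``pulse_gain`` seconds per pixel of error, capped at ``max_pulse_s``),
deliberately sized to overshoot the reference slightly against the drift
direction so corrections are needed only every few tens of seconds.
Hysteresis (re-engage threshold at half the deadband) prevents chatter at
the deadband boundary.  Transient occlusions (cloud, fog) make the moon
segmentation invalid; only ``loss_patience`` consecutive invalid
evaluations terminate the session.

The motor interface is an abstract command sink; :class:`MountState` is
the simulated plant used throughout this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Literal

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "TrackerConfig",
    "MoonState",
    "MotorCommand",
    "MountState",
    "MoonLossError",
    "extract_tracking_frame",
    "threshold_moon",
    "moon_centroid",
    "compute_correction",
    "detect_loss",
    "TrackingController",
    "run_tracking_loop",
    "SessionLog",
    "calibrate_axes",
]


class MoonLossError(RuntimeError):
    """Raised when the moon has been lost for ``loss_patience`` evaluations."""


@dataclass(frozen=True)
class TrackerConfig:
    """Tracking parameters; defaults follow the working-resolution
    conventions of the control loop (800x600 working frame)."""

    work_width_px: int = 800
    work_height_px: int = 600
    threshold: int = 127
    deadband_radius_px: float = 75.0  # 12.5% of working-frame height
    reference_point_px: tuple[float, float] | None = None  # default: frame center
    min_moon_area_px: int = 200
    sample_interval_s: float = 3.0
    pulse_gain: float = 0.0017  # seconds of pulse per pixel of error
    max_pulse_s: float = 1.5
    duty_cycle: float = 1.0
    overshoot_fraction: float = 0.45  # aim past the reference, against the error:
    # larger overshoot spaces corrections further apart (steadier video)
    hysteresis_fraction: float = 0.5  # stay engaged until error < this x deadband
    loss_patience: int = 5
    axis_sign_x: int = 1  # sign mapping +x image error -> azimuth pulse direction
    axis_sign_y: int = 1

    def __post_init__(self) -> None:
        if not (0 < self.threshold < 255):
            raise ValueError("threshold must be in (0, 255)")
        if self.deadband_radius_px >= min(self.work_width_px, self.work_height_px) / 2:
            raise ValueError("deadband must fit in the working frame")
        if self.sample_interval_s <= 0 or self.min_moon_area_px <= 0:
            raise ValueError("sample_interval_s and min_moon_area_px must be positive")

    @property
    def reference(self) -> tuple[float, float]:
        if self.reference_point_px is not None:
            return self.reference_point_px
        return (self.work_width_px / 2.0, self.work_height_px / 2.0)


@dataclass(frozen=True)
class MoonState:
    """Segmented-moon observation on the working frame."""

    centroid_px: tuple[float, float]
    area_px: int
    fitted_radius_px: float
    valid: bool


@dataclass(frozen=True)
class MotorCommand:
    axis: Literal["azimuth", "altitude"]
    direction: int  # +1 / -1
    pulse_duration_s: float
    duty_cycle: float = 1.0

    def __post_init__(self) -> None:
        if self.direction not in (-1, 1):
            raise ValueError("direction must be +1 or -1")
        if self.pulse_duration_s <= 0:
            raise ValueError("pulse duration must be positive")
        if not (0 < self.duty_cycle <= 1):
            raise ValueError("duty cycle must be in (0, 1]")


@dataclass
class MountState:
    """Simulated two-axis alt-az mount plant.

    The no-load motor rate (0.5 rpm class gear motors) divided by the
    scope gear reduction sets how fast a pulse moves the image;
    ``az_image_sign``/``alt_image_sign`` encode the optical train's
    inversions (image +x per +azimuth pulse, image +y per +altitude
    pulse).  Optional backlash swallows dead motion on direction reversal.
    """

    azimuth_deg: float = 180.0
    altitude_deg: float = 45.0
    no_load_rate_rpm: float = 0.5
    gear_reduction: float = 4.0
    backlash_deg: float = 0.0
    az_image_sign: int = 1
    alt_image_sign: int = 1
    _last_dir: dict = field(default_factory=dict, repr=False)

    @property
    def slew_rate_deg_s(self) -> float:
        return self.no_load_rate_rpm * 360.0 / 60.0 / self.gear_reduction

    def apply(self, cmd: MotorCommand) -> tuple[float, float]:
        """Execute a pulse; returns the image-plane pointing change
        (dx_deg, dy_deg) in image coordinates (x right, y down)."""
        travel = self.slew_rate_deg_s * cmd.duty_cycle * cmd.pulse_duration_s
        prev = self._last_dir.get(cmd.axis)
        if self.backlash_deg and prev is not None and prev != cmd.direction:
            travel = max(0.0, travel - self.backlash_deg)
        self._last_dir[cmd.axis] = cmd.direction
        signed = cmd.direction * travel
        if cmd.axis == "azimuth":
            self.azimuth_deg = (self.azimuth_deg + signed) % 360.0
            return (self.az_image_sign * signed, 0.0)
        new_alt = float(np.clip(self.altitude_deg + signed, 0.0, 90.0))
        moved = new_alt - self.altitude_deg
        self.altitude_deg = new_alt
        return (0.0, self.alt_image_sign * moved)


def extract_tracking_frame(frame: np.ndarray, cfg: TrackerConfig) -> np.ndarray:
    """Monotone bilinear resample of a frame to the working resolution."""
    frame = np.asarray(frame)
    if frame.size == 0:
        raise ValueError("empty frame")
    h, w = frame.shape[:2]
    if (w, h) == (cfg.work_width_px, cfg.work_height_px):
        return frame
    zoom = (cfg.work_height_px / h, cfg.work_width_px / w)
    out = ndimage.zoom(frame.astype(np.float32), zoom, order=1, grid_mode=True, mode="nearest")
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def threshold_moon(gray: np.ndarray, threshold: float) -> np.ndarray:
    """Binary mask of pixels strictly brighter than ``threshold``."""
    if not (0 < threshold < 255):
        raise ValueError("threshold must be in (0, 255)")
    return np.asarray(gray) > threshold


def moon_centroid(mask: np.ndarray, cfg: TrackerConfig) -> MoonState:
    """Binary-mask centroid, pixel area and equivalent-disk radius.

    The state is valid only when the segmented area reaches
    ``min_moon_area_px``; an invalid state feeds the loss policy upstream.
    """
    mask = np.asarray(mask, dtype=bool)
    area = int(mask.sum())
    if area == 0:
        return MoonState((np.nan, np.nan), 0, 0.0, False)
    cy, cx = ndimage.center_of_mass(mask)
    radius = float(np.sqrt(area / np.pi))
    return MoonState((float(cx), float(cy)), area, radius, area >= cfg.min_moon_area_px)


def compute_correction(
    state: MoonState, cfg: TrackerConfig, engaged: bool = False
) -> tuple[list[MotorCommand], bool]:
    """Deadband-gated proportional correction.

    Returns ``(commands, engaged)``.  No command while the centroid is
    within the deadband (or, once disengaged, until it exceeds it again);
    when triggered, one pulse per offending axis, sized
    ``pulse_gain * (error + overshoot_fraction * deadband)`` and capped at
    ``max_pulse_s``, signed to move the moon image toward the reference.
    """
    if not state.valid:
        raise ValueError("compute_correction requires a valid MoonState")
    ref = cfg.reference
    ex = state.centroid_px[0] - ref[0]
    ey = state.centroid_px[1] - ref[1]
    err = float(np.hypot(ex, ey))
    trigger = cfg.deadband_radius_px if not engaged else cfg.hysteresis_fraction * cfg.deadband_radius_px
    if err <= trigger:
        return [], False
    overshoot = cfg.overshoot_fraction * cfg.deadband_radius_px
    axes = [("azimuth", ex, cfg.axis_sign_x), ("altitude", ey, cfg.axis_sign_y)]
    offending = [a for a in axes if abs(a[1]) > trigger]
    if not offending:
        # the radial error tripped the band without any single axis doing so:
        # re-center every axis that is meaningfully off, else chattering
        # single-axis corrections alternate in a limit cycle
        floor = 0.25 * cfg.deadband_radius_px
        offending = [a for a in axes if abs(a[1]) > floor]
        if not offending:
            offending = [max(axes, key=lambda a: abs(a[1]))]
    commands = [
        MotorCommand(
            axis,
            int(sign * np.sign(comp)),
            # overshoot distributed along the error direction so the radial
            # residual lands inside the hysteresis band in one burst
            min(cfg.pulse_gain * (abs(comp) * (1.0 + overshoot / err)), cfg.max_pulse_s),
            cfg.duty_cycle,
        )
        for axis, comp, sign in offending
    ]
    return commands, True


def detect_loss(
    state: MoonState, consecutive_invalid: int, cfg: TrackerConfig
) -> Literal["continue", "error_and_close"]:
    """Loss policy: terminate only after ``loss_patience`` consecutive
    invalid evaluations; transient occlusions continue."""
    if consecutive_invalid < 0:
        raise ValueError("consecutive_invalid must be >= 0")
    if state.valid:
        return "continue"
    return "error_and_close" if consecutive_invalid >= cfg.loss_patience else "continue"


@dataclass
class LogRecord:
    time_s: float
    frame_index: int
    centroid_x: float
    centroid_y: float
    area: int
    valid: bool
    command_axis: str = ""
    command_sign: int = 0
    pulse_s: float = 0.0


@dataclass
class SessionLog:
    records: list[LogRecord] = field(default_factory=list)
    terminated_by_loss: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.records])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @property
    def command_times(self) -> list[float]:
        seen = []
        for r in self.records:
            if r.command_axis:
                seen.append(r.time_s)
        return sorted(set(seen))


class TrackingController:
    """Stateful per-session controller: evaluation cadence, hysteresis,
    loss counting.  ``on_frame`` is the callback the simulator (or a live
    capture loop) invokes per frame; it returns motor commands due now."""

    def __init__(self, cfg: TrackerConfig | None = None) -> None:
        self.cfg = cfg or TrackerConfig()
        self.log = SessionLog()
        self._next_eval = 0.0
        self._busy_until = 0.0
        self._engaged = False
        self._consecutive_invalid = 0

    def on_frame(self, t: float, frame: np.ndarray, frame_index: int = -1) -> list[MotorCommand]:
        if t < self._next_eval or t < self._busy_until:
            return []
        self._next_eval = t + self.cfg.sample_interval_s
        work = extract_tracking_frame(frame, self.cfg)
        state = moon_centroid(threshold_moon(work, self.cfg.threshold), self.cfg)
        if not state.valid:
            self._consecutive_invalid += 1
            self.log.records.append(
                LogRecord(t, frame_index, np.nan, np.nan, state.area_px, False)
            )
            if detect_loss(state, self._consecutive_invalid, self.cfg) == "error_and_close":
                self.log.terminated_by_loss = True
                raise MoonLossError(
                    f"moon lost for {self._consecutive_invalid} consecutive evaluations"
                )
            return []
        self._consecutive_invalid = 0
        commands, self._engaged = compute_correction(state, self.cfg, self._engaged)
        if commands:
            self._busy_until = t + max(c.pulse_duration_s for c in commands)
            for c in commands:
                self.log.records.append(
                    LogRecord(
                        t, frame_index, state.centroid_px[0], state.centroid_px[1],
                        state.area_px, True, c.axis, c.direction, c.pulse_duration_s,
                    )
                )
        else:
            self.log.records.append(
                LogRecord(t, frame_index, state.centroid_px[0], state.centroid_px[1],
                          state.area_px, True)
            )
        return commands


def run_tracking_loop(
    source: Iterable[tuple[float, np.ndarray]],
    plant: MountState,
    cfg: TrackerConfig | None = None,
    command_sink: Callable[[MotorCommand], None] | None = None,
) -> SessionLog:
    """Drive the controller over a (time, frame) stream.

    Commands go to the plant (and optionally to ``command_sink`` for
    logging/replay).  A moon-loss error closes the log cleanly and marks
    the session terminated.
    """
    controller = TrackingController(cfg)
    try:
        for item in source:
            t, frame = item[0], item[1]
            idx = item[2] if len(item) > 2 else -1
            for cmd in controller.on_frame(t, frame, idx):
                plant.apply(cmd)
                if command_sink is not None:
                    command_sink(cmd)
    except MoonLossError:
        pass
    return controller.log


def calibrate_axes(
    measure_centroid: Callable[[], tuple[float, float]],
    apply_command: Callable[[MotorCommand], None],
    probe_pulse_s: float = 0.2,
) -> tuple[int, int]:
    """One-pulse-per-axis probe returning (axis_sign_x, axis_sign_y):
    the sign to use so that a positive-direction pulse moves the moon
    image in -x / -y (i.e. corrects a positive error)."""
    signs = []
    for axis in ("azimuth", "altitude"):
        before = measure_centroid()
        apply_command(MotorCommand(axis, +1, probe_pulse_s))
        after = measure_centroid()
        delta = (after[0] - before[0]) if axis == "azimuth" else (after[1] - before[1])
        signs.append(-1 if delta > 0 else 1)
    return signs[0], signs[1]
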