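"""Silhouette detection, track linking and flock grouping.

Automates the frame-by-frame annotation a human performs on moonwatching
video: find small dark moving blobs on the bright lunar disk, link them
across frames into transit tracks, and group temporally coincident
tracks into flock events.

Static dark lunar features (maria, craters) are absorbed by a running
exponential-moving-average background of the disk, so only *movers*
survive background subtraction.  Detections are connected components of
pixels at least ``contrast_threshold`` levels darker than background,
inside the disk plus a small margin, with area at least
``min_detection_area`` (a few-pixel silhouette is real data).  Linking is
greedy nearest-neighbour with a gating radius; edge-skirting and
single-frame transits are kept and labelled, never discarded.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .timing import TimestampLog, frame_time, mean_frame_period
from .tracking import threshold_moon

__all__ = [
    "DetectionConfig",
    "MoonDiskFit",
    "Detection",
    "TransitTrack",
    "FlockEvent",
    "fit_moon_disk",
    "BackgroundModel",
    "detect_dark_objects",
    "link_tracks",
    "group_flocks",
    "detect_transits",
    "tracks_to_frame",
    "tracks_to_jsonl",
    "tracks_from_jsonl",
]


@dataclass(frozen=True)
class DetectionConfig:
    moon_threshold: int = 127
    min_moon_area_px: int = 200
    contrast_threshold: float = 40.0
    min_detection_area: int = 2
    edge_margin_px: float = 6.0  # detections allowed this far outside the fitted rim
    background_tau_s: float = 1.0  # EMA decay of the background model
    gating_radius_fraction: float = 0.25  # of disk radius, per frame
    gating_radius_px: float | None = None  # overrides the fraction when set:
    # the gate should be the maximum plausible per-frame displacement, which
    # exceeds radius/4 for fast transits at modest frame rates
    gap_frames: int = 1
    max_background_gradient: float = 20.0  # levels/px; masks the rim ring
    flock_window_s: float = 1.0
    min_linearity_r2: float = 0.8  # advisory insect flag below this
    min_angular_speed_px_per_frame: float = 0.0  # advisory floor


@dataclass(frozen=True)
class MoonDiskFit:
    frame_index: int
    center_px: tuple[float, float]
    radius_px: float


@dataclass(frozen=True)
class Detection:
    frame_index: int
    centroid_px: tuple[float, float]
    area_px: int
    mean_darkness: float  # mean contrast below the background, 8-bit levels
    on_edge: bool
    length_px: float  # blob major-axis extent
    elongation: float  # major/minor axis ratio
    axis_angle_deg: float  # undirected major-axis angle, image convention


@dataclass
class TransitTrack:
    track_id: int
    detections: list[Detection]
    start_time_s: float
    end_time_s: float
    duration_s: float
    mean_area_px: float
    image_path_angle_deg: float  # direction of motion, atan2(dy,dx); nan if undefined
    completeness: str  # full_crossing | edge_skirting | single_frame
    flagged_nonbird: bool = False
    flock_id: int = -1

    @property
    def n_frames(self) -> int:
        return len(self.detections)

    @property
    def frames(self) -> list[int]:
        return [d.frame_index for d in self.detections]


@dataclass
class FlockEvent:
    flock_id: int
    track_ids: list[int]
    start_time_s: float
    end_time_s: float

    @property
    def count(self) -> int:
        return len(self.track_ids)


class MoonNotFound(ValueError):
    """Frame contains no segmentable moon; caller should skip and log."""


def fit_moon_disk(
    frame: np.ndarray, threshold: float, frame_index: int = -1, min_area: int = 200
) -> MoonDiskFit:
    """Threshold-and-centroid disk fit at analysis resolution.

    Radius is the equivalent-area radius ``sqrt(area/pi)``; for a gibbous
    moon the fit is biased toward the lit limb (recorded, not corrected).
    """
    mask = threshold_moon(frame, threshold)
    area = int(mask.sum())
    if area < min_area:
        raise MoonNotFound(f"frame {frame_index}: thresholded area {area} < {min_area}")
    cy, cx = ndimage.center_of_mass(mask)
    return MoonDiskFit(frame_index, (float(cx), float(cy)), float(np.sqrt(area / np.pi)))


class BackgroundModel:
    """Per-pixel exponential moving average of frames.

    With a decay time of ~1 s, static lunar features converge into the
    background while a silhouette occupying a pixel for a few frames
    barely perturbs it.
    """

    def __init__(self, tau_s: float = 1.0):
        self.tau_s = tau_s
        self._bg: np.ndarray | None = None

    @property
    def initialized(self) -> bool:
        return self._bg is not None

    @property
    def background(self) -> np.ndarray:
        if self._bg is None:
            raise RuntimeError("background not initialized from any frame")
        return self._bg

    def update(self, frame: np.ndarray, dt_s: float) -> None:
        frame = np.asarray(frame, dtype=np.float32)
        if self._bg is None:
            self._bg = frame.copy()
            return
        alpha = 1.0 - math.exp(-max(dt_s, 0.0) / self.tau_s)
        self._bg += alpha * (frame - self._bg)

    def translate(self, dx: float, dy: float) -> None:
        """Shift the stored background to follow the (drifting or
        re-centered) moon, keeping it registered to the current frame."""
        if self._bg is None or (dx == 0.0 and dy == 0.0):
            return
        self._bg = ndimage.shift(self._bg, (dy, dx), order=1, mode="nearest")


def detect_dark_objects(
    frame: np.ndarray,
    disk: MoonDiskFit,
    background: BackgroundModel | np.ndarray,
    cfg: DetectionConfig = DetectionConfig(),
    frame_index: int | None = None,
) -> list[Detection]:
    """Connected components darker than background on the disk."""
    bg = background.background if isinstance(background, BackgroundModel) else background
    diff = bg.astype(np.float32) - np.asarray(frame, dtype=np.float32)
    h, w = diff.shape
    yy, xx = np.ogrid[0:h, 0:w]
    inside = (xx - disk.center_px[0]) ** 2 + (yy - disk.center_px[1]) ** 2 <= (
        disk.radius_px + cfg.edge_margin_px
    ) ** 2
    candidate = (diff >= cfg.contrast_threshold) & inside
    if cfg.max_background_gradient > 0:
        # the disk rim is a steep gradient in the background; subpixel
        # misregistration there mimics dark movers, so mask it out
        gy, gx = np.gradient(bg.astype(np.float32))
        steep = np.hypot(gx, gy) > cfg.max_background_gradient
        candidate &= ~ndimage.binary_dilation(steep)
    labels, n = ndimage.label(candidate)
    out: list[Detection] = []
    fidx = disk.frame_index if frame_index is None else frame_index
    for islice, lab in zip(ndimage.find_objects(labels), range(1, n + 1)):
        blob = labels[islice] == lab
        area = int(blob.sum())
        if area < cfg.min_detection_area:
            continue
        ys, xs = np.nonzero(blob)
        ys = ys + islice[0].start
        xs = xs + islice[1].start
        cx, cy = float(xs.mean()), float(ys.mean())
        mean_dark = float(diff[ys, xs].mean())
        length, elong, axis_deg = _blob_axis(xs, ys)
        rim_dist = disk.radius_px - math.hypot(cx - disk.center_px[0], cy - disk.center_px[1])
        out.append(
            Detection(
                frame_index=fidx,
                centroid_px=(cx, cy),
                area_px=area,
                mean_darkness=mean_dark,
                on_edge=rim_dist < length,
                length_px=length,
                elongation=elong,
                axis_angle_deg=axis_deg,
            )
        )
    return out


def _blob_axis(xs: np.ndarray, ys: np.ndarray) -> tuple[float, float, float]:
    """(major-axis length, elongation, axis angle deg) from second moments."""
    if len(xs) < 2:
        return 1.0, 1.0, 0.0
    x = xs - xs.mean()
    y = ys - ys.mean()
    cov = np.cov(np.stack([x, y])) + np.eye(2) / 12.0  # pixel quantization floor
    evals, evecs = np.linalg.eigh(cov)
    major = evecs[:, 1]
    length = 4.0 * math.sqrt(evals[1])  # +-2 sigma extent
    elong = math.sqrt(evals[1] / max(evals[0], 1e-9))
    angle = math.degrees(math.atan2(major[1], major[0])) % 180.0
    return float(length), float(elong), float(angle)


def link_tracks(
    detections_per_frame: Sequence[tuple[int, list[Detection]]],
    frame_times: TimestampLog | dict[int, float],
    gating_radius_px: float,
    gap_frames: int = 1,
    cfg: DetectionConfig = DetectionConfig(),
) -> list[TransitTrack]:
    """Greedy nearest-neighbour association of per-frame detections.

    Matches are taken in order of increasing distance up to the gating
    radius (scaled by frame gaps); unmatched detections start new tracks;
    a track closes after ``gap_frames`` frames without a match.  No
    detection belongs to two tracks.
    """
    t_of = _time_lookup(frame_times)
    frame_period = _frame_period(frame_times)
    active: list[list[Detection]] = []
    done: list[list[Detection]] = []
    for fidx, dets in detections_per_frame:
        # retire stale tracks
        still = []
        for tr in active:
            if fidx - tr[-1].frame_index > gap_frames + 1:
                done.append(tr)
            else:
                still.append(tr)
        active = still
        if not dets:
            continue
        pairs = []
        for ti, tr in enumerate(active):
            gap = fidx - tr[-1].frame_index
            if gap < 1:
                continue
            # once a track carries a velocity, gate on the constant-velocity
            # prediction (tighter), which keeps crossing birds separate
            if len(tr) >= 2:
                dgap = tr[-1].frame_index - tr[-2].frame_index
                vx = (tr[-1].centroid_px[0] - tr[-2].centroid_px[0]) / dgap
                vy = (tr[-1].centroid_px[1] - tr[-2].centroid_px[1]) / dgap
                px = tr[-1].centroid_px[0] + vx * gap
                py = tr[-1].centroid_px[1] + vy * gap
                gate = 0.5 * gating_radius_px * gap
            else:
                px, py = tr[-1].centroid_px
                gate = gating_radius_px * gap
            for di, det in enumerate(dets):
                dist = math.hypot(det.centroid_px[0] - px, det.centroid_px[1] - py)
                if dist <= gate:
                    pairs.append((dist, ti, di))
        pairs.sort()
        used_t: set[int] = set()
        used_d: set[int] = set()
        for dist, ti, di in pairs:
            if ti in used_t or di in used_d:
                continue
            active[ti].append(dets[di])
            used_t.add(ti)
            used_d.add(di)
        for di, det in enumerate(dets):
            if di not in used_d:
                active.append([det])
    done.extend(active)
    done.sort(key=lambda tr: tr[0].frame_index)
    return [
        _finalize_track(i, tr, t_of, frame_period, cfg) for i, tr in enumerate(done)
    ]


def _time_lookup(frame_times):
    if isinstance(frame_times, TimestampLog):
        return lambda k: frame_time(frame_times, k)
    return lambda k: frame_times[k]


def _frame_period(frame_times) -> float:
    if isinstance(frame_times, TimestampLog):
        return mean_frame_period(frame_times)
    keys = sorted(frame_times)
    if len(keys) < 2:
        return 0.0
    return (frame_times[keys[-1]] - frame_times[keys[0]]) / (keys[-1] - keys[0])


def _finalize_track(tid, dets, t_of, frame_period, cfg) -> TransitTrack:
    t0 = t_of(dets[0].frame_index)
    t1 = t_of(dets[-1].frame_index)
    duration = t1 - t0 + frame_period  # a single-frame event lasts one period
    if len(dets) == 1:
        completeness = "single_frame"
        path_angle = float("nan")
    else:
        completeness = (
            "edge_skirting" if all(d.on_edge for d in dets) else "full_crossing"
        )
        dx = dets[-1].centroid_px[0] - dets[0].centroid_px[0]
        dy = dets[-1].centroid_px[1] - dets[0].centroid_px[1]
        path_angle = math.degrees(math.atan2(dy, dx)) % 360.0
    flagged = False
    if len(dets) >= 3:
        xs = np.array([d.centroid_px[0] for d in dets])
        ys = np.array([d.centroid_px[1] for d in dets])
        flagged = _path_r2(xs, ys) < cfg.min_linearity_r2
        step = np.hypot(np.diff(xs), np.diff(ys)).mean()
        flagged = flagged or step < cfg.min_angular_speed_px_per_frame
    return TransitTrack(
        track_id=tid,
        detections=list(dets),
        start_time_s=float(t0),
        end_time_s=float(t1 + frame_period),
        duration_s=float(duration),
        mean_area_px=float(np.mean([d.area_px for d in dets])),
        image_path_angle_deg=path_angle,
        completeness=completeness,
        flagged_nonbird=bool(flagged),
    )


def _path_r2(xs: np.ndarray, ys: np.ndarray) -> float:
    """Fraction of positional variance explained by the best-fit line."""
    pts = np.stack([xs - xs.mean(), ys - ys.mean()])
    cov = np.cov(pts)
    evals = np.linalg.eigvalsh(cov)
    total = evals.sum()
    return 1.0 if total <= 1e-12 else float(evals[1] / total)


def group_flocks(tracks: list[TransitTrack], window_s: float = 1.0) -> list[FlockEvent]:
    """Single-linkage clustering of tracks by temporal proximity.

    Tracks whose [start, end] intervals come within ``window_s`` are
    linked; connected groups of two or more are flock events.  Members'
    ``flock_id`` is set in place.
    """
    if not tracks:
        return []
    order = sorted(range(len(tracks)), key=lambda i: tracks[i].start_time_s)
    groups: list[list[int]] = []
    current = [order[0]]
    reach = tracks[order[0]].end_time_s
    for i in order[1:]:
        if tracks[i].start_time_s - reach <= window_s:
            current.append(i)
        else:
            groups.append(current)
            current = [i]
        reach = max(reach, tracks[i].end_time_s)
    groups.append(current)
    events = []
    fid = 0
    for grp in groups:
        if len(grp) < 2:
            continue
        for i in grp:
            tracks[i].flock_id = fid
        events.append(
            FlockEvent(
                flock_id=fid,
                track_ids=[tracks[i].track_id for i in grp],
                start_time_s=min(tracks[i].start_time_s for i in grp),
                end_time_s=max(tracks[i].end_time_s for i in grp),
            )
        )
        fid += 1
    return events


def detect_transits(
    frames: Iterable[tuple[int, np.ndarray]],
    timestamp_log: TimestampLog,
    cfg: DetectionConfig = DetectionConfig(),
) -> tuple[list[TransitTrack], list[FlockEvent], list[int]]:
    """Full detection pipeline over a (frame_index, frame) stream.

    Returns (tracks, flock events, skipped frame indices).  The first
    usable frame initializes the background and yields no detections.
    """
    bg = BackgroundModel(cfg.background_tau_s)
    per_frame: list[tuple[int, list[Detection]]] = []
    skipped: list[int] = []
    radius_sum = 0.0
    n_fits = 0
    prev_t: float | None = None
    prev_center: tuple[float, float] | None = None
    for fidx, frame in frames:
        try:
            t = frame_time(timestamp_log, fidx)
        except ValueError:
            skipped.append(fidx)
            continue
        try:
            disk = fit_moon_disk(frame, cfg.moon_threshold, fidx, cfg.min_moon_area_px)
        except MoonNotFound:
            skipped.append(fidx)
            prev_t = t
            continue
        radius_sum += disk.radius_px
        n_fits += 1
        if bg.initialized and prev_center is not None:
            dx = disk.center_px[0] - prev_center[0]
            dy = disk.center_px[1] - prev_center[1]
            if math.hypot(dx, dy) > 0.05 * disk.radius_px:
                # a mount correction slewed the disk; translation of the
                # EMA background is no longer trustworthy - re-seed it and
                # skip this frame's detections
                bg = BackgroundModel(cfg.background_tau_s)
            else:
                # keep the background registered to the moving disk
                bg.translate(dx, dy)
                dets = detect_dark_objects(frame, disk, bg, cfg)
                per_frame.append((fidx, dets))
        bg.update(frame, 0.0 if prev_t is None else t - prev_t)
        prev_t = t
        prev_center = disk.center_px
    if n_fits == 0:
        return [], [], skipped
    gating = cfg.gating_radius_px
    if gating is None:
        gating = (radius_sum / n_fits) * cfg.gating_radius_fraction
    tracks = link_tracks(per_frame, timestamp_log, gating, cfg.gap_frames, cfg)
    flocks = group_flocks(tracks, cfg.flock_window_s)
    return tracks, flocks, skipped


# ----------------------------------------------------------------- exports

def tracks_to_frame(tracks: list[TransitTrack]) -> pd.DataFrame:
    rows = [
        {
            "track_id": tr.track_id,
            "start_s": tr.start_time_s,
            "end_s": tr.end_time_s,
            "duration_s": tr.duration_s,
            "n_frames": tr.n_frames,
            "mean_area_px": tr.mean_area_px,
            "image_path_angle_deg": tr.image_path_angle_deg,
            "completeness": tr.completeness,
            "flock_id": tr.flock_id,
            "flagged": tr.flagged_nonbird,
        }
        for tr in tracks
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "track_id", "start_s", "end_s", "duration_s", "n_frames",
            "mean_area_px", "image_path_angle_deg", "completeness",
            "flock_id", "flagged",
        ],
    )


def tracks_to_jsonl(tracks: list[TransitTrack], path) -> None:
    with open(path, "w") as fh:
        for tr in tracks:
            fh.write(json.dumps({
                "track_id": tr.track_id,
                "frames": tr.frames,
                "centroids_px": [list(d.centroid_px) for d in tr.detections],
                "areas_px": [d.area_px for d in tr.detections],
                "lengths_px": [d.length_px for d in tr.detections],
                "axis_angles_deg": [d.axis_angle_deg for d in tr.detections],
                "elongations": [d.elongation for d in tr.detections],
                "on_edge": [d.on_edge for d in tr.detections],
                "start_time_s": tr.start_time_s,
                "end_time_s": tr.end_time_s,
                "duration_s": tr.duration_s,
                "image_path_angle_deg": tr.image_path_angle_deg,
                "completeness": tr.completeness,
                "flagged": tr.flagged_nonbird,
                "flock_id": tr.flock_id,
            }) + "\n")


def tracks_from_jsonl(path) -> list[TransitTrack]:
    tracks = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            dets = [
                Detection(
                    frame_index=f,
                    centroid_px=tuple(c),
                    area_px=a,
                    mean_darkness=float("nan"),
                    on_edge=oe,
                    length_px=L,
                    elongation=e,
                    axis_angle_deg=ax,
                )
                for f, c, a, L, ax, e, oe in zip(
                    rec["frames"], rec["centroids_px"], rec["areas_px"],
                    rec["lengths_px"], rec["axis_angles_deg"],
                    rec["elongations"], rec["on_edge"],
                )
            ]
            tracks.append(
                TransitTrack(
                    track_id=rec["track_id"],
                    detections=dets,
                    start_time_s=rec["start_time_s"],
                    end_time_s=rec["end_time_s"],
                    duration_s=rec["duration_s"],
                    mean_area_px=float(np.mean(rec["areas_px"])),
                    image_path_angle_deg=rec["image_path_angle_deg"],
                    completeness=rec["completeness"],
                    flagged_nonbird=rec["flagged"],
                    flock_id=rec["flock_id"],
                )
            )
    return tracks
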