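"""Silhouette detection, track linking and flock grouping."""

import math

import numpy as np
import pytest

from moonwatch.detect import (
    BackgroundModel,
    Detection,
    DetectionConfig,
    MoonNotFound,
    detect_dark_objects,
    detect_transits,
    fit_moon_disk,
    group_flocks,
    link_tracks,
    tracks_from_jsonl,
    tracks_to_frame,
    tracks_to_jsonl,
)
from moonwatch.evaluate import match_tracks
from moonwatch.scene import SceneConfig, TransitSpec, render_frame, simulate_session
from moonwatch.timing import TimestampLog


def physics_gate_px(scene: SceneConfig, altitude_m=500.0, vmax=25.0) -> float:
    slant = altitude_m / math.sin(math.radians(scene.moon_altitude_deg))
    return 1.2 * math.degrees(vmax / slant) * scene.px_per_deg / scene.fps_nominal


class TestFitMoonDisk:
    def test_full_disk_radius(self, disk_image):
        img = disk_image(800, 600, 400, 300, 250)
        fit = fit_moon_disk(img, 127)
        assert fit.radius_px == pytest.approx(250.0, abs=1.0)
        assert fit.center_px == pytest.approx((400.0, 300.0), abs=0.5)

    def test_gibbous_disk_radius_within_five_percent(self):
        """85%-illuminated disk: equivalent radius within 5% of full, center
        biased toward the lit limb."""
        r = 200.0
        yy, xx = np.mgrid[0:600, 0:800]
        full = (xx - 400.0) ** 2 + (yy - 300.0) ** 2 <= r * r
        # clip a lune so ~85% of the disk area remains lit
        terminator_x = 400.0 - 0.6 * r
        lit = full & (xx >= terminator_x)
        frac = lit.sum() / full.sum()
        assert 0.80 < frac < 0.90
        img = np.where(lit, 230, 10).astype(np.uint8)
        fit = fit_moon_disk(img, 127)
        assert abs(fit.radius_px - r) / r < 0.05 or fit.radius_px < r
        assert fit.radius_px == pytest.approx(r * math.sqrt(frac), rel=0.02)
        assert fit.center_px[0] > 400.0  # toward the lit side

    def test_all_dark_frame_skip_signal(self):
        with pytest.raises(MoonNotFound):
            fit_moon_disk(np.zeros((600, 800), np.uint8), 127)


class TestDetectDarkObjects:
    def _scene_pair(self, small_scene, specs, t):
        clean = render_frame(small_scene, small_scene.frame_center, [], t)
        frame = render_frame(small_scene, small_scene.frame_center, specs, t)
        return clean, frame

    def test_no_silhouettes_empty(self, small_scene):
        clean, frame = self._scene_pair(small_scene, [], 0.0)
        disk = fit_moon_disk(frame, 127)
        assert detect_dark_objects(frame, disk, clean.astype(np.float32)) == []

    def test_single_silhouette_centroid_within_one_px(self, small_scene):
        spec = TransitSpec(0.0, 90.0, 90.0, 1.0, 5.0, silhouette_darkness=30)
        r = small_scene.moon_radius_px
        t_mid = (r + 2.5) / small_scene.px_per_deg  # blob at disk center
        clean, frame = self._scene_pair(small_scene, [spec], t_mid)
        disk = fit_moon_disk(frame, 127)
        dets = detect_dark_objects(frame, disk, clean.astype(np.float32))
        assert len(dets) == 1
        cx, cy = small_scene.frame_center
        assert dets[0].centroid_px == pytest.approx((cx, cy), abs=1.5)
        assert dets[0].area_px >= 2

    def test_fourteen_simultaneous_silhouettes(self, small_scene):
        """The flock load case: 14 birds on the disk at once."""
        specs = []
        r = small_scene.moon_radius_px
        for i in range(14):
            offset = -0.85 + i * (1.7 / 13)
            spec = TransitSpec(0.0, 0.0, 0.0, 1.0, 7.0, 30, offset)
            specs.append(spec)
        # time when each blob is mid-chord
        t = (r + 3.5) / small_scene.px_per_deg
        clean, frame = self._scene_pair(small_scene, specs, t)
        disk = fit_moon_disk(frame, 127)
        dets = detect_dark_objects(frame, disk, clean.astype(np.float32))
        assert len(dets) == 14


class TestLinkTracks:
    def _times(self, n, fps=25.0):
        return TimestampLog([0.0, (n - 1) / fps], [0, n - 1])

    def test_single_crossing_single_track(self, small_scene):
        spec = TransitSpec(0.2, 90.0, 90.0, 1.0, 8.0, 30, 0.0)
        res = simulate_session(small_scene, [spec], 4.0, collect_frames=True)
        tracks, _, _ = detect_transits(
            enumerate(res.frames), res.timestamp_log,
            DetectionConfig(gating_radius_px=physics_gate_px(small_scene)),
        )
        assert len(tracks) == 1
        truth = res.ground_truth.transits[0]
        assert abs(tracks[0].frames[0] - truth.entry_frame) <= 1
        assert abs(tracks[0].frames[-1] - truth.exit_frame) <= 1

    def test_parallel_paths_no_identity_swap(self, small_scene):
        specs = [
            TransitSpec(0.2, 90.0, 90.0, 0.9, 8.0, 30, -0.5),
            TransitSpec(0.2, 90.0, 90.0, 0.9, 8.0, 30, 0.5),
        ]
        res = simulate_session(small_scene, specs, 5.0, collect_frames=True)
        tracks, _, _ = detect_transits(
            enumerate(res.frames), res.timestamp_log,
            DetectionConfig(gating_radius_px=physics_gate_px(small_scene)),
        )
        assert len(tracks) == 2
        m = match_tracks(res.ground_truth, tracks)
        assert m.precision == 1.0 and m.recall == 1.0
        # no swap: each track's y span stays on its own side
        cy = small_scene.frame_center[1]
        sides = [
            {d.centroid_px[1] > cy for d in t.detections} for t in tracks
        ]
        assert all(len(s) == 1 for s in sides)

    def test_single_frame_blip(self):
        det = Detection(5, (100.0, 100.0), 4, 120.0, False, 3.0, 2.0, 0.0)
        log = TimestampLog([0.0, 4.0], [0, 100])  # 25 fps
        tracks = link_tracks([(5, [det])], log, gating_radius_px=20.0)
        assert len(tracks) == 1
        assert tracks[0].completeness == "single_frame"
        assert tracks[0].duration_s == pytest.approx(0.04)

    def test_no_detection_in_two_tracks(self, small_scene):
        specs = [
            TransitSpec(0.1 + 0.25 * i, 45.0 + 60 * i, 45.0, 1.1, 7.0, 30, -0.6 + 0.3 * i)
            for i in range(4)
        ]
        res = simulate_session(small_scene, specs, 4.0, collect_frames=True)
        tracks, _, _ = detect_transits(
            enumerate(res.frames), res.timestamp_log,
            DetectionConfig(gating_radius_px=physics_gate_px(small_scene)),
        )
        seen = set()
        total = 0
        for tr in tracks:
            for d in tr.detections:
                key = (d.frame_index, d.centroid_px)
                assert key not in seen
                seen.add(key)
                total += 1
        assert total == sum(t.n_frames for t in tracks)

    def test_duration_at_least_one_frame_period(self, small_scene):
        specs = [
            TransitSpec(0.1 * i, 30.0 * i % 360, 0.0, 1.0 + 0.2 * i, 6.0, 30, 0.1 * i - 0.5)
            for i in range(6)
        ]
        res = simulate_session(small_scene, specs, 4.0, collect_frames=True)
        tracks, _, _ = detect_transits(
            enumerate(res.frames), res.timestamp_log,
            DetectionConfig(gating_radius_px=physics_gate_px(small_scene)),
        )
        period = 1.0 / small_scene.fps_nominal
        assert tracks
        assert all(t.duration_s >= period * 0.9 for t in tracks)


class TestGroupFlocks:
    def _track(self, tid, t0, t1):
        det = Detection(0, (0.0, 0.0), 4, 100.0, False, 3.0, 2.0, 0.0)
        from moonwatch.detect import TransitTrack

        return TransitTrack(tid, [det], t0, t1, t1 - t0, 4.0, 0.0, "full_crossing")

    def test_separated_tracks_no_flock(self):
        tracks = [self._track(i, 10.0 * i, 10.0 * i + 1.0) for i in range(5)]
        assert group_flocks(tracks, window_s=1.0) == []

    def test_fourteen_tracks_one_flock(self):
        tracks = [self._track(i, 5.0 + 0.1 * i, 6.5 + 0.1 * i) for i in range(14)]
        events = group_flocks(tracks, window_s=2.0)
        assert len(events) == 1
        assert events[0].count == 14
        assert all(t.flock_id == events[0].flock_id for t in tracks)

    def test_single_linkage_chain(self):
        a = self._track(0, 0.0, 1.0)
        b = self._track(1, 1.5, 2.5)
        c = self._track(2, 3.0, 4.0)  # within window of b, not of a
        events = group_flocks([a, b, c], window_s=1.0)
        assert len(events) == 1 and events[0].count == 3


class TestNonBirdFlag:
    def test_erratic_path_flagged_advisory(self):
        from moonwatch.detect import TransitTrack  # noqa: F401

        # an insect-like loop: eight points around a circle
        dets = [
            Detection(
                k,
                (100.0 + 15.0 * math.cos(2 * math.pi * k / 8),
                 100.0 + 15.0 * math.sin(2 * math.pi * k / 8)),
                4, 100.0, False, 3.0, 2.0, 0.0,
            )
            for k in range(8)
        ]
        log = TimestampLog([0.0, 1.0], [0, 25])
        tracks = link_tracks([(d.frame_index, [d]) for d in dets], log, 50.0)
        assert len(tracks) == 1
        assert tracks[0].flagged_nonbird  # erratic, not deleted

    def test_straight_path_not_flagged(self):
        dets = [
            Detection(k, (50.0 + 12.0 * k, 80.0 + 6.0 * k), 4, 100.0, False, 3.0, 2.0, 0.0)
            for k in range(8)
        ]
        log = TimestampLog([0.0, 1.0], [0, 25])
        tracks = link_tracks([(d.frame_index, [d]) for d in dets], log, 50.0)
        assert not tracks[0].flagged_nonbird


def test_track_exports_round_trip(tmp_path, small_scene):
    specs = [TransitSpec(0.2, 120.0, 120.0, 1.0, 10.0, 30, 0.0)]
    res = simulate_session(small_scene, specs, 3.0, collect_frames=True)
    tracks, _, _ = detect_transits(
        enumerate(res.frames), res.timestamp_log,
        DetectionConfig(gating_radius_px=physics_gate_px(small_scene)),
    )
    df = tracks_to_frame(tracks)
    assert list(df.columns[:4]) == ["track_id", "start_s", "end_s", "duration_s"]
    path = tmp_path / "tracks.jsonl"
    tracks_to_jsonl(tracks, path)
    back = tracks_from_jsonl(path)
    assert len(back) == len(tracks)
    assert back[0].frames == tracks[0].frames
    assert back[0].duration_s == pytest.approx(tracks[0].duration_s)
    assert back[0].image_path_angle_deg == pytest.approx(tracks[0].image_path_angle_deg)
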