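"""Flight directions, orientation, size/distance, rose, traffic rate."""

import math

import numpy as np
import pytest

from moonwatch import geometry
from moonwatch.analytics import (
    FlightSolution,
    GeometryError,
    SessionGeometry,
    angular_size_and_distance,
    circular_mean_deg,
    direction_rose,
    image_to_ground_track,
    lowery_traffic_rate,
    solve_session,
)
from moonwatch.detect import DetectionConfig, detect_transits
from moonwatch.scene import SceneConfig, sample_transit_schedule, simulate_session
from test_detect import physics_gate_px


class TestImageToGroundTrack:
    def test_horizontal_motion_is_perpendicular_crossing(self):
        geom = SessionGeometry.fixed(210.0, 40.0)
        b, wide = image_to_ground_track(0.0, geom)
        assert abs(geometry.wrap_signed(b - (210.0 + 90.0))) < 1e-9
        assert not wide
        b2, _ = image_to_ground_track(180.0, geom)
        assert abs(geometry.wrap_signed(b2 - (210.0 - 90.0))) < 1e-9

    def test_low_moon_refused(self):
        geom = SessionGeometry.fixed(180.0, 3.0)
        with pytest.raises(GeometryError):
            image_to_ground_track(45.0, geom)

    def test_near_zenith_flagged_wide(self):
        geom = SessionGeometry.fixed(180.0, 88.0)
        _, wide = image_to_ground_track(45.0, geom)
        assert wide

    def test_round_trip_against_ray_oracle(self):
        from test_geometry import oracle_image_angle

        rng = np.random.default_rng(17)
        for _ in range(50):
            bearing = rng.uniform(0, 360)
            azimuth = rng.uniform(0, 360)
            altitude = rng.uniform(10, 85)
            roll = rng.uniform(-15, 15)
            img = oracle_image_angle(bearing, azimuth, altitude, roll)
            geom = SessionGeometry.fixed(azimuth, altitude, camera_roll_deg=roll)
            back, _ = image_to_ground_track(img, geom)
            assert abs(geometry.wrap_signed(back - bearing)) < 1.0


class TestAngularSizeAndDistance:
    def test_plate_scale_arithmetic(self):
        ang, dist, lb = angular_size_and_distance(10.0, 300.0, 0.52, 0.15)
        scale = math.radians(0.52) / 600.0
        assert ang == pytest.approx(10.0 * scale)
        assert ang == pytest.approx(1.513e-4, rel=1e-3)
        assert dist == pytest.approx(991.0, rel=0.005)
        assert not lb

    def test_doubling_assumed_length_doubles_distance(self):
        _, d1, _ = angular_size_and_distance(10.0, 300.0, 0.52, 0.10)
        _, d2, _ = angular_size_and_distance(10.0, 300.0, 0.52, 0.20)
        assert d2 == pytest.approx(2.0 * d1)

    def test_subresolution_is_lower_bound(self):
        _, dist, lb = angular_size_and_distance(1.0, 300.0, 0.52, 0.15)
        assert lb
        _, dist2px, _ = angular_size_and_distance(2.0, 300.0, 0.52, 0.15)
        assert dist == pytest.approx(dist2px)

    def test_passerine_length_bounds_enforced(self):
        with pytest.raises(ValueError):
            angular_size_and_distance(10.0, 300.0, 0.52, 0.5)

    def test_simulator_altitude_recovered_from_apparent_size(self, small_scene):
        """Distance from pixel size inverts the generator's size model."""
        H, theta = 500.0, small_scene.moon_altitude_deg
        slant = H / math.sin(math.radians(theta))
        specs = sample_transit_schedule(4e5, H, ("uniform",), 60.0, small_scene, 21)
        for spec in specs[:10]:
            body_m = math.radians(spec.silhouette_length_px / small_scene.px_per_deg) * slant
            _, dist, _ = angular_size_and_distance(
                spec.silhouette_length_px, small_scene.moon_radius_px,
                small_scene.moon_angular_diameter_deg, assumed_length_m=body_m,
            )
            assert dist == pytest.approx(slant, rel=0.01)


class TestDirectionRose:
    def test_identical_bearings_single_bin(self):
        rose = direction_rose([100.0] * 40, 16)
        assert max(rose["weights"]) == pytest.approx(1.0)
        assert sum(rose["weights"]) == pytest.approx(1.0)

    def test_uniform_bearings_flat(self):
        rng = np.random.default_rng(5)
        rose = direction_rose(rng.uniform(0, 360, 40000), 8)
        assert max(rose["weights"]) - min(rose["weights"]) < 0.02

    def test_empty_input(self):
        rose = direction_rose([], 8)
        assert rose["weights"] == [] and rose["circular_mean_bearing_deg"] is None

    def test_von_mises_mean_recovered_in_both_conventions(self):
        rng = np.random.default_rng(6)
        bearings = np.rad2deg(rng.vonmises(math.radians(290.0), 4.0, 5000)) % 360.0
        rose = direction_rose(bearings, 16)
        mean = rose["circular_mean_bearing_deg"]
        assert abs(geometry.wrap_signed(mean - 290.0)) < 5.0
        conv = rose["circular_mean_north_of_east_deg"]
        assert conv == pytest.approx((90.0 - mean) % 360.0)

    def test_mean_invariant_under_binning(self):
        rng = np.random.default_rng(7)
        bearings = np.rad2deg(rng.vonmises(math.radians(123.0), 3.0, 2000)) % 360.0
        m16 = direction_rose(bearings, 16)["circular_mean_bearing_deg"]
        m32 = direction_rose(bearings, 32)["circular_mean_bearing_deg"]
        assert m16 == pytest.approx(m32)  # mean computed from raw bearings

    def test_min_bins(self):
        with pytest.raises(ValueError):
            direction_rose([1.0], 3)


class TestLoweryTrafficRate:
    def test_zero_birds_zero_rate(self):
        geom = SessionGeometry.fixed(180.0, 50.0)
        est = lowery_traffic_rate([], geom, 500.0, 1.0)
        assert est.birds_per_km_front_per_hour == 0.0
        assert est.zero_count

    def test_zenith_worked_case_closed_form(self):
        """Moon at zenith: circular gate delta_rad * H; 45 birds in 1 h."""
        geom = SessionGeometry.fixed(0.0, 90.0, 0.52)
        rng = np.random.default_rng(0)
        sols = [FlightSolution(i, rng.uniform(0, 360), 0.0) for i in range(45)]
        est = lowery_traffic_rate(sols, geom, 1000.0, 1.0)
        gate_km = math.radians(0.52) * 1000.0 / 1000.0
        expected = 45.0 / gate_km
        assert est.mean_gate_width_m == pytest.approx(math.radians(0.52) * 1000.0)
        assert est.birds_per_km_front_per_hour == pytest.approx(expected, rel=1e-4)

    def test_unit_coherence(self):
        geom = SessionGeometry.fixed(100.0, 45.0)
        sols = [FlightSolution(i, 30.0 * i, 0.0) for i in range(7)]
        est = lowery_traffic_rate(sols, geom, 500.0, 0.5)
        assert est.birds_per_mile_front_per_hour == pytest.approx(
            est.birds_per_km_front_per_hour * 1.609344
        )

    def test_near_horizon_refused(self):
        geom = SessionGeometry.fixed(180.0, 4.0)
        with pytest.raises(GeometryError):
            lowery_traffic_rate([FlightSolution(0, 0.0, 90.0)], geom, 500.0, 1.0)

    @pytest.mark.parametrize("theta", [25.0, 50.0, 80.0])
    def test_flux_recovery_from_known_schedule(self, theta):
        """Estimator inverts the generator's flux within Monte-Carlo error."""
        F, H = 2.0e4, 500.0
        sc = SceneConfig(moon_altitude_deg=theta)
        sched = sample_transit_schedule(F, H, ("vonmises", 300.0, 2.0), 7200.0, sc, 13)
        geom = SessionGeometry.fixed(sc.moon_azimuth_deg, theta, sc.moon_angular_diameter_deg)
        sols = [FlightSolution(i, s.ground_track_bearing_deg, 0.0) for i, s in enumerate(sched)]
        est = lowery_traffic_rate(sols, geom, H, 2.0)
        assert len(sched) >= 100
        assert est.birds_per_km_front_per_hour == pytest.approx(
            F, rel=4.0 / math.sqrt(len(sched))
        )


class TestBodyOrientationAndSolve:
    def _session_with_offset(self, offset_deg, seed=31):
        sc = SceneConfig(frame_width_px=420, frame_height_px=420,
                         field_of_view_deg=0.7, fps_nominal=25.0, rng_seed=seed)
        specs = sample_transit_schedule(
            3e5, 500.0, ("vonmises", 300.0, 1.0), 25.0, sc, seed,
            body_length_range_m=(0.18, 0.25),
            ground_speed_mean_ms=10.0, ground_speed_sd_ms=1.0,
            orientation_offset_deg=offset_deg,
        )
        res = simulate_session(sc, specs, 25.0, collect_frames=True)
        tracks, _, _ = detect_transits(
            enumerate(res.frames), res.timestamp_log,
            DetectionConfig(gating_radius_px=physics_gate_px(sc)),
        )
        geom = SessionGeometry.fixed(sc.moon_azimuth_deg, sc.moon_altitude_deg,
                                     sc.moon_angular_diameter_deg)
        return sc, tracks, geom

    def test_compensating_flyer_zero_drift(self):
        sc, tracks, geom = self._session_with_offset(0.0)
        summary = solve_session(tracks, geom, 25.0 / 3600.0, 500.0,
                                disk_radius_px=sc.moon_radius_px)
        drifts = [s.drift_angle_deg for s in summary["solutions"]
                  if s.drift_angle_deg is not None]
        assert len(drifts) >= 3
        assert abs(np.median(drifts)) < 3.0

    def test_wind_drifted_flyer_offset_recovered(self):
        sc, tracks, geom = self._session_with_offset(20.0)
        summary = solve_session(tracks, geom, 25.0 / 3600.0, 500.0,
                                disk_radius_px=sc.moon_radius_px)
        drifts = [s.drift_angle_deg for s in summary["solutions"]
                  if s.drift_angle_deg is not None]
        assert len(drifts) >= 3
        assert abs(np.median(drifts) - 20.0) < 3.0

    def test_circular_blob_orientation_undefined(self):
        from moonwatch.analytics import body_orientation
        from moonwatch.detect import Detection, TransitTrack

        dets = [Detection(k, (50.0 + 10 * k, 50.0), 12, 100.0, False, 4.0, 1.05, 0.0)
                for k in range(5)]
        track = TransitTrack(0, dets, 0.0, 0.2, 0.2, 12.0, 0.0, "full_crossing")
        geom = SessionGeometry.fixed(180.0, 50.0)
        assert body_orientation(track, geom) is None


def test_circular_mean_basic():
    assert circular_mean_deg([350.0, 10.0]) == pytest.approx(0.0, abs=1e-9)
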