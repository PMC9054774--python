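import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from windhover.errors import ValidationError
from windhover.flow import integral_length_scale
from windhover.hover import HEAD, MANTLE, detect_hovers
from windhover.mapping import interpolate_at
from windhover.synthetic import (
    FlightPlan,
    FlightVolume,
    GridSpec,
    RampGeometry,
    Segment,
    TurbulenceSpec,
    cohort_flight_plan,
    default_flight_plan,
    generate_flight_trajectory,
    generate_turbulence,
    generate_updraft_field,
    position_with_angle,
    score_detection,
    updraft_angle_at,
)

from conftest import GRID_B


class TestGenerateTurbulence:
    def test_zero_intensity_is_constant(self):
        series = generate_turbulence(
            TurbulenceSpec(mean_speed=6.0, intensity=0.0, length_scale=0.31, duration=1.0)
        )
        assert np.all(series.u == 6.0)
        assert np.all(series.v == 0.0)
        assert np.all(series.w == 0.0)

    def test_length_and_time_base(self, grid_b_spec, grid_b_series):
        assert len(grid_b_series) == int(grid_b_spec.duration * grid_b_spec.sample_rate)
        assert np.allclose(np.diff(grid_b_series.t), 1.0 / grid_b_spec.sample_rate)

    def test_exact_moment_recovery(self, grid_b_series):
        # sample TI = std(u)/mean(u) must hit the target by exact rescaling
        ti = np.std(grid_b_series.u) / np.mean(grid_b_series.u)
        assert ti == pytest.approx(GRID_B[0], abs=1e-6)
        assert np.mean(grid_b_series.u) == pytest.approx(6.0, rel=1e-9)
        assert np.std(grid_b_series.u) == pytest.approx(0.126 * 6.0, rel=1e-9)

    def test_isotropic_lateral_components(self, grid_b_series):
        sigma = 0.126 * 6.0
        for comp in (grid_b_series.v, grid_b_series.w):
            assert np.mean(comp) == pytest.approx(0.0, abs=1e-9)
            assert np.std(comp) == pytest.approx(sigma, rel=1e-9)

    def test_length_scale_recovered(self, grid_b_series):
        # autocorrelation-integral oracle: target 0.31 m within +-20 %
        assert 0.248 <= integral_length_scale(grid_b_series) <= 0.372

    def test_seeds_differ_but_moments_match(self):
        spec0 = TurbulenceSpec(6.0, 0.126, 0.31, duration=5.0, seed=0)
        spec1 = TurbulenceSpec(6.0, 0.126, 0.31, duration=5.0, seed=1)
        a, b = generate_turbulence(spec0), generate_turbulence(spec1)
        assert not np.allclose(a.u, b.u)
        for s in (a, b):
            assert np.mean(s.u) == pytest.approx(6.0, rel=1e-9)
            assert np.std(s.u) == pytest.approx(0.756, rel=1e-9)

    def test_reproducible_from_seed(self):
        spec = TurbulenceSpec(6.0, 0.126, 0.31, duration=2.0, seed=7)
        assert np.array_equal(generate_turbulence(spec).u, generate_turbulence(spec).u)

    @settings(max_examples=10, deadline=None)
    @given(
        mean=st.floats(1.0, 15.0),
        ti=st.floats(0.01, 0.3),
        seed=st.integers(0, 2**31),
    )
    def test_moment_property(self, mean, ti, seed):
        spec = TurbulenceSpec(mean, ti, 0.25, sample_rate=500.0, duration=2.0, seed=seed)
        series = generate_turbulence(spec)
        assert np.mean(series.u) == pytest.approx(mean, rel=1e-9)
        assert np.std(series.u) == pytest.approx(ti * mean, rel=1e-9)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"mean_speed": 0.0},
            {"mean_speed": -1.0},
            {"intensity": -0.1},
            {"intensity": 1.0},
            {"length_scale": 0.0},
            {"sample_rate": 0.0},
            {"duration": -1.0},
        ],
    )
    def test_invalid_spec(self, kwargs):
        base = dict(mean_speed=6.0, intensity=0.1, length_scale=0.3)
        base.update(kwargs)
        with pytest.raises(ValidationError):
            TurbulenceSpec(**base)


class TestUpdraftField:
    def test_flat_ramp_gives_zero_angle(self, flight_volume):
        flat = RampGeometry(incline=0.0)
        grid = generate_updraft_field(flat, 6.0, GridSpec.covering(flight_volume), flight_volume)
        assert np.all(grid.angle_deg == 0.0)

    def test_speed_invariance_of_angles(self, ramp, flight_volume):
        spec = GridSpec.covering(flight_volume)
        g5 = generate_updraft_field(ramp, 5.0, spec, flight_volume)
        g7 = generate_updraft_field(ramp, 7.0, spec, flight_volume)
        assert np.array_equal(g5.angle_deg, g7.angle_deg)
        assert np.allclose(g5.speed / 5.0, g7.speed / 7.0, rtol=0, atol=1e-15)

    def test_default_field_matches_facility_envelope(self, default_map, flight_volume):
        # 6 m/s tunnel: speeds within [5, 8] m/s over the flight volume and
        # centroid angle within the 4.5-10 degree envelope
        assert np.all(default_map.speed >= 5.0)
        assert np.all(default_map.speed <= 8.0)
        cx, _, cz = flight_volume.centroid
        _, angle, _ = interpolate_at(default_map, cx, cz)
        assert 4.5 <= angle <= 10.0
        assert np.max(default_map.angle_deg) <= 42.0
        assert np.all(default_map.angle_deg >= 0.0)
        assert np.all(default_map.angle_deg <= 45.0)

    def test_invalid_tunnel_speed(self, ramp, flight_volume):
        with pytest.raises(ValidationError):
            generate_updraft_field(ramp, 0.0, GridSpec.covering(flight_volume))

    def test_grid_must_cover_volume(self, ramp, flight_volume):
        small = GridSpec(x_min=7.0, x_max=7.2, z_min=1.2, z_max=1.4)
        with pytest.raises(ValidationError):
            generate_updraft_field(ramp, 6.0, small, flight_volume)

    def test_position_with_angle_inverts_model(self, ramp):
        for angle in (2.0, 6.0, 10.0, 20.0):
            x, z = position_with_angle(ramp, angle, s_frac=0.7)
            assert updraft_angle_at(ramp, x, z) == pytest.approx(angle, rel=1e-9)


class TestFlightTrajectory:
    def test_noiseless_hover_is_constant(self):
        plan = FlightPlan(
            segments=(Segment("hover", 1.0, (7.0, 0.0, 1.3), noise_std_mm=0.0),)
        )
        traj, _ = generate_flight_trajectory(plan, sample_rate=200.0)
        head = traj.markers[HEAD]
        assert np.all(head == head[0])
        assert np.allclose(head[0], [7000.0, 0.0, 1300.0])

    def test_mantle_is_head_plus_offset_when_noiseless(self):
        plan = FlightPlan(
            segments=(Segment("hover", 0.5, (7.0, 0.0, 1.3)),),
            mantle_offset_mm=(30.0, 0.0, -20.0),
        )
        traj, _ = generate_flight_trajectory(plan)
        assert np.allclose(traj.markers[MANTLE] - traj.markers[HEAD], (30.0, 0.0, -20.0))

    def test_truth_matches_plan(self):
        plan = default_flight_plan(seed=0)
        _, truth = generate_flight_trajectory(plan)
        assert truth.intervals == tuple(plan.hover_intervals())

    def test_empty_plan_rejected(self):
        with pytest.raises(ValidationError):
            FlightPlan(segments=())

    def test_plan_must_start_with_hover(self):
        with pytest.raises(ValidationError):
            FlightPlan(segments=(Segment("transit", 1.0, (7.0, 0.0, 1.3)),))

    def test_short_hover_not_detected(self):
        # 0.8 s and 0.4 s hovers, 0.3 mm noise: only the 0.8 s one survives
        # the 0.5 s detection rule
        plan = FlightPlan(
            segments=(
                Segment("hover", 0.8, (7.0, 0.0, 1.3), noise_std_mm=0.3),
                Segment("transit", 0.5, (7.6, 0.0, 1.3)),
                Segment("hover", 0.4, (7.6, 0.0, 1.3), noise_std_mm=0.3),
            ),
            seed=2,
        )
        traj, truth = generate_flight_trajectory(plan)
        events = detect_hovers(traj)
        assert len(events) == 1
        start, end, _ = truth.intervals[0]
        overlap = min(events[0].end, end) - max(events[0].start, start)
        assert overlap >= 0.8 * (end - start)

    def test_closed_loop_recall_precision(self):
        # planted hovers >= 0.6 s, noise 0.3 mm, transits >= 1 m/s:
        # perfect detection over >= 20 random seeds
        for seed in range(20):
            plan = cohort_flight_plan(seed=seed, transit_speed=1.5)
            traj, truth = generate_flight_trajectory(plan)
            scores = score_detection(truth, detect_hovers(traj))
            assert scores["recall"] == 1.0
            assert scores["precision"] == 1.0


class TestGeometryTypes:
    def test_ramp_defaults(self, ramp):
        assert ramp.surface_length == 1.215
        assert ramp.incline == 52.0
        assert ramp.leading_edge_x == 7.14
        assert ramp.floor_gap == 0.145

    def test_flight_volume_defaults(self, flight_volume):
        assert (flight_volume.length, flight_volume.width, flight_volume.height) == (
            1.35, 1.5, 0.75,
        )
        assert flight_volume.centroid == (7.125, 0.0, 1.325)

    def test_invalid_geometry(self):
        with pytest.raises(ValidationError):
            RampGeometry(incline=90.0)
        with pytest.raises(ValidationError):
            FlightVolume(length=0.0)
        with pytest.raises(ValidationError):
            GridSpec(x_min=1.0, x_max=0.0, z_min=0.0, z_max=1.0)
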