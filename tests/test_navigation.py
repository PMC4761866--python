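"""Tests of the isoline-following, plume-following and search behaviours."""

import numpy as np
import pytest

from isohome._geodesy import KM_PER_DEG, haversine_km
from isohome.errors import ValidationError
from isohome.geomag import GeoPosition, coefficients_at
from isohome.navigation import (MODE_ARRIVED, MODE_FAILED, AgentParams,
                                AgentState, field_and_gradient,
                                isoline_following_step, odor_detected,
                                plume_following_step, search_step,
                                spiral_arc_length_km)
from isohome.particle_tracking import PlumeSnapshot
from isohome.scenarios import (NavigationScenarioConfig,
                               run_navigation_scenario)
from isohome.synthetic_fields import VelocityField
from tests.conftest import make_dipole_set


def uniform_flow(u, v):
    lats = np.arange(-15.0, 5.01, 1.0)
    lons = np.arange(-25.0, -4.99, 1.0)
    shape = (1, 1, lats.size, lons.size)
    return VelocityField(lats=lats, lons=lons, depths=[0.0], times_h=[0.0],
                         u=np.full(shape, float(u)), v=np.full(shape, float(v)))


class TestIsolineFollowing:
    def test_on_dipole_isoline_moves_along_latitude(self):
        coeffs = make_dipole_set()
        pos = GeoPosition(-8.0, -14.0)
        F0, _, _ = field_and_gradient(coeffs, pos.lat, pos.lon)
        params = AgentParams(target_level=float(F0))
        state = AgentState(pos=pos)
        for _ in range(20):
            state = isoline_following_step(coeffs, state, params, 1.0)
        assert abs(state.pos.lat - pos.lat) < 0.02     # stays on the parallel
        assert state.pos.lon > pos.lon + 0.2           # travels east

    def test_correction_points_equatorward_when_field_too_strong(self):
        # northern hemisphere dipole: F increases poleward; an agent north of
        # its target isoline must steer south
        coeffs = make_dipole_set()
        target_pos = GeoPosition(40.0, 0.0)
        F_target, _, _ = field_and_gradient(coeffs, target_pos.lat,
                                            target_pos.lon)
        params = AgentParams(target_level=float(F_target))
        state = AgentState(pos=GeoPosition(41.0, 0.0))  # displaced north
        state = isoline_following_step(coeffs, state, params, 1.0)
        heading = np.radians(state.heading_deg)
        assert np.cos(heading) < 0  # southward component

    def test_intensity_error_contracts_near_isoline(self, degree3_set):
        params = AgentParams(target_level=0.0, crosstrack_gain=1.0)
        rng = np.random.default_rng(2)
        for _ in range(5):
            pos = GeoPosition(float(rng.uniform(-10, -6)),
                              float(rng.uniform(-16, -12)))
            F, _, _ = field_and_gradient(degree3_set, pos.lat, pos.lon)
            p = AgentParams(target_level=float(F) + 30.0)  # ~small offset
            state = AgentState(pos=pos)
            errs = []
            for _ in range(30):
                state = isoline_following_step(degree3_set, state, p, 1.0)
                Fi, _, _ = field_and_gradient(degree3_set, state.pos.lat,
                                              state.pos.lon)
                errs.append(abs(float(Fi) - p.target_level))
            assert errs[-1] <= errs[0] + 1.0


class TestOdorDetection:
    def test_particle_at_agent_position(self):
        snap = PlumeSnapshot(0.0, np.array([[-8.0, -14.0]]))
        assert odor_detected(AgentState(pos=GeoPosition(-8.0, -14.0)),
                             snap, 1.0)

    def test_empty_snapshot(self):
        snap = PlumeSnapshot(0.0, np.empty((0, 2)))
        assert not odor_detected(AgentState(pos=GeoPosition(-8.0, -14.0)),
                                 snap, 1e9)

    def test_agrees_with_brute_force_nearest(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            pts = np.column_stack([rng.uniform(-10, -6, 50),
                                   rng.uniform(-16, -12, 50)])
            snap = PlumeSnapshot(0.0, pts)
            pos = GeoPosition(float(rng.uniform(-10, -6)),
                              float(rng.uniform(-16, -12)))
            dmin = min(haversine_km(pos.lat, pos.lon, la, lo)
                       for la, lo in pts)
            radius = float(rng.uniform(5, 150))
            if abs(dmin - radius) > 1e-6:
                assert odor_detected(AgentState(pos=pos), snap, radius) \
                    == (dmin <= radius)


class TestPlumeFollowing:
    def test_heads_upflow_in_eastward_current(self):
        state = AgentState(pos=GeoPosition(-8.0, -14.0))
        state = plume_following_step((0.5, 0.0), state, AgentParams(), 1.0)
        assert abs(abs(state.heading_deg) - 90.0) < 1e-6
        assert state.heading_deg < 0 or state.heading_deg > 180  # westward

    def test_reaches_upstream_island_within_kinematic_budget(self):
        params = AgentParams(swim_speed=0.6)
        island = GeoPosition(-8.0, -14.0)
        start = GeoPosition(-8.0, -13.0)  # ~110 km due east, flow eastward
        state = AgentState(pos=start)
        dist0 = haversine_km(start.lat, start.lon, island.lat, island.lon)
        budget_h = dist0 / (params.swim_speed * 3.6) * 1.05
        t = 0.0
        while t < budget_h:
            state = plume_following_step((0.5, 0.0), state, params, 0.5)
            t += 0.5
            if haversine_km(state.pos.lat, state.pos.lon, island.lat,
                            island.lon) <= params.island_radius_km:
                break
        assert haversine_km(state.pos.lat, state.pos.lon, island.lat,
                            island.lon) <= params.island_radius_km

    def test_zero_flow_falls_back_to_particle_centroid(self):
        state = AgentState(pos=GeoPosition(-8.0, -14.0))
        snap = PlumeSnapshot(0.0, np.array([[-8.05, -14.0]]))  # due south
        state = plume_following_step((0.0, 0.0), state, AgentParams(), 1.0,
                                     snapshot=snap)
        assert abs(abs(state.heading_deg) - 180.0) < 1.0


class TestSearchSpiral:
    def test_no_gap_wider_than_detection_diameter(self):
        params = AgentParams(detection_radius_km=10.0)
        state = AgentState(pos=GeoPosition(-8.0, -14.0))
        pts = []
        for _ in range(3000):
            state = search_step(state, params, 0.25)
            pts.append((state.pos.lat, state.pos.lon))
        pts = np.array(pts)
        center = state.spiral_center
        # any point within the covered disc lies within the detection radius
        # of some pass (pitch = 2 x detection radius)
        r_pts = haversine_km(pts[:, 0], pts[:, 1], center[0], center[1])
        r_cov = r_pts.max() - params.detection_radius_km
        rng = np.random.default_rng(1)
        for _ in range(50):
            r = rng.uniform(0, r_cov)
            th = rng.uniform(0, 2 * np.pi)
            q_lat = center[0] + (r / KM_PER_DEG) * np.cos(th)
            q_lon = center[1] + (r / KM_PER_DEG) * np.sin(th) \
                / np.cos(np.radians(center[0]))
            d = haversine_km(q_lat, q_lon, pts[:, 0], pts[:, 1])
            assert d.min() <= params.detection_radius_km + 0.5

    def test_island_in_first_ring_is_crossed_within_one_revolution(self):
        params = AgentParams(detection_radius_km=10.0)
        state = AgentState(pos=GeoPosition(-8.0, -14.0))
        island = GeoPosition(-8.0 + 8.0 / KM_PER_DEG, -14.0)  # 8 km north
        best = np.inf
        while state.spiral_phi < 2 * np.pi or state.spiral_center is None:
            state = search_step(state, params, 0.25)
            best = min(best, haversine_km(state.pos.lat, state.pos.lon,
                                          island.lat, island.lon))
        assert best <= params.detection_radius_km

    def test_path_length_matches_analytic_arc_length(self):
        params = AgentParams(detection_radius_km=10.0)
        state = AgentState(pos=GeoPosition(0.0, 0.0))
        total = 0.0
        prev = state.pos
        for _ in range(2000):
            state = search_step(state, params, 0.25)
            total += haversine_km(prev.lat, prev.lon,
                                  state.pos.lat, state.pos.lon)
            prev = state.pos
        expected = spiral_arc_length_km(state.spiral_phi,
                                        2 * params.detection_radius_km)
        assert total == pytest.approx(expected, rel=0.02)


@pytest.fixture(scope="module")
def small_outcomes():
    cfg = NavigationScenarioConfig(n_agents=40)
    return run_navigation_scenario(seed=3, cfg=cfg)


class TestRunScenario:
    def test_dual_beats_both_controls_on_paired_agents(self, small_outcomes):
        o = small_outcomes
        assert o["dual"].success_rate > o["magnetic_only"].success_rate
        assert o["dual"].success_rate > o["odor_only"].success_rate

    def test_magnetic_only_cannot_hit_island_past_drifted_isoline(
            self, small_outcomes):
        # isoline misses the island by ~100 km >> island + detection radius
        assert small_outcomes["magnetic_only"].success_rate == 0.0

    def test_final_modes_are_terminal(self, small_outcomes):
        for o in small_outcomes.values():
            assert set(np.unique(o.final_modes)) <= {MODE_ARRIVED, MODE_FAILED}
            assert o.n_arrived == int((o.final_modes == MODE_ARRIVED).sum())
            assert 0.0 <= o.success_rate <= 1.0

    def test_dual_without_plume_degenerates_to_magnetic_only(self):
        from isohome import scenarios
        from isohome.isoline import drifted_isoline
        from isohome.navigation import run_scenario
        series = scenarios.standard_magnetic_series(curved=True)
        rep = drifted_isoline(series, scenarios.ISLAND, scenarios.T0,
                              scenarios.DELTA_YEARS, window=scenarios.WINDOW,
                              step_deg=scenarios.STEP_DEG)
        flow = uniform_flow(0.0, 0.2)
        empty = PlumeSnapshot(0.0, np.empty((0, 2)))
        outs = {}
        for strat in ("dual", "magnetic_only"):
            params = AgentParams(strategy=strat, target_level=rep.level,
                                 time_limit_days=5.0)
            outs[strat] = run_scenario(
                20, series, flow, empty, params, seed=0,
                t_eval=scenarios.T0 + scenarios.DELTA_YEARS,
                island=scenarios.ISLAND, start_isoline=rep.drifted)
        assert outs["dual"].n_arrived == outs["magnetic_only"].n_arrived
        np.testing.assert_array_equal(outs["dual"].final_modes,
                                      outs["magnetic_only"].final_modes)

    def test_bad_strategy_rejected(self):
        with pytest.raises(ValidationError):
            AgentParams(strategy="psychic")
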