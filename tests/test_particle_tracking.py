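"""Tests of releases, RK4 advection, dispersion, lifetimes, and snapshots."""

import numpy as np
import pytest

from isohome._geodesy import M_PER_DEG, haversine_km
from isohome.errors import DomainError, ValidationError
from isohome.geomag import GeoPosition
from isohome.particle_tracking import (DispersionParams, ReleaseSchedule,
                                       advect, apply_dispersion,
                                       release_particles, rk4_step,
                                       season_window)
from isohome.synthetic_fields import VelocityField

ISLAND = GeoPosition(-7.933, -14.367)


def uniform_field(u=0.3, v=0.0, extent=6.0):
    lats = np.arange(ISLAND.lat - extent, ISLAND.lat + extent + 1e-9, 0.5)
    lons = np.arange(ISLAND.lon - extent, ISLAND.lon + extent + 1e-9, 0.5)
    shape = (1, 1, lats.size, lons.size)
    return VelocityField(lats=lats, lons=lons, depths=[0.0], times_h=[0.0],
                         u=np.full(shape, float(u)), v=np.full(shape, float(v)))


def single_release_schedule(**kw):
    kw.setdefault("zone_center", ISLAND)
    kw.setdefault("layer_depths", (0.0,))
    kw.setdefault("per_layer_per_release", 10)
    kw.setdefault("release_interval_h", 1e9)  # one release at t=0
    return ReleaseSchedule(**kw)


class TestSeasonCalendar:
    def test_default_season_is_135_days(self):
        _, hours = season_window(2004)
        assert hours == 135 * 24.0

    def test_leap_february_lengthens_season(self):
        _, hours = season_window(2003)  # spans Feb 2004 (leap)
        assert hours == 136 * 24.0

    def test_daily_releases_in_default_season(self):
        sched = ReleaseSchedule(zone_center=ISLAND, year=2004)
        assert sched.release_times_h().size == 136  # day 0 .. day 135


class TestReleaseParticles:
    def test_default_waterborne_release_is_500_particles(self):
        sched = ReleaseSchedule(zone_center=ISLAND)
        parts = release_particles(sched, 0.0, np.random.default_rng(0))
        assert len(parts) == 500  # 100 particles x 5 layers

    def test_zero_half_width_collapses_to_center(self):
        sched = single_release_schedule(zone_half_width_km=0.0)
        parts = release_particles(sched, 0.0, np.random.default_rng(0))
        for p in parts:
            assert p.pos.lat == pytest.approx(ISLAND.lat)
            assert p.pos.lon == pytest.approx(ISLAND.lon)

    def test_outside_season_is_empty(self):
        sched = single_release_schedule()
        assert release_particles(sched, -1.0, np.random.default_rng(0)) == []

    def test_uniformity_over_zone(self):
        sched = single_release_schedule(per_layer_per_release=10000)
        parts = release_particles(sched, 0.0, np.random.default_rng(3))
        dlat_km = np.array([p.pos.lat - ISLAND.lat for p in parts]) \
            * M_PER_DEG / 1000.0
        dlon_km = np.array([p.pos.lon - ISLAND.lon for p in parts]) \
            * M_PER_DEG / 1000.0 * np.cos(np.radians(ISLAND.lat))
        assert np.abs(dlat_km).max() <= 5.0 and np.abs(dlon_km).max() <= 5.0
        se = 5.0 / np.sqrt(3.0) / np.sqrt(len(parts))  # sd of U(-5,5)/sqrt(n)
        assert abs(dlat_km.mean()) < 3 * se
        assert abs(dlon_km.mean()) < 3 * se


class TestRK4:
    def test_uniform_flow_closed_form(self):
        f = VelocityField(lats=np.arange(-2, 2.1, 0.5),
                          lons=np.arange(-2, 2.1, 0.5), depths=[0.0],
                          times_h=[0.0],
                          u=np.full((1, 1, 9, 9), 1.0),
                          v=np.zeros((1, 1, 9, 9)))
        new = rk4_step(f, GeoPosition(0.0, 0.0), 0.0, 1.0)
        assert new.lon == pytest.approx(3600.0 / M_PER_DEG, rel=1e-12)
        assert new.lat == pytest.approx(0.0, abs=1e-12)

    def test_zero_flow_fixed_point(self):
        f = uniform_field(0.0, 0.0)
        p = GeoPosition(-8.0, -14.0)
        assert rk4_step(f, p, 0.0, 1.0) == p

    def test_out_of_domain_stage_freezes_particle(self):
        f = uniform_field(5.0, 0.0, extent=0.5)
        edge = GeoPosition(ISLAND.lat, ISLAND.lon + 0.49)
        assert rk4_step(f, edge, 0.0, 24.0) == edge

    @staticmethod
    def _rotation_field(omega_per_h):
        """Solid-body rotation about (0, 0): circular orbits in (lat, lon)."""
        lats = np.arange(-1.0, 1.001, 0.02)
        lons = np.arange(-1.0, 1.001, 0.02)
        la, lo = np.meshgrid(lats, lons, indexing="ij")
        R_m = M_PER_DEG * 180.0 / np.pi
        # dlat/dt = omega*lon, dlon/dt = -omega*lat  (degrees per hour)
        v = omega_per_h * np.radians(lo) * R_m / 3600.0
        u = -omega_per_h * np.radians(la) * R_m / 3600.0 \
            * np.cos(np.radians(la))
        return VelocityField(lats=lats, lons=lons, depths=[0.0], times_h=[0.0],
                             u=u[None, None], v=v[None, None])

    def test_solid_body_rotation_conserves_radius(self):
        omega = 2 * np.pi / 120.0  # one revolution per 5 days, rad/h
        f = self._rotation_field(omega)
        pos = GeoPosition(0.2, 0.0)
        r0 = np.hypot(pos.lat, pos.lon)
        for k in range(100):
            pos = rk4_step(f, pos, 0.0, 1.0)
        r = np.hypot(pos.lat, pos.lon)
        assert abs(r - r0) / r0 < 1e-6

    def test_heading_error_shrinks_as_dt4(self):
        omega = 2 * np.pi / 120.0
        f = self._rotation_field(omega)

        def final_angle_error(dt):
            pos = GeoPosition(0.2, 0.0)
            n = int(round(60.0 / dt))
            for _ in range(n):
                pos = rk4_step(f, pos, 0.0, dt)
            angle = np.arctan2(pos.lon, pos.lat)
            return abs(angle - (-omega * 60.0) % (2 * np.pi)
                       + 2 * np.pi * round(((-omega * 60.0) % (2 * np.pi)
                                            - angle) / (2 * np.pi)))

        e1, e2 = final_angle_error(2.0), final_angle_error(1.0)
        assert e2 < e1 / 8.0  # ~16x for a 4th-order scheme


class TestDispersion:
    def test_zero_diffusivity_is_identity(self):
        p = GeoPosition(-8.0, -14.0)
        out = apply_dispersion(p, DispersionParams(K_h=0.0), 1.0,
                               np.random.default_rng(0))
        assert out == p

    def test_fixed_seed_reproducible(self):
        p = GeoPosition(-8.0, -14.0)
        a = apply_dispersion(p, DispersionParams(K_h=100.0), 1.0,
                             np.random.default_rng(5))
        b = apply_dispersion(p, DispersionParams(K_h=100.0), 1.0,
                             np.random.default_rng(5))
        assert a == b

    def test_mean_square_displacement_matches_diffusion_law(self):
        # 2-D diffusion: MSD = 4 K dt; 1e5 samples at the equator
        K, dt_h = 100.0, 1.0
        dt_s = dt_h * 3600.0
        rng = np.random.default_rng(17)
        p0 = GeoPosition(0.0, 0.0)
        n = 100000
        msd = np.empty(n)
        for i in range(n):
            p = apply_dispersion(p0, DispersionParams(K_h=K), dt_h, rng)
            dx = p.lon * M_PER_DEG
            dy = p.lat * M_PER_DEG
            msd[i] = dx * dx + dy * dy
        expected = 4.0 * K * dt_s  # m^2
        sigma2 = 2.0 * K * dt_s
        se = 2.0 * sigma2 / np.sqrt(n)  # sd of (dx^2+dy^2) = 2 sigma^2
        assert abs(msd.mean() - expected) < 3 * se


class TestAdvect:
    def test_lifetime_bookkeeping(self):
        sched = single_release_schedule(lifetime_days=2.0)
        f = uniform_field(0.0, 0.0)
        ts = advect(sched, f, None, 0.0, 96.0, 1.0, seed=0,
                    record_interval_h=1.0)
        assert ts.alive_mask(48.0).all()          # age == lifetime: alive
        assert not ts.alive_mask(49.0).any()      # age > lifetime: expired
        c = ts.counts(96.0)
        assert c["released"] == c["alive"] + c["expired"] + c["exited"]

    def test_uniform_flow_displacement_10_days(self):
        sched = single_release_schedule(zone_half_width_km=0.0,
                                        lifetime_days=20.0)
        f = uniform_field(0.3, 0.0)
        ts = advect(sched, f, None, 0.0, 240.0, 1.0, seed=0)
        snap = ts.snapshot(240.0)
        d = haversine_km(ISLAND.lat, ISLAND.lon,
                         snap.positions[:, 0], snap.positions[:, 1])
        assert np.allclose(d, 259.2, atol=0.05)  # 0.3 m/s * 10 d = 259.2 km

    def test_same_seed_bit_identical(self):
        sched = single_release_schedule(lifetime_days=5.0)
        f = uniform_field(0.1, 0.05)
        kw = dict(dispersion=DispersionParams(K_h=20.0), t_start=0.0,
                  t_end=48.0, dt_h=1.0, seed=9)
        a = advect(sched, f, **kw)
        b = advect(sched, f, **kw)
        np.testing.assert_array_equal(a.lat, b.lat)
        np.testing.assert_array_equal(a.lon, b.lon)

    def test_seed_irrelevant_without_dispersion(self):
        sched = single_release_schedule(zone_half_width_km=0.0,
                                        lifetime_days=5.0)
        f = uniform_field(0.1, 0.05)
        a = advect(sched, f, None, 0.0, 48.0, 1.0, seed=1)
        b = advect(sched, f, None, 0.0, 48.0, 1.0, seed=2)
        np.testing.assert_array_equal(a.lat, b.lat)

    def test_halving_dt_matches_to_under_one_meter(self):
        sched = single_release_schedule(zone_half_width_km=0.0,
                                        lifetime_days=20.0)
        f = uniform_field(0.3, 0.1)
        a = advect(sched, f, None, 0.0, 240.0, 1.0, seed=0)
        b = advect(sched, f, None, 0.0, 240.0, 0.5, seed=0)
        sa, sb = a.snapshot(240.0), b.snapshot(240.0)
        d_m = haversine_km(sa.positions[:, 0], sa.positions[:, 1],
                           sb.positions[:, 0], sb.positions[:, 1]) * 1000.0
        assert d_m.max() < 1.0

    def test_lifetime_supersets_share_trajectories(self):
        sched = ReleaseSchedule(zone_center=ISLAND, layer_depths=(0.0,),
                                per_layer_per_release=5, lifetime_days=45.0,
                                year=2004)
        f = uniform_field(0.05, 0.02)
        ts = advect(sched, f, DispersionParams(K_h=10.0), 0.0, 40 * 24.0,
                    dt_h=2.0, seed=4)
        for t in (10 * 24.0, 20 * 24.0, 38 * 24.0):
            m15 = ts.alive_mask(t, 15 * 24.0)
            m30 = ts.alive_mask(t, 30 * 24.0)
            m45 = ts.alive_mask(t, 45 * 24.0)
            assert (m15 <= m30).all() and (m30 <= m45).all()

    def test_snapshot_before_first_release_empty(self):
        sched = single_release_schedule(lifetime_days=2.0)
        f = uniform_field(0.0, 0.0)
        ts = advect(sched, f, None, -24.0, 24.0, 1.0, seed=0,
                    record_interval_h=1.0)
        assert ts.snapshot(-24.0).n_particles == 0

    def test_snapshot_outside_span_rejected(self):
        sched = single_release_schedule(lifetime_days=2.0)
        ts = advect(sched, uniform_field(0, 0), None, 0.0, 24.0, 1.0, seed=0)
        with pytest.raises(DomainError):
            ts.snapshot(999.0)

    def test_bad_inputs_rejected(self):
        sched = single_release_schedule()
        with pytest.raises(ValidationError):
            advect(sched, uniform_field(0, 0), None, 0.0, 24.0, -1.0)
        far = single_release_schedule(zone_center=GeoPosition(40.0, 40.0))
        with pytest.raises(ValidationError):
            advect(far, uniform_field(0, 0), None, 0.0, 24.0, 1.0)

    def test_trajectory_csv_export(self, tmp_path):
        sched = single_release_schedule(per_layer_per_release=2,
                                        lifetime_days=1.0)
        ts = advect(sched, uniform_field(0.2, 0.0), None, 0.0, 24.0, 1.0,
                    seed=0, record_interval_h=12.0)
        path = tmp_path / "traj.csv"
        ts.to_csv(path)
        lines = path.read_text().splitlines()
        assert lines[0] == "id,time_h,lat,lon,depth_m,age_h,status"
        assert len(lines) > 3
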