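"""Standard synthetic study scenarios shared by the CLI, the test suite and
the acceptance script.

Two reference scenarios are defined around a virtual Ascension-like island:

* the **eddy scenario** — waterborne odorant dispersal through a mesoscale
  eddy field, scored against an intensity isoline that has drifted 100 km
  north of the island over a 25-year absence (4 km/yr of secular pattern
  translation), for odorant durations of 15/30/45 days;
* the **navigation scenario** — 200 virtual turtles approaching from the
  west along the remembered (now drifted) isoline through a steady
  northward flow that carries the island's odor plume across the isoline,
  run under the dual-cue strategy and both single-cue controls.

Problem sizes (particles per release, number of seasons) are reduced
relative to the full waterborne protocol so a complete scenario runs in
tens of seconds; the release geometry, season calendar, snapshot schedule
and lifetime structure follow the full protocol.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geomag import ASCENSION, GaussCoefficientSeries, GeoPosition, \
    coefficients_at, evaluate_field
from .isoline import IsolinePolyline, drifted_isoline
from .navigation import AgentParams, ScenarioOutcome, run_scenario
from .particle_tracking import DispersionParams, PlumeSnapshot, \
    ReleaseSchedule, TrajectorySet, advect
from .plume_analysis import duration_sensitivity
from .synthetic_fields import EddyFieldParams, SyntheticMagneticParams, \
    VelocityField, synth_magnetic_series, synth_ocean_field

ISLAND = ASCENSION

#: secular drift of the synthetic field: 4 km/yr northward -> 100 km per
#: 25-year absence, the paper-scale displacement of the remembered isoline
DRIFT_KM_PER_YR = 4.0
T0 = 2000.0
DELTA_YEARS = 25.0

#: analysis window around the island for isoline extraction
WINDOW = ((-12.0, -3.0), (-22.0, -9.0))
STEP_DEG = 0.05


def standard_magnetic_series(curved: bool = False) -> GaussCoefficientSeries:
    """Translating synthetic main field; optionally with a strong sectoral
    anomaly that curves the isolines (used by the navigation scenario so
    that dead-reckoning controls diverge from the corridor)."""
    anomalies = {("g", 3, 3): 2200.0, ("h", 3, 3): 900.0} if curved else {}
    params = SyntheticMagneticParams(
        base_dipole_nT=-31000.0,
        translation_km_per_yr=DRIFT_KM_PER_YR,
        translation_bearing_deg=0.0,
        reference_lon=ISLAND.lon,
        anomalies=anomalies,
        epoch_start=T0, epoch_end=T0 + 30.0, epoch_spacing=5.0)
    return synth_magnetic_series(params)


def remembered_level(series: GaussCoefficientSeries) -> float:
    """Intensity (nT) memorized at the island at the previous visit (t0)."""
    return evaluate_field(coefficients_at(series, T0), ISLAND).F


# ---------------------------------------------------------------------------
# eddy / duration-sensitivity scenario
# ---------------------------------------------------------------------------

@dataclass
class EddyScenarioConfig:
    years: tuple = (2004, 2005)
    per_layer_per_release: int = 25
    lifetimes_days: tuple = (15.0, 30.0, 45.0)
    snapshots_per_year: int = 10
    buffer_km: float = 10.0
    dt_h: float = 1.0
    K_h: float = 10.0
    mean_u: float = -0.15
    mean_v: float = 0.0
    n_eddies: int = 12
    eddy_amp: float = 3.0e4
    eddy_radius_km: float = 80.0


def eddy_velocity_field(year: int, seed: int,
                        cfg: EddyScenarioConfig,
                        sim_days: float) -> VelocityField:
    """Daily-frozen mesoscale flow for one season (year-specific eddies)."""
    times = tuple(np.arange(0.0, (sim_days + 2) * 24.0, 24.0))
    params = EddyFieldParams(
        mean_u=cfg.mean_u, mean_v=cfg.mean_v, n_eddies=cfg.n_eddies,
        eddy_amp=cfg.eddy_amp, eddy_radius_km=cfg.eddy_radius_km,
        domain=((-12.0, -4.0), (-20.0, -10.0)),
        times_h=times, seed=(seed * 1000 + year) % (2 ** 31))
    field = synth_ocean_field(params)
    field.time_mode = "previous"  # 00:00 snapshot convention
    return field


def run_eddy_scenario(seed: int = 0,
                      cfg: EddyScenarioConfig | None = None):
    """Simulate the waterborne protocol per year and score intersection
    rates against the 25-year drifted isoline for each odorant duration.

    Returns (results DataFrame, dict of TrajectorySet per year, isoline).
    """
    cfg = cfg or EddyScenarioConfig()
    series = standard_magnetic_series(curved=False)
    report = drifted_isoline(series, ISLAND, T0, DELTA_YEARS,
                             window=WINDOW, step_deg=STEP_DEG)
    iso = report.drifted
    max_life = max(cfg.lifetimes_days)
    trajs: dict[int, TrajectorySet] = {}
    for year in cfg.years:
        sched = ReleaseSchedule(
            zone_center=ISLAND, per_layer_per_release=cfg.per_layer_per_release,
            year=year, lifetime_days=max_life)
        sim_days = sched.season_length_h / 24.0 + max_life
        field = eddy_velocity_field(year, seed, cfg, sim_days)
        trajs[year] = advect(sched, field, DispersionParams(K_h=cfg.K_h),
                             t_start=0.0, t_end=sim_days * 24.0,
                             dt_h=cfg.dt_h, seed=(seed * 7919 + year) % (2 ** 31))
    df = duration_sensitivity(
        trajs, {y: iso for y in cfg.years},
        lifetimes_days=cfg.lifetimes_days,
        snapshots_per_year=cfg.snapshots_per_year,
        buffer_km=cfg.buffer_km, cue="waterborne", delta_years=DELTA_YEARS)
    return df, trajs, report


def run_airborne_scenario(seed: int = 0, year: int = 2009,
                          snapshots: int = 5, buffer_km: float = 10.0,
                          per_release: int = 2):
    """Airborne protocol: hourly surface releases carried WNW by the trade
    wind, scored against the 25-year drifted isoline.

    Returns (IntersectionResult, DriftReport).
    """
    from .plume_analysis import intersection_rate
    from .synthetic_fields import synth_wind_field

    series = standard_magnetic_series(curved=False)
    report = drifted_isoline(series, ISLAND, T0, DELTA_YEARS,
                             window=WINDOW, step_deg=STEP_DEG)
    sched = ReleaseSchedule.airborne(ISLAND, year=year,
                                     per_layer_per_release=per_release)
    sim_days = sched.season_length_h / 24.0 + sched.lifetime_days
    wind = synth_wind_field(
        8.0, toward_bearing=292.5, gust_sd=2.0,
        seed=(seed * 613 + year) % (2 ** 31),
        domain=((-12.0, -2.0), (-22.0, -10.0)), grid_step_deg=0.5,
        times_h=tuple(np.arange(0.0, (sim_days + 2) * 24.0, 1.0)))
    traj = advect(sched, wind, DispersionParams(enabled=False, K_h=0.0),
                  t_start=0.0, t_end=sim_days * 24.0, dt_h=1.0,
                  seed=(seed * 379 + year) % (2 ** 31),
                  record_interval_h=6.0)
    from .plume_analysis import snapshot_times
    times = snapshot_times(0.0, float(sched.season_length_h), snapshots)
    snaps = [traj.snapshot(float(t)) for t in times]
    rate = intersection_rate(snaps, report.drifted, buffer_km,
                             cue="airborne", duration_days=2.0,
                             year=year, delta_years=DELTA_YEARS)
    return rate, report


# ---------------------------------------------------------------------------
# navigation / strategy-comparison scenario
# ---------------------------------------------------------------------------

@dataclass
class NavigationScenarioConfig:
    n_agents: int = 200
    flow_v_north: float = 0.2          # m/s; carries the plume across the isoline
    plume_per_day: int = 40
    plume_lifetime_days: float = 30.0
    plume_age_days: float = 35.0       # snapshot taken with a mature plume
    K_h: float = 10.0
    dt_h: float = 0.5
    start_band_km: tuple = (300.0, 600.0)
    detection_radius_km: float = 10.0
    swim_speed: float = 0.6
    time_limit_days: float = 30.0


def navigation_flow_field(cfg: NavigationScenarioConfig) -> VelocityField:
    """Steady northward flow over the corridor (single snapshot in time)."""
    lats = np.arange(-12.0, -1.0 + 1e-9, 0.25)
    lons = np.arange(-22.0, -10.0 + 1e-9, 0.25)
    shape = (1, 1, lats.size, lons.size)
    return VelocityField(lats=lats, lons=lons, depths=np.array([0.0]),
                         times_h=np.array([0.0]),
                         u=np.zeros(shape),
                         v=np.full(shape, cfg.flow_v_north))


def navigation_plume(cfg: NavigationScenarioConfig, field: VelocityField,
                     seed: int) -> PlumeSnapshot:
    """Mature plume snapshot: a northward streak rooted at the island."""
    sched = ReleaseSchedule(
        zone_center=ISLAND, layer_depths=(0.0,),
        per_layer_per_release=cfg.plume_per_day,
        lifetime_days=cfg.plume_lifetime_days, year=2004)
    t_end = cfg.plume_age_days * 24.0
    traj = advect(sched, field, DispersionParams(K_h=cfg.K_h),
                  t_start=0.0, t_end=t_end, dt_h=1.0,
                  seed=seed % (2 ** 31))
    return traj.snapshot(t_end)


def run_navigation_scenario(seed: int = 0,
                            cfg: NavigationScenarioConfig | None = None,
                            strategies=("dual", "magnetic_only", "odor_only"),
                            ) -> dict[str, ScenarioOutcome]:
    """Paired comparison of homing strategies on the standard scenario.

    All strategies share the same drifted isoline, start positions, flow
    and plume (fixed seed), so differences in success rate are attributable
    to the strategy alone.
    """
    cfg = cfg or NavigationScenarioConfig()
    series = standard_magnetic_series(curved=True)
    t_eval = T0 + DELTA_YEARS
    report = drifted_isoline(series, ISLAND, T0, DELTA_YEARS,
                             window=WINDOW, step_deg=STEP_DEG)
    flow = navigation_flow_field(cfg)
    plume = navigation_plume(cfg, flow, seed=seed * 31 + 7)
    outcomes = {}
    for strategy in strategies:
        params = AgentParams(
            swim_speed=cfg.swim_speed, strategy=strategy,
            target_level=report.level,
            detection_radius_km=cfg.detection_radius_km,
            time_limit_days=cfg.time_limit_days)
        outcomes[strategy] = run_scenario(
            cfg.n_agents, series, flow, plume, params, seed=seed,
            t_eval=t_eval, island=ISLAND, start_isoline=report.drifted,
            dt_h=cfg.dt_h)
    return outcomes
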