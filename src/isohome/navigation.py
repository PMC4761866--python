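"""Agent-based simulation of isoline-following, plume-following and search.

The hypothesized island-finding strategy is sequential: swim along the
remembered intensity isoline toward the island's longitude; on first odor
contact, switch to localizing the source, either by heading up-flow through
the plume or, when the plume is lost, by an expanding-spiral search.  The
module also simulates the single-cue controls (magnetic-only, odor-only) so
the strategies can be compared on paired scenarios.

Agents are not advected by the current by default: the simulation isolates
the strategy logic from drift.  All quantitative agent parameters (swim
speed, detection radius, gains) are modelling choices exposed in
:class:`AgentParams`, not measured animal values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _geodesy, geomag
from ._geodesy import KM_PER_DEG
from .errors import ValidationError
from .isoline import IsolinePolyline
from .particle_tracking import PlumeSnapshot

MODE_ISOLINE = 0
MODE_PLUME = 1
MODE_SEARCH = 2
MODE_ARRIVED = 3
MODE_FAILED = 4
MODE_NAMES = {0: "isoline_phase", 1: "plume_phase", 2: "search_phase",
              3: "arrived", 4: "failed"}

STRATEGIES = ("magnetic_only", "odor_only", "dual")


@dataclass
class AgentParams:
    """Tunable parameters of a virtual navigating agent."""

    swim_speed: float = 0.6            # m/s, sustained cruising speed
    strategy: str = "dual"
    target_level: float = 0.0          # nT, intensity memorized at last visit
    detection_radius_km: float = 10.0  # odor detected within this range of a particle
    crosstrack_gain: float = 1.0
    search: str = "expanding_spiral"   # or "none"
    time_limit_days: float = 30.0
    island_radius_km: float = 2.5      # Ascension is ~5 km across
    plume_loss_lapse_h: float = 6.0
    grad_step_km: float = 5.0          # finite-difference step for grad F
    travel_bearing_deg: float = 90.0   # preferred along-isoline direction (east)
    grad_floor_nT_per_km: float = 1e-4

    def __post_init__(self):
        if self.swim_speed <= 0:
            raise ValidationError("swim_speed must be > 0")
        if self.island_radius_km <= 0:
            raise ValidationError("island_radius_km must be > 0")
        if self.strategy not in STRATEGIES:
            raise ValidationError(f"strategy must be one of {STRATEGIES}")


@dataclass
class AgentState:
    """Mutable per-agent state (scalar view used by the step functions)."""

    pos: geomag.GeoPosition
    mode: int = MODE_ISOLINE
    heading_deg: float = 90.0
    elapsed_h: float = 0.0
    last_contact_h: float = -np.inf
    spiral_center: tuple | None = None
    spiral_phi: float = 0.0
    track: list = field(default_factory=list)


@dataclass
class ScenarioOutcome:
    """Aggregate result of one strategy over ``n_agents`` paired agents."""

    strategy: str
    n_agents: int
    n_arrived: int
    success_rate: float
    median_arrival_days: float | None
    arrival_days: np.ndarray
    final_modes: np.ndarray

    def to_dict(self) -> dict:
        return {"strategy": self.strategy, "n_agents": self.n_agents,
                "n_arrived": self.n_arrived, "success_rate": self.success_rate,
                "median_arrival_days": self.median_arrival_days}


# ---------------------------------------------------------------------------
# field sampling helpers
# ---------------------------------------------------------------------------

def field_and_gradient(coeffs: geomag.GaussCoefficientSet, lat, lon,
                       step_km: float = 5.0):
    """F (nT) and its horizontal gradient (nT/km, north & east components)
    by central finite differences; vectorized over agent positions."""
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    dlat = step_km / KM_PER_DEG
    dlon = step_km / (KM_PER_DEG * np.cos(np.radians(lat)))
    F = geomag.total_intensity(coeffs, lat, lon)
    gn = (geomag.total_intensity(coeffs, lat + dlat, lon)
          - geomag.total_intensity(coeffs, lat - dlat, lon)) / (2 * step_km)
    ge = (geomag.total_intensity(coeffs, lat, lon + dlon)
          - geomag.total_intensity(coeffs, lat, lon - dlon)) / (2 * step_km)
    return F, gn, ge


def isoline_heading(F, gn, ge, heading_deg, params: AgentParams):
    """Heading (deg) for the isoline-following phase, vectorized.

    The base direction is the isoline tangent (perpendicular to grad F)
    signed toward the preferred travel bearing; a cross-track correction
    proportional to the intensity error steers the agent back onto the
    target isoline.  Where the gradient is below the plateau floor the
    previous heading is held.
    """
    gmag = np.hypot(gn, ge)
    plateau = gmag < params.grad_floor_nT_per_km
    g = np.where(plateau, 1.0, gmag)
    ghat_n, ghat_e = gn / g, ge / g
    # two tangents; pick the one aligned with the preferred travel bearing
    tb = np.radians(params.travel_bearing_deg)
    pref_n, pref_e = np.cos(tb), np.sin(tb)
    t1_n, t1_e = ghat_e, -ghat_n
    sign = np.where(t1_n * pref_n + t1_e * pref_e >= 0.0, 1.0, -1.0)
    t_n, t_e = sign * t1_n, sign * t1_e
    # cross-track error in km (positive when F is above target)
    err_km = (F - params.target_level) / g
    w = np.clip(params.crosstrack_gain * err_km / 10.0, -1.0, 1.0)
    dir_n = t_n - w * ghat_n
    dir_e = t_e - w * ghat_e
    norm = np.hypot(dir_n, dir_e)
    norm = np.where(norm == 0, 1.0, norm)
    new_heading = np.degrees(np.arctan2(dir_e / norm, dir_n / norm))
    return np.where(plateau, heading_deg, new_heading)


def isoline_following_step(coeffs: geomag.GaussCoefficientSet,
                           state: AgentState, params: AgentParams,
                           dt_h: float) -> AgentState:
    """Advance one agent one time step along the isoline (scalar wrapper)."""
    F, gn, ge = field_and_gradient(coeffs, state.pos.lat, state.pos.lon,
                                   params.grad_step_km)
    h = isoline_heading(F, gn, ge, state.heading_deg, params)
    state.heading_deg = float(np.asarray(h))
    step_km = params.swim_speed * dt_h * 3.6
    la, lo = _geodesy.destination_point(state.pos.lat, state.pos.lon,
                                        np.radians(state.heading_deg), step_km)
    state.pos = geomag.GeoPosition(float(la), float(lo))
    state.elapsed_h += dt_h
    return state


def odor_detected(state_or_pos, snapshot: PlumeSnapshot,
                  detection_radius_km: float) -> bool:
    """True iff any plume particle lies within the detection radius."""
    pos = state_or_pos.pos if isinstance(state_or_pos, AgentState) else state_or_pos
    if snapshot.n_particles == 0:
        return False
    d = _geodesy.haversine_km(pos.lat, pos.lon,
                              snapshot.positions[:, 0], snapshot.positions[:, 1])
    return bool(np.min(d) <= detection_radius_km)


def plume_following_step(flow_uv, state: AgentState, params: AgentParams,
                         dt_h: float,
                         snapshot: PlumeSnapshot | None = None) -> AgentState:
    """Head up-flow (particles stream downstream from the island, so the
    source lies up-flow); with negligible flow, fall back to heading toward
    the local centroid of detected particles."""
    u, v = flow_uv
    if np.hypot(u, v) > 1e-3:
        heading = np.degrees(np.arctan2(-u, -v))
    elif snapshot is not None and snapshot.n_particles > 0:
        d = _geodesy.haversine_km(state.pos.lat, state.pos.lon,
                                  snapshot.positions[:, 0],
                                  snapshot.positions[:, 1])
        near = d <= params.detection_radius_km
        if near.any():
            cen = snapshot.positions[near].mean(axis=0)
            heading = np.degrees(_geodesy.initial_bearing_rad(
                state.pos.lat, state.pos.lon, cen[0], cen[1]))
        else:
            heading = state.heading_deg
    else:
        heading = state.heading_deg
    state.heading_deg = float(heading)
    step_km = params.swim_speed * dt_h * 3.6
    la, lo = _geodesy.destination_point(state.pos.lat, state.pos.lon,
                                        np.radians(state.heading_deg), step_km)
    state.pos = geomag.GeoPosition(float(la), float(lo))
    state.elapsed_h += dt_h
    return state


def search_step(state: AgentState, params: AgentParams,
                dt_h: float) -> AgentState:
    """Advance along an Archimedean spiral of pitch 2 x detection radius,
    centered on the point where odor contact was lost."""
    if state.spiral_center is None:
        state.spiral_center = (state.pos.lat, state.pos.lon)
        state.spiral_phi = 0.0
    pitch = 2.0 * params.detection_radius_km
    b = pitch / (2.0 * np.pi)  # km per radian
    step_km = params.swim_speed * dt_h * 3.6
    r = b * state.spiral_phi
    dphi = step_km / np.hypot(max(r, 1e-6), b)
    state.spiral_phi += dphi
    r = b * state.spiral_phi
    la, lo = _geodesy.destination_point(state.spiral_center[0],
                                        state.spiral_center[1],
                                        state.spiral_phi % (2 * np.pi), r)
    prev = state.pos
    state.pos = geomag.GeoPosition(float(la), float(lo))
    state.heading_deg = float(np.degrees(_geodesy.initial_bearing_rad(
        prev.lat, prev.lon, state.pos.lat, state.pos.lon)))
    state.elapsed_h += dt_h
    return state


def spiral_arc_length_km(phi: float, pitch_km: float) -> float:
    """Analytic arc length of the Archimedean spiral r = (pitch/2pi) * phi."""
    b = pitch_km / (2.0 * np.pi)
    return 0.5 * b * (phi * np.sqrt(1 + phi ** 2) + np.arcsinh(phi))


# ---------------------------------------------------------------------------
# scenario driver
# ---------------------------------------------------------------------------

def place_agents_on_isoline(isoline_polyline: IsolinePolyline,
                            island: geomag.GeoPosition, n_agents: int,
                            band_km=(300.0, 600.0)) -> np.ndarray:
    """Start positions: ``n_agents`` points spaced along the isoline within
    a distance band west of the island (the Brazil-side approach)."""
    verts = isoline_polyline.all_vertices()
    d = _geodesy.haversine_km(verts[:, 0], verts[:, 1], island.lat, island.lon)
    west = verts[:, 1] < island.lon
    sel = verts[(d >= band_km[0]) & (d <= band_km[1]) & west]
    if sel.shape[0] < 2:
        raise ValidationError("isoline has too few vertices in the start band")
    idx = np.linspace(0, sel.shape[0] - 1, n_agents).round().astype(int)
    return sel[idx]


def run_scenario(n_agents: int, series: geomag.GaussCoefficientSeries,
                 flow_field, plume_snapshot: PlumeSnapshot,
                 params: AgentParams, seed: int, t_eval: float,
                 island: geomag.GeoPosition,
                 start_positions: np.ndarray | None = None,
                 start_isoline: IsolinePolyline | None = None,
                 dt_h: float = 0.5,
                 track_every_h: float | None = None) -> ScenarioOutcome:
    """Simulate ``n_agents`` agents under one strategy until arrival or the
    time limit.  Deterministic given the seed (used only for start-position
    jitter when explicit positions are not supplied).

    ``t_eval`` is the decimal year of the homing attempt: the magnetic field
    the agents experience is the field of that date, while ``target_level``
    in ``params`` is the intensity remembered from the previous visit.
    """
    coeffs = geomag.coefficients_at(series, t_eval)
    if start_positions is None:
        if start_isoline is None:
            raise ValidationError("need start_positions or start_isoline")
        start_positions = place_agents_on_isoline(start_isoline, island,
                                                  n_agents)
    if start_positions.shape[0] != n_agents:
        raise ValidationError("start_positions must have n_agents rows")

    lat = start_positions[:, 0].astype(float).copy()
    lon = start_positions[:, 1].astype(float).copy()
    mode = np.full(n_agents, MODE_ISOLINE, dtype=int)
    heading = np.full(n_agents, params.travel_bearing_deg, dtype=float)
    if params.strategy != "odor_only":
        # cruise along the local isoline tangent; the odor-only control has
        # no magnetic guidance, so it holds the preferred compass bearing
        F0, gn0, ge0 = field_and_gradient(coeffs, lat, lon, params.grad_step_km)
        heading[:] = isoline_heading(F0, gn0, ge0, heading, params)
    last_contact = np.full(n_agents, -np.inf)
    spiral_phi = np.full(n_agents, np.nan)  # NaN = spiral not started
    spiral_lat = np.zeros(n_agents)
    spiral_lon = np.zeros(n_agents)
    arrival_h = np.full(n_agents, np.nan)
    tracks = [] if track_every_h is not None else None

    step_km = params.swim_speed * dt_h * 3.6
    n_steps = int(round(params.time_limit_days * 24.0 / dt_h))
    pitch = 2.0 * params.detection_radius_km
    b_spiral = pitch / (2.0 * np.pi)
    plume = plume_snapshot
    has_plume = plume is not None and plume.n_particles > 0

    for step in range(n_steps):
        t = step * dt_h
        active = (mode != MODE_ARRIVED) & (mode != MODE_FAILED)
        if not active.any():
            break

        # odor detection (binary particle proximity), for dual & odor_only
        if has_plume and params.strategy in ("dual", "odor_only"):
            idx = np.flatnonzero(active & ((mode == MODE_ISOLINE)
                                           | (mode == MODE_PLUME)
                                           | (mode == MODE_SEARCH)))
            if idx.size:
                d = _geodesy.haversine_km(
                    lat[idx, None], lon[idx, None],
                    plume.positions[None, :, 0], plume.positions[None, :, 1])
                dmin = d.min(axis=1)
                contact = dmin <= params.detection_radius_km
                newly = idx[contact]
                last_contact[newly] = t
                # contact promotes isoline/search agents into the plume phase
                promote = newly[(mode[newly] == MODE_ISOLINE)
                                | (mode[newly] == MODE_SEARCH)]
                mode[promote] = MODE_PLUME
                spiral_phi[promote] = np.nan
                # plume agents that lost contact for too long start searching
                lost = idx[~contact]
                lost = lost[(mode[lost] == MODE_PLUME)
                            & (t - last_contact[lost] > params.plume_loss_lapse_h)]
                if params.search == "expanding_spiral":
                    mode[lost] = MODE_SEARCH
                    spiral_phi[lost] = np.nan

        # --- isoline phase (also the cruise mode of magnetic_only) --------
        iso = active & (mode == MODE_ISOLINE)
        if params.strategy == "odor_only":
            # no magnetic guidance: hold the initial heading
            pass
        elif iso.any():
            F, gn, ge = field_and_gradient(coeffs, lat[iso], lon[iso],
                                           params.grad_step_km)
            heading[iso] = isoline_heading(F, gn, ge, heading[iso], params)

        # --- plume phase ---------------------------------------------------
        # heading: up-flow toward the source, steadied by the centroid of
        # currently detected particles (keeps the agent on the streak
        # centerline, which converges on the island)
        plu = active & (mode == MODE_PLUME)
        if plu.any():
            u, v, _ = flow_field.sample(flow_field.times_h[0], 0.0,
                                        lat[plu], lon[plu])
            speed = np.hypot(u, v)
            dir_n = np.where(speed > 1e-3, -v / np.maximum(speed, 1e-12), 0.0)
            dir_e = np.where(speed > 1e-3, -u / np.maximum(speed, 1e-12), 0.0)
            if has_plume:
                i = np.flatnonzero(plu)
                d = _geodesy.haversine_km(
                    lat[i, None], lon[i, None],
                    plume.positions[None, :, 0], plume.positions[None, :, 1])
                near = d <= params.detection_radius_km
                for row, ai in enumerate(i):
                    if near[row].any():
                        cen = plume.positions[near[row]].mean(axis=0)
                        br = _geodesy.initial_bearing_rad(
                            lat[ai], lon[ai], cen[0], cen[1])
                        dir_n[row] += np.cos(br)
                        dir_e[row] += np.sin(br)
            norm = np.hypot(dir_n, dir_e)
            ok = norm > 1e-9
            new_h = np.degrees(np.arctan2(dir_e, dir_n))
            heading[plu] = np.where(ok, new_h, heading[plu])

        # --- search phase: expanding spiral --------------------------------
        sea = active & (mode == MODE_SEARCH)
        if sea.any():
            fresh = sea & np.isnan(spiral_phi)
            spiral_lat[fresh] = lat[fresh]
            spiral_lon[fresh] = lon[fresh]
            spiral_phi[fresh] = 0.0
            i = np.flatnonzero(sea)
            r = b_spiral * spiral_phi[i]
            dphi = step_km / np.hypot(np.maximum(r, 1e-6), b_spiral)
            spiral_phi[i] = spiral_phi[i] + dphi
            r = b_spiral * spiral_phi[i]
            la, lo = _geodesy.destination_point(
                spiral_lat[i], spiral_lon[i],
                spiral_phi[i] % (2 * np.pi), r)
            lat[i], lon[i] = la, lo

        # --- move non-searching active agents along their headings --------
        mov = active & (mode != MODE_SEARCH)
        if mov.any():
            la, lo = _geodesy.destination_point(lat[mov], lon[mov],
                                                np.radians(heading[mov]),
                                                step_km)
            lat[mov], lon[mov] = la, lo

        # --- arrival -------------------------------------------------------
        d_island = _geodesy.haversine_km(lat, lon, island.lat, island.lon)
        arrived = active & (d_island <= params.island_radius_km)
        mode[arrived] = MODE_ARRIVED
        arrival_h[arrived] = t + dt_h
        if tracks is not None and (t % track_every_h) < dt_h:
            tracks.append(np.column_stack([lat.copy(), lon.copy()]))

    mode[mode != MODE_ARRIVED] = MODE_FAILED  # time limit exhausted
    n_arrived = int((mode == MODE_ARRIVED).sum())
    arr_days = arrival_h[np.isfinite(arrival_h)] / 24.0
    outcome = ScenarioOutcome(
        strategy=params.strategy, n_agents=n_agents, n_arrived=n_arrived,
        success_rate=n_arrived / n_agents,
        median_arrival_days=float(np.median(arr_days)) if arr_days.size else None,
        arrival_days=arr_days, final_modes=mode.copy())
    if tracks is not None:
        outcome.tracks = np.stack(tracks) if tracks else None
    return outcome
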