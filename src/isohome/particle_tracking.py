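"""Lagrangian odorant-particle tracking through gridded velocity fields.

Virtual particles stand in for island-derived odorants: they are released on
a schedule from a square zone centered on the island, advected horizontally
at fixed depth layers with classical 4th-order Runge-Kutta stepping, jittered
by a Gaussian random-walk representing sub-gridscale turbulent dispersion,
and removed once their age exceeds the odorant lifetime.

Determinism contract: the whole simulation is a pure function of
(schedule, field, dispersion, seed).  Dispersion noise is drawn for every
*released* particle each step whether or not it is still alive, so particle
trajectories are identical across runs that differ only in odorant lifetime
— which makes the alive-set at any instant exactly nested across lifetimes
(the mechanism behind odorant-duration sensitivity analyses).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np

from ._geodesy import M_PER_DEG
from .errors import DomainError, ValidationError
from .geomag import GeoPosition
from .synthetic_fields import VelocityField

#: default waterborne layer depths (m) spanning turtle migration depths
DEFAULT_LAYERS_M = (0.0, 10.0, 20.0, 30.0, 50.0)


def season_window(year: int, start=(12, 15), end=(4, 29)):
    """(start datetime, length in hours) of a nesting season.

    ``start`` falls in ``year``; when the end month precedes the start month
    the window wraps into ``year + 1`` (Dec 15 – Apr 29 by default).
    Leap days are honoured by the calendar arithmetic.
    """
    t0 = _dt.datetime(year, start[0], start[1])
    end_year = year + 1 if (end[0], end[1]) < (start[0], start[1]) else year
    t1 = _dt.datetime(end_year, end[0], end[1])
    if t1 <= t0:
        raise ValidationError("season_end must fall after season_start")
    return t0, (t1 - t0).total_seconds() / 3600.0


@dataclass
class ReleaseSchedule:
    """Release protocol for odorant particles.

    Defaults are the waterborne protocol: 100 particles per layer at five
    depth layers, released daily from a 10 km x 10 km zone centered on the
    island throughout the Dec 15 – Apr 29 nesting season.
    """

    zone_center: GeoPosition
    zone_half_width_km: float = 5.0
    layer_depths: tuple = DEFAULT_LAYERS_M
    per_layer_per_release: int = 100
    release_interval_h: float = 24.0
    year: int = 2004
    season_start: tuple = (12, 15)
    season_end: tuple = (4, 29)
    lifetime_days: float = 45.0

    def __post_init__(self):
        if self.per_layer_per_release < 1:
            raise ValidationError("per_layer_per_release must be >= 1")
        if self.lifetime_days <= 0:
            raise ValidationError("lifetime must be > 0")
        if self.release_interval_h <= 0:
            raise ValidationError("release_interval_h must be > 0")
        if self.zone_half_width_km < 0:
            raise ValidationError("zone_half_width_km must be >= 0")
        # validates the calendar window
        season_window(self.year, self.season_start, self.season_end)

    @property
    def season_length_h(self) -> float:
        return season_window(self.year, self.season_start, self.season_end)[1]

    @property
    def lifetime_h(self) -> float:
        return self.lifetime_days * 24.0

    def release_times_h(self) -> np.ndarray:
        """Release instants (hours since season start), inclusive of t=0."""
        return np.arange(0.0, self.season_length_h + 1e-9,
                         self.release_interval_h)

    @classmethod
    def airborne(cls, zone_center: GeoPosition, year: int = 2009,
                 **kw) -> "ReleaseSchedule":
        """Airborne protocol: hourly releases at 0 m, 48-h lifetime."""
        kw.setdefault("layer_depths", (0.0,))
        kw.setdefault("per_layer_per_release", 1)
        kw.setdefault("release_interval_h", 1.0)
        kw.setdefault("lifetime_days", 2.0)
        return cls(zone_center=zone_center, year=year, **kw)


@dataclass
class DispersionParams:
    """Gaussian random-walk horizontal dispersion (diffusivity K_h, m^2/s)."""

    K_h: float = 10.0
    enabled: bool = True

    def __post_init__(self):
        if self.K_h < 0:
            raise ValidationError("K_h must be >= 0")


@dataclass
class Particle:
    """A single particle's bookkeeping view (mostly for inspection/tests)."""

    id: int
    release_time: float
    layer_depth: float
    pos: GeoPosition
    age: float
    alive: bool


@dataclass
class PlumeSnapshot:
    """Positions of all living odorant particles at one instant, with all
    depth layers pooled into a single 2-D point set."""

    time_h: float
    positions: np.ndarray  # (n, 2) of (lat, lon)
    n_particles: int = field(default=None)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 2)
        if self.n_particles is None:
            self.n_particles = self.positions.shape[0]
        if self.n_particles != self.positions.shape[0]:
            raise ValidationError("n_particles must equal |positions|")

    def to_geojson(self) -> dict:
        return {"type": "Feature",
                "geometry": {"type": "MultiPoint",
                             "coordinates": [[float(lon), float(lat)]
                                             for lat, lon in self.positions]},
                "properties": {"time_h": float(self.time_h),
                               "n_particles": int(self.n_particles)}}


def release_particles(schedule: ReleaseSchedule, t_h: float,
                      rng: np.random.Generator) -> list[Particle]:
    """Particles released at instant ``t_h`` (empty outside the season).

    Positions are uniform over the square zone; the km offsets are converted
    to degrees at the zone latitude.
    """
    if t_h < 0 or t_h > schedule.season_length_h:
        return []
    lat, lon = _release_positions(schedule, rng)
    out = []
    i = 0
    for d in schedule.layer_depths:
        for k in range(schedule.per_layer_per_release):
            out.append(Particle(id=i, release_time=t_h, layer_depth=d,
                                pos=GeoPosition(lat[i], lon[i]), age=0.0,
                                alive=True))
            i += 1
    return out


def _release_positions(schedule: ReleaseSchedule, rng: np.random.Generator):
    n = schedule.per_layer_per_release * len(schedule.layer_depths)
    hw = schedule.zone_half_width_km
    off = rng.uniform(-hw, hw, size=(n, 2))  # km (north, east)
    c = schedule.zone_center
    lat = c.lat + off[:, 0] / (M_PER_DEG / 1000.0)
    lon = c.lon + off[:, 1] / (M_PER_DEG / 1000.0 * np.cos(np.radians(c.lat)))
    return lat, lon


def _deg_rates(u, v, lat):
    """(dlat/dt, dlon/dt) in degrees/hour from m/s velocities."""
    dlat = v * 3600.0 / M_PER_DEG
    dlon = u * 3600.0 / (M_PER_DEG * np.cos(np.radians(lat)))
    return dlat, dlon


def _rk4(field: VelocityField, lat, lon, depth_m, t_h, dt_h):
    """Vectorized classical RK4 step; returns (lat, lon, ok) where ``ok``
    is False for particles whose stages sampled outside the domain."""
    ok = np.ones(np.shape(lat), dtype=bool)

    def rate(la, lo, t):
        u, v, inside = field.sample(t, depth_m, la, lo)
        nonlocal ok
        ok &= inside
        return _deg_rates(u, v, la)

    k1la, k1lo = rate(lat, lon, t_h)
    k2la, k2lo = rate(lat + 0.5 * dt_h * k1la, lon + 0.5 * dt_h * k1lo,
                      t_h + 0.5 * dt_h)
    k3la, k3lo = rate(lat + 0.5 * dt_h * k2la, lon + 0.5 * dt_h * k2lo,
                      t_h + 0.5 * dt_h)
    k4la, k4lo = rate(lat + dt_h * k3la, lon + dt_h * k3lo, t_h + dt_h)
    new_lat = lat + dt_h / 6.0 * (k1la + 2 * k2la + 2 * k3la + k4la)
    new_lon = lon + dt_h / 6.0 * (k1lo + 2 * k2lo + 2 * k3lo + k4lo)
    return new_lat, new_lon, ok


def rk4_step(field: VelocityField, pos: GeoPosition, t_h: float,
             dt_h: float) -> GeoPosition:
    """Single-particle RK4 step (position frozen if any stage leaves the
    domain).  Exact for velocity fields constant in space and time."""
    la, lo, ok = _rk4(field, np.array([pos.lat]), np.array([pos.lon]),
                      pos.depth_m, t_h, dt_h)
    if not ok[0]:
        return pos
    return GeoPosition(float(la[0]), float(lo[0]), pos.depth_m)


def apply_dispersion(pos: GeoPosition, params: DispersionParams, dt_h: float,
                     rng: np.random.Generator) -> GeoPosition:
    """Gaussian random-walk displacement, sd = sqrt(2 K_h dt) per axis."""
    if not params.enabled or params.K_h == 0.0:
        return pos
    sd_m = np.sqrt(2.0 * params.K_h * dt_h * 3600.0)
    dn, de = rng.normal(0.0, sd_m, 2)
    lat = pos.lat + dn / M_PER_DEG
    lon = pos.lon + de / (M_PER_DEG * np.cos(np.radians(pos.lat)))
    return GeoPosition(lat, lon, pos.depth_m)


@dataclass
class TrajectorySet:
    """Recorded particle histories from :func:`advect`.

    Positions are stored at the recorded instants for *all* particles (NaN
    before release); aliveness at any time is reconstructed from release
    time, lifetime, and exit time, so the same run answers queries for any
    odorant lifetime up to the simulated one.
    """

    times_h: np.ndarray            # recorded instants, strictly increasing
    lat: np.ndarray                # (n_rec, n_particles) float32
    lon: np.ndarray
    release_time: np.ndarray       # (n_particles,)
    layer_depth: np.ndarray
    exit_time: np.ndarray          # inf when the particle never left
    lifetime_h: float
    dt_h: float
    rng_seed: int

    @property
    def n_particles(self) -> int:
        return self.release_time.size

    def _rec_index(self, t_h: float) -> int:
        t0, t1 = self.times_h[0], self.times_h[-1]
        if t_h < t0 - 1e-9 or t_h > t1 + 1e-9:
            raise DomainError(f"t={t_h} h outside simulated span [{t0}, {t1}]")
        return int(np.argmin(np.abs(self.times_h - t_h)))

    def alive_mask(self, t_h: float, lifetime_h: float | None = None) -> np.ndarray:
        """Particles alive at ``t_h`` (age <= lifetime, not exited).

        ``lifetime_h`` may be shortened relative to the simulated lifetime;
        trajectories are lifetime-independent by construction, so the mask
        for a shorter lifetime is exactly the nested subset.
        """
        life = self.lifetime_h if lifetime_h is None else lifetime_h
        if life > self.lifetime_h + 1e-9:
            raise ValidationError("lifetime exceeds the simulated lifetime")
        age = t_h - self.release_time
        return (age >= 0) & (age <= life) & (self.exit_time > t_h)

    def snapshot(self, t_h: float,
                 lifetime_h: float | None = None) -> PlumeSnapshot:
        """Living-particle positions at ``t_h``, pooled across depth layers."""
        i = self._rec_index(t_h)
        t_rec = float(self.times_h[i])
        mask = self.alive_mask(t_rec, lifetime_h)
        pos = np.column_stack([self.lat[i, mask], self.lon[i, mask]]).astype(float)
        return PlumeSnapshot(time_h=t_rec, positions=pos)

    def counts(self, t_h: float) -> dict:
        """Conservation bookkeeping at ``t_h``."""
        i = self._rec_index(t_h)
        t = float(self.times_h[i])
        released = self.release_time <= t
        exited = released & (self.exit_time <= t)
        expired = released & ~exited & (t - self.release_time > self.lifetime_h)
        alive = released & ~exited & ~expired
        return {"released": int(released.sum()), "alive": int(alive.sum()),
                "expired": int(expired.sum()), "exited": int(exited.sum())}

    def to_csv(self, path, stride: int = 1) -> None:
        """Long-form CSV (id, time_h, lat, lon, depth, age_h, status)."""
        with open(path, "w") as fh:
            fh.write("id,time_h,lat,lon,depth_m,age_h,status\n")
            for i in range(0, self.times_h.size, stride):
                t = float(self.times_h[i])
                released = np.flatnonzero(self.release_time <= t)
                for p in released:
                    age = t - self.release_time[p]
                    if self.exit_time[p] <= t:
                        status = "exited"
                    elif age > self.lifetime_h:
                        status = "expired"
                    else:
                        status = "alive"
                    fh.write(f"{p},{t:.2f},{self.lat[i, p]:.5f},"
                             f"{self.lon[i, p]:.5f},{self.layer_depth[p]:g},"
                             f"{age:.2f},{status}\n")


def advect(schedule: ReleaseSchedule, velocity_field: VelocityField,
           dispersion: DispersionParams | None = None,
           t_start: float = 0.0, t_end: float | None = None,
           dt_h: float = 1.0, seed: int = 0,
           record_interval_h: float = 24.0) -> TrajectorySet:
    """Run the full release/advect/disperse/expire simulation.

    Time is in hours since the season start.  ``t_end`` defaults to the end
    of the season plus one odorant lifetime.  Positions are recorded every
    ``record_interval_h`` (and at ``t_end``).
    """
    if dt_h <= 0:
        raise ValidationError("dt_h must be > 0")
    dispersion = dispersion or DispersionParams(enabled=False, K_h=0.0)
    c = schedule.zone_center
    fld = velocity_field
    if not (fld.lats[0] <= c.lat <= fld.lats[-1]
            and fld.lons[0] <= c.lon <= fld.lons[-1]):
        raise ValidationError("release zone lies outside the velocity field")
    if t_end is None:
        t_end = schedule.season_length_h + schedule.lifetime_h
    if t_end <= t_start:
        raise ValidationError("t_end must exceed t_start")

    release_times = schedule.release_times_h()
    release_times = release_times[(release_times >= t_start)
                                  & (release_times <= t_end)]
    n_layers = len(schedule.layer_depths)
    per_release = schedule.per_layer_per_release * n_layers
    n_total = per_release * release_times.size

    lat = np.full(n_total, np.nan)
    lon = np.full(n_total, np.nan)
    release_time = np.repeat(release_times, per_release)
    layer_depth = np.tile(np.repeat(np.asarray(schedule.layer_depths, float),
                                    schedule.per_layer_per_release),
                          release_times.size)
    exit_time = np.full(n_total, np.inf)

    ss = np.random.SeedSequence(seed)
    rng_release, rng_disp = (np.random.default_rng(s) for s in ss.spawn(2))

    n_steps = int(np.ceil((t_end - t_start) / dt_h - 1e-9))
    rec_times = []
    rec_lat, rec_lon = [], []
    next_release = 0
    next_record = t_start
    sd_base = np.sqrt(2.0 * dispersion.K_h * dt_h * 3600.0) \
        if dispersion.enabled else 0.0

    t = t_start
    for step in range(n_steps + 1):
        # releases due at this instant
        while (next_release < release_times.size
               and release_times[next_release] <= t + 1e-9):
            sl = slice(next_release * per_release,
                       (next_release + 1) * per_release)
            la, lo = _release_positions(schedule, rng_release)
            lat[sl], lon[sl] = la, lo
            next_release += 1
        # record
        if t >= next_record - 1e-9 or step == n_steps:
            rec_times.append(t)
            rec_lat.append(lat.astype(np.float32).copy())
            rec_lon.append(lon.astype(np.float32).copy())
            while next_record <= t + 1e-9:
                next_record += record_interval_h
        if step == n_steps:
            break

        released = release_time <= t + 1e-9
        age = t - release_time
        active = released & (exit_time == np.inf) \
            & (age <= schedule.lifetime_h + 1e-9)
        # advect per depth layer
        for d in np.unique(layer_depth[active]):
            sel = active & (layer_depth == d)
            if not sel.any():
                continue
            la, lo, ok = _rk4(fld, lat[sel], lon[sel], float(d), t, dt_h)
            idx = np.flatnonzero(sel)
            moved = idx[ok]
            lat[moved] = la[ok]
            lon[moved] = lo[ok]
            exit_time[idx[~ok]] = t
        # dispersion: draw for every released particle (lifetime-independent
        # stream), apply to the still-active ones only
        if sd_base > 0.0:
            n_rel = int(released.sum())  # released block is a prefix
            noise = rng_disp.standard_normal((n_rel, 2)) * sd_base
            act = active[:n_rel] & (exit_time[:n_rel] == np.inf)
            lat[:n_rel][act] += noise[act, 0] / M_PER_DEG
            lon[:n_rel][act] += noise[act, 1] / (
                M_PER_DEG * np.cos(np.radians(lat[:n_rel][act])))
        t = t_start + (step + 1) * dt_h

    return TrajectorySet(times_h=np.asarray(rec_times),
                         lat=np.vstack(rec_lat), lon=np.vstack(rec_lon),
                         release_time=release_time, layer_depth=layer_depth,
                         exit_time=exit_time, lifetime_h=schedule.lifetime_h,
                         dt_h=dt_h, rng_seed=seed)


def snapshot(trajectories: TrajectorySet, t_h: float,
             lifetime_h: float | None = None) -> PlumeSnapshot:
    """Module-level convenience wrapper around :meth:`TrajectorySet.snapshot`."""
    return trajectories.snapshot(t_h, lifetime_h)
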