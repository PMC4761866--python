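"""Synthetic ocean, wind, and magnetic-field generators with known ground truth.

Real analyses of island-finding cues run on data-assimilative hindcasts
(mesoscale ocean state, reanalysis winds) and on the IGRF.  Those inputs are
multi-gigabyte external products, so this module provides controllable
stand-ins that reproduce the features the downstream stages depend on:

* a divergence-free mesoscale ocean flow (mean current + Gaussian eddies via
  a streamfunction) on an ~0.08° grid around Ascension Island;
* steady trade winds toward the WNW with optional temporally-correlated
  gusts;
* a main-field coefficient series whose intensity pattern translates at a
  configured speed, giving an exact ground truth for isoline-drift recovery.

All generators are pure functions of (params, seed): reruns are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import xarray as xr

from ._geodesy import EARTH_RADIUS_KM, M_PER_DEG
from .errors import DomainError, ValidationError
from .geomag import GaussCoefficientSeries, GaussCoefficientSet

#: ~900 x 900 km box around Ascension Island (7.933 S, 14.367 W)
DEFAULT_DOMAIN = ((-12.0, -4.0), (-19.0, -10.0))
DEFAULT_GRID_STEP_DEG = 0.08
DEFAULT_DEPTHS_M = (0.0, 10.0, 20.0, 30.0, 50.0)


@dataclass
class VelocityField:
    """Gridded horizontal velocities u (east) / v (north) in m/s.

    Arrays have shape (time, depth, lat, lon).  Sampling contract: bilinear
    in space, linear in time (or piecewise-constant when
    ``time_mode='previous'``, emulating daily-frozen snapshots), nearest in
    depth.  Queries outside the horizontal hull are flagged, never
    extrapolated.
    """

    lats: np.ndarray
    lons: np.ndarray
    depths: np.ndarray
    times_h: np.ndarray
    u: np.ndarray
    v: np.ndarray
    time_mode: str = "linear"  # or "previous"

    def __post_init__(self):
        self.lats = np.asarray(self.lats, dtype=float)
        self.lons = np.asarray(self.lons, dtype=float)
        self.depths = np.asarray(self.depths, dtype=float)
        self.times_h = np.atleast_1d(np.asarray(self.times_h, dtype=float))
        expected = (self.times_h.size, self.depths.size,
                    self.lats.size, self.lons.size)
        for name in ("u", "v"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != expected:
                raise ValidationError(
                    f"{name} shape {arr.shape} != (time, depth, lat, lon) {expected}")
            if not np.isfinite(arr).all():
                raise ValidationError(f"{name} contains non-finite values")
            setattr(self, name, arr)
        if self.time_mode not in ("linear", "previous"):
            raise ValidationError("time_mode must be 'linear' or 'previous'")

    # -- sampling ----------------------------------------------------------

    def _time_weights(self, t_h: float):
        times = self.times_h
        if times.size == 1:
            return (0, 0, 0.0)
        if t_h < times[0] - 1e-9 or t_h > times[-1] + 1e-9:
            raise DomainError(f"t={t_h} h outside field time span "
                              f"[{times[0]}, {times[-1]}]")
        t_h = min(max(t_h, times[0]), times[-1])
        i = int(np.searchsorted(times, t_h, side="right") - 1)
        i = min(i, times.size - 2)
        if self.time_mode == "previous":
            return (i, i, 0.0)
        w = (t_h - times[i]) / (times[i + 1] - times[i])
        return (i, i + 1, float(w))

    def _depth_index(self, depth_m: float) -> int:
        return int(np.argmin(np.abs(self.depths - depth_m)))

    def sample(self, t_h: float, depth_m: float, lats, lons):
        """Sample (u, v) at points; returns (u, v, inside) arrays.

        Outside-the-hull points get u = v = 0 and inside=False.
        """
        lats = np.asarray(lats, dtype=float)
        lons = np.asarray(lons, dtype=float)
        i0, i1, wt = self._time_weights(t_h)
        k = self._depth_index(depth_m)
        inside = ((lats >= self.lats[0]) & (lats <= self.lats[-1])
                  & (lons >= self.lons[0]) & (lons <= self.lons[-1]))
        la = np.clip(lats, self.lats[0], self.lats[-1])
        lo = np.clip(lons, self.lons[0], self.lons[-1])
        fi = np.interp(la, self.lats, np.arange(self.lats.size))
        fj = np.interp(lo, self.lons, np.arange(self.lons.size))
        i = np.clip(fi.astype(int), 0, self.lats.size - 2)
        j = np.clip(fj.astype(int), 0, self.lons.size - 2)
        di = fi - i
        dj = fj - j

        def bilin(a):
            return ((1 - di) * (1 - dj) * a[i, j] + (1 - di) * dj * a[i, j + 1]
                    + di * (1 - dj) * a[i + 1, j] + di * dj * a[i + 1, j + 1])

        u = (1 - wt) * bilin(self.u[i0, k]) + wt * bilin(self.u[i1, k])
        v = (1 - wt) * bilin(self.v[i0, k]) + wt * bilin(self.v[i1, k])
        u = np.where(inside, u, 0.0)
        v = np.where(inside, v, 0.0)
        return u, v, inside

    # -- NetCDF round-trip (HYCOM-dialect variable names) ------------------

    def to_netcdf(self, path) -> None:
        ds = xr.Dataset(
            {"water_u": (("time", "depth", "lat", "lon"), self.u),
             "water_v": (("time", "depth", "lat", "lon"), self.v)},
            coords={"time": self.times_h, "depth": self.depths,
                    "lat": self.lats, "lon": self.lons},
            attrs={"time_units": "hours since run start",
                   "time_mode": self.time_mode})
        ds.to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path) -> "VelocityField":
        with xr.open_dataset(path, engine="scipy") as ds:
            return cls(lats=ds["lat"].values, lons=ds["lon"].values,
                       depths=ds["depth"].values, times_h=ds["time"].values,
                       u=ds["water_u"].values, v=ds["water_v"].values,
                       time_mode=str(ds.attrs.get("time_mode", "linear")))


@dataclass
class EddyFieldParams:
    """Parameters of the streamfunction-based mesoscale ocean generator."""

    mean_u: float = -0.15       # m/s; South Equatorial Current flows westward
    mean_v: float = 0.0
    n_eddies: int = 12
    eddy_amp: float = 2.0e4     # m^2/s streamfunction amplitude (~0.25 m/s swirl)
    eddy_radius_km: float = 80.0
    eddy_drift: float = 0.0     # m/s, westward translation of eddy centers
    domain: tuple = DEFAULT_DOMAIN
    grid_step_deg: float = DEFAULT_GRID_STEP_DEG
    depths: tuple = DEFAULT_DEPTHS_M
    times_h: tuple = (0.0,)
    seed: int = 0

    def __post_init__(self):
        if self.eddy_radius_km <= 0:
            raise ValidationError("eddy_radius_km must be > 0")
        if self.n_eddies < 0:
            raise ValidationError("n_eddies must be >= 0")


def _local_xy(lats, lons, domain):
    """Local Cartesian meters (equirectangular about the domain center)."""
    (lat0, lat1), (lon0, lon1) = domain
    latc = 0.5 * (lat0 + lat1)
    x = (np.asarray(lons) - lon0) * M_PER_DEG * np.cos(np.radians(latc))
    y = (np.asarray(lats) - lat0) * M_PER_DEG
    return x, y


def synth_ocean_field(params: EddyFieldParams) -> VelocityField:
    """Divergence-free mesoscale flow: mean current plus Gaussian eddies.

    The velocity derives from a streamfunction, so passive tracers neither
    concentrate nor evacuate (mirroring the large-scale incompressibility of
    assimilative ocean-model surface flow).  Each depth layer receives
    independently seeded eddy phases over a shared mean flow, emulating
    vertical shear.
    """
    (lat0, lat1), (lon0, lon1) = params.domain
    if lat0 >= lat1 or lon0 >= lon1:
        raise ValidationError("degenerate domain")
    lats = np.arange(lat0, lat1 + 1e-9, params.grid_step_deg)
    lons = np.arange(lon0, lon1 + 1e-9, params.grid_step_deg)
    xg, yg = _local_xy(lats, lons, params.domain)
    width_m = xg[-1] - xg[0]
    height_m = yg[-1] - yg[0]
    R = params.eddy_radius_km * 1000.0
    if params.n_eddies > 0 and min(width_m, height_m) < R:
        raise ValidationError("domain smaller than one eddy radius")

    times = np.atleast_1d(np.asarray(params.times_h, dtype=float))
    depths = np.asarray(params.depths, dtype=float)
    X, Y = np.meshgrid(xg, yg, indexing="xy")  # shape (nlat, nlon) after swap
    X = np.tile(xg, (lats.size, 1))
    Y = np.tile(yg[:, None], (1, lons.size))

    rng = np.random.default_rng(params.seed)
    u = np.zeros((times.size, depths.size, lats.size, lons.size))
    v = np.zeros_like(u)
    for d in range(depths.size):
        # independent eddy population per layer, shared mean flow
        cx = rng.uniform(0, width_m, params.n_eddies)
        cy = rng.uniform(0, height_m, params.n_eddies)
        amp = rng.choice([-1.0, 1.0], params.n_eddies) * params.eddy_amp
        for ti, t in enumerate(times):
            cxt = cx - params.eddy_drift * t * 3600.0  # westward drift
            dx = X[None] - cxt[:, None, None]
            dy = Y[None] - cy[:, None, None]
            gauss = np.exp(-(dx ** 2 + dy ** 2) / (2 * R ** 2))
            # psi = -mean_u*y + mean_v*x + sum A*gauss
            u[ti, d] = params.mean_u + np.sum(
                amp[:, None, None] * gauss * dy / R ** 2, axis=0)
            v[ti, d] = params.mean_v - np.sum(
                amp[:, None, None] * gauss * dx / R ** 2, axis=0)
    return VelocityField(lats=lats, lons=lons, depths=depths, times_h=times,
                         u=u, v=v)


def synth_wind_field(mean_speed: float, toward_bearing: float = 292.5,
                     gust_sd: float = 0.0, seed: int = 0,
                     domain=DEFAULT_DOMAIN, grid_step_deg: float = 0.25,
                     times_h=(0.0,), gust_corr_h: float = 6.0) -> VelocityField:
    """Steady wind toward ``toward_bearing`` (default WNW, 292.5°) plus
    temporally correlated, spatially uniform AR(1) gusts of sd ``gust_sd``."""
    if mean_speed < 0:
        raise ValidationError("mean_speed must be >= 0")
    (lat0, lat1), (lon0, lon1) = domain
    lats = np.arange(lat0, lat1 + 1e-9, grid_step_deg)
    lons = np.arange(lon0, lon1 + 1e-9, grid_step_deg)
    times = np.atleast_1d(np.asarray(times_h, dtype=float))
    b = np.radians(toward_bearing)
    u_mean = mean_speed * np.sin(b)
    v_mean = mean_speed * np.cos(b)
    gu = np.zeros(times.size)
    gv = np.zeros(times.size)
    if gust_sd > 0 and times.size > 1:
        rng = np.random.default_rng(seed)
        dt = float(np.median(np.diff(times)))
        rho = float(np.exp(-dt / gust_corr_h))
        innov = np.sqrt(1 - rho ** 2) * gust_sd
        gu[0], gv[0] = rng.normal(0, gust_sd, 2)
        for i in range(1, times.size):
            gu[i] = rho * gu[i - 1] + rng.normal(0, innov)
            gv[i] = rho * gv[i - 1] + rng.normal(0, innov)
    shape = (times.size, 1, lats.size, lons.size)
    u = np.broadcast_to((u_mean + gu)[:, None, None, None], shape).copy()
    v = np.broadcast_to((v_mean + gv)[:, None, None, None], shape).copy()
    return VelocityField(lats=lats, lons=lons, depths=np.array([0.0]),
                         times_h=times, u=u, v=v)


@dataclass
class SyntheticMagneticParams:
    """Controllable main-field series with a rigidly translating pattern.

    The meridional component of the translation is realized by tilting the
    dipole axis (an exact rigid rotation of the pattern, hence an exact
    ground truth for drift near the reference meridian); the zonal component
    rotates all tesseral terms in longitude.  Static anomaly terms of degree
    <= 3 may be superposed to shape the isolines.
    """

    base_dipole_nT: float = -31000.0
    translation_km_per_yr: float = 0.0
    translation_bearing_deg: float = 0.0      # 0 = pattern moves north
    reference_lon: float = -14.5              # meridian where drift is exact
    anomalies: dict = field(default_factory=dict)  # {(key,n,m): nT}, key 'g'|'h'
    epoch_start: float = 2000.0
    epoch_end: float = 2030.0
    epoch_spacing: float = 5.0

    def __post_init__(self):
        if self.epoch_spacing <= 0:
            raise ValidationError("epoch_spacing must be > 0")
        if self.epoch_end < self.epoch_start:
            raise ValidationError("epoch_end must be >= epoch_start")
        for (key, n, m) in self.anomalies:
            if key not in ("g", "h") or not (1 <= n <= 3) or not (0 <= m <= n):
                raise ValidationError(f"bad anomaly term {(key, n, m)}")


#: guard against pattern aliasing between epochs
_MAX_SHIFT_PER_EPOCH_KM = 500.0


def synth_magnetic_series(params: SyntheticMagneticParams) -> GaussCoefficientSeries:
    """Coefficient series whose intensity pattern translates at the
    configured velocity (exact for the meridional component at the reference
    meridian).  Ground truth is recorded in ``series.metadata``."""
    shift_per_epoch = abs(params.translation_km_per_yr) * params.epoch_spacing
    if shift_per_epoch > _MAX_SHIFT_PER_EPOCH_KM:
        raise ValidationError(
            f"translation of {shift_per_epoch:.0f} km per epoch interval "
            f"exceeds {_MAX_SHIFT_PER_EPOCH_KM:.0f} km (pattern aliasing)")
    epochs = np.arange(params.epoch_start, params.epoch_end + 1e-9,
                       params.epoch_spacing)
    b = np.radians(params.translation_bearing_deg)
    v_north = params.translation_km_per_yr * np.cos(b)
    v_east = params.translation_km_per_yr * np.sin(b)
    nmax = 3 if params.anomalies else 1
    latc_for_zonal = -8.0  # domain latitude used to convert east km -> deg

    sets = []
    for t in epochs:
        yrs = t - params.epoch_start
        g = np.zeros((nmax + 1, nmax + 1))
        h = np.zeros((nmax + 1, nmax + 1))
        # meridional translation: tilt the dipole axis.  Tilting the boreal
        # pole toward longitude phi_t moves the intensity pattern southward
        # on that meridian, so a northward pattern shift tilts the pole away
        # from the reference meridian.
        alpha = (v_north * yrs) / EARTH_RADIUS_KM  # radians
        phi_t = np.radians(params.reference_lon + 180.0)
        g[1, 0] = params.base_dipole_nT * np.cos(alpha)
        g[1, 1] = params.base_dipole_nT * np.sin(alpha) * np.cos(phi_t)
        h[1, 1] = params.base_dipole_nT * np.sin(alpha) * np.sin(phi_t)
        for (key, n, m), val in params.anomalies.items():
            (g if key == "g" else h)[n, m] += val
        # zonal translation: rotate tesseral terms in longitude
        if v_east != 0.0:
            dphi = np.radians((v_east * yrs)
                              / (EARTH_RADIUS_KM * np.cos(np.radians(latc_for_zonal)))
                              * 180.0 / np.pi)
            for n in range(1, nmax + 1):
                for m in range(1, n + 1):
                    c, s = np.cos(m * dphi), np.sin(m * dphi)
                    g[n, m], h[n, m] = (g[n, m] * c - h[n, m] * s,
                                        g[n, m] * s + h[n, m] * c)
        sets.append(GaussCoefficientSet(float(t), g, h))
    meta = {"translation_km_per_yr": params.translation_km_per_yr,
            "translation_bearing_deg": params.translation_bearing_deg,
            "reference_lon": params.reference_lon}
    return GaussCoefficientSeries(sets, metadata=meta)
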