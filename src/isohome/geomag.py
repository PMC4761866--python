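"""Main geomagnetic field evaluation from epoch-tabulated Gauss coefficients.

The internal (core) field is represented by the usual spherical-harmonic
potential

    V(r, theta, phi) = a * sum_{n=1}^{N} (a/r)^{n+1}
                        sum_{m=0}^{n} (g_n^m cos(m phi) + h_n^m sin(m phi))
                        * P_n^m(cos theta)

with Schmidt quasi-normalized associated Legendre functions ``P_n^m`` and
geocentric colatitude ``theta``.  Coefficients g/h are in nT, tabulated at a
series of epochs (decimal years) and interpolated linearly in time, which is
the convention of the International Geomagnetic Reference Field (IGRF).

Evaluation is carried out on the reference sphere r = a = 6371.2 km
(geocentric convention; no geodetic correction — the ~0.2% ellipticity
effect is irrelevant at the precision of isoline-drift analyses).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import DomainError, ParseError, ValidationError

REFERENCE_RADIUS_KM = 6371.2

#: Maximum |latitude| used internally; avoids the 1/sin(theta) pole singularity.
_LAT_CLIP = 89.9999


@dataclass(frozen=True)
class GeoPosition:
    """Geographic position: latitude °N in [-90, 90], longitude °E in (-180, 180]."""

    lat: float
    lon: float
    depth_m: float = 0.0

    def __post_init__(self):
        if not -90.0 <= self.lat <= 90.0:
            raise ValidationError(f"latitude {self.lat} outside [-90, 90]")
        if self.depth_m < 0.0:
            raise ValidationError("depth_m must be >= 0")
        lon = ((-(self.lon) + 180.0) % 360.0)
        lon = -(lon - 180.0)
        if lon <= -180.0:
            lon += 360.0
        object.__setattr__(self, "lon", float(lon))


#: Center of Ascension Island, the study's reference point.
ASCENSION = GeoPosition(-7.933, -14.367)


@dataclass(frozen=True)
class FieldElements:
    """The seven standard geomagnetic elements at a point (nT / degrees)."""

    X: float  # north
    Y: float  # east
    Z: float  # down
    H: float  # horizontal intensity
    F: float  # total intensity
    I: float  # inclination, degrees, positive down
    D: float  # declination, degrees, positive east


@dataclass
class GaussCoefficientSet:
    """Gauss coefficients g[n, m], h[n, m] (nT) for one epoch.

    Arrays are square of shape (N+1, N+1) indexed [n, m]; entries with
    m > n are zero, as is h[n, 0].  ``sv_g``/``sv_h`` hold secular-variation
    rates (nT/yr) and are used only to extrapolate beyond the final epoch
    of a series.
    """

    epoch: float
    g: np.ndarray
    h: np.ndarray
    sv_g: np.ndarray | None = None
    sv_h: np.ndarray | None = None

    def __post_init__(self):
        self.g = np.asarray(self.g, dtype=float)
        self.h = np.asarray(self.h, dtype=float)
        if self.g.shape != self.h.shape or self.g.ndim != 2 \
                or self.g.shape[0] != self.g.shape[1]:
            raise ValidationError("g and h must be square arrays of equal shape")
        if self.g.shape[0] < 2:
            raise ValidationError("max_degree must be >= 1")
        if not (np.isfinite(self.g).all() and np.isfinite(self.h).all()):
            raise ValidationError("coefficients must be finite")
        self.h[:, 0] = 0.0
        for arr_name in ("sv_g", "sv_h"):
            arr = getattr(self, arr_name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if arr.shape != self.g.shape:
                    raise ValidationError(f"{arr_name} shape mismatch")
                setattr(self, arr_name, arr)

    @property
    def max_degree(self) -> int:
        return self.g.shape[0] - 1


@dataclass
class GaussCoefficientSeries:
    """Time series of coefficient sets with strictly increasing epochs."""

    sets: list[GaussCoefficientSet]
    reference_radius_km: float = REFERENCE_RADIUS_KM
    #: optional generator-provided ground truth (e.g. configured pattern drift)
    metadata: dict | None = None

    def __post_init__(self):
        if len(self.sets) < 1:
            raise ValidationError("series needs at least one epoch")
        epochs = [s.epoch for s in self.sets]
        if any(b <= a for a, b in zip(epochs, epochs[1:])):
            raise ValidationError(f"epochs must be strictly increasing, got {epochs}")

    @property
    def epochs(self) -> np.ndarray:
        return np.array([s.epoch for s in self.sets])

    @property
    def max_degree(self) -> int:
        return max(s.max_degree for s in self.sets)


@dataclass
class ScalarGrid:
    """Regular lat/lon raster of total intensity F (nT) at one instant."""

    lats: np.ndarray
    lons: np.ndarray
    values: np.ndarray  # shape (nlat, nlon)
    time: float

    def __post_init__(self):
        self.lats = np.asarray(self.lats, dtype=float)
        self.lons = np.asarray(self.lons, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.lats.size, self.lons.size):
            raise ValidationError("values shape must be (nlat, nlon)")
        if np.any(np.diff(self.lats) <= 0) or np.any(np.diff(self.lons) <= 0):
            raise ValidationError("lats and lons must be strictly ascending")
        if not np.isfinite(self.values).all():
            raise ValidationError("grid values must be finite")

    def to_csv(self, path):
        """Write long-form CSV with columns lat, lon, F_nT."""
        lat2, lon2 = np.meshgrid(self.lats, self.lons, indexing="ij")
        out = np.column_stack([lat2.ravel(), lon2.ravel(), self.values.ravel()])
        header = f"time={self.time}\nlat,lon,F_nT"
        np.savetxt(path, out, delimiter=",", header=header, fmt="%.6f")

    def to_gridtext(self, path):
        """Write a plain whitespace grid (rows = lats, cols = lons)."""
        with open(path, "w") as fh:
            fh.write(f"# time {self.time}\n")
            fh.write("# lats " + " ".join(f"{v:g}" for v in self.lats) + "\n")
            fh.write("# lons " + " ".join(f"{v:g}" for v in self.lons) + "\n")
            np.savetxt(fh, self.values, fmt="%.3f")


# ---------------------------------------------------------------------------
# IGRF-format table I/O
# ---------------------------------------------------------------------------

def _as_lines(source) -> list[str]:
    if hasattr(source, "read"):
        return source.read().splitlines()
    if isinstance(source, str) and "\n" in source:
        return source.splitlines()
    if isinstance(source, (str,)) or hasattr(source, "__fspath__"):
        with open(source) as fh:
            return fh.read().splitlines()
    return list(source)


def read_coefficients(source) -> GaussCoefficientSeries:
    """Parse a coefficient table laid out like the published IGRF text files.

    Layout: '#' comment lines; an optional 'c/s ...' column-label line; a
    header line beginning 'g/h' listing the epochs (last column may be a
    secular-variation span such as '2020-25' or the label 'SV'); then one
    row per coefficient: ``g|h  n  m  v_epoch1 ... v_epochK  sv``.
    """
    lines = _as_lines(source)
    epochs: list[float] | None = None
    has_sv = False
    rows: list[tuple[str, int, int, list[float], int]] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#") or line.startswith("c/s"):
            continue
        tokens = line.split()
        if tokens[0] == "g/h":
            cols = tokens[3:]
            epochs = []
            for tok in cols:
                if tok.upper() == "SV" or "-" in tok[1:]:
                    has_sv = True
                else:
                    try:
                        epochs.append(float(tok))
                    except ValueError as exc:
                        raise ParseError(
                            f"line {lineno}: bad epoch column {tok!r}") from exc
            continue
        key = tokens[0]
        if key not in ("g", "h"):
            raise ParseError(f"line {lineno}: unknown row key {key!r}")
        try:
            n, m = int(tokens[1]), int(tokens[2])
            values = [float(t) for t in tokens[3:]]
        except ValueError as exc:
            raise ParseError(f"line {lineno}: non-numeric cell in {line!r}") from exc
        if m > n or n < 1:
            raise ParseError(f"line {lineno}: invalid degree/order ({n},{m})")
        rows.append((key, n, m, values, lineno))

    if not rows:
        raise ValidationError("coefficient table contains no data rows")
    if epochs is None:
        # headerless tables are ambiguous; require the g/h header line
        raise ParseError("missing 'g/h' header line listing epochs")
    if any(b <= a for a, b in zip(epochs, epochs[1:])):
        raise ValidationError(f"epochs must be strictly increasing, got {epochs}")

    k = len(epochs)
    expected = k + (1 if has_sv else 0)
    nmax = max(n for _, n, _, _, _ in rows)
    g = np.zeros((k, nmax + 1, nmax + 1))
    h = np.zeros((k, nmax + 1, nmax + 1))
    sv_g = np.zeros((nmax + 1, nmax + 1))
    sv_h = np.zeros((nmax + 1, nmax + 1))
    for key, n, m, values, lineno in rows:
        if len(values) != expected:
            raise ParseError(
                f"line {lineno}: expected {expected} values, got {len(values)}")
        main, sv = (values[:-1], values[-1]) if has_sv else (values, 0.0)
        tgt, tgt_sv = (g, sv_g) if key == "g" else (h, sv_h)
        tgt[:, n, m] = main
        tgt_sv[n, m] = sv

    sets = []
    for i, ep in enumerate(epochs):
        last = i == k - 1
        sets.append(GaussCoefficientSet(
            epoch=ep, g=g[i], h=h[i],
            sv_g=sv_g if (last and has_sv) else None,
            sv_h=sv_h if (last and has_sv) else None))
    return GaussCoefficientSeries(sets)


def write_coefficients(series: GaussCoefficientSeries, stream=None) -> str:
    """Serialize a series back to the IGRF text layout (round-trip of
    :func:`read_coefficients`).  Returns the text; also writes to ``stream``
    if given."""
    nmax = series.max_degree
    last = series.sets[-1]
    has_sv = last.sv_g is not None
    cols = [f"{s.epoch:.1f}" for s in series.sets]
    if has_sv:
        cols.append("SV")
    out = io.StringIO()
    out.write("g/h n m " + " ".join(cols) + "\n")

    def padded(s: GaussCoefficientSet, which: str, n: int, m: int) -> float:
        arr = getattr(s, which)
        return float(arr[n, m]) if n < arr.shape[0] else 0.0

    for n in range(1, nmax + 1):
        for m in range(0, n + 1):
            for key in ("g", "h"):
                if key == "h" and m == 0:
                    continue
                vals = [padded(s, key, n, m) for s in series.sets]
                if has_sv:
                    sv = getattr(last, f"sv_{key}")
                    vals.append(float(sv[n, m]) if n < sv.shape[0] else 0.0)
                out.write(f"{key} {n} {m} " + " ".join(f"{v:g}" for v in vals) + "\n")
    text = out.getvalue()
    if stream is not None:
        stream.write(text)
    return text


def _padded_to(arr: np.ndarray, nmax: int) -> np.ndarray:
    if arr.shape[0] == nmax + 1:
        return arr
    out = np.zeros((nmax + 1, nmax + 1))
    out[: arr.shape[0], : arr.shape[1]] = arr
    return out


def coefficients_at(series: GaussCoefficientSeries, t: float) -> GaussCoefficientSet:
    """Coefficient set at decimal year ``t``.

    Linear interpolation between bracketing epochs; beyond the last epoch,
    linear extrapolation with the secular-variation rates (zero rates when
    none are tabulated).  At a tabulated epoch the stored set is returned
    exactly (a copy).
    """
    epochs = series.epochs
    if t < epochs[0]:
        raise DomainError(f"t={t} precedes first epoch {epochs[0]}")
    idx = np.searchsorted(epochs, t)
    if idx < len(epochs) and epochs[idx] == t:
        s = series.sets[idx]
        return GaussCoefficientSet(t, s.g.copy(), s.h.copy(),
                                   None if s.sv_g is None else s.sv_g.copy(),
                                   None if s.sv_h is None else s.sv_h.copy())
    nmax = series.max_degree
    if t > epochs[-1]:
        s = series.sets[-1]
        dt = t - epochs[-1]
        g = _padded_to(s.g, nmax).copy()
        h = _padded_to(s.h, nmax).copy()
        if s.sv_g is not None:
            g += dt * _padded_to(s.sv_g, nmax)
        if s.sv_h is not None:
            h += dt * _padded_to(s.sv_h, nmax)
        return GaussCoefficientSet(t, g, h)
    lo, hi = series.sets[idx - 1], series.sets[idx]
    w = (t - lo.epoch) / (hi.epoch - lo.epoch)
    g = (1 - w) * _padded_to(lo.g, nmax) + w * _padded_to(hi.g, nmax)
    h = (1 - w) * _padded_to(lo.h, nmax) + w * _padded_to(hi.h, nmax)
    return GaussCoefficientSet(t, g, h)


# ---------------------------------------------------------------------------
# Spherical-harmonic synthesis
# ---------------------------------------------------------------------------

def _schmidt_legendre(nmax: int, theta: np.ndarray):
    """Schmidt quasi-normalized P[n, m](cos theta) and dP/dtheta.

    Stable upward recurrence in degree; ``theta`` is colatitude in radians,
    any shape.  Returns arrays of shape (nmax+1, nmax+1) + theta.shape.
    """
    ct, st = np.cos(theta), np.sin(theta)
    shape = (nmax + 1, nmax + 1) + theta.shape
    P = np.zeros(shape)
    dP = np.zeros(shape)
    P[0, 0] = 1.0
    for n in range(1, nmax + 1):
        for m in range(0, n + 1):
            if m == n:
                if n == 1:
                    P[1, 1] = st
                    dP[1, 1] = ct
                else:
                    c = np.sqrt((2 * n - 1) / (2.0 * n))
                    P[n, n] = c * st * P[n - 1, n - 1]
                    dP[n, n] = c * (st * dP[n - 1, n - 1] + ct * P[n - 1, n - 1])
            else:
                a = 2 * n - 1
                b = np.sqrt((n - 1) ** 2 - m ** 2)
                d = np.sqrt(float(n ** 2 - m ** 2))
                P[n, m] = (a * ct * P[n - 1, m] - b * P[n - 2, m]) / d
                dP[n, m] = (a * (ct * dP[n - 1, m] - st * P[n - 1, m])
                            - b * dP[n - 2, m]) / d
    return P, dP


def synthesize(coeffs: GaussCoefficientSet, lats, lons):
    """Vectorized field synthesis at r = a.

    Returns (X, Y, Z) arrays in nT, broadcast over ``lats``/``lons``
    (degrees).  Latitudes are clipped to ±89.9999° to avoid the polar
    singularity of the east component.
    """
    if coeffs.max_degree < 1:
        raise ValidationError("max_degree must be >= 1")
    lats = np.clip(np.asarray(lats, dtype=float), -_LAT_CLIP, _LAT_CLIP)
    lons = np.asarray(lons, dtype=float)
    lats, lons = np.broadcast_arrays(lats, lons)
    theta = np.radians(90.0 - lats)
    phi = np.radians(lons)
    nmax = coeffs.max_degree
    P, dP = _schmidt_legendre(nmax, theta)
    st = np.sin(theta)

    m_arr = np.arange(nmax + 1)
    cos_m = np.cos(m_arr[:, None] * phi.ravel()[None, :]).reshape((nmax + 1,) + phi.shape)
    sin_m = np.sin(m_arr[:, None] * phi.ravel()[None, :]).reshape((nmax + 1,) + phi.shape)

    X = np.zeros(theta.shape)
    Y = np.zeros(theta.shape)
    Z = np.zeros(theta.shape)
    for n in range(1, nmax + 1):
        for m in range(0, n + 1):
            gg, hh = coeffs.g[n, m], coeffs.h[n, m]
            if gg == 0.0 and hh == 0.0:
                continue
            A = gg * cos_m[m] + hh * sin_m[m]
            X += A * dP[n, m]
            Z -= (n + 1) * A * P[n, m]
            if m > 0:
                Y += m * (gg * sin_m[m] - hh * cos_m[m]) * P[n, m] / st
    return X, Y, Z


def evaluate_field(coeffs: GaussCoefficientSet, pos: GeoPosition) -> FieldElements:
    """All seven field elements at a single position (on the reference sphere)."""
    X, Y, Z = synthesize(coeffs, np.array([pos.lat]), np.array([pos.lon]))
    x, y, z = float(X[0]), float(Y[0]), float(Z[0])
    H = float(np.hypot(x, y))
    F = float(np.sqrt(x * x + y * y + z * z))
    inc = float(np.degrees(np.arctan2(z, H)))
    dec = float(np.degrees(np.arctan2(y, x)))
    return FieldElements(X=x, Y=y, Z=z, H=H, F=F, I=inc, D=dec)


def total_intensity(coeffs: GaussCoefficientSet, lats, lons) -> np.ndarray:
    """Total intensity F (nT) over broadcast lat/lon arrays."""
    X, Y, Z = synthesize(coeffs, lats, lons)
    return np.sqrt(X * X + Y * Y + Z * Z)


def intensity_grid(series: GaussCoefficientSeries, t: float,
                   lat_range: Sequence[float], lon_range: Sequence[float],
                   step_deg: float, chunk_rows: int = 40) -> ScalarGrid:
    """Regular grid of total intensity F at decimal year ``t``.

    The grid includes both range endpoints; evaluation is chunked row-wise
    to bound the memory of the Legendre-function workspace.
    """
    if step_deg <= 0:
        raise ValidationError("step_deg must be positive")
    (lat0, lat1), (lon0, lon1) = lat_range, lon_range
    if lat0 >= lat1 or lon0 >= lon1:
        raise ValidationError("degenerate lat/lon range (min >= max)")
    if not (-90 <= lat0 and lat1 <= 90):
        raise ValidationError("latitude range outside [-90, 90]")
    nlat = int(round((lat1 - lat0) / step_deg)) + 1
    nlon = int(round((lon1 - lon0) / step_deg)) + 1
    lats = np.linspace(lat0, lat1, nlat)
    lons = np.linspace(lon0, lon1, nlon)
    coeffs = coefficients_at(series, t)
    values = np.empty((nlat, nlon))
    for i in range(0, nlat, chunk_rows):
        block = slice(i, min(i + chunk_rows, nlat))
        la, lo = np.meshgrid(lats[block], lons, indexing="ij")
        values[block] = total_intensity(coeffs, la, lo)
    return ScalarGrid(lats=lats, lons=lons, values=values, time=t)
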