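"""Constant-intensity isoline extraction, temporal drift, and distances.

Secular variation makes the magnetic signature of a fixed location move over
the years; an animal that remembers the total intensity F at an island and
later steers along "its" isoline will find that the curve has drifted.  This
module extracts F-isolines from a raster (marching squares), relocates the
level at a later date, and quantifies the drift as the minimum great-circle
distance from the reference point to the drifted curve.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field

import numpy as np
from skimage import measure

from . import _geodesy, geomag
from .errors import IsolineNotFoundError, ValidationError

#: Default extraction window covering the Brazil-to-Ascension corridor.
DEFAULT_WINDOW = ((-25.0, 10.0), (-45.0, 5.0))
DEFAULT_STEP_DEG = 0.1


@dataclass
class IsolinePolyline:
    """One connected constant-intensity contour.

    ``segments`` holds ordered (lat, lon) vertex arrays; a single connected
    component has one segment, but clipped or multi-part curves may carry
    several.
    """

    level: float
    segments: list  # list of (K, 2) float arrays of (lat, lon)
    time: float

    def __post_init__(self):
        self.segments = [np.asarray(s, dtype=float) for s in self.segments]
        for s in self.segments:
            if s.ndim != 2 or s.shape[1] != 2:
                raise ValidationError("segment must be an (K, 2) array")
        if not np.isfinite(self.level):
            raise ValidationError("level must be finite")

    @property
    def n_vertices(self) -> int:
        return sum(s.shape[0] for s in self.segments)

    def all_vertices(self) -> np.ndarray:
        return np.vstack(self.segments) if self.segments else np.empty((0, 2))

    def to_geojson(self) -> dict:
        """GeoJSON Feature (LineString or MultiLineString, lon-lat order)."""
        coords = [[[float(lon), float(lat)] for lat, lon in seg]
                  for seg in self.segments]
        geometry = ({"type": "LineString", "coordinates": coords[0]}
                    if len(coords) == 1 else
                    {"type": "MultiLineString", "coordinates": coords})
        return {"type": "Feature", "geometry": geometry,
                "properties": {"level_nT": float(self.level),
                               "time": float(self.time)}}


@dataclass
class DriftReport:
    """Displacement of a remembered-intensity isoline after ``delta_years``."""

    reference_point: geomag.GeoPosition
    t0: float
    delta_years: float
    level: float
    drifted: IsolinePolyline
    drift_km: float

    def to_dict(self) -> dict:
        return {"t0": self.t0, "delta_years": self.delta_years,
                "level_nT": self.level, "drift_km": self.drift_km,
                "reference_lat": self.reference_point.lat,
                "reference_lon": self.reference_point.lon}

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def extract_isolines(grid: geomag.ScalarGrid, level: float) -> list[IsolinePolyline]:
    """Marching-squares contours of ``grid`` at ``level``.

    Returns one polyline per connected contour component (possibly empty when
    the level is outside the grid's value range).  Vertices are linearly
    interpolated along cell edges and mapped to geographic coordinates.
    """
    if not np.isfinite(grid.values).all():
        raise ValidationError("grid contains non-finite values")
    vmin, vmax = grid.values.min(), grid.values.max()
    if not (vmin <= level <= vmax):
        return []
    contours = measure.find_contours(grid.values, level)
    out = []
    for c in contours:
        lats = np.interp(c[:, 0], np.arange(grid.lats.size), grid.lats)
        lons = np.interp(c[:, 1], np.arange(grid.lons.size), grid.lons)
        out.append(IsolinePolyline(level=float(level),
                                   segments=[np.column_stack([lats, lons])],
                                   time=grid.time))
    return out


def geodesic_distance_point_to_polyline(point: geomag.GeoPosition,
                                        polyline: IsolinePolyline) -> float:
    """Minimum great-circle distance (km) from a point to a polyline."""
    if not polyline.segments or polyline.n_vertices == 0:
        raise ValidationError("polyline is empty")
    return min(_geodesy.point_to_polyline_km(point.lat, point.lon, seg)
               for seg in polyline.segments if seg.shape[0] > 0)


def _segment_length_km(seg: np.ndarray) -> float:
    if seg.shape[0] < 2:
        return 0.0
    return float(np.sum(_geodesy.haversine_km(seg[:-1, 0], seg[:-1, 1],
                                              seg[1:, 0], seg[1:, 1])))


def nearest_component(polylines: list[IsolinePolyline],
                      point: geomag.GeoPosition) -> IsolinePolyline:
    """The component nearest the point; ties broken by the longest component."""
    if not polylines:
        raise IsolineNotFoundError("no contour components to choose from")
    keyed = []
    for p in polylines:
        d = geodesic_distance_point_to_polyline(point, p)
        length = sum(_segment_length_km(s) for s in p.segments)
        keyed.append((round(d, 9), -length, p))
    keyed.sort(key=lambda t: (t[0], t[1]))
    return keyed[0][2]


def isoline_through_point(series: geomag.GaussCoefficientSeries, t: float,
                          point: geomag.GeoPosition,
                          window=DEFAULT_WINDOW,
                          step_deg: float = DEFAULT_STEP_DEG) -> IsolinePolyline:
    """The intensity isoline passing through ``point`` at decimal year ``t``.

    The level is F(point, t); among all contour components at that level in
    the window, the one passing nearest the point is returned.
    """
    (lat0, lat1), (lon0, lon1) = window
    if not (lat0 <= point.lat <= lat1 and lon0 <= point.lon <= lon1):
        raise ValidationError("point must lie inside the extraction window")
    coeffs = geomag.coefficients_at(series, t)
    level = geomag.evaluate_field(coeffs, point).F
    grid = geomag.intensity_grid(series, t, window[0], window[1], step_deg)
    components = extract_isolines(grid, level)
    if not components:
        raise IsolineNotFoundError(
            f"no contour at level {level:.1f} nT in window at t={t}")
    return nearest_component(components, point)


def drifted_isoline(series: geomag.GaussCoefficientSeries,
                    point: geomag.GeoPosition, t0: float, delta_years: float,
                    window=DEFAULT_WINDOW,
                    step_deg: float = DEFAULT_STEP_DEG) -> DriftReport:
    """Where the isoline that marked ``point`` at ``t0`` lies ``delta_years`` later.

    The level is frozen at F(point, t0); the contour of that level is
    extracted at t0 + delta_years and the drift distance is the minimum
    great-circle distance from the reference point to the drifted curve
    (the natural displacement metric for a curve that originally passed
    through the point).
    """
    coeffs0 = geomag.coefficients_at(series, t0)
    level = geomag.evaluate_field(coeffs0, point).F
    t1 = t0 + delta_years
    grid = geomag.intensity_grid(series, t1, window[0], window[1], step_deg)
    components = extract_isolines(grid, level)
    if not components:
        raise IsolineNotFoundError(
            f"level {level:.1f} nT (from t0={t0}) not present in window at "
            f"t={t1}; the isoline has left the window")
    best = nearest_component(components, point)
    drift = geodesic_distance_point_to_polyline(point, best)
    return DriftReport(reference_point=point, t0=t0, delta_years=delta_years,
                       level=level, drifted=best, drift_km=drift)


def drift_reports_to_csv(reports: list[DriftReport], path, header_lines=()) -> None:
    """CSV rows (t0, delta_years, level_nT, drift_km) with optional metadata."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("t0,delta_years,level_nT,drift_km\n")
        for r in reports:
            fh.write(f"{r.t0:.1f},{r.delta_years:.1f},"
                     f"{r.level:.3f},{r.drift_km:.3f}\n")


def isolines_to_geojson(polylines: list[IsolinePolyline], path=None) -> dict:
    """FeatureCollection of isolines; optionally written to ``path``."""
    fc = {"type": "FeatureCollection",
          "features": [p.to_geojson() for p in polylines]}
    if path is not None:
        with open(path, "w") as fh:
            json.dump(fc, fh)
    return fc
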