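"""Great-circle geometry helpers on a spherical Earth (R = 6371 km).

All public functions accept scalars or numpy arrays of latitude/longitude in
degrees (north/east positive) and return kilometers.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0
#: meters per degree of latitude (and of longitude at the equator)
M_PER_DEG = EARTH_RADIUS_KM * 1000.0 * np.pi / 180.0
KM_PER_DEG = M_PER_DEG / 1000.0


def normalize_lon(lon):
    """Wrap longitude(s) into (-180, 180]."""
    lon = np.asarray(lon, dtype=float)
    wrapped = ((-lon + 180.0) % 360.0)
    out = -(wrapped - 180.0)
    # map -180 -> 180
    out = np.where(out <= -180.0, out + 360.0, out)
    return out if out.ndim else float(out)


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km; broadcasts over array inputs."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return d if np.ndim(d) else float(d)


def initial_bearing_rad(lat1, lon1, lat2, lon2):
    """Initial great-circle bearing (radians clockwise from north)."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lat1, lon1, lat2, lon2))
    dlon = lon2 - lon1
    y = np.sin(dlon) * np.cos(lat2)
    x = np.cos(lat1) * np.sin(lat2) - np.sin(lat1) * np.cos(lat2) * np.cos(dlon)
    return np.arctan2(y, x)


def point_to_segments_km(lat, lon, seg_lat1, seg_lon1, seg_lat2, seg_lon2):
    """Great-circle distance from point(s) to great-circle segment(s).

    Uses the exact cross-track formula when the perpendicular foot lies
    within the segment, otherwise the nearer endpoint.  Points and segments
    broadcast: pass point arrays of shape (P, 1) against segment arrays of
    shape (S,) to obtain a (P, S) distance matrix.
    """
    d13 = haversine_km(seg_lat1, seg_lon1, lat, lon) / EARTH_RADIUS_KM  # angular
    th13 = initial_bearing_rad(seg_lat1, seg_lon1, lat, lon)
    th12 = initial_bearing_rad(seg_lat1, seg_lon1, seg_lat2, seg_lon2)
    d12 = haversine_km(seg_lat1, seg_lon1, seg_lat2, seg_lon2) / EARTH_RADIUS_KM

    sin_dxt = np.sin(d13) * np.sin(th13 - th12)
    dxt = np.arcsin(np.clip(sin_dxt, -1.0, 1.0))
    # along-track angular distance from the segment start to the foot point
    cos_dxt = np.cos(dxt)
    with np.errstate(invalid="ignore", divide="ignore"):
        dat = np.arccos(np.clip(np.cos(d13) / np.where(cos_dxt == 0, 1.0, cos_dxt),
                                -1.0, 1.0))
    # sign of the along-track distance: negative when the foot lies behind start
    behind = np.cos(th13 - th12) < 0.0
    inside = (~behind) & (dat <= d12)

    d_end1 = d13 * EARTH_RADIUS_KM
    d_end2 = haversine_km(seg_lat2, seg_lon2, lat, lon)
    d_perp = np.abs(dxt) * EARTH_RADIUS_KM
    out = np.where(inside, d_perp, np.minimum(d_end1, d_end2))
    return out if np.ndim(out) else float(out)


def point_to_polyline_km(lat, lon, vertices):
    """Minimum great-circle distance (km) from one point to a polyline.

    ``vertices`` is an (N, 2) array of (lat, lon) rows, N >= 1.
    """
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[0] < 1 or v.shape[1] != 2:
        raise ValueError("polyline must be an (N, 2) array of (lat, lon)")
    if v.shape[0] == 1:
        return haversine_km(lat, lon, v[0, 0], v[0, 1])
    d = point_to_segments_km(lat, lon, v[:-1, 0], v[:-1, 1], v[1:, 0], v[1:, 1])
    return float(np.min(d))


def points_to_polyline_min_km(lats, lons, vertices, chunk=2048):
    """Per-point minimum distance (km) from many points to one polyline."""
    v = np.asarray(vertices, dtype=float)
    lats = np.asarray(lats, dtype=float).ravel()
    lons = np.asarray(lons, dtype=float).ravel()
    if v.shape[0] == 1:
        return haversine_km(lats, lons, v[0, 0], v[0, 1])
    out = np.empty(lats.shape[0])
    for i in range(0, lats.shape[0], chunk):
        sl = slice(i, i + chunk)
        d = point_to_segments_km(lats[sl, None], lons[sl, None],
                                 v[None, :-1, 0], v[None, :-1, 1],
                                 v[None, 1:, 0], v[None, 1:, 1])
        out[sl] = d.min(axis=1)
    return out


def destination_point(lat, lon, bearing_rad, distance_km):
    """Great-circle destination from a start point along a bearing."""
    lat1 = np.radians(np.asarray(lat, dtype=float))
    lon1 = np.radians(np.asarray(lon, dtype=float))
    delta = np.asarray(distance_km, dtype=float) / EARTH_RADIUS_KM
    lat2 = np.arcsin(np.sin(lat1) * np.cos(delta)
                     + np.cos(lat1) * np.sin(delta) * np.cos(bearing_rad))
    lon2 = lon1 + np.arctan2(np.sin(bearing_rad) * np.sin(delta) * np.cos(lat1),
                             np.cos(delta) - np.sin(lat1) * np.sin(lat2))
    return np.degrees(lat2), normalize_lon(np.degrees(lon2))
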