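"""Spherical geometry helpers shared across the pipeline.

All distances are great-circle distances on a sphere of mean Earth radius
(6371.0088 km).  Planar work (Kalman smoothing, kernel density estimation)
uses a spherical azimuthal-equidistant projection centred on a reference
point, which preserves distance and bearing from that centre exactly.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0088


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km between points given in decimal degrees.

    Accepts scalars or broadcastable arrays.
    """
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(a)))


def initial_bearing_rad(lat1, lon1, lat2, lon2):
    """Initial bearing (radians, clockwise from north) from point 1 to 2."""
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    dlon = lon2 - lon1
    y = np.sin(dlon) * np.cos(lat2)
    x = np.cos(lat1) * np.sin(lat2) - np.sin(lat1) * np.cos(lat2) * np.cos(dlon)
    return np.arctan2(y, x)


def turning_angle_deg(lat0, lon0, lat1, lon1, lat2, lon2):
    """Inner angle at the middle vertex of a three-point path, in [0, 180].

    180 deg means the track continues straight on; small angles are sharp
    doubling-back spikes.
    """
    b_in = initial_bearing_rad(lat1, lon1, lat0, lon0)
    b_out = initial_bearing_rad(lat1, lon1, lat2, lon2)
    ang = np.abs(np.degrees(b_out - b_in))
    ang = np.where(ang > 180.0, 360.0 - ang, ang)
    return ang


class AzimuthalEquidistant:
    """Spherical azimuthal-equidistant projection about a centre point.

    ``to_xy`` maps (lat, lon) degrees to planar (x, y) in km with the centre
    at the origin, x east and y north; ``to_latlon`` inverts it.
    """

    def __init__(self, lat0: float, lon0: float):
        self.lat0 = float(lat0)
        self.lon0 = float(lon0)
        self._phi0 = np.radians(lat0)
        self._lam0 = np.radians(lon0)

    def to_xy(self, lat, lon):
        phi = np.radians(np.asarray(lat, dtype=float))
        lam = np.radians(np.asarray(lon, dtype=float))
        dlam = lam - self._lam0
        cos_c = np.sin(self._phi0) * np.sin(phi) + np.cos(self._phi0) * np.cos(phi) * np.cos(dlam)
        cos_c = np.clip(cos_c, -1.0, 1.0)
        c = np.arccos(cos_c)
        # k = c / sin(c), with the removable singularity at c = 0
        with np.errstate(invalid="ignore", divide="ignore"):
            k = np.where(c > 1e-12, c / np.sin(np.where(c > 1e-12, c, 1.0)), 1.0)
        x = EARTH_RADIUS_KM * k * np.cos(phi) * np.sin(dlam)
        y = EARTH_RADIUS_KM * k * (
            np.cos(self._phi0) * np.sin(phi) - np.sin(self._phi0) * np.cos(phi) * np.cos(dlam)
        )
        return x, y

    def to_latlon(self, x, y):
        x = np.asarray(x, dtype=float) / EARTH_RADIUS_KM
        y = np.asarray(y, dtype=float) / EARTH_RADIUS_KM
        c = np.hypot(x, y)
        safe_c = np.where(c > 1e-12, c, 1.0)
        phi = np.where(
            c > 1e-12,
            np.arcsin(
                np.clip(
                    np.cos(safe_c) * np.sin(self._phi0)
                    + y * np.sin(safe_c) * np.cos(self._phi0) / safe_c,
                    -1.0,
                    1.0,
                )
            ),
            self._phi0,
        )
        lam = np.where(
            c > 1e-12,
            self._lam0
            + np.arctan2(
                x * np.sin(safe_c),
                safe_c * np.cos(self._phi0) * np.cos(safe_c)
                - y * np.sin(self._phi0) * np.sin(safe_c),
            ),
            self._lam0,
        )
        return np.degrees(phi), np.degrees(lam)


def point_to_polyline_km(lat, lon, line_lats, line_lons) -> float:
    """Great-circle distance (km) from a point to a lat/lon polyline.

    The polyline is projected into a local azimuthal-equidistant plane
    centred on the query point, where distance from the origin equals
    great-circle distance; the planar point-segment minimum is then exact
    up to the (tiny, local) projection distortion of the segment chords.
    """
    proj = AzimuthalEquidistant(lat, lon)
    xs, ys = proj.to_xy(np.asarray(line_lats, float), np.asarray(line_lons, float))
    if xs.ndim == 0:
        return float(np.hypot(xs, ys))
    best = np.inf
    for i in range(len(xs) - 1):
        best = min(best, _point_segment_dist(0.0, 0.0, xs[i], ys[i], xs[i + 1], ys[i + 1]))
    if len(xs) == 1:
        best = float(np.hypot(xs[0], ys[0]))
    return float(best)


def _point_segment_dist(px, py, ax, ay, bx, by) -> float:
    abx, aby = bx - ax, by - ay
    denom = abx * abx + aby * aby
    if denom == 0.0:
        return float(np.hypot(px - ax, py - ay))
    t = np.clip(((px - ax) * abx + (py - ay) * aby) / denom, 0.0, 1.0)
    return float(np.hypot(px - (ax + t * abx), py - (ay + t * aby)))


def solar_zenith_deg(timestamp, lat, lon) -> float:
    """Solar zenith angle (degrees) at a UTC timestamp and position.

    NOAA's general solar-position approximation: fractional year ->
    equation of time and declination (Fourier fits), then hour angle and
    zenith.  Accurate to well under a degree, ample for a day/night split.
    """
    ts = np.asarray(timestamp, dtype="datetime64[s]")
    doy = (ts - ts.astype("datetime64[Y]").astype("datetime64[D]")).astype(
        "timedelta64[D]"
    ).astype(float) + 1.0
    secs = (ts - ts.astype("datetime64[D]")).astype("timedelta64[s]").astype(float)
    hour = secs / 3600.0
    gamma = 2.0 * np.pi / 365.0 * (doy - 1.0 + (hour - 12.0) / 24.0)
    eqtime = 229.18 * (
        0.000075
        + 0.001868 * np.cos(gamma)
        - 0.032077 * np.sin(gamma)
        - 0.014615 * np.cos(2 * gamma)
        - 0.040849 * np.sin(2 * gamma)
    )
    decl = (
        0.006918
        - 0.399912 * np.cos(gamma)
        + 0.070257 * np.sin(gamma)
        - 0.006758 * np.cos(2 * gamma)
        + 0.000907 * np.sin(2 * gamma)
        - 0.002697 * np.cos(3 * gamma)
        + 0.00148 * np.sin(3 * gamma)
    )
    time_offset = eqtime + 4.0 * np.asarray(lon, float)
    tst = hour * 60.0 + time_offset
    ha = np.radians(tst / 4.0 - 180.0)
    phi = np.radians(np.asarray(lat, float))
    cos_zen = np.sin(phi) * np.sin(decl) + np.cos(phi) * np.cos(decl) * np.cos(ha)
    return np.degrees(np.arccos(np.clip(cos_zen, -1.0, 1.0)))
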