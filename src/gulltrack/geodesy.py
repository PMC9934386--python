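"""Spherical geometry for GPS tracks.

Distances, path lengths, mean positions, time-regularized resampling and a
Lambert azimuthal equal-area (LAEA) projection, all on a sphere of radius
6371.0088 km (IUGG mean Earth radius).  Printed track distances in this kind
of analysis are at km precision and are insensitive to the sphere/ellipsoid
choice; geodesic (ellipsoidal) distances are out of scope.

Longitude arithmetic goes through 3-D unit vectors or wrapped deltas
throughout: Chukotka tracks approach the antimeridian and naive degree
differencing would break there.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0088


def wrap_lon(lon):
    """Normalize longitudes to [-180, 180)."""
    return (np.asarray(lon, dtype=float) + 180.0) % 360.0 - 180.0


def _to_unit_vectors(lat, lon):
    """Geographic degrees -> unit vectors, shape (..., 3)."""
    phi = np.radians(np.asarray(lat, dtype=float))
    lam = np.radians(np.asarray(lon, dtype=float))
    return np.stack(
        [np.cos(phi) * np.cos(lam), np.cos(phi) * np.sin(lam), np.sin(phi)], axis=-1
    )


def _from_unit_vectors(v):
    """Unit vectors (..., 3) -> (lat, lon) degrees."""
    x, y, z = v[..., 0], v[..., 1], v[..., 2]
    lat = np.degrees(np.arctan2(z, np.hypot(x, y)))
    lon = wrap_lon(np.degrees(np.arctan2(y, x)))
    return lat, lon


def great_circle_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km between points given in decimal degrees.

    Uses the Vincenty spherical (atan2) formulation, which is numerically
    stable for both near-coincident and near-antipodal points.  Accepts
    scalars or broadcastable arrays.
    """
    phi1, phi2 = np.radians(np.asarray(lat1, float)), np.radians(np.asarray(lat2, float))
    dlam = np.radians(np.asarray(lon2, float) - np.asarray(lon1, float))
    s1, c1 = np.sin(phi1), np.cos(phi1)
    s2, c2 = np.sin(phi2), np.cos(phi2)
    sd, cd = np.sin(dlam), np.cos(dlam)
    num = np.hypot(c2 * sd, c1 * s2 - s1 * c2 * cd)
    den = s1 * s2 + c1 * c2 * cd
    return EARTH_RADIUS_KM * np.arctan2(num, den)


def spherical_mean(lat, lon):
    """Mean position as the normalized 3-D vector mean, returned as (lat, lon).

    Safe across the antimeridian and at high latitude where arithmetic
    means of raw coordinates are biased or outright wrong.

    Raises ``ValueError`` for an empty input or an (antipodally balanced)
    zero resultant vector, for which the mean is undefined.
    """
    v = _to_unit_vectors(lat, lon)
    if v.size == 0:
        raise ValueError("spherical_mean of no points is undefined")
    m = v.reshape(-1, 3).mean(axis=0)
    norm = np.linalg.norm(m)
    if norm < 1e-12:
        raise ValueError("spherical_mean undefined: zero resultant vector")
    la, lo = _from_unit_vectors(m / norm)
    return float(la), float(lo)


def path_length_km(lat, lon):
    """Summed consecutive great-circle distances along an ordered track (km)."""
    lat = np.asarray(lat, float)
    lon = np.asarray(lon, float)
    if lat.size < 2:
        return 0.0
    return float(np.sum(great_circle_km(lat[:-1], lon[:-1], lat[1:], lon[1:])))


def interpolate_on_great_circle(lat1, lon1, lat2, lon2, frac):
    """Point(s) a fraction ``frac`` in [0, 1] along the minor great-circle arc.

    Spherical linear interpolation (slerp); degenerate arcs fall back to the
    start point.  Broadcasts over arrays.
    """
    v1 = _to_unit_vectors(lat1, lon1)
    v2 = _to_unit_vectors(lat2, lon2)
    frac = np.asarray(frac, float)[..., None]
    dot = np.clip(np.sum(v1 * v2, axis=-1, keepdims=True), -1.0, 1.0)
    omega = np.arccos(dot)
    small = omega[..., 0] < 1e-9
    sin_omega = np.where(small[..., None], 1.0, np.sin(omega))
    w1 = np.where(small[..., None], 1.0 - frac, np.sin((1.0 - frac) * omega) / sin_omega)
    w2 = np.where(small[..., None], frac, np.sin(frac * omega) / sin_omega)
    v = w1 * v1 + w2 * v2
    v = v / np.linalg.norm(v, axis=-1, keepdims=True)
    return _from_unit_vectors(v)


@dataclass
class RegularTrack:
    """A track resampled to an exact fixed time interval.

    ``positions`` has columns timestamp (tz-aware UTC), lat, lon and an
    ``interpolated_gap`` flag marking points generated inside data gaps
    longer than ``gap_flag_days``.
    """

    bird_id: str
    interval: pd.Timedelta
    positions: pd.DataFrame
    gap_flag_days: float = 7.0


def regularize(fixes: pd.DataFrame, interval="1D", bird_id: str = "",
               gap_flag_days: float = 7.0, anchor=None) -> RegularTrack:
    """Resample a fix table to uniform time steps along its space-time path.

    Output instants are exact multiples of ``interval`` counted from
    ``anchor`` (default: the first fix timestamp) and never extend beyond the
    observed time range.  Each output position is obtained by linear
    interpolation in time along the great-circle segment between the two
    bracketing fixes, so every resampled point lies on the source polyline.
    Segments spanning more than ``gap_flag_days`` days are still interpolated
    but the points they generate are flagged.

    Equivalent in intent to trajectory "redistribution" utilities used for
    daily normalization of animal tracks.
    """
    if len(fixes) < 2:
        raise ValueError("regularize needs at least 2 fixes")
    interval = pd.Timedelta(interval)
    if interval <= pd.Timedelta(0):
        raise ValueError("interval must be positive")
    t = fixes["timestamp"].to_numpy(dtype="datetime64[ns]")
    lat = fixes["lat"].to_numpy(float)
    lon = fixes["lon"].to_numpy(float)
    t0 = t[0] if anchor is None else pd.Timestamp(anchor).to_datetime64()
    step = interval.to_timedelta64()
    first_k = int(np.ceil((t[0] - t0) / step))
    last_k = int(np.floor((t[-1] - t0) / step))
    if last_k < first_k:  # interval longer than the track span: single anchor point
        ks = np.array([first_k]) if t0 + first_k * step <= t[-1] else np.array([], int)
        if ks.size == 0:
            ks = np.array([0])
            times = t[:1]
        else:
            times = t0 + ks * step
    else:
        ks = np.arange(first_k, last_k + 1)
        times = t0 + ks * step
    idx = np.clip(np.searchsorted(t, times, side="right") - 1, 0, len(t) - 2)
    seg_dt = (t[idx + 1] - t[idx]) / np.timedelta64(1, "s")
    frac = np.clip((times - t[idx]) / np.timedelta64(1, "s") / seg_dt, 0.0, 1.0)
    out_lat, out_lon = interpolate_on_great_circle(
        lat[idx], lon[idx], lat[idx + 1], lon[idx + 1], frac
    )
    gap_flag = seg_dt > gap_flag_days * 86400.0
    pos = pd.DataFrame(
        {
            "timestamp": pd.DatetimeIndex(times, tz="UTC"),
            "lat": np.atleast_1d(out_lat),
            "lon": np.atleast_1d(out_lon),
            "interpolated_gap": gap_flag,
        }
    )
    return RegularTrack(bird_id=bird_id, interval=interval, positions=pos,
                        gap_flag_days=gap_flag_days)


# ---------------------------------------------------------------------------
# Lambert azimuthal equal-area projection (spherical form)
# ---------------------------------------------------------------------------

@dataclass
class LaeaProjection:
    """Spherical Lambert azimuthal equal-area projection centred on a point.

    Forward maps (lat, lon) degrees to plane coordinates in km; the plane
    preserves areas exactly on the sphere.  Valid everywhere except the
    exact antipode of the centre.
    """

    center_lat: float
    center_lon: float
    radius_km: float = field(default=EARTH_RADIUS_KM)

    def forward(self, lat, lon):
        phi = np.radians(np.asarray(lat, float))
        lam = np.radians(wrap_lon(np.asarray(lon, float) - self.center_lon))
        phi0 = np.radians(self.center_lat)
        cosc = np.sin(phi0) * np.sin(phi) + np.cos(phi0) * np.cos(phi) * np.cos(lam)
        if np.any(cosc <= -1.0 + 1e-12):
            raise ValueError("LAEA projection undefined at the antipode of the center")
        k = np.sqrt(2.0 / (1.0 + cosc))
        x = self.radius_km * k * np.cos(phi) * np.sin(lam)
        y = self.radius_km * k * (
            np.cos(phi0) * np.sin(phi) - np.sin(phi0) * np.cos(phi) * np.cos(lam)
        )
        return x, y

    def inverse(self, x_km, y_km):
        x = np.asarray(x_km, float) / self.radius_km
        y = np.asarray(y_km, float) / self.radius_km
        rho = np.hypot(x, y)
        phi0 = np.radians(self.center_lat)
        c = 2.0 * np.arcsin(np.clip(rho / 2.0, -1.0, 1.0))
        safe_rho = np.where(rho < 1e-15, 1.0, rho)
        lat = np.degrees(
            np.arcsin(np.clip(
                np.cos(c) * np.sin(phi0) + y * np.sin(c) * np.cos(phi0) / safe_rho,
                -1.0, 1.0,
            ))
        )
        lon = self.center_lon + np.degrees(
            np.arctan2(
                x * np.sin(c),
                safe_rho * np.cos(phi0) * np.cos(c) - y * np.sin(phi0) * np.sin(c),
            )
        )
        lat = np.where(rho < 1e-15, self.center_lat, lat)
        lon = np.where(rho < 1e-15, self.center_lon, lon)
        return lat, wrap_lon(lon)


def laea_for_points(lat, lon) -> LaeaProjection:
    """Projection centred on the spherical mean of the input points."""
    la, lo = spherical_mean(lat, lon)
    return LaeaProjection(center_lat=la, center_lon=lo)


def regular_track_to_csv(rt: RegularTrack, path) -> None:
    """Write a RegularTrack as (bird_id, date, lat, lon) CSV."""
    out = rt.positions.copy()
    out.insert(0, "bird_id", rt.bird_id)
    out["date"] = out.pop("timestamp").dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    out[["bird_id", "date", "lat", "lon"]].to_csv(path, index=False)


def regular_track_to_geojson(rt: RegularTrack, path) -> None:
    """Write a RegularTrack as a single GeoJSON LineString feature."""
    import json

    coords = [[round(float(lo), 6), round(float(la), 6)]
              for la, lo in zip(rt.positions["lat"], rt.positions["lon"])]
    feature = {
        "type": "FeatureCollection",
        "features": [{
            "type": "Feature",
            "properties": {"bird_id": rt.bird_id,
                           "interval_h": rt.interval / pd.Timedelta(hours=1)},
            "geometry": {"type": "LineString", "coordinates": coords},
        }],
    }
    with open(path, "w") as fh:
        json.dump(feature, fh)
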