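"""Join gridded wind/wave fields to GPS fixes; speeds and relative directions.

Wind u10/v10 are meteorological "toward" components: the wind vector points
downwind. Wave mean direction (mwd) arrives in the oceanographic "from"
convention and is converted to "toward" at read time, so every direction
handled downstream is a direction of flow. Relative direction folds the
angle between the travel bearing and the flow direction to [0, 180]:
0 = tailwind / receding waves, 90 = crosswind, 180 = headwind / oncoming
waves.

Extraction is nearest neighbour in space and time (ties break toward the
earlier time / lower index); bilinear interpolation in space is available
behind a flag.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import xarray as xr

from . import geo


class OutOfDomainError(ValueError):
    """A fix falls outside the field's spatial bbox or time span."""


def wind_from_uv(u, v):
    """(speed m/s, compass direction the wind blows TOWARD in [0, 360))."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    speed = np.hypot(u, v)
    direction_to = np.degrees(np.arctan2(u, v)) % 360.0
    return speed, direction_to


def relative_direction(track_bearing, flow_direction_to):
    """Angle between travel bearing and flow direction, folded to [0, 180].

    0 means the flow is aligned with travel (tailwind); 180 means opposed
    (headwind). Symmetric in the sign of the offset and invariant to adding
    full turns to either argument.
    """
    return np.abs(geo.wrap_angle_deg180(np.asarray(track_bearing, dtype=float) - np.asarray(flow_direction_to, dtype=float)))


def _nearest_index(grid: np.ndarray, value: float) -> int:
    """Index of the nearest grid node; exact midpoints resolve to the lower index."""
    d = np.abs(grid - value)
    return int(np.argmin(d))


def _nearest_indices(grid: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Vectorized nearest grid-node indices; exact midpoints take the lower index."""
    hi = np.clip(np.searchsorted(grid, values), 1, len(grid) - 1)
    lo = hi - 1
    pick_hi = np.abs(grid[hi] - values) < np.abs(values - grid[lo])
    return np.where(pick_hi, hi, lo)


def _times_naive(ts) -> np.ndarray:
    ts = pd.to_datetime(pd.Series(ts))
    if getattr(ts.dt, "tz", None) is not None:
        ts = ts.dt.tz_convert("UTC").dt.tz_localize(None)
    return ts.to_numpy()


def _check_domain(field: xr.Dataset, lat: float, lon: float, when) -> None:
    lats = field["latitude"].values
    lons = field["longitude"].values
    times = field["time"].values
    t = np.datetime64(pd.Timestamp(when).tz_localize(None) if pd.Timestamp(when).tzinfo else pd.Timestamp(when))
    if not (lats.min() <= lat <= lats.max()) or not (lons.min() <= lon <= lons.max()):
        raise OutOfDomainError(f"fix ({lat:.3f}, {lon:.3f}) outside field bbox")
    if not (times.min() <= t <= times.max()):
        raise OutOfDomainError(f"time {when} outside field span")


def nearest_cell_values(field: xr.Dataset, lat: float, lon: float, when, variables):
    """Values of ``variables`` at the nearest cell/hour (tie -> earlier/lower)."""
    _check_domain(field, lat, lon, when)
    ts = pd.Timestamp(when)
    t = np.datetime64(ts.tz_localize(None) if ts.tzinfo else ts)
    i = _nearest_index(field["latitude"].values, lat)
    j = _nearest_index(field["longitude"].values, lon)
    tnum = field["time"].values.astype("datetime64[s]").astype(np.int64)
    k = _nearest_index(tnum.astype(float), float(t.astype("datetime64[s]").astype(np.int64)))
    return tuple(float(field[v].values[i, j, k]) for v in variables)


def _bilinear_values(field: xr.Dataset, lat: float, lon: float, when, variables):
    _check_domain(field, lat, lon, when)
    ts = pd.Timestamp(when)
    t = np.datetime64(ts.tz_localize(None) if ts.tzinfo else ts)
    tnum = field["time"].values.astype("datetime64[s]").astype(np.int64)
    k = _nearest_index(tnum.astype(float), float(t.astype("datetime64[s]").astype(np.int64)))
    sliced = field.isel(time=k)
    out = []
    for v in variables:
        out.append(float(sliced[v].interp(latitude=lat, longitude=lon).values))
    return tuple(out)


def extract_env(
    fix,
    wind_field: xr.Dataset | None = None,
    wave_field: xr.Dataset | None = None,
    interpolate: bool = False,
) -> dict:
    """Environmental sample at one fix: dict with wind speed/direction and
    wave statistics, all flow directions in the "toward" convention.

    ``fix`` is a mapping with lat, lon, timestamp. Raises
    :class:`OutOfDomainError` outside the field bbox/time span.
    """
    lat, lon, when = float(fix["lat"]), float(fix["lon"]), fix["timestamp"]
    grab = _bilinear_values if interpolate else nearest_cell_values
    out: dict[str, float] = {}
    if wind_field is not None:
        u, v = grab(wind_field, lat, lon, when, ("u10", "v10"))
        ws, wdir_to = wind_from_uv(u, v)
        out.update(ws=float(ws), wdir_to=float(wdir_to))
    if wave_field is not None:
        swh, mwp, mwd_from = grab(wave_field, lat, lon, when, ("swh", "mwp", "mwd"))
        out.update(swh=swh, mwp=mwp, wave_dir_to=(mwd_from + 180.0) % 360.0)
    return out


def annotate_trip(
    trip: pd.DataFrame,
    wind_field: xr.Dataset | None = None,
    wave_field: xr.Dataset | None = None,
    interpolate: bool = False,
) -> pd.DataFrame:
    """Append environmental columns to a trip with per-step bearings.

    Adds ws, wdir_to, rwd (relative wind direction) and, when a wave field
    is supplied, swh, mwp, rwavd. Relative directions need the
    ``bearing_deg`` column from step metrics; rows without a bearing get NaN
    relative directions but keep their raw environmental values.
    """
    out = trip.copy()
    n = len(out)
    if interpolate:
        cols: dict[str, np.ndarray] = {}
        for i in range(n):
            sample = extract_env(out.iloc[i], wind_field, wave_field, interpolate=True)
            for k, val in sample.items():
                cols.setdefault(k, np.full(n, np.nan))[i] = val
        for k, arr in cols.items():
            out[k] = arr
    else:
        lat = out["lat"].to_numpy(dtype=float)
        lon = out["lon"].to_numpy(dtype=float)
        t = _times_naive(out["timestamp"])
        for field, names in ((wind_field, ("u10", "v10")), (wave_field, ("swh", "mwp", "mwd"))):
            if field is None:
                continue
            lats = field["latitude"].values
            lons = field["longitude"].values
            times = field["time"].values
            if lat.min() < lats.min() or lat.max() > lats.max() or lon.min() < lons.min() or lon.max() > lons.max():
                raise OutOfDomainError("fixes outside field bbox")
            if t.min() < times.min() or t.max() > times.max():
                raise OutOfDomainError("fixes outside field time span")
            i = _nearest_indices(lats, lat)
            j = _nearest_indices(lons, lon)
            k = _nearest_indices(
                times.astype("datetime64[s]").astype(np.int64).astype(float),
                t.astype("datetime64[s]").astype(np.int64).astype(float),
            )
            vals = {v: field[v].values[i, j, k] for v in names}
            if "u10" in vals:
                ws, wdir_to = wind_from_uv(vals["u10"], vals["v10"])
                out["ws"] = ws
                out["wdir_to"] = wdir_to
            else:
                out["swh"] = vals["swh"]
                out["mwp"] = vals["mwp"]
                out["wave_dir_to"] = (vals["mwd"] + 180.0) % 360.0
    if "bearing_deg" in out.columns:
        if "wdir_to" in out.columns:
            out["rwd"] = relative_direction(out["bearing_deg"], out["wdir_to"])
        if "wave_dir_to" in out.columns:
            out["rwavd"] = relative_direction(out["bearing_deg"], out["wave_dir_to"])
    return out
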