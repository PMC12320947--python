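"""Raw GPS fixes -> regularized foraging trips with stages and step metrics.

A foraging trip is a maximal excursion more than ``dist_threshold`` (1 km)
from the colony lasting longer than ``dur_threshold`` (30 min), extended to
the adjacent boundary fixes nearest the colony. Trips are regularized onto a
5-min lattice by piecewise great-circle interpolation of burst centroids
(a deliberate, deterministic simplification of state-space smoothing that is
adequate at this resolution; fixes inside gaps longer than ``max_gap`` are
flagged low-confidence). The distal "middle" stage is the contiguous span
where colony distance is at least 75% of the trip maximum; outbound/inbound
are the spans before/after it.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import geo

logger = logging.getLogger(__name__)

STAGES = ("outbound", "middle", "inbound")


def _naive_utc(ts: pd.Series) -> pd.Series:
    """Timestamps as tz-naive UTC for numpy datetime64 arithmetic."""
    ts = pd.to_datetime(ts)
    if getattr(ts.dt, "tz", None) is not None:
        ts = ts.dt.tz_convert("UTC").dt.tz_localize(None)
    return ts


def split_trips(
    track: pd.DataFrame,
    colony,
    dist_threshold_km: float = 1.0,
    dur_threshold_min: float = 30.0,
) -> list[pd.DataFrame]:
    """Cut a deployment's track into trip candidate segments.

    Each returned segment is a maximal run of fixes beyond
    ``dist_threshold_km`` from the colony lasting more than
    ``dur_threshold_min``, extended by one boundary fix on each side (the
    adjacent fixes nearest the colony) when available. A track that never
    leaves the threshold yields an empty list.
    """
    if len(track) < 2:
        raise ValueError("track needs at least 2 fixes")
    df = track.reset_index(drop=True)
    ts = pd.to_datetime(df["timestamp"])
    dist = geo.haversine_km(df["lat"], df["lon"], colony[0], colony[1])
    away = dist > dist_threshold_km

    trips = []
    i = 0
    n = len(df)
    while i < n:
        if not away[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and away[j + 1]:
            j += 1
        duration_min = (ts.iloc[j] - ts.iloc[i]).total_seconds() / 60.0
        if duration_min > dur_threshold_min:
            lo = max(i - 1, 0)
            hi = min(j + 1, n - 1)
            trips.append(df.iloc[lo : hi + 1].reset_index(drop=True))
        i = j + 1
    return trips


def _burst_centroids(trip: pd.DataFrame, burst_gap_s: float = 5.0) -> pd.DataFrame:
    """Collapse 1-Hz bursts (consecutive fixes <= burst_gap_s apart) to their
    mean-vector centroid at the burst's mean timestamp."""
    ts = pd.to_datetime(trip["timestamp"]).to_numpy()
    gaps = np.diff(ts) / np.timedelta64(1, "s")
    burst_id = np.concatenate([[0], np.cumsum(gaps > burst_gap_s)])
    rows = []
    for b in np.unique(burst_id):
        sel = burst_id == b
        vecs = geo.latlon_to_ecef(trip["lat"].to_numpy()[sel], trip["lon"].to_numpy()[sel])
        lat, lon = geo.ecef_to_latlon(vecs.mean(axis=0))
        mid = ts[sel][0] + (ts[sel][-1] - ts[sel][0]) / 2
        rows.append({"timestamp": mid, "lat": float(lat), "lon": float(lon)})
    return pd.DataFrame(rows)


def regularize(
    trip: pd.DataFrame,
    interval: str | pd.Timedelta = "5min",
    max_gap: str | pd.Timedelta = "30min",
) -> pd.DataFrame:
    """Interpolate a trip onto a regular time lattice.

    Output timestamps run from the first to the last fix at ``interval``;
    positions come from piecewise great-circle interpolation of burst
    centroids. Lattice points falling inside observation gaps longer than
    ``max_gap`` are flagged ``interp_flag='low_confidence'``, otherwise
    ``'high_confidence'``.
    """
    if len(trip) < 2:
        raise ValueError("regularize needs at least 2 fixes")
    interval = pd.Timedelta(interval)
    max_gap = pd.Timedelta(max_gap)
    trip = trip.assign(timestamp=_naive_utc(trip["timestamp"]))
    cent = _burst_centroids(trip)
    ts = pd.to_datetime(cent["timestamp"]).to_numpy()
    lat = cent["lat"].to_numpy()
    lon = cent["lon"].to_numpy()
    t0 = pd.to_datetime(trip["timestamp"].iloc[0])
    t1 = pd.to_datetime(trip["timestamp"].iloc[-1])
    n_out = int(np.floor((t1 - t0) / interval)) + 1
    lattice = np.array([np.datetime64(t0 + k * interval) for k in range(n_out)])

    tnum = ts.astype("datetime64[ns]").astype(np.int64)
    xnum = lattice.astype("datetime64[ns]").astype(np.int64)
    out_lat = np.empty(n_out)
    out_lon = np.empty(n_out)
    flags = np.full(n_out, "high_confidence", dtype=object)
    for k, x in enumerate(xnum):
        i = int(np.clip(np.searchsorted(tnum, x, side="right") - 1, 0, len(tnum) - 2))
        denom = tnum[i + 1] - tnum[i]
        f = 0.0 if denom <= 0 else np.clip((x - tnum[i]) / denom, 0.0, 1.0)
        la, lo = geo.gc_interpolate(lat[i], lon[i], lat[i + 1], lon[i + 1], [f])
        out_lat[k], out_lon[k] = float(la[0]), float(lo[0])
        if 0.0 < f < 1.0 and denom > max_gap.value:
            flags[k] = "low_confidence"
    out = pd.DataFrame(
        {
            "timestamp": lattice,
            "lat": out_lat,
            "lon": out_lon,
            "interp_flag": flags,
        }
    )
    for col in ("individual_id", "trip_id"):
        if col in trip.columns:
            out[col] = trip[col].iloc[0]
    return out


def label_stages(trip: pd.DataFrame, colony, fraction: float = 0.75) -> pd.DataFrame:
    """Assign outbound/middle/inbound stages by the distal-distance rule.

    The middle stage is the contiguous span from the first to the last fix
    whose colony distance is at least ``fraction`` of the trip maximum
    (robust to brief dips below the threshold); outbound precedes it,
    inbound follows. Adds ``colony_dist_km`` and ``stage`` columns.
    """
    out = trip.copy().reset_index(drop=True)
    dist = np.asarray(geo.haversine_km(out["lat"], out["lon"], colony[0], colony[1]), dtype=float)
    out["colony_dist_km"] = dist
    thresh = fraction * dist.max()
    above = np.flatnonzero(dist >= thresh)
    first, last = int(above[0]), int(above[-1])
    stage = np.full(len(out), "middle", dtype=object)
    stage[:first] = "outbound"
    stage[last + 1 :] = "inbound"
    out["stage"] = stage
    return out


def step_metrics(trip: pd.DataFrame, interval: str | pd.Timedelta | None = None) -> pd.DataFrame:
    """Per-step length, bearing, turning angle and ground speed.

    Step k describes the move arriving at fix k: ``step_km`` by haversine,
    ``bearing_deg`` the initial great-circle azimuth, ``turn_rad`` the
    wrapped bearing difference (NaN at the first step and after zero-length
    steps, where the bearing is undefined), ``speed_ms`` = step / elapsed
    time. First row carries NaNs.
    """
    out = trip.copy().reset_index(drop=True)
    lat = out["lat"].to_numpy(dtype=float)
    lon = out["lon"].to_numpy(dtype=float)
    ts = pd.to_datetime(out["timestamp"])
    n = len(out)
    step = np.full(n, np.nan)
    bearing = np.full(n, np.nan)
    turn = np.full(n, np.nan)
    speed = np.full(n, np.nan)
    step[1:] = geo.haversine_km(lat[:-1], lon[:-1], lat[1:], lon[1:])
    raw_bearing = geo.initial_bearing_deg(lat[:-1], lon[:-1], lat[1:], lon[1:])
    dup = step[1:] <= 1e-9
    bearing[1:] = np.where(dup, np.nan, raw_bearing)
    if dup.any():
        logger.info("%d duplicate consecutive positions -> bearing/turn missing", int(dup.sum()))
    dt = ts.diff().dt.total_seconds().to_numpy()
    if interval is not None:
        dt = np.full(n, pd.Timedelta(interval).total_seconds())
        dt[0] = np.nan
    with np.errstate(invalid="ignore", divide="ignore"):
        speed = step * 1000.0 / dt
    turn[2:] = np.radians(geo.wrap_angle_deg180(bearing[2:] - bearing[1:-1]))
    out["step_km"] = step
    out["bearing_deg"] = bearing
    out["turn_rad"] = turn
    out["speed_ms"] = speed
    return out


def process_track(
    track: pd.DataFrame,
    colony,
    dist_threshold_km: float = 1.0,
    dur_threshold_min: float = 30.0,
    interval: str = "5min",
    max_gap: str = "30min",
    stage_fraction: float = 0.75,
) -> list[pd.DataFrame]:
    """Full chain: split -> regularize -> stage -> step metrics.

    Returns one staged, regularized DataFrame per trip with a ``trip_id``
    column '<individual>_<k>'.
    """
    indiv = str(track["individual_id"].iloc[0]) if "individual_id" in track else "bird01"
    trips = []
    for k, seg in enumerate(split_trips(track, colony, dist_threshold_km, dur_threshold_min)):
        reg = regularize(seg, interval=interval, max_gap=max_gap)
        reg["individual_id"] = indiv
        reg["trip_id"] = f"{indiv}_{k}"
        staged = label_stages(reg, colony, fraction=stage_fraction)
        trips.append(step_metrics(staged, interval=interval))
    return trips
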