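"""Synthetic tracks, environmental fields and accelerometer streams.

Every downstream stage of the pipeline is testable against known ground
truth generated here: multi-state correlated-random-walk foraging trips from
a colony, gridded hourly wind/wave fields on a 0.25 deg lattice (ERA5-style
layout), the two GPS sampling schemes used in the field (30-s regular fixes
and 1-Hz bursts of 15 s every 5 min), and 25 Hz tri-axial acceleration with
a 1 Hz temperature channel.

Wind selectivity is injected as a heading bias: during commute stages each
step's heading is, with probability equal to ``selectivity_strength``, drawn
from a von Mises centred on the local downwind direction. This is the
simplest mechanism that a used-available selectivity model must be able to
detect; with strength 0 commute headings carry no wind information.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr
from scipy import ndimage

from . import geo, hmm

GRID_SPACING_DEG = 0.25

BEHAVIOURS = ("flap", "glide", "dive", "sit", "takeoff")


# --------------------------------------------------------------------------- #
# wind / wave fields
# --------------------------------------------------------------------------- #


def _grid_axes(bbox):
    lat_min, lat_max, lon_min, lon_max = bbox
    lats = np.arange(lat_min, lat_max + 1e-9, GRID_SPACING_DEG)
    lons = np.arange(lon_min, lon_max + 1e-9, GRID_SPACING_DEG)
    if lats.size < 2 or lons.size < 2:
        raise ValueError("bbox must span at least 2 grid cells on each axis")
    return lats, lons


def _smooth_noise(shape, smoothness, rng):
    """Zero-mean unit-variance spatially/temporally smooth noise field."""
    raw = rng.standard_normal(shape)
    if smoothness > 0:
        raw = ndimage.gaussian_filter(raw, sigma=smoothness, mode="nearest")
        sd = raw.std()
        if sd > 0:
            raw = raw / sd
    return raw


def simulate_wind_field(
    bbox,
    time_span,
    mean_direction_from: float = 225.0,
    speed_range=(0.5, 11.8),
    smoothness: float = 2.0,
    direction_sd: float = 15.0,
    seed: int = 0,
) -> xr.Dataset:
    """Hourly 0.25-degree wind field (u10, v10) with a controllable regime.

    ``bbox`` is (lat_min, lat_max, lon_min, lon_max);  ``time_span`` a
    (start, end) pair accepted by pandas. Speeds fill ``speed_range``
    (m s^-1) and blow-from directions concentrate around
    ``mean_direction_from`` with circular spread ``direction_sd`` degrees.
    Regeneration with the same seed is bit-identical.
    """
    lo, hi = float(speed_range[0]), float(speed_range[1])
    if not (0 < lo <= hi <= 20):
        raise ValueError("speed_range must satisfy 0 < lo <= hi <= 20 m/s")
    lats, lons = _grid_axes(bbox)
    times = pd.date_range(time_span[0], time_span[1], freq="1h")
    rng = np.random.default_rng(seed)
    shape = (lats.size, lons.size, times.size)

    z = _smooth_noise(shape, smoothness, rng)
    # map smooth gaussian noise through its CDF onto the speed interval
    from scipy.stats import norm

    speed = lo + (hi - lo) * norm.cdf(z)
    dir_to = (mean_direction_from + 180.0 + direction_sd * _smooth_noise(shape, smoothness, rng)) % 360.0
    u = speed * np.sin(np.radians(dir_to))
    v = speed * np.cos(np.radians(dir_to))
    ds = xr.Dataset(
        {
            "u10": (("latitude", "longitude", "time"), u),
            "v10": (("latitude", "longitude", "time"), v),
        },
        coords={"latitude": lats, "longitude": lons, "time": times},
        attrs={
            "mean_direction_from": mean_direction_from,
            "speed_range": (lo, hi),
            "seed": seed,
        },
    )
    ds["u10"].attrs.update(units="m s-1", long_name="10 metre zonal wind")
    ds["v10"].attrs.update(units="m s-1", long_name="10 metre meridional wind")
    return ds


def simulate_wave_field(
    bbox,
    time_span,
    mean_direction_from: float = 225.0,
    swh_range=(0.5, 3.0),
    mwp_range=(4.0, 10.0),
    smoothness: float = 2.0,
    direction_sd: float = 20.0,
    seed: int = 1,
) -> xr.Dataset:
    """Wave field with significant height (swh, m), period (mwp, s) and mean
    direction (mwd, degrees, oceanographic blow-FROM convention)."""
    lats, lons = _grid_axes(bbox)
    times = pd.date_range(time_span[0], time_span[1], freq="1h")
    rng = np.random.default_rng(seed)
    shape = (lats.size, lons.size, times.size)
    from scipy.stats import norm

    swh = swh_range[0] + (swh_range[1] - swh_range[0]) * norm.cdf(_smooth_noise(shape, smoothness, rng))
    mwp = mwp_range[0] + (mwp_range[1] - mwp_range[0]) * norm.cdf(_smooth_noise(shape, smoothness, rng))
    mwd = (mean_direction_from + direction_sd * _smooth_noise(shape, smoothness, rng)) % 360.0
    ds = xr.Dataset(
        {
            "swh": (("latitude", "longitude", "time"), swh),
            "mwp": (("latitude", "longitude", "time"), mwp),
            "mwd": (("latitude", "longitude", "time"), mwd),
        },
        coords={"latitude": lats, "longitude": lons, "time": times},
        attrs={"seed": seed},
    )
    ds["swh"].attrs.update(units="m", long_name="significant wave height")
    ds["mwp"].attrs.update(units="s", long_name="mean wave period")
    ds["mwd"].attrs.update(units="degrees", long_name="mean wave direction (from)")
    return ds


# --------------------------------------------------------------------------- #
# trips
# --------------------------------------------------------------------------- #


@dataclass
class SimTruth:
    """Ground truth emitted alongside a simulated artefact."""

    states: np.ndarray | None = None
    emitted_steps: np.ndarray | None = None
    emitted_turns: np.ndarray | None = None
    hmm_params: "hmm.HMMParams | None" = None
    selectivity_strength: float = 0.0
    departure_bearing: float | None = None
    behaviour_schedule: list = field(default_factory=list)
    positions: pd.DataFrame | None = None


def _wind_to_direction_at(wind_field, lat, lon, when):
    """Downwind compass direction at the nearest cell/hour (degrees)."""
    from . import environment

    u, v = environment.nearest_cell_values(wind_field, lat, lon, when, ("u10", "v10"))
    _speed, dir_to = environment.wind_from_uv(u, v)
    return dir_to


def simulate_trip(
    colony,
    hmm_params: hmm.HMMParams,
    wind_field: xr.Dataset | None = None,
    selectivity_strength: float = 0.0,
    n_steps: int = 120,
    step_interval: str | pd.Timedelta = "5min",
    start_time="2022-02-01T06:00:00Z",
    departure_bearing: float | None = None,
    steer_out: float = 0.35,
    steer_in: float = 0.6,
    selectivity_kappa: float = 4.0,
    selectivity_stages: tuple = ("outbound", "inbound"),
    individual_id: str = "bird01",
    seed: int = 0,
) -> tuple[pd.DataFrame, SimTruth]:
    """One out-and-back foraging trip from the colony with known truth.

    Behavioural states evolve by the Markov chain in ``hmm_params``; step
    lengths and turning angles are drawn from the state emissions. Headings
    are steered: away from the colony along a (random, unless given)
    departure bearing for the first 40% of steps, free in the middle 20%,
    and back toward the colony thereafter; the trip ends when it re-reaches
    the colony (final fix snapped there). With ``selectivity_strength`` > 0
    each commute-stage heading (restricted to ``selectivity_stages``) is,
    with that probability, drawn from a von Mises centred downwind — a
    tailwind preference the selectivity model should detect.

    Returns (track DataFrame with individual_id/timestamp/lat/lon, SimTruth).
    """
    if n_steps < 20:
        raise ValueError("n_steps must be >= 20")
    if not (0.0 <= selectivity_strength <= 1.0):
        raise ValueError("selectivity_strength must lie in [0, 1]")
    if selectivity_strength > 0 and wind_field is None:
        raise ValueError("selectivity requires a wind field")
    for arr in (hmm_params.step_mean, hmm_params.step_sd, hmm_params.turn_kappa):
        if not np.all(np.isfinite(arr)):
            raise ValueError("hmm_params must be finite")

    rng = np.random.default_rng(seed)
    interval = pd.Timedelta(step_interval)
    start = pd.Timestamp(start_time)
    colony_lat, colony_lon = float(colony[0]), float(colony[1])
    if departure_bearing is None:
        departure_bearing = float(rng.uniform(0.0, 360.0))

    gamma = hmm.transition_matrix(hmm_params.beta[:, :1])
    delta = hmm.stationary_distribution(gamma)
    if np.any(~np.isfinite(delta)):
        delta = np.full(3, 1.0 / 3.0)
    shape, scale = hmm_params.gamma_shape_scale()

    n_out = int(0.4 * n_steps)
    n_mid = int(0.2 * n_steps)

    lat, lon = colony_lat, colony_lon
    heading = departure_bearing
    state = int(rng.choice(3, p=delta))
    lats, lons, states, steps_em, turns_em = [lat], [lon], [], [], []
    for t in range(n_steps):
        if t > 0:
            state = int(rng.choice(3, p=gamma[state]))
        step = float(rng.gamma(shape[state], scale[state]))
        turn = float(rng.vonmises(hmm_params.turn_mu[state], max(hmm_params.turn_kappa[state], 1e-8)))
        states.append(state)
        steps_em.append(step)
        turns_em.append(turn)

        crw = heading + np.degrees(turn)
        if t < n_out:
            stage, target, steer = "outbound", departure_bearing, steer_out
        elif t < n_out + n_mid:
            stage, target, steer = "middle", None, 0.0
        else:
            stage = "inbound"
            target = geo.initial_bearing_deg(lat, lon, colony_lat, colony_lon)
            steer = steer_in
        if target is None:
            heading = crw % 360.0
        else:
            heading = (crw + steer * geo.wrap_angle_deg180(target - crw)) % 360.0
        if (
            stage in selectivity_stages
            and stage in ("outbound", "inbound")
            and selectivity_strength > 0
            and rng.uniform() < selectivity_strength
        ):
            when = start + (t + 1) * interval
            wind_to = _wind_to_direction_at(wind_field, lat, lon, when)
            heading = float(np.degrees(rng.vonmises(np.radians(wind_to), selectivity_kappa))) % 360.0

        if stage == "inbound":
            dist_home = geo.haversine_km(lat, lon, colony_lat, colony_lon)
            if dist_home <= step:
                lats.append(colony_lat)
                lons.append(colony_lon)
                break
        lat, lon = (float(x) for x in geo.destination_point(lat, lon, heading, step))
        lats.append(lat)
        lons.append(lon)
    else:
        # ran out of steps before re-reaching the colony: close the loop
        lats.append(colony_lat)
        lons.append(colony_lon)
        states.append(states[-1])
        steps_em.append(float(geo.haversine_km(lats[-2], lons[-2], colony_lat, colony_lon)))
        turns_em.append(0.0)

    n_fix = len(lats)
    track = pd.DataFrame(
        {
            "individual_id": individual_id,
            "timestamp": [start + k * interval for k in range(n_fix)],
            "lat": lats,
            "lon": lons,
        }
    )
    truth = SimTruth(
        states=np.asarray(states),
        emitted_steps=np.asarray(steps_em),
        emitted_turns=np.asarray(turns_em),
        hmm_params=hmm_params,
        selectivity_strength=selectivity_strength,
        departure_bearing=departure_bearing,
        positions=track[["timestamp", "lat", "lon"]].copy(),
    )
    return track, truth


def densify(track: pd.DataFrame, interval_s: float = 5.0) -> pd.DataFrame:
    """Upsample a track to a fine time step by great-circle interpolation.

    Used to feed the GPS sampling schemes, which require input denser than
    the scheme they emulate.
    """
    ts = pd.to_datetime(track["timestamp"]).to_numpy()
    lat = track["lat"].to_numpy(dtype=float)
    lon = track["lon"].to_numpy(dtype=float)
    out_t, out_lat, out_lon = [], [], []
    for i in range(len(track) - 1):
        span = (ts[i + 1] - ts[i]) / np.timedelta64(1, "s")
        n_sub = max(1, int(round(span / interval_s)))
        fracs = np.arange(n_sub) / n_sub
        la, lo = geo.gc_interpolate(lat[i], lon[i], lat[i + 1], lon[i + 1], fracs)
        out_t.extend(ts[i] + (fracs * span * 1e9).astype("timedelta64[ns]"))
        out_lat.extend(la)
        out_lon.extend(lo)
    out_t.append(ts[-1])
    out_lat.append(lat[-1])
    out_lon.append(lon[-1])
    return pd.DataFrame(
        {
            "individual_id": track["individual_id"].iloc[0] if "individual_id" in track else "bird01",
            "timestamp": out_t,
            "lat": out_lat,
            "lon": out_lon,
        }
    )


def simulate_gps_sampling(
    track: pd.DataFrame,
    scheme: str = "regular_30s",
    dropout_rate: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Resample a dense track under one of the two field sampling schemes.

    ``regular_30s`` emits one fix every 30 s; ``burst_1Hz_15s_per_5min``
    emits 15 fixes at 1 Hz at the start of every 5-min window. Dropout
    removes individual fixes (regular scheme) or whole bursts (burst scheme)
    with the given probability; reproducible under ``seed``.
    """
    if not (0.0 <= dropout_rate < 1.0):
        raise ValueError("dropout_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    ts = pd.to_datetime(track["timestamp"])
    t0, t1 = ts.iloc[0], ts.iloc[-1]
    span_s = (t1 - t0).total_seconds()
    median_dt = np.median(np.diff(ts.to_numpy()) / np.timedelta64(1, "s"))

    if scheme == "regular_30s":
        if median_dt > 30.0:
            raise ValueError("input track must be denser than the 30-s scheme")
        sample_times = [t0 + pd.Timedelta(seconds=30.0 * k) for k in range(int(span_s // 30) + 1)]
        keep = rng.uniform(size=len(sample_times)) >= dropout_rate
        sample_times = [t for t, k in zip(sample_times, keep) if k]
    elif scheme == "burst_1Hz_15s_per_5min":
        if median_dt > 1.0:
            raise ValueError("input track must be denser than the 1-Hz burst scheme")
        sample_times = []
        k = 0
        while True:
            burst_start = t0 + pd.Timedelta(seconds=300.0 * k)
            if (burst_start + pd.Timedelta(seconds=14) - t0).total_seconds() > span_s:
                break
            if rng.uniform() >= dropout_rate:
                sample_times.extend(burst_start + pd.Timedelta(seconds=j) for j in range(15))
            k += 1
        sample_times = [t for t in sample_times if t <= t1]
    else:
        raise ValueError(f"unknown scheme '{scheme}'")

    lat = track["lat"].to_numpy(dtype=float)
    lon = track["lon"].to_numpy(dtype=float)
    tnum = (ts - t0).dt.total_seconds().to_numpy()
    out_lat, out_lon = [], []
    for t in sample_times:
        x = (t - t0).total_seconds()
        i = int(np.clip(np.searchsorted(tnum, x, side="right") - 1, 0, len(tnum) - 2))
        denom = tnum[i + 1] - tnum[i]
        f = 0.0 if denom <= 0 else np.clip((x - tnum[i]) / denom, 0.0, 1.0)
        la, lo = geo.gc_interpolate(lat[i], lon[i], lat[i + 1], lon[i + 1], [f])
        out_lat.append(float(la[0]))
        out_lon.append(float(lo[0]))
    return pd.DataFrame(
        {
            "individual_id": track["individual_id"].iloc[0] if "individual_id" in track else "bird01",
            "timestamp": sample_times,
            "lat": out_lat,
            "lon": out_lon,
        }
    )


# --------------------------------------------------------------------------- #
# accelerometry
# --------------------------------------------------------------------------- #

#: per-behaviour signal archetypes; amplitudes in g, frequencies in Hz.
DEFAULT_ACCEL_PARAMS = {
    "flap": {"heave_amp": 1.0, "surge_amp": 0.3, "freq": 4.0, "noise": 0.10, "wet": False},
    "glide": {"heave_amp": 0.0, "surge_amp": 0.0, "freq": 0.0, "noise": 0.05, "wet": False},
    "sit": {"heave_amp": 0.05, "surge_amp": 0.02, "freq": 0.3, "noise": 0.03, "wet": True},
    "dive": {"heave_amp": 1.5, "surge_amp": 0.8, "freq": 2.0, "noise": 0.15, "wet": True},
    "takeoff": {"heave_amp": 1.8, "surge_amp": 0.6, "freq": 5.0, "noise": 0.15, "wet": False},
}
_TEMP_DRY_C = 30.0
_TEMP_WET_C = 24.0


def simulate_accel(
    schedule,
    rate: int = 25,
    orientation_offset: float = 0.0,
    params: dict | None = None,
    start_time="2022-02-01T06:00:00Z",
    seed: int = 0,
) -> pd.DataFrame:
    """25 Hz tri-axial acceleration stream for a per-second behaviour schedule.

    Flapping and take-off are sinusoidal heave oscillations (take-off larger
    and faster), gliding is near-static (0, 0, 1) g, sitting is near-static
    with the temperature channel dropping (wet logger), diving adds a
    transient heave/surge spike with a temperature drop. The whole stream is
    rigidly rotated by ``orientation_offset`` degrees about the sway axis to
    exercise downstream axis standardization. Temperature is emitted at 1 Hz
    (repeated across each second's samples).
    """
    schedule = list(schedule)
    if not schedule:
        raise ValueError("schedule must be non-empty")
    unknown = set(schedule) - set(BEHAVIOURS)
    if unknown:
        raise ValueError(f"unknown behaviour labels: {sorted(unknown)}")
    p = dict(DEFAULT_ACCEL_PARAMS)
    if params:
        p = {k: {**p[k], **params.get(k, {})} for k in p}
    rng = np.random.default_rng(seed)

    n_sec = len(schedule)
    n = n_sec * rate
    t_rel = np.arange(n) / rate
    surge = np.zeros(n)
    sway = np.zeros(n)
    heave = np.ones(n)
    temp = np.empty(n)
    current_temp = _TEMP_DRY_C
    for s, label in enumerate(schedule):
        sl = slice(s * rate, (s + 1) * rate)
        cfg = p[label]
        tt = t_rel[sl]
        phase = rng.uniform(0, 2 * np.pi)
        if label == "dive":
            # transient spike in the first ~0.4 s of the second
            env = np.exp(-((tt - tt[0]) / 0.15))
            heave[sl] += cfg["heave_amp"] * env * np.sin(2 * np.pi * cfg["freq"] * tt + phase)
            surge[sl] += cfg["surge_amp"] * env * np.cos(2 * np.pi * cfg["freq"] * tt + phase)
        elif cfg["freq"] > 0:
            heave[sl] += cfg["heave_amp"] * np.sin(2 * np.pi * cfg["freq"] * tt + phase)
            surge[sl] += cfg["surge_amp"] * np.sin(2 * np.pi * cfg["freq"] * tt + phase + np.pi / 2)
        if cfg["noise"] > 0:
            surge[sl] += rng.normal(0, cfg["noise"], rate)
            sway[sl] += rng.normal(0, cfg["noise"], rate)
            heave[sl] += rng.normal(0, cfg["noise"], rate)
        target = _TEMP_WET_C if cfg["wet"] else _TEMP_DRY_C
        current_temp += 0.6 * (target - current_temp)
        temp[sl] = current_temp

    if orientation_offset != 0.0:
        th = np.radians(orientation_offset)
        surge, heave = (
            surge * np.cos(th) - heave * np.sin(th),
            surge * np.sin(th) + heave * np.cos(th),
        )

    start = pd.Timestamp(start_time)
    stamps = start + pd.to_timedelta((t_rel * 1e9).astype("int64"), unit="ns")
    return pd.DataFrame({"timestamp": stamps, "ax": surge, "ay": sway, "az": heave, "temp": temp})


def schedule_from_states(states, seconds_per_step: int = 300, seed: int = 0) -> list[str]:
    """Plausible per-second behaviour schedule for a sequence of HMM states.

    Travelling seconds alternate flap/glide bouts; feeding mixes flight with
    dives and brief sits (with take-offs after each water contact); resting is
    sitting. Purely a convenience for end-to-end synthetic runs.
    """
    rng = np.random.default_rng(seed)
    out: list[str] = []
    for st in states:
        sec = 0
        while sec < seconds_per_step:
            if st == 2:  # resting
                bout = min(int(rng.integers(20, 60)), seconds_per_step - sec)
                out.extend(["sit"] * bout)
            elif st == 1:  # travelling
                bout = min(int(rng.integers(3, 10)), seconds_per_step - sec)
                out.extend([("flap" if rng.uniform() < 0.45 else "glide")] * bout)
            else:  # feeding
                u = rng.uniform()
                if u < 0.1:
                    out.extend(["dive", "takeoff"])
                    bout = 2
                elif u < 0.3:
                    bout = min(int(rng.integers(3, 8)), seconds_per_step - sec)
                    out.extend(["sit"] * bout)
                else:
                    bout = min(int(rng.integers(2, 6)), seconds_per_step - sec)
                    out.extend([("flap" if rng.uniform() < 0.6 else "glide")] * bout)
            sec += bout
    return out[: len(states) * seconds_per_step]


# --------------------------------------------------------------------------- #
# I/O
# --------------------------------------------------------------------------- #


def write_tracks_csv(tracks: pd.DataFrame, path) -> None:
    """Track CSV: individual_id, ISO-8601 UTC timestamp, lat, lon."""
    out = tracks.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S.%f%z")
    out.to_csv(path, index=False)


def read_tracks_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["timestamp"] = pd.to_datetime(df["timestamp"], format="ISO8601")
    return df


def write_field_netcdf(field: xr.Dataset, path) -> None:
    """CF-style NetCDF with latitude/longitude/time coordinates."""
    enc = {v: {"zlib": False} for v in field.data_vars}
    field.to_netcdf(path, encoding=enc)


def read_field_netcdf(path) -> xr.Dataset:
    return xr.load_dataset(path)
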