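"""Stage orchestration: one-command synthetic reproduction, file I/O, provenance.

Each stage is a pure function of its input files, the config and its seed,
so re-running a stage with the same inputs reproduces its outputs exactly.
Every output CSV/JSON gets a ``<name>.meta.json`` sidecar recording the
stage, config hash and seeds. CSV/JSON are the contract; figures are out of
scope here.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import accel as accel_mod
from . import config as config_mod
from . import environment, gam, hmm, rotation, simulate, tracks

logger = logging.getLogger(__name__)


def _write_meta(path: Path, stage: str, cfg: dict, extra: dict | None = None) -> None:
    meta = {
        "stage": stage,
        "config_hash": config_mod.config_hash(cfg),
        "seeds": {k: v.get("seed") for k, v in cfg.items() if isinstance(v, dict) and "seed" in v},
    }
    if extra:
        meta.update(extra)
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=1, default=str))


def stage_simulate(cfg: dict, outdir: Path) -> dict:
    """Wind/wave fields (NetCDF) + synthetic trips (CSV) + truth (JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = cfg["simulate"]
    colony = (cfg["colony"]["lat"], cfg["colony"]["lon"])
    wind = simulate.simulate_wind_field(
        sim["bbox"], sim["time_span"], seed=sim["seed"], **sim["wind"]
    )
    wave = simulate.simulate_wave_field(sim["bbox"], sim["time_span"], seed=sim["seed"] + 1)
    simulate.write_field_netcdf(wind, outdir / "wind.nc")
    simulate.write_field_netcdf(wave, outdir / "wave.nc")

    params = hmm.reference_params()
    frames, truths = [], {}
    for k in range(sim["n_trips"]):
        track, truth = simulate.simulate_trip(
            colony,
            params,
            wind_field=wind,
            selectivity_strength=sim["selectivity_strength"],
            n_steps=sim["n_steps"],
            start_time=pd.Timestamp(sim["time_span"][0]) + pd.Timedelta(hours=6 + 24 * (k % 8)),
            individual_id=f"bird{k:02d}",
            seed=sim["seed"] * 1000 + k,
        )
        frames.append(track)
        truths[f"bird{k:02d}"] = {
            "states": truth.states.tolist(),
            "departure_bearing": truth.departure_bearing,
            "selectivity_strength": truth.selectivity_strength,
        }
    all_tracks = pd.concat(frames, ignore_index=True)
    simulate.write_tracks_csv(all_tracks, outdir / "tracks.csv")
    (outdir / "truth.json").write_text(json.dumps(truths))
    _write_meta(outdir / "tracks.csv", "simulate", cfg)
    return {"tracks": outdir / "tracks.csv", "wind": outdir / "wind.nc", "wave": outdir / "wave.nc"}


def stage_trips(cfg: dict, outdir: Path, tracks_csv=None) -> dict:
    """Split/regularize/stage/step-metric every deployment into trips."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tracks_csv = Path(tracks_csv or outdir / "tracks.csv")
    colony = (cfg["colony"]["lat"], cfg["colony"]["lon"])
    t = cfg["trips"]
    try:
        raw = simulate.read_tracks_csv(tracks_csv)
    except pd.errors.EmptyDataError:
        raw = pd.DataFrame(columns=["individual_id", "timestamp", "lat", "lon"])
    all_trips = []
    for _ind, track in raw.groupby("individual_id") if len(raw) else []:
        all_trips.extend(
            tracks.process_track(
                track.reset_index(drop=True),
                colony,
                dist_threshold_km=t["dist_threshold_km"],
                dur_threshold_min=t["dur_threshold_min"],
                interval=t["interval"],
                max_gap=t["max_gap"],
                stage_fraction=t["stage_fraction"],
            )
        )
    if not all_trips:
        logger.warning("no trips found in %s", tracks_csv)
        out = pd.DataFrame(
            columns=["trip_id", "individual_id", "timestamp", "lat", "lon", "stage",
                     "colony_dist_km", "step_km", "turn_rad", "bearing_deg", "speed_ms", "interp_flag"]
        )
    else:
        out = pd.concat(all_trips, ignore_index=True)
    out.to_csv(outdir / "trips.csv", index=False)
    _write_meta(outdir / "trips.csv", "trips", cfg, {"n_trips": len(all_trips)})
    return {"trips": outdir / "trips.csv", "n_trips": len(all_trips)}


def stage_rotate(cfg: dict, outdir: Path, trips_csv=None) -> dict:
    """Rotated null legs for every trip."""
    outdir = Path(outdir)
    trips_csv = Path(trips_csv or outdir / "trips.csv")
    trips_df = pd.read_csv(trips_csv, parse_dates=["timestamp"])
    colony = (cfg["colony"]["lat"], cfg["colony"]["lon"])
    rot = cfg["rotation"]
    frames = []
    for k, (_tid, trip) in enumerate(trips_df.groupby("trip_id")):
        nulls = rotation.generate_null(trip, colony, n_rotations=rot["n_rotations"], seed=rot["seed"] + k)
        for leg, legs in nulls.items():
            for j, r in enumerate(legs):
                r = r.copy()
                r["null_id"] = f"{r['trip_id'].iloc[0]}_{leg}_{j}"
                frames.append(r)
    nulls_df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    nulls_df.to_csv(outdir / "null_routes.csv", index=False)
    _write_meta(outdir / "null_routes.csv", "rotate", cfg)
    return {"null_routes": outdir / "null_routes.csv"}


def build_selectivity_table(
    staged_trips: list[pd.DataFrame],
    colony,
    wind_field,
    wave_field=None,
    n_rotations: int = 20,
    ratio: int = 10,
    seed: int = 0,
    interval: str = "5min",
) -> pd.DataFrame:
    """Used-available table straight from staged trips with step metrics.

    Per trip and commute leg: annotate the observed leg, generate
    ``n_rotations`` rotated alternatives, subsample ``ratio`` of them, give
    each fresh step metrics (bearings rotate with the leg) and environmental
    annotation, then assemble the per-stratum weighted table.
    """
    rng = np.random.default_rng(seed)
    observed, rotated = [], []
    for k, trip in enumerate(staged_trips):
        ann_obs = environment.annotate_trip(trip, wind_field, wave_field)
        nulls = rotation.generate_null(trip, colony, n_rotations=n_rotations, seed=seed + 7919 * k)
        for leg in rotation.LEGS:
            if "rwd" not in ann_obs.columns:
                continue
            obs_leg = ann_obs[(ann_obs["stage"] == leg) & np.isfinite(ann_obs["rwd"])]
            alts_all = nulls[leg]
            if obs_leg.empty or not alts_all:
                continue
            if len(alts_all) > ratio:
                pick = rng.choice(len(alts_all), size=ratio, replace=False)
                alts_all = [alts_all[i] for i in pick]
            alts = []
            for alt in alts_all:
                alt = tracks.step_metrics(alt, interval=interval)
                alt = environment.annotate_trip(alt, wind_field, wave_field)
                alt = alt[np.isfinite(alt["rwd"])]
                if not alt.empty:
                    alts.append(alt)
            if alts:
                observed.append(obs_leg)
                rotated.append(alts)
    if not observed:
        return pd.DataFrame()
    return rotation.build_used_available(observed, rotated, ratio=ratio, seed=seed)


def stage_annotate(cfg: dict, outdir: Path) -> dict:
    """Join wind/wave to observed trips; build the used-available table."""
    outdir = Path(outdir)
    wind = simulate.read_field_netcdf(outdir / "wind.nc")
    wave = simulate.read_field_netcdf(outdir / "wave.nc")
    trips_df = pd.read_csv(outdir / "trips.csv", parse_dates=["timestamp"])
    rot = cfg["rotation"]
    colony = (cfg["colony"]["lat"], cfg["colony"]["lon"])

    staged = [t.reset_index(drop=True) for _tid, t in trips_df.groupby("trip_id")]
    ann_trips = [environment.annotate_trip(t, wind, wave) for t in staged]
    ann = pd.concat(ann_trips, ignore_index=True) if ann_trips else trips_df
    ann.to_csv(outdir / "trips_annotated.csv", index=False)

    table = build_selectivity_table(
        staged, colony, wind, wave,
        n_rotations=rot["n_rotations"], ratio=rot["ratio"], seed=rot["seed"],
        interval=cfg["trips"]["interval"],
    )
    table.to_csv(outdir / "used_available.csv", index=False)
    _write_meta(outdir / "used_available.csv", "annotate", cfg)
    return {"used_available": outdir / "used_available.csv", "trips_annotated": outdir / "trips_annotated.csv"}


def stage_hmm(cfg: dict, outdir: Path) -> dict:
    """Fit the movement HMM to annotated trips; decode states."""
    outdir = Path(outdir)
    ann = pd.read_csv(outdir / "trips_annotated.csv", parse_dates=["timestamp"])
    h = cfg["hmm"]
    data = ann.dropna(subset=["step_km", "turn_rad"]).copy()
    fit = hmm.fit(data, tuple(h["formula"]), n_starts=h["n_starts"], seed=h["seed"])
    states = hmm.viterbi(fit, data)
    data["state"] = np.array(hmm.STATE_NAMES)[states]
    data.to_csv(outdir / "trips_states.csv", index=False)
    result = {
        "formula": list(fit.formula),
        "neg_log_lik": fit.neg_log_lik,
        "aic": fit.aic,
        "n_parameters": fit.n_parameters,
        "converged": fit.converged,
        "step_mean_km": fit.params.step_mean.tolist(),
        "step_sd_km": fit.params.step_sd.tolist(),
        "turn_mu_rad": fit.params.turn_mu.tolist(),
        "turn_kappa": fit.params.turn_kappa.tolist(),
        "beta": fit.params.beta.tolist(),
        "state_order": list(hmm.STATE_NAMES),
    }
    (outdir / "hmm_fit.json").write_text(json.dumps(result, indent=1))
    _write_meta(outdir / "hmm_fit.json", "hmm", cfg)
    return {"hmm_fit": outdir / "hmm_fit.json", "trips_states": outdir / "trips_states.csv"}


def stage_gam(cfg: dict, outdir: Path) -> dict:
    """Selectivity model per commute leg: AUC and prediction surface."""
    outdir = Path(outdir)
    table = pd.read_csv(outdir / "used_available.csv")
    g = cfg["gam"]
    results = {}
    for leg in rotation.LEGS:
        sub = table[table["stage"] == leg]
        if sub.empty or sub["used"].nunique() < 2:
            continue
        spec = gam.GAMSpec(
            family="bernoulli", response="used", x1="ws", x2="rwd",
            knots=g["knots"], weights="weight", individual="individual_id", trip="trip_id",
        )
        fit = gam.fit_gam(sub, spec, seed=g["seed"])
        ws_grid = np.linspace(sub["ws"].quantile(0.05), sub["ws"].quantile(0.95), 25)
        rwd_grid = np.linspace(0, 180, 37)
        surface, _ = gam.predict_surface(fit, ws_grid, rwd_grid)
        pd.DataFrame(surface, index=rwd_grid, columns=np.round(ws_grid, 3)).to_csv(
            outdir / f"selectivity_surface_{leg}.csv"
        )
        results[leg] = {"auc": fit.auc, "edf": fit.edf, "lambda": fit.lam, "n": fit.n_obs}
    (outdir / "gam_results.json").write_text(json.dumps(results, indent=1))
    _write_meta(outdir / "gam_results.json", "gam", cfg)
    return {"gam_results": outdir / "gam_results.json"}


def stage_accel(cfg: dict, outdir: Path, stream_csv=None, labels_csv=None) -> dict:
    """Train the behaviour classifier on labelled segments; report recall."""
    outdir = Path(outdir)
    a = cfg["accel"]
    stream = pd.read_csv(stream_csv)
    stream["timestamp"] = pd.to_datetime(stream["timestamp"], format="ISO8601")
    labelled = pd.read_csv(labels_csv)
    model, recall = accel_mod.train_classifier(
        labelled, n_trees=a["n_trees"], vars_per_node=a["vars_per_node"], seed=a["seed"]
    )
    feats = accel_mod.segment_features(stream)
    feats["label"] = accel_mod.logic_correct(accel_mod.predict_labels(model, feats))
    feats.to_csv(outdir / "accel_labels.csv", index=False)
    recall.to_csv(outdir / "accel_recall.csv", index=False)
    _write_meta(outdir / "accel_labels.csv", "accel", cfg)
    return {"accel_labels": outdir / "accel_labels.csv", "recall": outdir / "accel_recall.csv"}


def stage_report(cfg: dict, outdir: Path) -> dict:
    """Aggregate stage outputs into one JSON summary with full provenance."""
    outdir = Path(outdir)
    report: dict = {
        "config": cfg,
        "config_hash": config_mod.config_hash(cfg),
        "seeds": {k: v.get("seed") for k, v in cfg.items() if isinstance(v, dict) and "seed" in v},
    }
    trips_path = outdir / "trips.csv"
    if trips_path.exists():
        trips_df = pd.read_csv(trips_path)
        report["n_trips"] = int(trips_df["trip_id"].nunique()) if len(trips_df) else 0
        if len(trips_df):
            report["stage_fix_counts"] = trips_df["stage"].value_counts().to_dict()
    for name in ("hmm_fit", "gam_results"):
        p = outdir / f"{name}.json"
        if p.exists():
            report[name] = json.loads(p.read_text())
    (outdir / "report.json").write_text(json.dumps(report, indent=1, default=str))
    return {"report": outdir / "report.json"}


STAGES = {
    "simulate": stage_simulate,
    "trips": stage_trips,
    "rotate": stage_rotate,
    "annotate": stage_annotate,
    "hmm": stage_hmm,
    "gam": stage_gam,
    "report": stage_report,
}


def run(stage: str, cfg: dict, outdir) -> dict:
    """Run one pipeline stage by name into ``outdir``."""
    if stage not in STAGES and stage != "accel":
        raise ValueError(f"unknown stage '{stage}'; choose from {sorted(STAGES)} or 'accel'")
    fn = STAGES.get(stage, stage_accel)
    return fn(cfg, Path(outdir))
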