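"""Pipeline configuration: defaults, validation, provenance hashing."""

from __future__ import annotations

import copy
import hashlib
import json

import yaml

DEFAULT_CONFIG: dict = {
    "colony": {"lat": -7.23, "lon": 72.42},
    "simulate": {
        "n_trips": 8,
        "n_steps": 120,
        "selectivity_strength": 0.0,
        "bbox": [-10.0, -4.0, 69.0, 76.0],
        "time_span": ["2022-02-01", "2022-02-10"],
        "wind": {"mean_direction_from": 315.0, "speed_range": [0.5, 11.8], "smoothness": 2.0},
        "seed": 1,
    },
    "trips": {
        "dist_threshold_km": 1.0,
        "dur_threshold_min": 30.0,
        "interval": "5min",
        "max_gap": "30min",
        "stage_fraction": 0.75,
    },
    "rotation": {"n_rotations": 20, "ratio": 10, "seed": 2},
    "hmm": {"n_starts": 25, "formula": [], "seed": 3},
    "gam": {"knots": 4, "seed": 4},
    "accel": {"n_trees": 10000, "vars_per_node": 5, "seed": 5},
}


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Defaults, overlaid with a YAML file and then explicit overrides."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        _merge(cfg, user)
    if overrides:
        _merge(cfg, overrides)
    validate(cfg)
    return cfg


def _merge(base: dict, extra: dict) -> None:
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _merge(base[k], v)
        else:
            base[k] = v


def validate(cfg: dict) -> None:
    t = cfg["trips"]
    for key in ("dist_threshold_km", "dur_threshold_min", "stage_fraction"):
        if not t[key] > 0:
            raise ValueError(f"trips.{key} must be positive")
    if cfg["rotation"]["n_rotations"] < 0 or cfg["rotation"]["ratio"] < 1:
        raise ValueError("rotation.n_rotations must be >= 0 and rotation.ratio >= 1")
    if cfg["hmm"]["n_starts"] < 1:
        raise ValueError("hmm.n_starts must be >= 1")
    if abs(cfg["colony"]["lat"]) > 90:
        raise ValueError("colony.lat out of range")


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:12]
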