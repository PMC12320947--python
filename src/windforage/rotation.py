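"""Rotation-based null routes and the weighted used-available table.

Availability for the route-selection analysis is generated by rigidly
rotating each observed commute leg (outbound or inbound) about the colony by
random angles: rotation about the Earth-centre axis through the colony is an
exact isometry, so every rotated fix keeps its colony distance and the leg
keeps its internal geometry, while the wind it samples changes. Timestamps
are inherited unchanged (same times, different places). The used-available
table pairs each observed leg with a subsample of its rotated alternatives
and weights rows so used and available carry equal total weight within each
trip-by-leg stratum.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import geo

logger = logging.getLogger(__name__)

LEGS = ("outbound", "inbound")


def rotate_leg(leg_fixes: pd.DataFrame, colony, angle: float) -> pd.DataFrame:
    """Rotate a leg's fixes rigidly about the colony axis by ``angle`` degrees.

    Spherical (Rodrigues) rotation of ECEF vectors about the axis through
    the colony and the Earth's centre; colony distances and inter-fix
    distances are preserved to well under a metre. Timestamps and identifier
    columns are carried through; a ``rotation_angle`` column is added.
    """
    if not (0.0 <= angle < 360.0):
        raise ValueError("angle must lie in [0, 360)")
    axis = geo.latlon_to_ecef(colony[0], colony[1])
    vecs = geo.latlon_to_ecef(leg_fixes["lat"].to_numpy(dtype=float), leg_fixes["lon"].to_numpy(dtype=float))
    if np.any(vecs @ axis < -1.0 + 1e-12):
        raise ValueError("fix antipodal to the colony cannot be rotated stably")
    rot = geo.rotate_about_axis(vecs, axis, angle)
    lat, lon = geo.ecef_to_latlon(rot)
    out = leg_fixes.copy().reset_index(drop=True)
    out["lat"] = lat
    out["lon"] = lon
    out["rotation_angle"] = angle
    return out


def generate_null(
    staged_trip: pd.DataFrame,
    colony,
    n_rotations: int = 20,
    seed: int = 0,
) -> dict[str, list[pd.DataFrame]]:
    """Null routes: ``n_rotations`` uniformly rotated copies of each commute leg.

    Angles are i.i.d. uniform on [0, 360) per leg, reproducible under
    ``seed``. A missing stage is skipped with a warning. Returns
    {'outbound': [...], 'inbound': [...]}.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, list[pd.DataFrame]] = {}
    for leg in LEGS:
        sel = staged_trip[staged_trip["stage"] == leg]
        if sel.empty:
            logger.warning("trip %s has no %s stage; skipping",
                           staged_trip.get("trip_id", pd.Series(["?"])).iloc[0], leg)
            out[leg] = []
            continue
        angles = rng.uniform(0.0, 360.0, size=n_rotations)
        out[leg] = [rotate_leg(sel, colony, float(a)) for a in angles]
    return out


def build_used_available(
    observed_legs: list[pd.DataFrame],
    rotated_legs: list[list[pd.DataFrame]],
    ratio: int = 10,
    seed: int = 0,
    weighting: str = "stratum",
) -> pd.DataFrame:
    """Assemble the weighted used-available table (one row per fix).

    ``observed_legs[k]`` is an env-annotated observed leg (columns ws, rwd,
    individual_id, trip_id, stage); ``rotated_legs[k]`` its annotated
    rotated alternatives. Per stratum (one observed leg), ``ratio`` rotated
    legs are subsampled without replacement (all of them, with a warning, if
    fewer are available). Weights make used and available rows carry equal
    total weight within each stratum (``weighting='stratum'``) or across the
    whole table (``'global'``).
    """
    if len(observed_legs) != len(rotated_legs):
        raise ValueError("observed_legs and rotated_legs must align")
    rng = np.random.default_rng(seed)
    rows = []
    for k, (obs, alts) in enumerate(zip(observed_legs, rotated_legs)):
        if len(alts) > ratio:
            pick = rng.choice(len(alts), size=ratio, replace=False)
            chosen = [alts[i] for i in pick]
        else:
            if len(alts) < ratio:
                logger.warning("stratum %d has %d < ratio=%d rotated legs; using all",
                               k, len(alts), ratio)
            chosen = list(alts)
        stratum = f"s{k}"
        o = obs.copy()
        o["used"] = 1
        o["stratum"] = stratum
        rows.append(o)
        for alt in chosen:
            a = alt.copy()
            a["used"] = 0
            a["stratum"] = stratum
            rows.append(a)
    table = pd.concat(rows, ignore_index=True)

    table["weight"] = 1.0
    if weighting == "stratum":
        for s, grp in table.groupby("stratum"):
            n_avail = (grp["used"] == 0).sum()
            n_used = (grp["used"] == 1).sum()
            if n_used and n_avail:
                table.loc[grp.index[grp["used"] == 1], "weight"] = n_avail / n_used
    elif weighting == "global":
        n_avail = (table["used"] == 0).sum()
        n_used = (table["used"] == 1).sum()
        table.loc[table["used"] == 1, "weight"] = n_avail / max(n_used, 1)
    else:
        raise ValueError("weighting must be 'stratum' or 'global'")
    return table


def tune_ratio(
    fit_fn,
    observed_legs,
    rotated_legs,
    ratios=(1, 5, 10, 15, 20),
    seed: int = 0,
) -> tuple[int, pd.DataFrame]:
    """AUC sweep over candidate available:used ratios.

    ``fit_fn(table) -> auc`` fits the selectivity model and returns its AUC;
    the ratio maximizing AUC wins (ties to the smaller ratio). Reproducible
    under ``seed``.
    """
    rows = []
    for r in ratios:
        table = build_used_available(observed_legs, rotated_legs, ratio=r, seed=seed)
        rows.append({"ratio": r, "auc": float(fit_fn(table))})
    sweep = pd.DataFrame(rows)
    best = int(sweep.loc[sweep["auc"].idxmax(), "ratio"])
    return best, sweep
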