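"""Behaviour classification from 25 Hz tri-axial acceleration.

The chain mirrors standard biologging practice: standardize device
orientation so the static (gravity) vector sits at (0, 0, 1) g, split each
axis into a static (running-mean) and dynamic component, summarize 1-s
segments into a feature vector (ODBA, VeDBA, pitch/roll statistics,
per-axis moments and extremes, temperature), classify five behaviours
(flapping flight, gliding flight, diving, sitting on water, take-off) with
a random forest, clean contextually impossible single-second labels, and
summarize flight into a per-fix flapping proportion.

Axis conventions: ax = surge (anterior-posterior), ay = sway (lateral),
az = heave (dorso-ventral). Pitch = atan2(static_x, sqrt(static_y^2 +
static_z^2)); roll = atan2(static_y, static_z), both from the static
component.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

logger = logging.getLogger(__name__)

FLIGHT_LABELS = ("flap", "glide")
FEATURE_COLUMNS = (
    "mean_odba", "mean_vedba",
    "mean_roll", "sd_roll", "mean_pitch", "sd_pitch",
    "mean_surge", "sd_surge", "min_surge", "max_surge",
    "mean_sway", "sd_sway", "min_sway", "max_sway",
    "mean_heave", "sd_heave", "min_heave", "max_heave",
    "mean_temp",
)
# effort (ODBA/VeDBA), posture (roll/pitch moments), per-axis summaries, temperature


def standardize_axes(stream: pd.DataFrame, rate: int = 25, low_dyn_quantile: float = 0.25):
    """Rotate the stream so the static gravity vector is (0, 0, 1) g.

    The orientation is estimated from the median acceleration vector over
    the lowest-dynamic windows (bottom ``low_dyn_quantile`` of 1-s VeDBA);
    the rotation is the orthonormal map taking that vector onto +Z. Returns
    (rotated stream, rotation matrix). Raises if no low-dynamic window
    exists (streams shorter than 10 s cannot be calibrated).
    """
    n_sec = len(stream) // rate
    if n_sec < 10:
        raise ValueError("need >= 10 s of data to estimate orientation; supply the rotation manually")
    acc = stream[["ax", "ay", "az"]].to_numpy(dtype=float)[: n_sec * rate]
    static, dynamic = _running_mean_split(acc, rate, window_s=2.0)
    vedba_1s = np.linalg.norm(dynamic, axis=1).reshape(n_sec, rate).mean(axis=1)
    cut = np.quantile(vedba_1s, low_dyn_quantile)
    quiet = np.flatnonzero(vedba_1s <= cut)
    if quiet.size == 0:
        raise ValueError("no low-dynamic window found; supply the rotation manually")
    sample = acc.reshape(n_sec, rate, 3)[quiet].reshape(-1, 3)
    g_vec = np.median(sample, axis=0)
    g_vec = g_vec / np.linalg.norm(g_vec)
    rot = _rotation_to_z(g_vec)
    out = stream.copy()
    out[["ax", "ay", "az"]] = stream[["ax", "ay", "az"]].to_numpy(dtype=float) @ rot.T
    return out, rot


def _rotation_to_z(v: np.ndarray) -> np.ndarray:
    """Orthonormal rotation taking unit vector v onto (0, 0, 1)."""
    z = np.array([0.0, 0.0, 1.0])
    c = float(np.clip(np.dot(v, z), -1.0, 1.0))
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        return np.diag([1.0, -1.0, -1.0])
    axis = np.cross(v, z)
    s = np.linalg.norm(axis)
    axis = axis / s
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + s * k + (1 - c) * (k @ k)


def _running_mean_split(acc: np.ndarray, rate: int, window_s: float = 2.0):
    win = max(1, int(round(window_s * rate)))
    kernel = np.ones(win) / win
    pad = win // 2
    static = np.empty_like(acc)
    for a in range(3):
        padded = np.pad(acc[:, a], pad, mode="edge")
        sm = np.convolve(padded, kernel, mode="same")[pad : pad + len(acc)]
        static[:, a] = sm
    return static, acc - static


def split_static_dynamic(stream: pd.DataFrame, rate: int = 25, window_s: float = 2.0):
    """Centred running-mean split: static + dynamic = raw exactly."""
    acc = stream[["ax", "ay", "az"]].to_numpy(dtype=float)
    if len(acc) <= int(window_s * rate):
        raise ValueError("stream shorter than the smoothing window")
    static, dynamic = _running_mean_split(acc, rate, window_s)
    return static, dynamic


def segment_features(
    stream: pd.DataFrame,
    rate: int = 25,
    segment_s: float = 1.0,
    window_s: float = 2.0,
) -> pd.DataFrame:
    """1-s feature vectors: ODBA, VeDBA, posture and per-axis summaries.

    ODBA = mean(|dx| + |dy| + |dz|) and VeDBA = mean(sqrt(dx^2 + dy^2 +
    dz^2)) over the dynamic component; pitch and roll come from the static
    component. A trailing partial segment is dropped.
    """
    seg_len = int(round(segment_s * rate))
    n_seg = len(stream) // seg_len
    if n_seg * seg_len < len(stream):
        logger.info("dropping trailing partial segment of %d samples", len(stream) - n_seg * seg_len)
    if n_seg == 0:
        raise ValueError("stream shorter than one segment")
    static, dynamic = _running_mean_split(
        stream[["ax", "ay", "az"]].to_numpy(dtype=float)[: n_seg * seg_len], rate, window_s
    )
    acc = stream[["ax", "ay", "az"]].to_numpy(dtype=float)[: n_seg * seg_len]
    temp = stream["temp"].to_numpy(dtype=float)[: n_seg * seg_len] if "temp" in stream else np.zeros(n_seg * seg_len)
    ts = pd.to_datetime(stream["timestamp"]).to_numpy()[: n_seg * seg_len : seg_len] if "timestamp" in stream else np.arange(n_seg)

    def seg(x):
        return x.reshape(n_seg, seg_len, -1)

    d = seg(dynamic)
    s = seg(static)
    a = seg(acc)
    odba = np.abs(d).sum(axis=2).mean(axis=1)
    vedba = np.linalg.norm(d, axis=2).mean(axis=1)
    pitch = np.degrees(np.arctan2(s[:, :, 0], np.hypot(s[:, :, 1], s[:, :, 2])))
    roll = np.degrees(np.arctan2(s[:, :, 1], s[:, :, 2]))
    rows = {
        "start_ts": ts,
        "mean_odba": odba,
        "mean_vedba": vedba,
        "mean_roll": roll.mean(axis=1),
        "sd_roll": roll.std(axis=1),
        "mean_pitch": pitch.mean(axis=1),
        "sd_pitch": pitch.std(axis=1),
    }
    for ax_i, name in enumerate(("surge", "sway", "heave")):
        rows[f"mean_{name}"] = a[:, :, ax_i].mean(axis=1)
        rows[f"sd_{name}"] = a[:, :, ax_i].std(axis=1)
        rows[f"min_{name}"] = a[:, :, ax_i].min(axis=1)
        rows[f"max_{name}"] = a[:, :, ax_i].max(axis=1)
    rows["mean_temp"] = temp.reshape(n_seg, seg_len).mean(axis=1)
    return pd.DataFrame(rows)


def train_classifier(
    segments: pd.DataFrame,
    n_trees: int = 10000,
    vars_per_node: int = 5,
    seed: int = 0,
    holdout_fraction: float = 0.0,
):
    """Random forest over the 17-feature segments; returns (model, recall table).

    Requires >= 2 classes with >= 10 segments each. Recall is reported
    out-of-bag by default; with ``holdout_fraction`` > 0 a stratified
    holdout is carved off and recall is computed on it instead.
    """
    counts = segments["label"].value_counts()
    if len(counts) < 2:
        raise ValueError(f"need >= 2 behaviour classes, got {list(counts.index)}")
    thin = counts[counts < 10]
    if len(thin):
        raise ValueError(f"classes with < 10 segments: {list(thin.index)}")

    rng = np.random.default_rng(seed)
    df = segments.reset_index(drop=True)
    if holdout_fraction > 0:
        test_idx = []
        for lab, grp in df.groupby("label"):
            k = max(1, int(round(holdout_fraction * len(grp))))
            test_idx.extend(rng.choice(grp.index.to_numpy(), size=k, replace=False))
        test_mask = df.index.isin(test_idx)
        train, test = df[~test_mask], df[test_mask]
    else:
        train, test = df, None

    model = RandomForestClassifier(
        n_estimators=n_trees,
        max_features=vars_per_node,
        oob_score=test is None,
        random_state=int(seed),
        n_jobs=1,
    )
    x_cols = list(FEATURE_COLUMNS)
    model.fit(train[x_cols].to_numpy(), train["label"].to_numpy())
    if test is None:
        pred = model.classes_[np.argmax(model.oob_decision_function_, axis=1)]
        truth = train["label"].to_numpy()
        kind = "out_of_bag"
    else:
        pred = model.predict(test[x_cols].to_numpy())
        truth = test["label"].to_numpy()
        kind = "holdout"
    recall = (
        pd.DataFrame({"label": truth, "correct": pred == truth})
        .groupby("label")["correct"].mean()
        .rename("recall").reset_index()
    )
    recall["evaluation"] = kind
    return model, recall


def predict_labels(model, segments: pd.DataFrame) -> np.ndarray:
    return model.predict(segments[list(FEATURE_COLUMNS)].to_numpy())


def logic_correct(labels, max_run: int = 1):
    """Relabel contextually impossible blips inside flight.

    Any run of non-flight labels (sit/takeoff/dive) of length <= ``max_run``
    flanked on both sides by flight (flap/glide) becomes the nearer flanking
    flight label (ties go to the preceding label). Idempotent.
    """
    labels = list(labels)
    n = len(labels)
    out = labels.copy()
    i = 0
    while i < n:
        if out[i] in FLIGHT_LABELS:
            i += 1
            continue
        j = i
        while j + 1 < n and out[j + 1] not in FLIGHT_LABELS:
            j += 1
        run_len = j - i + 1
        left = out[i - 1] if i > 0 else None
        right = out[j + 1] if j + 1 < n else None
        if run_len <= max_run and left in FLIGHT_LABELS and right in FLIGHT_LABELS:
            for k in range(i, j + 1):
                dist_left = k - (i - 1)
                dist_right = (j + 1) - k
                out[k] = left if dist_left <= dist_right else right
        i = j + 1
    return out


def flapping_proportion(
    labels,
    label_times,
    fix_times,
    window: str | pd.Timedelta = "5min",
    tolerance: str | pd.Timedelta = "1min",
) -> np.ndarray:
    """Per-fix proportion of flight seconds spent flapping.

    For each fix, the window covers [fix - window, fix); the proportion is
    flap / (flap + glide) over the per-second labels inside it, NaN when the
    window holds no flight. Raises when label and fix clocks are misaligned
    beyond ``tolerance``.
    """
    window = pd.Timedelta(window)
    tolerance = pd.Timedelta(tolerance)
    lt = pd.to_datetime(pd.Series(list(label_times))).to_numpy()
    ft = pd.to_datetime(pd.Series(list(fix_times))).to_numpy()
    labels = np.asarray(list(labels), dtype=object)
    if len(lt) and len(ft):
        if lt[0] - ft[0] > window + tolerance or ft[-1] - lt[-1] > window + tolerance:
            raise ValueError("label and fix clocks are misaligned beyond tolerance")
    out = np.full(len(ft), np.nan)
    for k, t in enumerate(ft):
        sel = (lt >= t - np.timedelta64(int(window.total_seconds()), "s")) & (lt < t)
        lab = labels[sel]
        n_flap = int((lab == "flap").sum())
        n_glide = int((lab == "glide").sum())
        if n_flap + n_glide > 0:
            out[k] = n_flap / (n_flap + n_glide)
    return out
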