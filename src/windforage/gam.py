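"""Penalized tensor-product spline models for selectivity and flight metrics.

Three response families share one fitting route:

* bernoulli — route selectivity on the weighted used-available table
  (1 = observed leg, 0 = rotated alternative);
* beta — per-fix proportion of flight spent flapping (boundary values
  shrunk by the usual (y (n-1) + 0.5) / n transform, mean on the logit
  scale, quasi-likelihood variance mu (1 - mu));
* gaussian — ground speed.

The wind-speed x relative-wind-direction surface is a tensor product of two
low-rank cubic B-spline margins (rank 4 each by default) with second-order
difference penalties per margin; a single smoothing parameter shared by the
two penalties is chosen by generalized cross-validation. Covariates are
centred and standardized with the transform stored for prediction-grid
back-transforms. Grouping (individual, trip within individual) enters as
ridge-penalized random intercepts; uncertainty comes from a cluster
bootstrap resampling trips. Discrimination of the binary model is the
weighted Mann-Whitney AUC.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

logger = logging.getLogger(__name__)

FAMILIES = ("bernoulli", "beta", "gaussian")


@dataclass
class GAMSpec:
    """Model specification for one selectivity / flight-metric fit."""

    family: str = "bernoulli"
    response: str = "used"
    x1: str = "ws"
    x2: str = "rwd"
    knots: int = 4  # marginal basis rank
    penalty_order: int = 2
    weights: str | None = None
    individual: str | None = None
    trip: str | None = None
    re_ridge: float = 1.0

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}")


@dataclass
class GAMFit:
    """Fitted penalized spline model."""

    spec: GAMSpec
    coef: np.ndarray
    lam: float
    edf: float
    x1_mean: float
    x1_sd: float
    x2_mean: float
    x2_sd: float
    knots1: np.ndarray
    knots2: np.ndarray
    group_levels: dict = field(default_factory=dict)
    auc: float | None = None
    converged: bool = True
    n_obs: int = 0
    train_support: dict = field(default_factory=dict)
    phi: float | None = None  # beta-family precision (method of moments)


# --------------------------------------------------------------------------- #
# bases and penalties
# --------------------------------------------------------------------------- #


def _marginal_knots(x: np.ndarray, rank: int) -> np.ndarray:
    """Open cubic knot vector with rank - 4 interior knots at quantiles."""
    lo, hi = float(np.min(x)), float(np.max(x))
    span = max(hi - lo, 1e-12)
    lo -= 1e-6 * span
    hi += 1e-6 * span
    n_interior = rank - 4
    interior = (
        np.quantile(x, np.linspace(0, 1, n_interior + 2)[1:-1]) if n_interior > 0 else np.array([])
    )
    return np.concatenate([[lo] * 4, interior, [hi] * 4])


def _bspline_design(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    x = np.clip(x, knots[3] + 1e-12, knots[-4] - 1e-12)
    return BSpline.design_matrix(x, knots, 3).toarray()


def _difference_penalty(dim: int, order: int = 2) -> np.ndarray:
    d = np.diff(np.eye(dim), n=order, axis=0)
    return d.T @ d


def tensor_basis(x1, x2, knots: int = 4, penalty_order: int = 2,
                 knots1: np.ndarray | None = None, knots2: np.ndarray | None = None):
    """Row-wise Kronecker tensor design with per-margin difference penalties.

    Returns (design (n, knots^2), [S1, S2], knots1, knots2). Each marginal
    cubic B-spline basis has rank ``knots`` (interior knots at quantiles);
    rows of each margin sum to one (partition of unity). Raises on a
    constant covariate.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    for name, x in (("x1", x1), ("x2", x2)):
        if np.ptp(x) < 1e-12:
            raise ValueError(f"covariate {name} is constant; cannot build a spline basis")
    if knots < 4:
        raise ValueError("marginal rank must be >= 4 for a cubic basis")
    if knots1 is None:
        knots1 = _marginal_knots(x1, knots)
    if knots2 is None:
        knots2 = _marginal_knots(x2, knots)
    b1 = _bspline_design(x1, knots1)
    b2 = _bspline_design(x2, knots2)
    m1, m2 = b1.shape[1], b2.shape[1]
    design = (b1[:, :, None] * b2[:, None, :]).reshape(len(x1), m1 * m2)
    p = _difference_penalty(m1, penalty_order)
    s1 = np.kron(p, np.eye(m2))
    s2 = np.kron(np.eye(m1), _difference_penalty(m2, penalty_order))
    return design, [s1, s2], knots1, knots2


# --------------------------------------------------------------------------- #
# weighted AUC
# --------------------------------------------------------------------------- #


def auc(scores, labels, weights=None) -> float:
    """Weighted Mann-Whitney AUC with tie correction.

    Probability (weighted) that a random positive scores above a random
    negative, ties counting half. Raises on a single-class input.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    w = np.ones_like(s) if weights is None else np.asarray(weights, dtype=float)
    if y.min() == y.max():
        raise ValueError("AUC needs both classes present")
    order = np.argsort(s, kind="mergesort")
    s, y, w = s[order], y[order], w[order]
    w_pos = np.where(y == 1, w, 0.0)
    w_neg = np.where(y == 0, w, 0.0)
    total = 0.0
    cum_neg = 0.0
    i = 0
    n = len(s)
    while i < n:
        j = i
        while j + 1 < n and s[j + 1] == s[i]:
            j += 1
        tie_pos = w_pos[i : j + 1].sum()
        tie_neg = w_neg[i : j + 1].sum()
        total += tie_pos * (cum_neg + 0.5 * tie_neg)
        cum_neg += tie_neg
        i = j + 1
    denom = w_pos.sum() * w_neg.sum()
    return float(total / denom)


# --------------------------------------------------------------------------- #
# fitting
# --------------------------------------------------------------------------- #


def _link_funs(family: str):
    if family == "gaussian":
        return (lambda eta: eta), (lambda mu: np.ones_like(mu))
    expit = lambda eta: 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
    var = lambda mu: np.clip(mu * (1.0 - mu), 1e-8, None)
    return expit, var


def _shrink_beta(y: np.ndarray) -> np.ndarray:
    n = len(y)
    return (y * (n - 1) + 0.5) / n


def fit_gam(table: pd.DataFrame, spec: GAMSpec, seed: int = 0,
            lam_grid=None, max_iter: int = 60, tol: float = 1e-8,
            select: str | None = None, n_folds: int = 5) -> GAMFit:
    """Fit a penalized tensor-spline model by (quasi-)likelihood PIRLS.

    The smoothing parameter is chosen over ``lam_grid`` (log-spaced
    1e-4..1e4 by default) either by generalized cross-validation
    (``select='gcv'``) or, when grouping columns are present (the default in
    that case), by cluster cross-validation: whole trips are held out and
    scored with their random intercepts at zero, so rows pseudo-replicated
    within a leg cannot masquerade as independent evidence for wiggliness.
    Case weights from ``spec.weights`` multiply the working weights;
    grouping columns add ridge-penalized random intercepts. For the
    bernoulli family the weighted AUC of the population-level surface on the
    training table is stored.
    """
    df = table.reset_index(drop=True)
    y = df[spec.response].to_numpy(dtype=float)
    if spec.family == "bernoulli" and not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("bernoulli response must be 0/1")
    if spec.family == "beta":
        if np.any((y < 0) | (y > 1)):
            raise ValueError("beta response must lie in [0, 1]")
        y = _shrink_beta(y)
    w_case = df[spec.weights].to_numpy(dtype=float) if spec.weights else np.ones(len(df))
    if np.any(w_case <= 0):
        raise ValueError("case weights must be positive")

    x1_raw = df[spec.x1].to_numpy(dtype=float)
    x2_raw = df[spec.x2].to_numpy(dtype=float)
    x1m, x1s = float(x1_raw.mean()), float(max(x1_raw.std(), 1e-12))
    x2m, x2s = float(x2_raw.mean()), float(max(x2_raw.std(), 1e-12))
    x1 = (x1_raw - x1m) / x1s
    x2 = (x2_raw - x2m) / x2s
    basis, pens, kn1, kn2 = tensor_basis(x1, x2, knots=spec.knots, penalty_order=spec.penalty_order)

    blocks = [np.ones((len(df), 1)), basis]
    group_levels: dict[str, list] = {}
    for col in (spec.individual, spec.trip):
        if col:
            levels = list(pd.unique(df[col]))
            group_levels[col] = levels
            dummies = (df[col].to_numpy()[:, None] == np.array(levels)[None, :]).astype(float)
            blocks.append(dummies)
    x_mat = np.column_stack(blocks)
    p_smooth = np.zeros((x_mat.shape[1], x_mat.shape[1]))
    off = 1
    dim = basis.shape[1]
    p_smooth[off : off + dim, off : off + dim] = pens[0] + pens[1]
    p_ridge = np.zeros_like(p_smooth)
    if group_levels:
        start = 1 + dim
        n_re = x_mat.shape[1] - start
        p_ridge[start:, start:] = np.eye(n_re)

    inv_link, var_fun = _link_funs(spec.family)
    if lam_grid is None:
        lam_grid = np.logspace(-4, 4, 9)

    # tiny ridge fixes the intercept/partition-of-unity confounding (the
    # tensor basis spans the constant) without visible shrinkage
    p_ident = 1e-8 * np.eye(x_mat.shape[1])

    def deviance(yy, mu, ww):
        if spec.family == "gaussian":
            return float(np.sum(ww * (yy - mu) ** 2))
        mu_c = np.clip(mu, 1e-10, 1 - 1e-10)
        y_c = np.clip(yy, 1e-10, 1 - 1e-10)
        return float(
            2.0 * np.sum(ww * (yy * np.log(y_c / mu_c) + (1 - yy) * np.log((1 - y_c) / (1 - mu_c))))
        )

    def pirls(lam: float, x: np.ndarray, yy: np.ndarray, ww: np.ndarray, beta0=None):
        pen = lam * p_smooth + spec.re_ridge * p_ridge + p_ident
        if beta0 is not None:
            beta = beta0.copy()
        else:
            beta = np.zeros(x.shape[1])
            if spec.family == "gaussian":
                beta[0] = np.average(yy, weights=ww)
            else:
                mu0 = np.clip(np.average(yy, weights=ww), 1e-3, 1 - 1e-3)
                beta[0] = np.log(mu0 / (1 - mu0))
        dev_prev = np.inf
        for it in range(max_iter):
            eta = x @ beta
            mu = inv_link(eta)
            if spec.family == "gaussian":
                z, wk = yy, ww
            else:
                v = var_fun(mu)
                z = eta + (yy - mu) / v
                wk = ww * v
            xtw = x.T * wk
            a = xtw @ x + pen
            b = xtw @ z
            beta = np.linalg.solve(a, b)
            dev = deviance(yy, inv_link(x @ beta), ww)
            if abs(dev_prev - dev) < tol * (abs(dev) + 1.0) or spec.family == "gaussian":
                break
            dev_prev = dev
        else:
            it = max_iter
        eta = x @ beta
        mu = inv_link(eta)
        wk = ww if spec.family == "gaussian" else ww * var_fun(mu)
        xtw = x.T * wk
        a = xtw @ x + pen
        edf = float(np.trace(np.linalg.solve(a, xtw @ x)))
        dev = deviance(yy, mu, ww)
        converged = it < max_iter
        return beta, edf, dev, converged

    n = len(df)
    n_pop = 1 + dim  # intercept + smooth: the population-level block
    if select is None:
        select = "cluster_cv" if group_levels else "gcv"
    if select == "cluster_cv":
        cluster_col = spec.trip or spec.individual
        clusters = df[cluster_col].to_numpy()
        uniq = pd.unique(clusters)
        rng = np.random.default_rng(seed)
        assignment = rng.permutation(len(uniq)) % n_folds
        fold_of = dict(zip(uniq, assignment))
        fold = np.array([fold_of[c] for c in clusters])
        cv_dev = {lam: 0.0 for lam in lam_grid}
        for f in range(n_folds):
            tr = fold != f
            te = ~tr
            if not te.any() or not tr.any():
                continue
            warm = None
            for lam in sorted(lam_grid, reverse=True):
                beta_f, _edf, _dev, _c = pirls(lam, x_mat[tr], y[tr], w_case[tr], beta0=warm)
                warm = beta_f
                eta_te = x_mat[te, :n_pop] @ beta_f[:n_pop]
                cv_dev[lam] += deviance(y[te], inv_link(eta_te), w_case[te])
        lam = min(cv_dev, key=cv_dev.get)
        beta, edf, _dev, conv = pirls(lam, x_mat, y, w_case)
    elif select == "gcv":
        best = None
        warm = None
        for lam in sorted(lam_grid, reverse=True):  # stiff to wiggly, warm-started
            beta_l, edf_l, dev_l, conv_l = pirls(lam, x_mat, y, w_case, beta0=warm)
            warm = beta_l
            gcv = n * dev_l / max(n - edf_l, 1.0) ** 2
            if best is None or gcv < best[0]:
                best = (gcv, lam, beta_l, edf_l, conv_l)
        _gcv, lam, beta, edf, conv = best
    else:
        raise ValueError("select must be 'gcv' or 'cluster_cv'")
    if not conv:
        warnings.warn("PIRLS did not fully converge at the selected smoothing parameter")

    fit = GAMFit(
        spec=spec, coef=beta, lam=float(lam), edf=edf,
        x1_mean=x1m, x1_sd=x1s, x2_mean=x2m, x2_sd=x2s,
        knots1=kn1, knots2=kn2, group_levels=group_levels,
        converged=conv, n_obs=n,
        train_support={
            "x1": (float(np.quantile(x1_raw, 0.05)), float(np.quantile(x1_raw, 0.95))),
            "x2": (float(np.quantile(x2_raw, 0.05)), float(np.quantile(x2_raw, 0.95))),
        },
    )
    if spec.family == "beta":
        mu = inv_link(x_mat @ beta)
        resid_var = np.average((y - mu) ** 2, weights=w_case)
        mean_v = np.average(mu * (1 - mu), weights=w_case)
        fit.phi = float(max(mean_v / max(resid_var, 1e-12) - 1.0, 0.0))
    if spec.family == "bernoulli":
        # discrimination of the population-level surface (random intercepts
        # marginalized out): what the covariates alone can separate
        scores = linear_predictor(fit, x1_raw, x2_raw)
        fit.auc = auc(scores, df[spec.response].to_numpy(), w_case)
    return fit


def _population_design(fit: GAMFit, x1_raw, x2_raw) -> np.ndarray:
    x1 = (np.asarray(x1_raw, dtype=float) - fit.x1_mean) / fit.x1_sd
    x2 = (np.asarray(x2_raw, dtype=float) - fit.x2_mean) / fit.x2_sd
    b1 = _bspline_design(x1, fit.knots1)
    b2 = _bspline_design(x2, fit.knots2)
    design = (b1[:, :, None] * b2[:, None, :]).reshape(len(x1), -1)
    return np.column_stack([np.ones(len(x1)), design])


def linear_predictor(fit: GAMFit, x1_raw, x2_raw) -> np.ndarray:
    """Population-level linear predictor (random intercepts at zero)."""
    xp = _population_design(fit, x1_raw, x2_raw)
    return xp @ fit.coef[: xp.shape[1]]


def predict_surface(fit: GAMFit, x1_grid, x2_grid):
    """Response-scale prediction matrix over an x1 x x2 grid.

    Returns (matrix with shape (len(x2_grid), len(x1_grid)), extrapolation
    mask flagging grid cells outside the 5-95% training support).
    """
    x1_grid = np.asarray(x1_grid, dtype=float)
    x2_grid = np.asarray(x2_grid, dtype=float)
    g1, g2 = np.meshgrid(x1_grid, x2_grid)
    eta = linear_predictor(fit, g1.ravel(), g2.ravel()).reshape(g1.shape)
    inv_link, _ = _link_funs(fit.spec.family)
    surface = inv_link(eta)
    lo1, hi1 = fit.train_support["x1"]
    lo2, hi2 = fit.train_support["x2"]
    extrap = (g1 < lo1) | (g1 > hi1) | (g2 < lo2) | (g2 > hi2)
    if extrap.any():
        logger.info("%d of %d surface cells extrapolate beyond the 5-95%% training support",
                    int(extrap.sum()), extrap.size)
    return surface, extrap


def smooth_effect_summary(
    fit: GAMFit,
    table: pd.DataFrame,
    n_boot: int = 200,
    seed: int = 0,
    cluster: str | None = None,
) -> pd.DataFrame:
    """Mean absolute effect of each smooth term on the linear predictor.

    The fitted surface f(x1, x2) is decomposed functionally over the
    training rows into main effects and an interaction (f = f0 + f1 + f2 +
    f12 by averaging over the empirical covariate distribution); the effect
    size of a term is the mean |term| across rows. 95% intervals come from
    a cluster bootstrap (resampling ``cluster`` groups, default trips, with
    replacement and refitting at the selected smoothing parameter).
    """
    if n_boot < 50:
        warnings.warn("n_boot < 50 gives unstable percentile intervals")
    cluster = cluster or fit.spec.trip or fit.spec.individual
    df = table.reset_index(drop=True)

    def effect_sizes(f: GAMFit, frame: pd.DataFrame) -> dict[str, float]:
        x1 = frame[f.spec.x1].to_numpy(dtype=float)
        x2 = frame[f.spec.x2].to_numpy(dtype=float)
        # decompose on a product grid of the observed margins (quantile knots)
        q1 = np.quantile(x1, np.linspace(0.02, 0.98, 21))
        q2 = np.quantile(x2, np.linspace(0.02, 0.98, 21))
        g1, g2 = np.meshgrid(q1, q2)
        eta = linear_predictor(f, g1.ravel(), g2.ravel()).reshape(g1.shape)
        f0 = eta.mean()
        f1 = eta.mean(axis=0) - f0  # varies with x1
        f2 = eta.mean(axis=1) - f0
        f12 = eta - f0 - f1[None, :] - f2[:, None]
        return {
            f.spec.x1: float(np.mean(np.abs(f1))),
            f.spec.x2: float(np.mean(np.abs(f2))),
            f"{f.spec.x1}:{f.spec.x2}": float(np.mean(np.abs(f12))),
        }

    point = effect_sizes(fit, df)
    rows = {k: [] for k in point}
    rng = np.random.default_rng(seed)
    if cluster:
        groups = list(pd.unique(df[cluster]))
    for _b in range(n_boot):
        if cluster:
            pick = rng.choice(groups, size=len(groups), replace=True)
            boot = pd.concat([df[df[cluster] == g] for g in pick], ignore_index=True)
        else:
            boot = df.sample(n=len(df), replace=True, random_state=int(rng.integers(2**31)))
        try:
            f_b = fit_gam(boot, fit.spec, lam_grid=[fit.lam])
        except (ValueError, np.linalg.LinAlgError):
            continue
        for k, v in effect_sizes(f_b, boot).items():
            rows[k].append(v)
    out = []
    for k, v in point.items():
        draws = np.asarray(rows[k])
        out.append(
            {
                "term": k,
                "mean_effect": v,
                "ci_lo": float(np.percentile(draws, 2.5)) if draws.size else np.nan,
                "ci_hi": float(np.percentile(draws, 97.5)) if draws.size else np.nan,
                "n_boot": int(draws.size),
            }
        )
    return pd.DataFrame(out)
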