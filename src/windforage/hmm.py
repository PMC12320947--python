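"""Three-state hidden Markov movement model with covariate-dependent transitions.

States are behavioural modes of a central-place forager at sea — feeding,
travelling, resting — inferred from two emission channels computed on
regularized 5-min fixes:

* step length (km), gamma-distributed per state, parametrized by (mean, sd);
* turning angle (rad), von Mises-distributed per state, (mu, kappa).

Transition probabilities follow a multinomial logit with the diagonal as the
reference category: for row i and column j != i,

    eta_ij = beta0_ij + beta_ij . x,
    Gamma_ij = exp(eta_ij) / (1 + sum_{j' != i} exp(eta_ij')),

where x is the (standardized) covariate vector (e.g. wind speed, relative
wind and wave direction, and their products). Fitting maximizes the forward
log-likelihood over independent per-trip blocks with multiple random starts;
decoding is Viterbi; long-run state occupancy is the stationary distribution
delta(x) solving delta Gamma(x) = delta.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

try:  # numba accelerates the forward recursion; the numpy path is equivalent
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]


logger = logging.getLogger(__name__)

STATE_NAMES = ("feeding", "travelling", "resting")
N_STATES = 3
#: off-diagonal (row, col) pairs in row-major order — the multinomial-logit rows
OFFDIAG = [(0, 1), (0, 2), (1, 0), (1, 2), (2, 0), (2, 1)]

_MIN_STEP_KM = 1e-3  # steps below ~1 m are jittered to avoid a gamma singularity


# --------------------------------------------------------------------------- #
# parameters
# --------------------------------------------------------------------------- #


@dataclass
class HMMParams:
    """Emission and transition parameters of the 3-state movement HMM.

    State order is (feeding, travelling, resting). ``beta`` has one row per
    off-diagonal transition in :data:`OFFDIAG` order and one column per design
    term (intercept first, then one per covariate term). ``cov_means`` /
    ``cov_sds`` record the standardization applied to the covariate columns
    before the logit; identity (0, 1) means beta acts on raw covariates.
    """

    step_mean: np.ndarray
    step_sd: np.ndarray
    turn_mu: np.ndarray
    turn_kappa: np.ndarray
    beta: np.ndarray
    terms: tuple[str, ...] = ()
    cov_means: np.ndarray | None = None
    cov_sds: np.ndarray | None = None

    def __post_init__(self):
        self.step_mean = np.asarray(self.step_mean, dtype=float)
        self.step_sd = np.asarray(self.step_sd, dtype=float)
        self.turn_mu = np.asarray(self.turn_mu, dtype=float)
        self.turn_kappa = np.asarray(self.turn_kappa, dtype=float)
        self.beta = np.atleast_2d(np.asarray(self.beta, dtype=float))
        self.terms = tuple(self.terms)
        if self.beta.shape != (len(OFFDIAG), 1 + len(self.terms)):
            raise ValueError(
                f"beta must be {(len(OFFDIAG), 1 + len(self.terms))}, got {self.beta.shape}"
            )
        for name in ("step_mean", "step_sd", "turn_kappa"):
            arr = getattr(self, name)
            if arr.shape != (N_STATES,):
                raise ValueError(f"{name} must have shape (3,)")
        if not (np.all(np.isfinite(self.step_mean)) and np.all(self.step_mean > 0)):
            raise ValueError("step means must be finite and positive")
        if not np.all(self.step_sd > 0):
            raise ValueError("step sds must be positive")
        if not np.all(self.turn_kappa >= 0):
            raise ValueError("kappa must be non-negative")
        n_base = len(_base_covariates(self.terms))
        if self.cov_means is None:
            self.cov_means = np.zeros(n_base)
        if self.cov_sds is None:
            self.cov_sds = np.ones(n_base)

    @property
    def n_parameters(self) -> int:
        return 4 * N_STATES + self.beta.size

    def gamma_shape_scale(self):
        shape = (self.step_mean / self.step_sd) ** 2
        scale = self.step_sd**2 / self.step_mean
        return shape, scale


@dataclass
class HMMFit:
    """Result of multistart maximum-likelihood fitting."""

    params: HMMParams
    formula: tuple[str, ...]
    neg_log_lik: float
    n_parameters: int
    converged: bool
    n_starts: int
    start_values: list = field(default_factory=list, repr=False)
    decoded_states: np.ndarray | None = None
    hessian: np.ndarray | None = field(default=None, repr=False)
    _working_theta: np.ndarray | None = field(default=None, repr=False)

    @property
    def aic(self) -> float:
        return 2.0 * self.neg_log_lik + 2.0 * self.n_parameters


def reference_params() -> HMMParams:
    """Reference movement parameters for a flap-gliding tropical seabird.

    Field-scale values typical of 5-min regularized booby foraging tracks:
    feeding has short, tortuous steps; travelling long, straight ones;
    resting short, straight drift. Self-transition probabilities are high
    (0.91/0.92/0.88) with off-diagonal mass split equally. These are the
    default ground truth of the synthetic-data generator.
    """
    return HMMParams(
        step_mean=np.array([0.7, 3.1, 0.1]),
        step_sd=np.array([0.8, 0.6, 0.04]),
        turn_mu=np.array([-0.03, -0.0008, 0.003]),
        turn_kappa=np.array([0.7, 19.2, 25.2]),
        beta=persistence_intercepts(np.array([0.91, 0.92, 0.88]))[:, None],
    )


def persistence_intercepts(diagonals) -> np.ndarray:
    """Logit intercepts giving the requested self-transition probabilities.

    Off-diagonal mass is split equally within each row, so for diagonal d the
    intercept of each of the row's two transitions is log(((1 - d)/2) / d).
    """
    d = np.asarray(diagonals, dtype=float)
    if d.shape != (N_STATES,) or np.any(d <= 0) or np.any(d >= 1):
        raise ValueError("diagonals must be 3 probabilities in (0, 1)")
    beta0 = np.empty(len(OFFDIAG))
    for r, (i, _j) in enumerate(OFFDIAG):
        beta0[r] = np.log((1.0 - d[i]) / 2.0 / d[i])
    return beta0


# --------------------------------------------------------------------------- #
# transition matrices and stationary distributions
# --------------------------------------------------------------------------- #


def transition_matrix(beta, covariate_row=None) -> np.ndarray:
    """3x3 transition matrix from logit coefficients at one covariate vector.

    ``beta`` is (6, 1 + p); ``covariate_row`` supplies the p covariate values
    (already on the scale beta was estimated on). Rows sum to one.
    """
    beta = np.atleast_2d(np.asarray(beta, dtype=float))
    x = np.concatenate([[1.0], np.atleast_1d(covariate_row).astype(float)]) if covariate_row is not None and np.size(covariate_row) else np.ones(1)
    if beta.shape[1] != x.size:
        raise ValueError(f"beta has {beta.shape[1]} columns but design row has {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError("covariates must be finite")
    eta = beta @ x
    return _gamma_from_eta(eta[None, :])[0]


def _gamma_from_eta(eta: np.ndarray) -> np.ndarray:
    """Batch (N, 6) etas -> (N, 3, 3) row-stochastic matrices, log-sum-exp guarded."""
    n = eta.shape[0]
    full = np.zeros((n, N_STATES, N_STATES))
    for r, (i, j) in enumerate(OFFDIAG):
        full[:, i, j] = eta[:, r]
    # diagonal reference eta = 0; normalize each row via softmax
    m = full.max(axis=2, keepdims=True)
    e = np.exp(full - m)
    # zero out entries that are not in the row's choice set? all entries are:
    # diagonal (eta=0) plus the two off-diagonals.
    return e / e.sum(axis=2, keepdims=True)


def stationary_distribution(gamma: np.ndarray) -> np.ndarray:
    """Solve delta Gamma = delta, sum(delta) = 1; NaNs if Gamma is reducible."""
    g = np.asarray(gamma, dtype=float)
    a = np.vstack([g.T - np.eye(N_STATES), np.ones((1, N_STATES))])
    b = np.zeros(N_STATES + 1)
    b[-1] = 1.0
    delta, *_ = np.linalg.lstsq(a, b, rcond=None)
    if np.any(delta < -1e-9) or not np.all(np.isfinite(delta)):
        return np.full(N_STATES, np.nan)
    delta = np.clip(delta, 0.0, None)
    return delta / delta.sum()


# --------------------------------------------------------------------------- #
# formulas / design matrices
# --------------------------------------------------------------------------- #


def _base_covariates(terms) -> list[str]:
    seen: list[str] = []
    for t in terms:
        for c in t.split(":"):
            if c not in seen:
                seen.append(c)
    return seen


def _design_from_frame(df: pd.DataFrame, terms, cov_means, cov_sds) -> np.ndarray:
    """Design matrix (N, 1 + p): intercept, then standardized terms/products."""
    base = _base_covariates(terms)
    std = {}
    for k, name in enumerate(base):
        std[name] = (df[name].to_numpy(dtype=float) - cov_means[k]) / cov_sds[k]
    cols = [np.ones(len(df))]
    for t in terms:
        parts = t.split(":")
        col = np.ones(len(df))
        for p in parts:
            col = col * std[p]
        cols.append(col)
    return np.column_stack(cols)


# --------------------------------------------------------------------------- #
# data preparation
# --------------------------------------------------------------------------- #


class _Prepared:
    """Trips padded into rectangular arrays for the batched forward pass."""

    def __init__(self, df: pd.DataFrame, terms, cov_means=None, cov_sds=None, rng=None):
        df = df.copy()
        base = _base_covariates(terms)
        for c in ("step_km", "turn_rad"):
            if c not in df.columns:
                raise ValueError(f"data must contain column '{c}'")
        for c in base:
            if c not in df.columns:
                raise ValueError(f"formula term needs covariate column '{c}'")
            bad = ~np.isfinite(df[c].to_numpy(dtype=float))
            if bad.any():
                raise ValueError(f"non-finite covariate '{c}' at row {int(np.flatnonzero(bad)[0])}")
        if "trip_id" not in df.columns:
            df["trip_id"] = 0

        steps_raw = df["step_km"].to_numpy(dtype=float)
        tiny = np.isfinite(steps_raw) & (steps_raw < _MIN_STEP_KM)
        if tiny.any():
            rng = rng or np.random.default_rng(0)
            steps_raw = steps_raw.copy()
            steps_raw[tiny] = rng.uniform(0.5 * _MIN_STEP_KM, 1.5 * _MIN_STEP_KM, tiny.sum())
            logger.info("jittered %d near-zero steps below %g km", tiny.sum(), _MIN_STEP_KM)
        df = df.assign(step_km=steps_raw)

        if cov_means is None:
            cov_means = np.array([df[c].mean() for c in base]) if base else np.zeros(0)
            cov_sds = np.array([max(df[c].std(ddof=0), 1e-12) for c in base]) if base else np.zeros(0)
        self.cov_means, self.cov_sds = np.asarray(cov_means), np.asarray(cov_sds)
        self.terms = tuple(terms)
        self.n_terms = 1 + len(terms)

        design = _design_from_frame(df, terms, self.cov_means, self.cov_sds) if terms else None

        groups = [np.flatnonzero(df["trip_id"].to_numpy() == t) for t in pd.unique(df["trip_id"])]
        self.n_trips = len(groups)
        self.t_max = max(len(g) for g in groups)
        self.n_obs = sum(len(g) for g in groups)
        shape = (self.n_trips, self.t_max)
        self.steps = np.full(shape, np.nan)
        self.angles = np.full(shape, np.nan)
        self.mask = np.zeros(shape, dtype=bool)
        self.X = np.zeros(shape + (self.n_terms,)) if terms else None
        for k, idx in enumerate(groups):
            n = len(idx)
            self.steps[k, :n] = df["step_km"].to_numpy(dtype=float)[idx]
            self.angles[k, :n] = df["turn_rad"].to_numpy(dtype=float)[idx]
            self.mask[k, :n] = True
            if terms:
                self.X[k, :n, :] = design[idx]
        self.trip_ids = list(pd.unique(df["trip_id"]))
        self.trip_lengths = np.array([len(g) for g in groups])

        # per-dataset emission ingredients, fixed across likelihood evaluations
        self.s_ok = np.isfinite(self.steps)
        self.s_safe = np.where(self.s_ok, self.steps, 1.0)
        self.log_s = np.log(self.s_safe)
        self.a_ok = np.isfinite(self.angles)
        a_safe = np.where(self.a_ok, self.angles, 0.0)
        self.cos_a = np.cos(a_safe)
        self.sin_a = np.sin(a_safe)


def _emission_loglik(prep: _Prepared, step_mean, step_sd, turn_mu, turn_kappa):
    """(n_trips, T, 3) log emission density; missing channels contribute 0.

    Uses precomputed log-steps and cos/sin of angles so each evaluation is
    multiply-add only (cos(a - mu) = cos a cos mu + sin a sin mu).
    """
    shape = (step_mean / step_sd) ** 2
    scale = step_sd**2 / step_mean
    step_const = shape * np.log(scale) + special.gammaln(shape)
    lb_step = (
        (shape - 1.0) * prep.log_s[..., None]
        - prep.s_safe[..., None] / scale
        - step_const
    ) * prep.s_ok[..., None]
    log_i0 = np.log(special.i0e(turn_kappa)) + turn_kappa
    ang_const = np.log(2 * np.pi) + log_i0
    lb_ang = (
        turn_kappa * (prep.cos_a[..., None] * np.cos(turn_mu) + prep.sin_a[..., None] * np.sin(turn_mu))
        - ang_const
    ) * prep.a_ok[..., None]
    return lb_step + lb_ang


@njit(cache=True)
def _forward_kernel_const(logb, gamma, delta, lengths):  # pragma: no cover — exercised via _forward_nll
    n_trips = logb.shape[0]
    n_states = logb.shape[2]
    ll = 0.0
    alpha = np.empty(n_states)
    a_new = np.empty(n_states)
    for k in range(n_trips):
        n = lengths[k]
        m = logb[k, 0, 0]
        for s in range(1, n_states):
            if logb[k, 0, s] > m:
                m = logb[k, 0, s]
        c = 0.0
        for s in range(n_states):
            alpha[s] = delta[k, s] * np.exp(logb[k, 0, s] - m)
            c += alpha[s]
        if not (c > 0.0) or not np.isfinite(c):
            return np.inf
        ll += np.log(c) + m
        for s in range(n_states):
            alpha[s] /= c
        for t in range(1, n):
            m = logb[k, t, 0]
            for s in range(1, n_states):
                if logb[k, t, s] > m:
                    m = logb[k, t, s]
            c = 0.0
            for j in range(n_states):
                p = 0.0
                for i in range(n_states):
                    p += alpha[i] * gamma[i, j]
                a_new[j] = p * np.exp(logb[k, t, j] - m)
                c += a_new[j]
            if not (c > 0.0) or not np.isfinite(c):
                return np.inf
            ll += np.log(c) + m
            for s in range(n_states):
                alpha[s] = a_new[s] / c
    return -ll


@njit(cache=True)
def _forward_kernel_varying(logb, gammas, delta, lengths):  # pragma: no cover
    n_trips = logb.shape[0]
    n_states = logb.shape[2]
    ll = 0.0
    alpha = np.empty(n_states)
    a_new = np.empty(n_states)
    for k in range(n_trips):
        n = lengths[k]
        m = logb[k, 0, 0]
        for s in range(1, n_states):
            if logb[k, 0, s] > m:
                m = logb[k, 0, s]
        c = 0.0
        for s in range(n_states):
            alpha[s] = delta[k, s] * np.exp(logb[k, 0, s] - m)
            c += alpha[s]
        if not (c > 0.0) or not np.isfinite(c):
            return np.inf
        ll += np.log(c) + m
        for s in range(n_states):
            alpha[s] /= c
        for t in range(1, n):
            m = logb[k, t, 0]
            for s in range(1, n_states):
                if logb[k, t, s] > m:
                    m = logb[k, t, s]
            c = 0.0
            for j in range(n_states):
                p = 0.0
                for i in range(n_states):
                    p += alpha[i] * gammas[k, t, i, j]
                a_new[j] = p * np.exp(logb[k, t, j] - m)
                c += a_new[j]
            if not (c > 0.0) or not np.isfinite(c):
                return np.inf
            ll += np.log(c) + m
            for s in range(n_states):
                alpha[s] = a_new[s] / c
    return -ll


def _transition_stack(prep: _Prepared, beta: np.ndarray):
    """Per-observation transition matrices; constant matrix when no covariates."""
    if prep.X is None:
        eta = beta[:, 0][None, :]
        return _gamma_from_eta(eta)[0]  # (3, 3)
    eta = np.einsum("ntk,rk->ntr", prep.X, beta)
    eta = np.clip(eta, -35.0, 35.0)
    return _gamma_from_eta(eta.reshape(-1, len(OFFDIAG))).reshape(
        prep.n_trips, prep.t_max, N_STATES, N_STATES
    )


def _forward_nll(prep: _Prepared, step_mean, step_sd, turn_mu, turn_kappa, beta) -> float:
    """Negative log-likelihood via the scaled forward algorithm, trips batched."""
    logb = _emission_loglik(prep, step_mean, step_sd, turn_mu, turn_kappa)
    gammas = _transition_stack(prep, beta)
    constant_gamma = gammas.ndim == 2

    # initial distribution: stationary at each trip's first covariate row
    if constant_gamma:
        delta0 = stationary_distribution(gammas)
        if np.any(~np.isfinite(delta0)):
            delta0 = np.full(N_STATES, 1.0 / N_STATES)
        deltas = np.tile(delta0, (prep.n_trips, 1))
    else:
        deltas = np.empty((prep.n_trips, N_STATES))
        for k in range(prep.n_trips):
            d = stationary_distribution(gammas[k, 0])
            deltas[k] = d if np.all(np.isfinite(d)) else 1.0 / N_STATES

    lengths = prep.trip_lengths.astype(np.int64)
    if constant_gamma:
        out = _forward_kernel_const(logb, gammas, deltas, lengths)
    else:
        out = _forward_kernel_varying(logb, gammas, deltas, lengths)
    # a large finite value keeps finite-difference gradients well defined
    return min(out, 1e15)


# --------------------------------------------------------------------------- #
# public likelihood / decoding entry points
# --------------------------------------------------------------------------- #


def log_likelihood(params: HMMParams, data: pd.DataFrame) -> float:
    """Forward log-likelihood of per-trip step/turn sequences under ``params``.

    ``data`` needs columns step_km, turn_rad, optional trip_id and the
    covariate columns named in ``params.terms``. Missing emissions (NaN)
    contribute likelihood 1; trips are independent blocks.
    """
    prep = _Prepared(data, params.terms, params.cov_means, params.cov_sds)
    return -_forward_nll(
        prep, params.step_mean, params.step_sd, params.turn_mu, params.turn_kappa, params.beta
    )


def viterbi(params_or_fit, data: pd.DataFrame) -> np.ndarray:
    """Most likely state sequence per trip (log-space dynamic programming).

    Ties break to the lowest state index. Returns an int array aligned with
    ``data`` rows; 0=feeding, 1=travelling, 2=resting.
    """
    params = params_or_fit.params if isinstance(params_or_fit, HMMFit) else params_or_fit
    prep = _Prepared(data, params.terms, params.cov_means, params.cov_sds)
    logb = _emission_loglik(prep, params.step_mean, params.step_sd, params.turn_mu, params.turn_kappa)
    gammas = _transition_stack(prep, params.beta)
    constant_gamma = gammas.ndim == 2
    with np.errstate(divide="ignore"):
        log_gamma_const = np.log(gammas) if constant_gamma else None

    def argmax_low(arr, axis=None):
        # first index within numerical tolerance of the max: exact ties (and
        # ties blurred by solver noise) resolve to the lowest state index
        m = arr.max(axis=axis, keepdims=axis is not None)
        close = arr >= m - 1e-10 * (1.0 + np.abs(m))
        if axis is None:
            return int(np.argmax(close))
        return np.argmax(close, axis=axis)

    out = []
    for k in range(prep.n_trips):
        n = prep.trip_lengths[k]
        lb = logb[k, :n]
        if constant_gamma:
            lg = np.broadcast_to(log_gamma_const, (n, N_STATES, N_STATES))
            d = stationary_distribution(gammas)
        else:
            with np.errstate(divide="ignore"):
                lg = np.log(gammas[k, :n])
            d = stationary_distribution(gammas[k, 0])
        if np.any(~np.isfinite(d)):
            d = np.full(N_STATES, 1.0 / N_STATES)
        with np.errstate(divide="ignore"):
            score = np.log(d) + lb[0]
        back = np.zeros((n, N_STATES), dtype=int)
        for t in range(1, n):
            cand = score[:, None] + lg[t]  # cand[i, j]
            back[t] = argmax_low(cand, axis=0)
            score = np.take_along_axis(cand, back[t][None, :], axis=0)[0] + lb[t]
        path = np.empty(n, dtype=int)
        path[-1] = argmax_low(score)
        for t in range(n - 1, 0, -1):
            path[t - 1] = back[t, path[t]]
        out.append(path)
    return np.concatenate(out)


def pseudo_residuals(params_or_fit, data: pd.DataFrame) -> pd.DataFrame:
    """One-step-ahead forward-conditional CDF residuals per channel.

    Under a well-specified model each residual column is U(0, 1). NaN where
    the channel is missing.
    """
    params = params_or_fit.params if isinstance(params_or_fit, HMMFit) else params_or_fit
    prep = _Prepared(data, params.terms, params.cov_means, params.cov_sds)
    logb = _emission_loglik(prep, params.step_mean, params.step_sd, params.turn_mu, params.turn_kappa)
    gammas = _transition_stack(prep, params.beta)
    constant_gamma = gammas.ndim == 2
    shape, scale = params.gamma_shape_scale()

    step_res = np.full((prep.n_trips, prep.t_max), np.nan)
    ang_res = np.full((prep.n_trips, prep.t_max), np.nan)
    for k in range(prep.n_trips):
        n = prep.trip_lengths[k]
        d = stationary_distribution(gammas if constant_gamma else gammas[k, 0])
        if np.any(~np.isfinite(d)):
            d = np.full(N_STATES, 1.0 / N_STATES)
        pred = d
        alpha = None
        for t in range(n):
            if t > 0:
                g_t = gammas if constant_gamma else gammas[k, t]
                pred = alpha @ g_t
            s = prep.steps[k, t]
            if np.isfinite(s):
                step_res[k, t] = float(pred @ stats.gamma.cdf(s, a=shape, scale=scale))
            a = prep.angles[k, t]
            if np.isfinite(a):
                # von Mises CDF on the (-pi, pi] convention: scipy's cdf is the
                # periodic integral, so subtract its value at -pi
                cdfs = np.array(
                    [
                        stats.vonmises.cdf(a, kappa=max(params.turn_kappa[i], 1e-8), loc=params.turn_mu[i])
                        - stats.vonmises.cdf(-np.pi, kappa=max(params.turn_kappa[i], 1e-8), loc=params.turn_mu[i])
                        for i in range(N_STATES)
                    ]
                )
                ang_res[k, t] = float(pred @ np.clip(cdfs, 0.0, 1.0))
            b = np.exp(logb[k, t] - logb[k, t].max())
            alpha = pred * b
            tot = alpha.sum()
            alpha = alpha / tot if tot > 0 else np.full(N_STATES, 1.0 / N_STATES)
    mask = prep.mask
    return pd.DataFrame(
        {"step_residual": step_res[mask], "angle_residual": ang_res[mask]}
    )


# --------------------------------------------------------------------------- #
# fitting
# --------------------------------------------------------------------------- #


def _pack(step_mean, step_sd, turn_mu, turn_kappa, beta):
    return np.concatenate(
        [np.log(step_mean), np.log(step_sd), turn_mu, np.log(turn_kappa), beta.ravel()]
    )


def _unpack(theta, n_terms):
    step_mean = np.exp(theta[0:3])
    step_sd = np.exp(theta[3:6])
    turn_mu = theta[6:9]
    turn_kappa = np.exp(theta[9:12])
    beta = theta[12:].reshape(len(OFFDIAG), n_terms)
    return step_mean, step_sd, turn_mu, turn_kappa, beta


def _random_start(prep: _Prepared, rng: np.random.Generator) -> np.ndarray:
    steps = prep.steps[prep.mask]
    steps = steps[np.isfinite(steps)]
    q = np.sort(rng.uniform(0.05, 0.95, N_STATES))
    means = np.maximum(np.quantile(steps, q), _MIN_STEP_KM)
    # separate collided quantiles
    for i in range(1, N_STATES):
        means[i] = max(means[i], means[i - 1] * 1.5)
    sds = means * rng.uniform(0.3, 1.2, N_STATES)
    mus = rng.uniform(-0.3, 0.3, N_STATES)
    kappas = np.exp(rng.uniform(np.log(0.1), np.log(30.0), N_STATES))
    diag = rng.uniform(0.7, 0.95, N_STATES)
    beta = np.zeros((len(OFFDIAG), prep.n_terms))
    beta[:, 0] = persistence_intercepts(diag)
    return _pack(means, sds, mus, kappas, beta)


def fit(
    data: pd.DataFrame,
    formula=(),
    n_starts: int = 25,
    seed: int = 0,
    maxiter: int = 500,
    screen_maxiter: int = 40,
    n_polish: int = 3,
    gtol: float = 1e-6,
) -> HMMFit:
    """Fit the 3-state HMM by multistart quasi-Newton maximum likelihood.

    Each of ``n_starts`` random starts (step means spanning the data's 5-95%
    quantiles, kappa log-uniform on [0.1, 30], transition intercepts implying
    self-transition probabilities in [0.7, 0.95]) is run with L-BFGS-B for a
    capped screening pass; the ``n_polish`` best are refined to convergence
    and the lowest negative log-likelihood wins. Covariates named in
    ``formula`` (terms like "ws" or products like "ws:rwd") are centred and
    standardized internally; the transform is stored on the returned params.
    States are post-hoc ordered feeding/travelling/resting by their movement
    signature (travelling = longest steps; of the short-step pair, resting is
    the straighter, higher-kappa one).
    """
    terms = tuple(formula)
    rng = np.random.default_rng(seed)
    prep = _Prepared(data, terms, rng=rng)
    if prep.n_obs < 100:
        logger.warning("only %d steps; fits below ~100 steps are unreliable", prep.n_obs)

    def nll(theta):
        return _forward_nll(prep, *_unpack(theta, prep.n_terms))

    bounds = (
        [(np.log(1e-4), np.log(5e3))] * 6
        + [(-2 * np.pi, 2 * np.pi)] * 3
        + [(np.log(1e-3), np.log(500.0))] * 3
        + [(-25.0, 25.0)] * (len(OFFDIAG) * prep.n_terms)
    )

    starts = [_random_start(prep, rng) for _ in range(n_starts)]
    screened = []
    for s in starts:
        try:
            res = optimize.minimize(
                nll, s, method="L-BFGS-B", bounds=bounds,
                options={"maxiter": screen_maxiter, "maxfun": 10**6},
            )
            screened.append((res.fun, res.x))
        except Exception:  # a start may land in a degenerate corner
            continue
    screened = [sc for sc in screened if np.isfinite(sc[0])]
    if not screened:
        raise RuntimeError("all starts failed to produce a finite likelihood")
    screened.sort(key=lambda t: t[0])

    best = None
    for _fun0, x0 in screened[: max(1, n_polish)]:
        res = optimize.minimize(
            nll, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": maxiter, "maxfun": 10**6, "gtol": gtol},
        )
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise RuntimeError("no polished start converged to a finite likelihood")

    sm, ss, mu, kap, beta = _unpack(best.x, prep.n_terms)
    mu = np.arctan2(np.sin(mu), np.cos(mu))  # wrap to (-pi, pi]
    params = HMMParams(sm, ss, mu, kap, beta, terms, prep.cov_means, prep.cov_sds)
    params, perm = order_states(params)
    theta_ordered = _pack(
        params.step_mean, params.step_sd, params.turn_mu, params.turn_kappa, params.beta
    )
    return HMMFit(
        params=params,
        formula=terms,
        neg_log_lik=float(best.fun),
        n_parameters=params.n_parameters,
        converged=bool(best.success),
        n_starts=n_starts,
        start_values=[s for s in starts],
        _working_theta=theta_ordered,
    )


def order_states(params: HMMParams):
    """Relabel states to (feeding, travelling, resting) by movement signature.

    Travelling takes the largest step mean; of the remaining short-step
    states, resting is the straighter one (higher kappa) and feeding the more
    tortuous. Returns (reordered params, permutation new->old).
    """
    travelling = int(np.argmax(params.step_mean))
    rest_pair = [i for i in range(N_STATES) if i != travelling]
    resting = rest_pair[int(np.argmax(params.turn_kappa[rest_pair]))]
    feeding = next(i for i in rest_pair if i != resting)
    perm = [feeding, travelling, resting]  # new index -> old index
    new_beta = np.empty_like(params.beta)
    for r, (i, j) in enumerate(OFFDIAG):
        old_r = OFFDIAG.index((perm[i], perm[j]))
        new_beta[r] = params.beta[old_r]
    out = replace(
        params,
        step_mean=params.step_mean[perm],
        step_sd=params.step_sd[perm],
        turn_mu=params.turn_mu[perm],
        turn_kappa=params.turn_kappa[perm],
        beta=new_beta,
    )
    return out, perm


# --------------------------------------------------------------------------- #
# model set / AIC table
# --------------------------------------------------------------------------- #

DEFAULT_MODEL_SET: tuple[tuple[str, ...], ...] = (
    (),
    ("ws",),
    ("rwd",),
    ("rwavd",),
    ("ws", "rwd"),
    ("ws", "rwavd"),
    ("rwd", "rwavd"),
    ("ws", "rwd", "rwavd"),
    ("ws", "rwd", "ws:rwd", "rwavd"),
    ("ws", "rwd", "ws:rwd", "rwavd", "ws:rwavd"),
)


def model_set(data: pd.DataFrame, formulas=DEFAULT_MODEL_SET, n_starts=25, seed=0, **kwargs):
    """Fit the candidate covariate structures and rank them by AIC.

    Returns (fits dict keyed by formula string, AIC table DataFrame sorted
    ascending with a delta_aic column). Individual fit failures are recorded
    and the set continues.
    """
    fits, rows = {}, []
    for k, terms in enumerate(formulas):
        key = " + ".join(terms) if terms else "1"
        try:
            f = fit(data, terms, n_starts=n_starts, seed=seed + k, **kwargs)
            fits[key] = f
            rows.append({"formula": key, "neg_log_lik": f.neg_log_lik,
                         "n_parameters": f.n_parameters, "aic": f.aic})
        except Exception as exc:  # noqa: BLE001 — per-model failure must not kill the set
            logger.warning("model '%s' failed: %s", key, exc)
            rows.append({"formula": key, "neg_log_lik": np.nan, "n_parameters": np.nan, "aic": np.nan})
    table = pd.DataFrame(rows).sort_values("aic").reset_index(drop=True)
    table["delta_aic"] = table["aic"] - table["aic"].min()
    return fits, table


# --------------------------------------------------------------------------- #
# stationary curves
# --------------------------------------------------------------------------- #


def stationary(params_or_fit, covariate_grid: pd.DataFrame | None = None,
               n_boot: int = 0, seed: int = 0, data: pd.DataFrame | None = None):
    """Stationary state probabilities delta(x) over a covariate grid.

    Returns a DataFrame with one row per grid point and columns
    feeding/travelling/resting (plus *_lo/*_hi 95% bounds when ``n_boot`` > 0
    and a fit with data is supplied for the parametric bootstrap). Grid
    points where Gamma(x) is reducible come back as NaN.
    """
    fit_obj = params_or_fit if isinstance(params_or_fit, HMMFit) else None
    params = fit_obj.params if fit_obj is not None else params_or_fit

    def curve(p: HMMParams) -> np.ndarray:
        if covariate_grid is None or not p.terms:
            g = transition_matrix(p.beta[:, :1])
            return stationary_distribution(g)[None, :]
        design = _design_from_frame(covariate_grid, p.terms, p.cov_means, p.cov_sds)
        out = np.empty((len(design), N_STATES))
        for r, row in enumerate(design):
            eta = p.beta @ row
            out[r] = stationary_distribution(_gamma_from_eta(eta[None, :])[0])
        return out

    base = curve(params)
    cols = dict(zip(STATE_NAMES, base.T))
    result = pd.DataFrame(cols)
    if covariate_grid is not None:
        result = pd.concat([covariate_grid.reset_index(drop=True), result], axis=1)

    if n_boot > 0:
        if fit_obj is None or data is None:
            raise ValueError("bootstrap CIs need an HMMFit and the fitting data")
        draws = _bootstrap_beta_draws(fit_obj, data, n_boot, seed)
        stack = np.empty((n_boot, base.shape[0], N_STATES))
        for b, beta_b in enumerate(draws):
            stack[b] = curve(replace(params, beta=beta_b))
        lo = np.nanpercentile(stack, 2.5, axis=0)
        hi = np.nanpercentile(stack, 97.5, axis=0)
        for s, name in enumerate(STATE_NAMES):
            result[f"{name}_lo"] = lo[:, s]
            result[f"{name}_hi"] = hi[:, s]
    return result


def _bootstrap_beta_draws(fit_obj: HMMFit, data: pd.DataFrame, n_boot: int, seed: int):
    """Parametric bootstrap of transition coefficients from the curvature at the MLE."""
    params = fit_obj.params
    prep = _Prepared(data, params.terms, params.cov_means, params.cov_sds)
    theta0 = fit_obj._working_theta
    idx = np.arange(12, theta0.size)  # beta block of the working vector

    def nll_beta(b):
        th = theta0.copy()
        th[idx] = b
        return _forward_nll(prep, *_unpack(th, prep.n_terms))

    b0 = theta0[idx]
    h = _fd_hessian(nll_beta, b0)
    try:
        cov = np.linalg.inv(h)
        # symmetrize and repair if the FD Hessian is slightly indefinite
        cov = (cov + cov.T) / 2.0
        w, v = np.linalg.eigh(cov)
        cov = (v * np.clip(w, 1e-10, None)) @ v.T
    except np.linalg.LinAlgError:
        cov = np.eye(b0.size) * 1e-4
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal(b0, cov, size=n_boot)
    return [d.reshape(params.beta.shape) for d in draws]


def _fd_hessian(f, x0, eps=1e-4):
    n = x0.size
    h = np.empty((n, n))
    f0 = f(x0)
    fp = np.empty(n)
    for i in range(n):
        e = np.zeros(n); e[i] = eps
        fp[i] = f(x0 + e)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = eps
            ej = np.zeros(n); ej[j] = eps
            fij = f(x0 + ei + ej)
            h[i, j] = h[j, i] = (fij - fp[i] - fp[j] + f0) / eps**2
    return h


# --------------------------------------------------------------------------- #
# simulation
# --------------------------------------------------------------------------- #


def simulate_hmm_data(
    params: HMMParams,
    n_trips: int,
    n_steps: int,
    seed: int = 0,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Simulate step/turn sequences (plus true states) from the model.

    ``covariates`` optionally supplies n_trips*n_steps rows of the base
    covariate columns driving the transitions; otherwise transitions use the
    intercepts only. Returns a DataFrame with trip_id, step_km, turn_rad,
    state (truth, 0/1/2) and any covariate columns.
    """
    rng = np.random.default_rng(seed)
    shape, scale = params.gamma_shape_scale()
    frames = []
    base = _base_covariates(params.terms)
    for k in range(n_trips):
        if covariates is not None:
            cov_k = covariates.iloc[k * n_steps : (k + 1) * n_steps].reset_index(drop=True)
            design = _design_from_frame(cov_k, params.terms, params.cov_means, params.cov_sds)
            gam = _gamma_from_eta(np.clip(design @ params.beta.T, -35, 35))
        else:
            gam = np.tile(_gamma_from_eta(params.beta[:, :1].T)[0], (n_steps, 1, 1))
        d0 = stationary_distribution(gam[0])
        if np.any(~np.isfinite(d0)):
            d0 = np.full(N_STATES, 1.0 / N_STATES)
        states = np.empty(n_steps, dtype=int)
        states[0] = rng.choice(N_STATES, p=d0)
        for t in range(1, n_steps):
            states[t] = rng.choice(N_STATES, p=gam[t, states[t - 1]])
        steps = rng.gamma(shape[states], scale[states])
        angles = rng.vonmises(params.turn_mu[states], np.maximum(params.turn_kappa[states], 1e-8))
        frame = pd.DataFrame(
            {"trip_id": k, "step_km": steps, "turn_rad": angles, "state": states}
        )
        if covariates is not None:
            for c in base:
                frame[c] = cov_k[c].to_numpy()
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)
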