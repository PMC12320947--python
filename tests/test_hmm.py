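import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from windforage import hmm


def brute_force_loglik(params, df):
    """Exhaustive path-sum oracle for short single-trip sequences."""
    shape, scale = params.gamma_shape_scale()
    g = hmm.transition_matrix(params.beta[:, :1])
    delta = hmm.stationary_distribution(g)
    n = len(df)

    def emis(t, s):
        lp = 0.0
        step = df["step_km"].iloc[t]
        if np.isfinite(step):
            lp += stats.gamma.logpdf(max(step, 1e-3), a=shape[s], scale=scale[s])
        ang = df["turn_rad"].iloc[t]
        if np.isfinite(ang):
            lp += stats.vonmises.logpdf(ang, kappa=params.turn_kappa[s], loc=params.turn_mu[s])
        return lp

    total = -np.inf
    for path in itertools.product(range(3), repeat=n):
        lp = np.log(delta[path[0]]) + emis(0, path[0])
        for t in range(1, n):
            lp += np.log(g[path[t - 1], path[t]]) + emis(t, path[t])
        total = np.logaddexp(total, lp)
    return total


def brute_force_viterbi(params, df):
    shape, scale = params.gamma_shape_scale()
    g = hmm.transition_matrix(params.beta[:, :1])
    delta = hmm.stationary_distribution(g)
    n = len(df)

    def emis(t, s):
        lp = stats.gamma.logpdf(max(df["step_km"].iloc[t], 1e-3), a=shape[s], scale=scale[s])
        lp += stats.vonmises.logpdf(df["turn_rad"].iloc[t], kappa=params.turn_kappa[s], loc=params.turn_mu[s])
        return lp

    best, best_lp = None, -np.inf
    for path in itertools.product(range(3), repeat=n):
        lp = np.log(delta[path[0]]) + emis(0, path[0])
        for t in range(1, n):
            lp += np.log(g[path[t - 1], path[t]]) + emis(t, path[t])
        if lp > best_lp:
            best, best_lp = path, lp
    return np.array(best)


class TestTransitionMatrix:
    def test_zero_coefficients_give_uniform_rows(self):
        g = hmm.transition_matrix(np.zeros((6, 1)))
        assert np.allclose(g, 1.0 / 3.0)

    def test_persistence_intercepts_recover_diagonals(self):
        diag = np.array([0.91, 0.92, 0.88])
        g = hmm.transition_matrix(hmm.persistence_intercepts(diag)[:, None])
        assert np.allclose(np.diag(g), diag, atol=1e-10)
        off = g[~np.eye(3, dtype=bool)].reshape(3, 2)
        assert np.allclose(off, ((1 - diag) / 2)[:, None], atol=1e-10)
        assert np.allclose(g.sum(axis=1), 1.0, atol=1e-12)

    def test_positive_coefficient_is_monotone_in_covariate(self):
        beta = np.zeros((6, 2))
        beta[0, 1] = 1.0  # feeding -> travelling increases with x
        g_lo = hmm.transition_matrix(beta, [0.0])
        g_hi = hmm.transition_matrix(beta, [1.0])
        assert g_hi[0, 1] > g_lo[0, 1]
        assert g_hi[0, 0] < g_lo[0, 0]

    def test_rows_sum_to_one_for_extreme_covariates(self):
        beta = np.full((6, 2), 5.0)
        for x in (-100.0, 0.0, 100.0):
            g = hmm.transition_matrix(beta, [x])
            assert np.allclose(g.sum(axis=1), 1.0)
            assert np.all(g >= 0)


class TestForwardLikelihood:
    def test_matches_exhaustive_enumeration(self, reference_params):
        data = hmm.simulate_hmm_data(reference_params, n_trips=1, n_steps=4, seed=3)
        expected = brute_force_loglik(reference_params, data)
        got = hmm.log_likelihood(reference_params, data)
        assert got == pytest.approx(expected, abs=1e-10)

    def test_invariant_to_trip_ordering(self, reference_params):
        data = hmm.simulate_hmm_data(reference_params, n_trips=4, n_steps=30, seed=9)
        ll1 = hmm.log_likelihood(reference_params, data)
        shuffled = pd.concat(
            [data[data.trip_id == k] for k in (2, 0, 3, 1)], ignore_index=True
        )
        assert hmm.log_likelihood(reference_params, shuffled) == pytest.approx(ll1, abs=1e-8)

    def test_missing_emissions_contribute_unit_likelihood(self, reference_params):
        data = hmm.simulate_hmm_data(reference_params, n_trips=1, n_steps=5, seed=4)
        full = hmm.log_likelihood(reference_params, data)
        # blanking an angle can only remove (negative) log-density terms
        data2 = data.copy()
        data2.loc[2, "turn_rad"] = np.nan
        partial = hmm.log_likelihood(reference_params, data2)
        assert np.isfinite(partial) and partial != full

    def test_identical_emissions_collapse_to_mixture(self):
        # all states share one emission law and a uniform transition matrix:
        # the log-likelihood is the iid sum of single-state densities
        p = hmm.HMMParams(
            step_mean=[2.0, 2.0, 2.0],
            step_sd=[1.0, 1.0, 1.0],
            turn_mu=[0.0, 0.0, 0.0],
            turn_kappa=[1.5, 1.5, 1.5],
            beta=np.zeros((6, 1)),
        )
        data = hmm.simulate_hmm_data(p, n_trips=1, n_steps=40, seed=0)
        shape, scale = p.gamma_shape_scale()
        iid = (
            stats.gamma.logpdf(data.step_km, a=shape[0], scale=scale[0]).sum()
            + stats.vonmises.logpdf(data.turn_rad, kappa=1.5, loc=0.0).sum()
        )
        assert hmm.log_likelihood(p, data) == pytest.approx(iid, abs=1e-8)

    def test_non_finite_covariate_raises(self, reference_params):
        data = hmm.simulate_hmm_data(reference_params, n_trips=1, n_steps=30, seed=2)
        data["ws"] = 1.0
        data.loc[3, "ws"] = np.nan
        with pytest.raises(ValueError, match="ws"):
            hmm.fit(data, ("ws",), n_starts=1)


class TestViterbi:
    def test_matches_exhaustive_argmax(self, reference_params):
        data = hmm.simulate_hmm_data(reference_params, n_trips=1, n_steps=5, seed=8)
        expected = brute_force_viterbi(reference_params, data)
        got = hmm.viterbi(reference_params, data)
        assert np.array_equal(got, expected)

    def test_near_deterministic_emissions_recover_states(self, reference_params):
        data = hmm.simulate_hmm_data(reference_params, n_trips=10, n_steps=300, seed=12)
        decoded = hmm.viterbi(reference_params, data)
        agree = (decoded == data["state"].to_numpy()).mean()
        assert agree >= 0.95  # states are well separated at these parameters

    def test_uniform_model_breaks_ties_to_lowest_state(self):
        p = hmm.HMMParams(
            step_mean=[1.0, 1.0, 1.0], step_sd=[1.0, 1.0, 1.0],
            turn_mu=[0.0, 0.0, 0.0], turn_kappa=[1.0, 1.0, 1.0],
            beta=np.zeros((6, 1)),
        )
        data = hmm.simulate_hmm_data(p, n_trips=1, n_steps=10, seed=1)
        assert np.all(hmm.viterbi(p, data) == 0)


class TestStationary:
    def test_uniform_for_doubly_stochastic_symmetric(self):
        g = np.array([[0.8, 0.1, 0.1], [0.1, 0.8, 0.1], [0.1, 0.1, 0.8]])
        assert np.allclose(hmm.stationary_distribution(g), 1.0 / 3.0, atol=1e-12)

    def test_two_state_embedding_closed_form(self):
        # states 1 and 2 merged: delta proportional to (b, a) for the
        # embedded 2-state chain with off-diagonals a (0->1) and b (1->0)
        a, b = 0.2, 0.05
        g = np.array(
            [[1 - a, a / 2, a / 2], [b, (1 - b) / 2, (1 - b) / 2], [b, (1 - b) / 2, (1 - b) / 2]]
        )
        delta = hmm.stationary_distribution(g)
        expected0 = b / (a + b)
        assert delta[0] == pytest.approx(expected0, abs=1e-12)
        assert delta[1] == pytest.approx((1 - expected0) / 2, abs=1e-12)

    def test_residual_below_1e10_on_random_matrices(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            raw = rng.gamma(1.0, 1.0, (3, 3))
            g = raw / raw.sum(axis=1, keepdims=True)
            d = hmm.stationary_distribution(g)
            assert np.max(np.abs(d @ g - d)) < 1e-10


class TestSimulationAndRecovery:
    def test_simulation_is_seed_deterministic(self, reference_params):
        a = hmm.simulate_hmm_data(reference_params, 3, 50, seed=5)
        b = hmm.simulate_hmm_data(reference_params, 3, 50, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_emission_samples_pass_distributional_gof(self, reference_params):
        data = hmm.simulate_hmm_data(reference_params, n_trips=20, n_steps=500, seed=23)
        shape, scale = reference_params.gamma_shape_scale()
        for s in range(3):
            steps = data.loc[data.state == s, "step_km"]
            assert len(steps) > 500
            p = stats.kstest(
                steps, lambda q, s=s: stats.gamma.cdf(q, a=shape[s], scale=scale[s])
            ).pvalue
            assert p > 0.01
            angles = data.loc[data.state == s, "turn_rad"]

            def vm_cdf(q, s=s):
                # PIT on (-pi, pi]: scipy's cdf is the periodic integral
                kap, mu = reference_params.turn_kappa[s], reference_params.turn_mu[s]
                return stats.vonmises.cdf(q, kappa=kap, loc=mu) - stats.vonmises.cdf(
                    -np.pi, kappa=kap, loc=mu
                )

            assert stats.kstest(angles, vm_cdf).pvalue > 0.01

    def test_travelling_mean_step_law_of_large_numbers(self, reference_params):
        data = hmm.simulate_hmm_data(reference_params, n_trips=20, n_steps=500, seed=22)
        trav = data.loc[data.state == 1, "step_km"]
        se = reference_params.step_sd[1] / np.sqrt(len(trav))
        assert abs(trav.mean() - reference_params.step_mean[1]) < 2 * se + 1e-9

    def test_fit_is_seed_deterministic(self, reference_params):
        data = hmm.simulate_hmm_data(reference_params, n_trips=4, n_steps=120, seed=30)
        f1 = hmm.fit(data, n_starts=4, seed=11)
        f2 = hmm.fit(data, n_starts=4, seed=11)
        assert f1.neg_log_lik == f2.neg_log_lik
        assert np.array_equal(f1.params.step_mean, f2.params.step_mean)

    def test_order_states_maps_movement_signatures(self):
        # scrambled state order: travelling (long) at index 0, feeding at 2
        p = hmm.HMMParams(
            step_mean=[3.1, 0.1, 0.7], step_sd=[0.6, 0.04, 0.8],
            turn_mu=[0.0, 0.0, 0.0], turn_kappa=[19.2, 25.2, 0.7],
            beta=hmm.persistence_intercepts([0.92, 0.88, 0.91])[:, None],
        )
        q, perm = hmm.order_states(p)
        assert perm == [2, 0, 1]
        assert np.allclose(q.step_mean, [0.7, 3.1, 0.1])
        assert np.allclose(q.turn_kappa, [0.7, 19.2, 25.2])
        g = hmm.transition_matrix(q.beta[:, :1])
        assert np.allclose(np.diag(g), [0.91, 0.92, 0.88], atol=1e-10)

    def test_aic_identity(self, reference_params):
        data = hmm.simulate_hmm_data(reference_params, n_trips=4, n_steps=120, seed=31)
        f = hmm.fit(data, n_starts=3, seed=1)
        assert f.aic == pytest.approx(2 * f.neg_log_lik + 2 * f.n_parameters)


class TestPseudoResiduals:
    def test_residuals_in_unit_interval_and_uniform_when_well_specified(self, reference_params):
        data = hmm.simulate_hmm_data(reference_params, n_trips=10, n_steps=300, seed=40)
        res = hmm.pseudo_residuals(reference_params, data)
        for col in ("step_residual", "angle_residual"):
            r = res[col].dropna()
            assert ((r >= 0) & (r <= 1)).all()
            assert stats.kstest(r, "uniform").pvalue > 0.01

    def test_misspecified_model_is_rejected(self, reference_params):
        data = hmm.simulate_hmm_data(reference_params, n_trips=10, n_steps=300, seed=41)
        lumped = hmm.HMMParams(
            step_mean=[1.0, 1.0, 1.0], step_sd=[1.0, 1.0, 1.0],
            turn_mu=[0.0, 0.0, 0.0], turn_kappa=[1.0, 1.0, 1.0],
            beta=np.zeros((6, 1)),
        )
        res = hmm.pseudo_residuals(lumped, data)
        assert stats.kstest(res["step_residual"].dropna(), "uniform").pvalue < 0.01


class TestModelSet:
    def test_default_enumeration_has_ten_models(self):
        assert len(hmm.DEFAULT_MODEL_SET) == 10
        assert hmm.DEFAULT_MODEL_SET[0] == ()
        assert "ws:rwd" in hmm.DEFAULT_MODEL_SET[-1]

    def test_null_data_keeps_null_model_competitive(self, reference_params):
        data = hmm.simulate_hmm_data(reference_params, n_trips=6, n_steps=250, seed=50)
        rng = np.random.default_rng(1)
        data["ws"] = rng.uniform(0.5, 11.8, len(data))
        fits, table = hmm.model_set(
            data, formulas=((), ("ws",)), n_starts=4, seed=3, screen_maxiter=25
        )
        null_aic = table.loc[table.formula == "1", "aic"].iloc[0]
        assert null_aic - table.aic.min() < 2.0 + 1e-9

    def test_covariate_driven_transitions_win_by_aic(self):
        # feeding persistence increases strongly with wind speed
        beta = hmm.persistence_intercepts([0.85, 0.9, 0.85])[:, None]
        beta_cov = np.hstack([beta, np.zeros((6, 1))])
        beta_cov[0, 1] = -1.6  # feeding -> travelling drops with ws
        beta_cov[1, 1] = -1.6  # feeding -> resting drops with ws
        p = hmm.HMMParams(
            step_mean=[0.7, 3.1, 0.1], step_sd=[0.8, 0.6, 0.04],
            turn_mu=[0.0, 0.0, 0.0], turn_kappa=[0.7, 19.2, 25.2],
            beta=beta_cov, terms=("ws",),
        )
        rng = np.random.default_rng(7)
        n_trips, n_steps = 10, 400
        cov = pd.DataFrame({"ws": rng.uniform(-1.5, 1.5, n_trips * n_steps)})
        data = hmm.simulate_hmm_data(p, n_trips, n_steps, seed=8, covariates=cov)
        fits, table = hmm.model_set(
            data, formulas=((), ("ws",)), n_starts=5, seed=2, screen_maxiter=25
        )
        aic_null = table.loc[table.formula == "1", "aic"].iloc[0]
        aic_ws = table.loc[table.formula == "ws", "aic"].iloc[0]
        assert aic_ws < aic_null - 10.0
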