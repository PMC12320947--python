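import numpy as np
import pandas as pd
import pytest

from windforage import gam


@pytest.fixture(scope="module")
def xy():
    rng = np.random.default_rng(0)
    n = 800
    return rng.uniform(0, 10, n), rng.uniform(0, 180, n), rng


class TestTensorBasis:
    def test_marginal_partition_of_unity(self, xy):
        x1, x2, _ = xy
        design, pens, k1, k2 = gam.tensor_basis(x1, x2, knots=4)
        # tensor rows sum to one because each margin does
        assert np.allclose(design.sum(axis=1), 1.0, atol=1e-10)

    def test_tensor_dimension_is_square_of_marginal(self, xy):
        x1, x2, _ = xy
        for k in (4, 6):
            design, pens, *_ = gam.tensor_basis(x1, x2, knots=k)
            assert design.shape[1] == k * k
            assert pens[0].shape == (k * k, k * k)

    def test_constant_covariate_raises(self, xy):
        x1, _, _ = xy
        with pytest.raises(ValueError, match="constant"):
            gam.tensor_basis(x1, np.full_like(x1, 3.0))

    def test_linear_function_reproduced(self, xy):
        x1, x2, _ = xy
        y = 2.0 + 0.5 * x1
        df = pd.DataFrame({"y": y, "ws": x1, "rwd": x2})
        fit = gam.fit_gam(df, gam.GAMSpec(family="gaussian", response="y"))
        pred = gam.linear_predictor(fit, x1, x2)
        assert np.max(np.abs(pred - y)) < 1e-6


class TestAUC:
    def test_perfect_separation_is_one(self):
        assert gam.auc([1, 2, 3, 10, 11], [0, 0, 0, 1, 1]) == 1.0

    def test_toy_table_matches_pairwise_brute_force(self):
        rng = np.random.default_rng(5)
        scores = rng.choice([0.1, 0.3, 0.3, 0.7, 0.9], size=30)
        labels = rng.integers(0, 2, 30)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        weights = rng.uniform(0.5, 3.0, 30)
        brute = 0.0
        for i in np.flatnonzero(labels == 1):
            for j in np.flatnonzero(labels == 0):
                c = 1.0 if scores[i] > scores[j] else (0.5 if scores[i] == scores[j] else 0.0)
                brute += weights[i] * weights[j] * c
        brute /= weights[labels == 1].sum() * weights[labels == 0].sum()
        assert gam.auc(scores, labels, weights) == pytest.approx(brute, abs=1e-12)

    def test_permuted_labels_near_half(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=4000)
        labels = rng.integers(0, 2, 4000)
        assert gam.auc(scores, labels) == pytest.approx(0.5, abs=0.03)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            gam.auc([1, 2], [1, 1])


class TestFitGam:
    def test_gaussian_noiseless_linear_recovery(self, xy):
        x1, x2, _ = xy
        y = 1.0 - 0.2 * x1 + 0.01 * x2
        df = pd.DataFrame({"y": y, "ws": x1, "rwd": x2})
        fit = gam.fit_gam(df, gam.GAMSpec(family="gaussian", response="y"))
        resid = gam.linear_predictor(fit, x1, x2) - y
        assert np.max(np.abs(resid)) < 1e-6

    def test_unit_weights_match_unweighted_fit(self, xy):
        x1, x2, rng = xy
        y = (rng.uniform(size=len(x1)) < 1 / (1 + np.exp(-(x1 - 5) / 2))).astype(int)
        df = pd.DataFrame({"used": y, "ws": x1, "rwd": x2, "weight": 1.0})
        f_w = gam.fit_gam(df, gam.GAMSpec(family="bernoulli", weights="weight"))
        f_u = gam.fit_gam(df, gam.GAMSpec(family="bernoulli"))
        assert np.allclose(f_w.coef, f_u.coef, atol=1e-8)
        assert f_w.auc == pytest.approx(f_u.auc, abs=1e-12)

    def test_beta_family_recovers_mean_structure(self, xy):
        x1, x2, rng = xy
        mu = 1 / (1 + np.exp(-(-1.0 + 0.3 * (x1 - 5))))
        y = np.clip(mu + rng.normal(0, 0.05, len(x1)), 0.0, 1.0)
        df = pd.DataFrame({"prop": y, "ws": x1, "rwd": x2})
        fit = gam.fit_gam(df, gam.GAMSpec(family="beta", response="prop"))
        surf, _ = gam.predict_surface(fit, np.array([2.0, 8.0]), np.array([90.0]))
        assert surf[0, 1] > surf[0, 0]  # increasing in wind speed
        assert fit.phi is not None and fit.phi > 0

    def test_bernoulli_invalid_response_raises(self, xy):
        x1, x2, _ = xy
        df = pd.DataFrame({"used": np.full(len(x1), 0.5), "ws": x1, "rwd": x2})
        with pytest.raises(ValueError, match="0/1"):
            gam.fit_gam(df, gam.GAMSpec(family="bernoulli"))

    def test_seeded_fit_deterministic_with_grouping(self, xy):
        x1, x2, rng = xy
        y = rng.integers(0, 2, len(x1))
        df = pd.DataFrame({
            "used": y, "ws": x1, "rwd": x2,
            "individual_id": np.repeat(np.arange(8), 100),
            "trip_id": np.repeat(np.arange(40), 20),
        })
        spec = gam.GAMSpec(family="bernoulli", individual="individual_id", trip="trip_id")
        f1 = gam.fit_gam(df, spec, seed=4)
        f2 = gam.fit_gam(df, spec, seed=4)
        assert f1.lam == f2.lam
        assert np.array_equal(f1.coef, f2.coef)


class TestPredictSurface:
    def test_constant_fit_gives_flat_surface(self, xy):
        x1, x2, _ = xy
        df = pd.DataFrame({"y": np.full(len(x1), 3.3), "ws": x1, "rwd": x2})
        fit = gam.fit_gam(df, gam.GAMSpec(family="gaussian", response="y"))
        surf, _ = gam.predict_surface(fit, np.linspace(1, 9, 9), np.linspace(10, 170, 9))
        assert np.allclose(surf, 3.3, atol=1e-6)

    def test_surface_is_smooth_between_adjacent_cells(self, xy):
        x1, x2, rng = xy
        eta = 0.5 * np.sin(x1 / 3) + 0.3 * np.cos(x2 / 60)
        y = (rng.uniform(size=len(x1)) < 1 / (1 + np.exp(-eta))).astype(int)
        df = pd.DataFrame({"used": y, "ws": x1, "rwd": x2})
        fit = gam.fit_gam(df, gam.GAMSpec(family="bernoulli"))
        grid1 = np.linspace(1, 9, 80)
        surf, _ = gam.predict_surface(fit, grid1, np.linspace(10, 170, 80))
        assert np.max(np.abs(np.diff(surf, axis=0))) < 0.05
        assert np.max(np.abs(np.diff(surf, axis=1))) < 0.05

    def test_extrapolation_flagged(self, xy):
        x1, x2, _ = xy
        df = pd.DataFrame({"y": x1, "ws": x1, "rwd": x2})
        fit = gam.fit_gam(df, gam.GAMSpec(family="gaussian", response="y"))
        _, extrap = gam.predict_surface(fit, np.array([-5.0, 5.0]), np.array([90.0]))
        assert extrap[0, 0] and not extrap[0, 1]


class TestEffectSummary:
    def test_deterministic_under_seed_and_signal_ordering(self, xy):
        x1, x2, rng = xy
        for scale, label in ((0.5, "weak"), (1.5, "strong")):
            eta = scale * (x1 - 5) / 3
            y = (rng.uniform(size=len(x1)) < 1 / (1 + np.exp(-eta))).astype(int)
            df = pd.DataFrame({"used": y, "ws": x1, "rwd": x2,
                               "trip_id": np.repeat(np.arange(40), 20)})
            fit = gam.fit_gam(df, gam.GAMSpec(family="bernoulli", trip="trip_id"))
            with pytest.warns(UserWarning):
                s1 = gam.smooth_effect_summary(fit, df, n_boot=20, seed=2)
                s2 = gam.smooth_effect_summary(fit, df, n_boot=20, seed=2)
            pd.testing.assert_frame_equal(s1, s2)
            if label == "weak":
                weak_ws = s1.set_index("term").mean_effect["ws"]
            else:
                strong_ws = s1.set_index("term").mean_effect["ws"]
        assert strong_ws > weak_ws


def test_outbound_only_preference_creates_leg_asymmetry(wind_field):
    """Selectivity injected on outbound legs only produces leg-specific
    selection patterns: the outbound model detects a tailwind preference
    (AUC > 0.6, surface peaking at low relative wind direction), while the
    inbound surface shows the geometrically induced mirror (a downwind
    outbound forces an upwind return, so its peak sits at high relative
    wind direction) rather than any tailwind preference."""
    from windforage import hmm, pipeline, simulate, tracks

    colony = (-7.23, 72.42)
    params = hmm.reference_params()
    staged = []
    for k in range(150):
        tr, _ = simulate.simulate_trip(
            colony, params, wind_field=wind_field, selectivity_strength=0.9,
            selectivity_stages=("outbound",), n_steps=60,
            individual_id=f"bird{k % 15:02d}",
            start_time=pd.Timestamp("2022-02-01T06:00Z") + pd.Timedelta(hours=(k % 10) * 12),
            seed=9000 + k,
        )
        for j, t in enumerate(tracks.process_track(tr, colony)):
            t["trip_id"] = f"t{k}_{j}"
            staged.append(t)
    table = pipeline.build_selectivity_table(
        staged, colony, wind_field, None, n_rotations=20, ratio=10, seed=6
    )
    spec = gam.GAMSpec(
        family="bernoulli", response="used", x1="ws", x2="rwd",
        weights="weight", individual="individual_id", trip="trip_id",
    )
    rwd_grid = np.linspace(0.0, 180.0, 19)
    profiles = {}
    for leg in ("outbound", "inbound"):
        sub = table[table.stage == leg]
        fit = gam.fit_gam(sub, spec, seed=0)
        ws_grid = np.linspace(sub.ws.quantile(0.1), sub.ws.quantile(0.9), 9)
        surface, _ = gam.predict_surface(fit, ws_grid, rwd_grid)
        profiles[leg] = surface.mean(axis=1)
        if leg == "outbound":
            assert fit.auc > 0.6
    assert rwd_grid[int(np.argmax(profiles["outbound"]))] <= 45.0
    assert rwd_grid[int(np.argmax(profiles["inbound"]))] >= 135.0
    assert profiles["inbound"][0] < profiles["inbound"][-1]  # no tailwind preference inbound
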