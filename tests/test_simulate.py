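import numpy as np
import pandas as pd
import pytest
from scipy import stats

from windforage import environment, geo, hmm, simulate

COLONY = (-7.23, 72.42)
BBOX = (-10.0, -4.0, 69.0, 76.0)
SPAN = ("2022-02-01", "2022-02-03")


class TestWindField:
    def test_constant_regime_gives_pythagorean_speed(self):
        # from-direction chosen so that (u, v) = (3, 4) everywhere
        dir_to = np.degrees(np.arctan2(3.0, 4.0))
        f = simulate.simulate_wind_field(
            BBOX, SPAN, mean_direction_from=(dir_to + 180.0) % 360.0,
            speed_range=(5.0, 5.0), direction_sd=0.0, seed=1,
        )
        speed = np.hypot(f.u10.values, f.v10.values)
        assert np.allclose(speed, 5.0)
        assert np.allclose(f.u10.values, 3.0, atol=1e-9)
        assert np.allclose(f.v10.values, 4.0, atol=1e-9)

    def test_zero_spread_blows_opposite_to_from_direction(self):
        f = simulate.simulate_wind_field(
            BBOX, SPAN, mean_direction_from=225.0, speed_range=(4.0, 4.0),
            direction_sd=0.0, seed=1,
        )
        _, dir_to = environment.wind_from_uv(f.u10.values, f.v10.values)
        assert np.allclose(dir_to, 45.0, atol=1e-9)

    def test_speeds_within_range_and_seed_reproducible(self):
        a = simulate.simulate_wind_field(BBOX, SPAN, 225.0, (0.5, 11.8), seed=9)
        b = simulate.simulate_wind_field(BBOX, SPAN, 225.0, (0.5, 11.8), seed=9)
        speed = np.hypot(a.u10.values, a.v10.values)
        assert speed.min() >= 0.5 and speed.max() <= 11.8
        assert np.array_equal(a.u10.values, b.u10.values)
        assert np.array_equal(a.v10.values, b.v10.values)

    def test_degenerate_bbox_raises(self):
        with pytest.raises(ValueError, match="2 grid cells"):
            simulate.simulate_wind_field((-7.0, -7.0, 70.0, 72.0), SPAN)

    def test_wave_field_invariants(self):
        w = simulate.simulate_wave_field(BBOX, SPAN, seed=4)
        assert (w.swh.values >= 0).all()
        assert (w.mwp.values > 0).all()
        assert ((w.mwd.values >= 0) & (w.mwd.values < 360)).all()


class TestTrip:
    def test_trip_starts_and_ends_at_colony(self, reference_params):
        track, truth = simulate.simulate_trip(COLONY, reference_params, n_steps=80, seed=3)
        assert (track.lat.iloc[0], track.lon.iloc[0]) == COLONY
        assert (track.lat.iloc[-1], track.lon.iloc[-1]) == COLONY
        assert len(truth.states) == len(track) - 1

    def test_seed_determinism(self, reference_params):
        a, _ = simulate.simulate_trip(COLONY, reference_params, n_steps=60, seed=7)
        b, _ = simulate.simulate_trip(COLONY, reference_params, n_steps=60, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_absorbing_travelling_state_emits_only_travelling(self, reference_params):
        beta = hmm.persistence_intercepts([1e-9, 1.0 - 1e-9, 1e-9])
        p = hmm.HMMParams(
            step_mean=reference_params.step_mean, step_sd=reference_params.step_sd,
            turn_mu=reference_params.turn_mu, turn_kappa=reference_params.turn_kappa,
            beta=np.clip(beta, -20, 20)[:, None],
        )
        _, truth = simulate.simulate_trip(COLONY, p, n_steps=60, seed=1)
        assert np.all(truth.states == 1)

    def test_zero_selectivity_outbound_relative_directions_uniform(self, reference_params, wind_field):
        # over 200 trips the outbound relative wind directions carry no wind
        # information: chi-squared GOF against uniform on [0, 180]
        # one value per trip: fixes within a leg share a departure bearing, so
        # the leg (not the fix) is the independent unit
        rel_dirs = []
        _, wind_to = environment.wind_from_uv(3.0, 3.0)  # fixed reference flow
        for k in range(200):
            track, truth = simulate.simulate_trip(
                COLONY, reference_params, wind_field=None, selectivity_strength=0.0,
                n_steps=40, seed=100 + k,
            )
            n_out = int(0.4 * 40)
            leg_bearing = geo.initial_bearing_deg(
                track.lat.iloc[0], track.lon.iloc[0], track.lat.iloc[n_out], track.lon.iloc[n_out]
            )
            rel_dirs.append(float(environment.relative_direction(leg_bearing, wind_to)))
        counts, _ = np.histogram(rel_dirs, bins=6, range=(0, 180))
        p = stats.chisquare(counts).pvalue
        assert p > 0.01

    def test_emitted_travelling_steps_match_generating_mean(self, reference_params):
        steps, states = [], []
        for k in range(60):
            _, truth = simulate.simulate_trip(COLONY, reference_params, n_steps=200, seed=500 + k)
            steps.append(truth.emitted_steps[:-1])
            states.append(truth.states[:-1])
        steps = np.concatenate(steps)
        states = np.concatenate(states)
        trav = steps[states == 1]
        assert len(trav) > 1e4 * 0.3
        se = reference_params.step_sd[1] / np.sqrt(len(trav))
        assert abs(trav.mean() - reference_params.step_mean[1]) < 2 * se

    def test_invalid_inputs_raise(self, reference_params):
        with pytest.raises(ValueError, match="n_steps"):
            simulate.simulate_trip(COLONY, reference_params, n_steps=5)
        with pytest.raises(ValueError, match="wind field"):
            simulate.simulate_trip(COLONY, reference_params, selectivity_strength=0.5)
        bad = hmm.reference_params()
        bad.step_mean = np.array([np.nan, 3.1, 0.1])
        with pytest.raises(ValueError, match="finite"):
            simulate.simulate_trip(COLONY, bad, n_steps=30)


@pytest.fixture(scope="module")
def one_hour_dense(reference_params):
    track, _ = simulate.simulate_trip(COLONY, reference_params, n_steps=20, seed=2)
    track = track.iloc[:13].reset_index(drop=True)  # exactly 1 h at 5-min steps
    return simulate.densify(track, interval_s=1.0)


class TestGPSSampling:
    def test_regular_scheme_hourly_fix_count(self, one_hour_dense):
        out = simulate.simulate_gps_sampling(one_hour_dense, "regular_30s", 0.0)
        assert len(out) == 121

    def test_burst_scheme_hourly_burst_count(self, one_hour_dense):
        out = simulate.simulate_gps_sampling(one_hour_dense, "burst_1Hz_15s_per_5min", 0.0)
        ts = pd.to_datetime(out.timestamp)
        bursts = ((ts - ts.iloc[0]).dt.total_seconds() // 300).nunique()
        assert bursts == 12
        assert len(out) <= 12 * 15

    def test_dropout_reproducible_and_bounded(self, one_hour_dense):
        a = simulate.simulate_gps_sampling(one_hour_dense, "regular_30s", 0.5, seed=4)
        b = simulate.simulate_gps_sampling(one_hour_dense, "regular_30s", 0.5, seed=4)
        pd.testing.assert_frame_equal(a, b)
        assert 0 < len(a) < 121

    def test_invalid_dropout_and_scheme(self, one_hour_dense):
        with pytest.raises(ValueError, match="dropout"):
            simulate.simulate_gps_sampling(one_hour_dense, "regular_30s", 1.0)
        with pytest.raises(ValueError, match="scheme"):
            simulate.simulate_gps_sampling(one_hour_dense, "every_minute")


class TestAccel:
    def test_all_glide_zero_noise_has_zero_odba(self):
        from windforage import accel

        params = {b: {"noise": 0.0} for b in simulate.BEHAVIOURS}
        stream = simulate.simulate_accel(["glide"] * 20, params=params, seed=0)
        feats = accel.segment_features(stream)
        assert np.allclose(feats.mean_odba, 0.0, atol=1e-12)
        assert np.allclose(feats.mean_vedba, 0.0, atol=1e-12)

    def test_static_vector_is_unit_heave_without_offset(self):
        stream = simulate.simulate_accel(["sit"] * 30, orientation_offset=0.0, seed=1)
        mean_vec = stream[["ax", "ay", "az"]].mean().to_numpy()
        assert np.allclose(mean_vec, [0.0, 0.0, 1.0], atol=0.03)

    def test_flap_vedba_exceeds_glide_across_seed_sweep(self):
        from windforage import accel

        for seed in range(50):
            stream = simulate.simulate_accel(["flap"] * 5 + ["glide"] * 5, seed=seed)
            feats = accel.segment_features(stream)
            flap = feats.mean_vedba.iloc[:5].mean()
            glide = feats.mean_vedba.iloc[5:].mean()
            assert flap > glide

    def test_wet_behaviours_cool_the_temperature_channel(self):
        stream = simulate.simulate_accel(["glide"] * 10 + ["sit"] * 10, seed=3)
        dry = stream.temp.iloc[: 10 * 25].mean()
        wet = stream.temp.iloc[-5 * 25 :].mean()
        assert wet < dry - 2.0

    def test_unknown_label_and_empty_schedule_raise(self):
        with pytest.raises(ValueError, match="unknown"):
            simulate.simulate_accel(["swim"])
        with pytest.raises(ValueError, match="non-empty"):
            simulate.simulate_accel([])

    def test_stream_seed_determinism(self):
        a = simulate.simulate_accel(["flap", "sit"] * 5, seed=9)
        b = simulate.simulate_accel(["flap", "sit"] * 5, seed=9)
        pd.testing.assert_frame_equal(a, b)


def test_track_csv_roundtrip(tmp_path, reference_params):
    track, _ = simulate.simulate_trip(COLONY, reference_params, n_steps=30, seed=11)
    path = tmp_path / "t.csv"
    simulate.write_tracks_csv(track, path)
    back = simulate.read_tracks_csv(path)
    assert np.allclose(back.lat, track.lat)
    assert (pd.to_datetime(back.timestamp).astype("int64") == pd.to_datetime(track.timestamp).astype("int64")).all()


def test_field_netcdf_roundtrip(tmp_path):
    f = simulate.simulate_wind_field(BBOX, SPAN, seed=5)
    path = tmp_path / "w.nc"
    simulate.write_field_netcdf(f, path)
    back = simulate.read_field_netcdf(path)
    assert np.allclose(back.u10.values, f.u10.values)
    assert list(back.dims) == ["latitude", "longitude", "time"]
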