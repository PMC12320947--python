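import numpy as np
import pandas as pd
import pytest

from windforage import hmm, simulate, tracks

COLONY = (-7.23, 72.42)
BBOX = (-10.0, -4.0, 69.0, 76.0)
SPAN = ("2022-02-01", "2022-02-11")


@pytest.fixture(scope="session")
def colony():
    return COLONY


@pytest.fixture(scope="session")
def reference_params():
    return hmm.reference_params()


@pytest.fixture(scope="session")
def wind_field():
    return simulate.simulate_wind_field(BBOX, SPAN, 315.0, (0.5, 11.8), seed=2)


@pytest.fixture(scope="session")
def wave_field():
    return simulate.simulate_wave_field(BBOX, SPAN, 315.0, seed=3)


@pytest.fixture(scope="session")
def sim_track(reference_params):
    track, truth = simulate.simulate_trip(
        COLONY, reference_params, n_steps=120, seed=5, individual_id="bird00"
    )
    return track, truth


@pytest.fixture(scope="session")
def staged_trip(sim_track):
    track, _ = sim_track
    trips = tracks.process_track(track, COLONY)
    assert len(trips) == 1
    return trips[0]


def make_staged_trips(wind_field, params, n_trips, strength=0.0, seed0=1000, n_steps=80):
    """Simulate, split and stage a batch of trips (helper shared by tests)."""
    staged = []
    for k in range(n_trips):
        tr, _ = simulate.simulate_trip(
            COLONY,
            params,
            wind_field=wind_field if strength > 0 else None,
            selectivity_strength=strength,
            n_steps=n_steps,
            individual_id=f"bird{k % 20:02d}",
            start_time=pd.Timestamp("2022-02-01T06:00Z") + pd.Timedelta(hours=(k % 10) * 12),
            seed=seed0 + k,
        )
        for j, t in enumerate(tracks.process_track(tr, COLONY)):
            t["trip_id"] = f"t{k}_{j}"
            staged.append(t)
    return staged


@pytest.fixture(scope="session")
def labelled_segments():
    """Balanced labelled accelerometer segments at default separability."""
    from windforage import accel

    rng = np.random.default_rng(42)
    per_class = 120
    labels = []
    for b in simulate.BEHAVIOURS:
        labels.extend([b] * per_class)
    labels = list(rng.permutation(labels))
    stream = simulate.simulate_accel(labels, seed=7)
    feats = accel.segment_features(stream)
    feats["label"] = labels[: len(feats)]
    return feats
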