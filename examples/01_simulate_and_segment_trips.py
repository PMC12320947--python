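"""Simulate foraging trips from a colony and segment them into staged trips.

Generates three out-and-back trips driven by the 3-state movement model,
splits them from the deployment track with the 1 km / 30 min rule,
regularizes to 5-min fixes and labels outbound/middle/inbound stages with
the 75%-of-maximum-distance rule.
"""

import pandas as pd

from windforage import hmm, simulate, tracks

COLONY = (-7.23, 72.42)

params = hmm.reference_params()
frames = []
for k in range(3):
    track, truth = simulate.simulate_trip(
        COLONY, params, n_steps=80, seed=10 + k,
        start_time=pd.Timestamp("2022-02-01T06:00Z") + pd.Timedelta(hours=12 * k),
        individual_id="bird00",
    )
    frames.append(track)
deployment = pd.concat(frames, ignore_index=True)

trips = tracks.process_track(deployment, COLONY)
print(f"deployment of {len(deployment)} fixes -> {len(trips)} trips")
for trip in trips:
    counts = trip.stage.value_counts().to_dict()
    print(
        f"  {trip.trip_id.iloc[0]}: {len(trip)} regularized fixes, "
        f"max distance {trip.colony_dist_km.max():.1f} km, stages {counts}"
    )
    print(
        f"    mean step {trip.step_km.mean():.2f} km, "
        f"mean ground speed {trip.speed_ms.mean():.1f} m/s"
    )
# Each trip leaves and returns to the colony; the 'middle' block is the
# distal foraging span, the stages around it are the commute legs analysed
# for wind selectivity.
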