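"""Track a particle that disappears for five frames.

A spot blinks out (leaves the focal plane) for frames 20-24. Under the
automatic policy the tracker records those frames as gaps (NaN positions)
and re-acquires the particle when it returns, because the scan region stays
parked at the last known position.
"""

import math

import dimtrack as dt

sigma = dt.calibrate_noise_for_snr(100.0, 1.5, 1.5, 5, target_snr=5.0)
spec = dt.SyntheticMovieSpec(
    n_frames=40, height=64, width=64,
    particles=(dt.ParticleSpec(start=(30.0, 25.0), blink_frames=frozenset(range(20, 25))),),
    noise_sigma=sigma, seed=7,
)
stack, truth = dt.simulate_movie(spec)

result = dt.track_movie(stack, [(30.0, 25.0)], dt.TrackingConfig(), dt.AutomaticPolicy())
track = result.tracks[0]

gaps = [p.frame for p in track.points if p.status == "gap"]
print(f"gap frames: {gaps}")
print(f"interventions issued: {len(result.interventions)} "
      "(one no-maximum request per blinked frame)")
after = track.points[25]
err = math.hypot(after.x - truth.positions[0, 25, 0], after.y - truth.positions[0, 25, 1])
print(f"frame 25 re-acquisition error: {err:.3f} px (status {after.status})")
print("Exactly the five blinked frames are gaps; re-acquisition lands back on")
print("the true position to well under a pixel.")
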