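"""Resolve a two-particle crossing with the linear-motion option.

A particle transported at 1.3 um/s passes through the scan region of a
stationary one. Every contested frame raises a two-particle-overlap
intervention, which the automatic policy answers with linear motion:
extrapolate the previous velocity and localize around the prediction. Both
identities survive the pass.
"""

import math

import dimtrack as dt

cfg = dt.TrackingConfig(scan_rows=21, scan_cols=21, window_size=5)
sigma = dt.calibrate_noise_for_snr(100.0, 1.5, 1.5, 5, target_snr=5.0)
spec = dt.SyntheticMovieSpec(
    n_frames=40, height=48, width=72,
    particles=(
        dt.ParticleSpec(start=(10.0, 20.0),
                        motion=dt.MotionModel(kind="directed", velocity=(1.3, 0.0))),
        dt.ParticleSpec(start=(32.0, 26.0)),  # stationary, 6 px off the mover's path
    ),
    noise_sigma=sigma, seed=3,
)
stack, truth = dt.simulate_movie(spec)

result = dt.track_movie(stack, [(10, 20), (32, 26)], cfg, dt.AutomaticPolicy())
overlaps = [r for r in result.interventions if r.request.kind == "overlap"]
print(f"overlap interventions during the pass: {len(overlaps)}")

for tid, name in [(0, "mover"), (1, "stationary")]:
    last = result.tracks[tid].points[-1]
    err = math.hypot(last.x - truth.positions[tid, last.frame, 0],
                     last.y - truth.positions[tid, last.frame, 1])
    n_pred = sum(p.status == "predicted" for p in result.tracks[tid].points)
    print(f"{name}: final error {err:.2f} px, {n_pred} linear-motion frames")
print("Final errors well under a pixel on both tracks mean no identity swap:")
print("each track ends on its own particle after the crossing.")
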