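"""TA-MSD analysis: diffusion coefficient and anomalous exponent.

Simulates a Brownian trajectory (D = 0.1 um^2/s) and a directed one
(1.0 um/s), computes the time-averaged MSD with closed-form relative-error
bars, and fits D (slope/4 over lags 1-4) and the anomalous exponent alpha
(log-log slope): alpha ~ 1 for diffusion, ~ 2 for transport.
"""

import dimtrack as dt

dt_s, px = 0.1, 0.1  # 10 frames/s, 0.1 um pixels

brown = dt.simulate_trajectory(dt.MotionModel(kind="brownian", D=0.1), 1000, dt_s, px, (0, 0), 1)
direct = dt.simulate_trajectory(
    dt.MotionModel(kind="directed", velocity=(1.0, 0.0)), 1000, dt_s, px, (0, 0), 1
)

for name, xy in [("brownian", brown), ("directed", direct)]:
    curve = dt.ta_msd_from_xy(xy[:, 0], xy[:, 1], dt=dt_s, pixel_size=px)
    est = dt.fit_diffusion_coefficient(curve, range(1, 5))
    print(f"{name}: first lags rho = "
          + ", ".join(f"{r:.4f}" for r in curve.rho[:4]) + " um^2")
    print(f"  relative error bars (lags 1-4): "
          + ", ".join(f"{e:.3f}" for e in curve.rel_error[:4]))
    print(f"  D = {est.D:.4f} um^2/s, alpha = {est.alpha:.3f}")

print("The Brownian track recovers D near 0.1 um^2/s with alpha near 1; the")
print("directed track shows alpha = 2 (its 'D' is not a diffusion constant).")
print("Error bars depend only on lag and track length, growing toward 1 at")
print("the longest lag where a single displacement pair remains.")
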