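# Methods

This note documents the models, numerical choices, and limitations of
`dimtrack`: a frame-by-frame hybrid tracker for dim fluorescent spots with
an intervention-policy layer, sub-pixel localization, TA-MSD analysis, and
a ground-truth simulator.

## Coordinate and region conventions

Images are indexed `[row, col]`; a particle position is `(x, y)` with `x`
the column and `y` the row coordinate; pixel centers sit at integer
coordinates; everything is 0-based; rectangular regions include both
bounds. Sub-pixel → pixel conversion rounds halves up (`floor(v + 0.5)`)
so the chosen pixel never depends on banker's-rounding parity. These
conventions are stated once here and relied on everywhere; most historical
tracking bugs are half-pixel convention drift.

## The tracking engine

Each annotated particle advances independently, one frame at a time. The
scan region is `scan_rows × scan_cols` (odd, so it has a center pixel),
centered on the particle's last non-gap position and clipped to the image;
clipping shrinks the region without shifting the opposite edge. After a
gap the region stays parked at the last fix — no region growth — which is
the simplest rule consistent with per-frame region updates; a particle
that drifts away during a long blink must be recovered manually.

**Detection.** The window-mean map assigns to every interior placement of
a `window_size × window_size` square its mean intensity (computed with a
uniform filter and cropped to valid placements). Candidates are local
maxima of this map (plateau-tolerant 3×3 comparison) that pass a
brightness test, ordered brightest-first, with non-maximum suppression at
`min_separation` (default: `window_size`). Ties are broken by distance to
the previous position, then row-major order, for determinism.

Two detection details matter in the dim regime:

- *Border maxima are excluded.* A maximum on the border of the valid map
  has an incomplete neighborhood and is usually the shoulder of a particle
  just outside the region (the same reason `skimage`'s peak finder
  excludes borders by default). Keeping them lets a border artifact
  suppress the true peak during NMS and capture the track onto a
  neighboring particle. Maps narrower than 3 px keep their border so
  `window_size == scan` still detects.
- *Brightness test.* A candidate's window mean must exceed the background
  level by `brightness_k` (default 2) background standard deviations,
  with background level = median and spread = SD of the scan-region
  pixels outside the brightest window. The threshold rule is this
  package's own operationalization of "bright enough"; it is exposed in
  the configuration precisely because it is a modeling choice. A flat
  region yields no candidates (nothing exceeds its own median at k > 0).

**Ambiguity resolution.** Zero candidates raise a `no_maximum` request
(legal answers: stop / manual / gap); two or more raise an `overlap`
request (manual / pick_candidate / linear_motion). Linear motion
extrapolates the velocity between the last two non-gap points (bridging
gaps by dividing by the frame difference) and localizes around the
prediction. The policy layer generalizes an interactive pop-up into a
decision contract, so a session can be driven by a terminal prompt, a
scripted CSV, fixed automatic rules, or ground truth in tests; every
request/decision pair is logged. With fewer than two usable points the
linear-motion branch degrades to a zero-velocity (stay-put) prediction
rather than failing mid-movie.

Tracks are advanced independently and may localize the same spot during
close passes; this is logged as a warning, not prevented — inter-track
exclusion is a linking model this engine deliberately does not have.

**Statuses.** Each frame yields exactly one point with status `detected`,
`manual`, `predicted`, `gap`, or `stopped`. Gap points have NaN
coordinates and intensity. A `stopped` point is terminal and repeats the
last known coordinates with NaN intensity (an all-NaN terminal point would
be indistinguishable from a gap in the table).

## Localization

**Centroid.** Intensity-weighted mean position over the window after
background subtraction, with negative residuals clipped to zero (negative
mass drags the centroid out of the signal). Reported intensity is the raw
window sum minus `background × n_pixels`, i.e. the multiplier is the
window's pixel count — the only dimensionally consistent reading.

**2D Gaussian.** An axis-aligned elliptical Gaussian fit by
log-linearization: `ln I` is quadratic in x and y, solved by weighted
linear least squares with weights `I²` (error propagation of `ln`:
bright pixels carry the smallest log-noise). Pixels non-positive after
background subtraction are excluded (undefined log); at least 6 usable
pixels are required for the 5-parameter fit. The fit is declared
non-converged — falling back to the centroid — when either quadratic
coefficient is non-negative (no peak) or when the recovered center falls
outside the window (a noise-only window can produce an arbitrary
extrapolated center; the guard rejects it as a non-detection rather than
constraining the fit). The method is exact on noiseless data, which is
what the machine-precision recovery tests exploit. Integrated intensity
is the analytic `2πA·w_x·w_y`. No rotation term, no Poisson MLE, no PSF
calibration — out of scope.

**Background.** Median of the scan-region pixels outside the window
(median, not mean: robust to a neighboring particle in the surround);
the region median if the window covers everything.

**SNR.** `(μ_sig − μ_bg)/σ_bg` with, by default, signal = the
localization window and background = scan region minus window. The
region geometry is a package convention; published SNR values from other
tools may use different regions and are not directly comparable.

## TA-MSD and diffusion

For an N-frame track, `ρ_n` averages squared displacements over all pairs
`(i, i+n)` where both endpoints are non-gap; the denominator is the count
of valid pairs (equal to `N − n` on gapless tracks). Coordinates are
scaled to µm before squaring. A terminal `stopped` marker is excluded (its
coordinates merely repeat the last fix and would inject a spurious zero
displacement). The per-lag relative error uses the closed form of Qian,
Sheetz & Elson (Biophys J 59:910, 1991), a function of `(n, N)` only, with
branches for `n ≤ N/2` and `n > N/2`; it equals exactly 1 at `n = N − 1`.
On gapped tracks the error formula still uses the full N — a documented
approximation, slightly optimistic about the effective pair count.

`D` comes from OLS of `ρ(τ) = 4Dτ + b` over lags 1–4 by default: short
lags limit the bias from correlated MSD errors, and the free intercept
absorbs static localization noise. A negative slope is reported and
flagged, not clamped. `α` is the log-log slope over the same lags and is
NaN when any fitted `ρ` is non-positive (a perfectly stationary track has
no log-log slope). Motion-state classification (diffusive vs stationary,
HMM/Bayesian segmentation) is intentionally left to the user.

## The simulator

The simulator emulates the data regime the tracker is built for: Gaussian
PSF spots (default amplitude 100 counts, width 1.5 px) on a constant
background (default 100 counts) with additive Gaussian noise, sampled at
10 frames/s with 0.1 µm pixels; motion models are stationary, Brownian
(per-axis step variance `2D·dt`), directed (defaults exercised at
1.3 µm/s, the transport-speed class of dendritic mRNA), and
schedule-switching; blinking removes the spot entirely for listed frames.
All randomness flows from a mandatory seed.

Choices and what they imply:

- *Additive Gaussian noise, not Poisson.* The pipeline's only noise
  statistic is the background SD entering the SNR, and Gaussian noise
  makes `calibrate_noise_for_snr` exact: σ = (expected window-mean spot
  excess)/SNR. Passing tests therefore demonstrate behavior at a given
  nominal SNR, not robustness to shot-noise statistics, EMCCD gain, or
  photobleaching decay.
- *PSF sampled at pixel centers, not integrated over pixels* — matching
  how the localization model evaluates the Gaussian, so render→fit round
  trips are exact. Real cameras integrate over pixels; at w ≈ 1.5 px the
  difference is small but nonzero.
- *Blinking is total disappearance*, emulating focal-plane exit; there is
  no partial defocus PSF.

Recovery tests on these movies show the algorithm is correct under its
own model assumptions; they do not certify performance on real data with
structured background, drift, or non-Gaussian noise.

## Problem sizes in tests and the acceptance script

Simulation-backed checks use 31–72 px frames, 40–50-frame movies, 100–500
trajectories of 100–200 frames, and 20 seeded crossing replicates — sizes
at which the measured quantities (RMSE, gap counts, swap counts, D/α
means, MSD error-bar consistency) are statistically stable while the whole
suite runs in seconds. The crossing scenario uses a 21×21 scan region,
5×5 window, and a 6 px perpendicular offset so both spots remain distinct
interior candidates throughout the pass: every contested frame is then a
genuine two-particle overlap resolved by linear motion. A head-on merge
collapses to a single candidate whose ownership is undecidable without a
human — that regime is covered by the oracle-policy assignment test, not
by the automatic policy.

## Known limitations

- No inter-track exclusion or global linking; simultaneous claims on one
  spot are only warned about.
- The brightness criterion is a k·σ rule by construction; data with
  structured (non-stationary) background will need per-dataset `brightness_k`.
- MSD error bars assume Brownian statistics; for directed or confined
  motion they are indicative only.
- The interactive policy is a terminal prompt; there is no GUI.
- 2D only; no drift correction; no proprietary microscope formats.
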