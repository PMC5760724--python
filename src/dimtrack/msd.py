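"""Time-averaged mean squared displacement (TA-MSD) and diffusion fitting.

For an N-frame trajectory r(i*dt) = [x_i, y_i], the TA-MSD at lag n is

    rho_n = sum_i [ (x_{i+n} - x_i)^2 + (y_{i+n} - y_i)^2 ] / (#valid pairs),

where a pair is valid when both endpoints are non-gap; on a gapless track
the denominator is N - n. Coordinates are converted to micrometers with the
pixel size, so rho is in um^2 and the fitted diffusion coefficient in um^2/s.

The statistical relative error of rho_n for a Brownian trajectory follows
the closed form of Qian, Sheetz & Elson (Biophys J, 1991), a function of the
lag n and the trajectory length N only:

    rel_err(n, N) = sqrt( (4 n^2 N - 5 n^3 + 2 N - n) / (6 n (N - n)^2) )
                                                         for n <= N/2,
    rel_err(n, N) = sqrt( 1 + (N^3 - 5 n^3 - 7 n N^2 + 11 n^2 N + 5 n - N)
                              / (6 n^2 (N - n)) )        for n >  N/2.

At the single-pair limit n = N - 1 both branches give exactly 1.

The diffusion coefficient is obtained by ordinary least squares of
rho(tau) = 4 D tau + b over short lags (default 1..4, free intercept: the
intercept absorbs static localization noise, and short lags limit the bias
from correlated MSD errors). The anomalous exponent alpha is the slope of
ln rho vs ln tau over the same lags: alpha = 1 for Brownian motion, 2 for
ballistic, < 1 for sub-diffusion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "MSDCurve",
    "DiffusionEstimate",
    "qian_relative_error",
    "compute_ta_msd",
    "ta_msd_from_xy",
    "fit_diffusion_coefficient",
]


@dataclass(frozen=True)
class MSDCurve:
    """Lag-indexed TA-MSD. ``rho`` is NaN where no valid pair exists."""

    lags: np.ndarray          # int, 1..N-1
    taus: np.ndarray          # seconds, n * dt
    rho: np.ndarray           # um^2
    n_valid_pairs: np.ndarray  # int
    rel_error: np.ndarray     # Qian relative error, uses total N
    N: int
    dt: float


@dataclass(frozen=True)
class DiffusionEstimate:
    D: float                  # um^2/s (slope/4; may be negative, see flag)
    intercept: float          # um^2
    fit_lags: tuple[int, ...]
    alpha: float              # log-log slope; NaN if rho <= 0 on the fit lags
    r_squared: float
    negative_slope: bool = False


def qian_relative_error(n: int, N: int) -> float:
    """Closed-form relative standard deviation of the TA-MSD at lag ``n``
    for an ``N``-frame Brownian trajectory."""
    if not (1 <= n <= N - 1):
        raise ValueError(f"lag n must satisfy 1 <= n <= N-1; got n={n}, N={N}")
    n = float(n)
    Nf = float(N)
    if n <= Nf / 2.0:
        val = (4 * n**2 * Nf - 5 * n**3 + 2 * Nf - n) / (6 * n * (Nf - n) ** 2)
    else:
        val = 1.0 + (Nf**3 - 5 * n**3 - 7 * n * Nf**2 + 11 * n**2 * Nf + 5 * n - Nf) / (
            6 * n**2 * (Nf - n)
        )
    return math.sqrt(val)


def _track_xy(track) -> tuple[np.ndarray, np.ndarray]:
    """Extract x/y arrays (NaN at gaps) from a Track, dropping a terminal
    stopped marker whose coordinates merely repeat the last fix."""
    pts = list(track.points)
    if pts and pts[-1].status == "stopped":
        pts = pts[:-1]
    x = np.array([p.x for p in pts], dtype=float)
    y = np.array([p.y for p in pts], dtype=float)
    return x, y


def compute_ta_msd(track, dt: float, pixel_size: float, max_lag: int | None = None) -> MSDCurve:
    """TA-MSD of a track; gap frames (NaN coordinates) are excluded pairwise."""
    x, y = _track_xy(track)
    return ta_msd_from_xy(x, y, dt=dt, pixel_size=pixel_size, max_lag=max_lag)


def ta_msd_from_xy(
    x: Sequence[float],
    y: Sequence[float],
    dt: float,
    pixel_size: float,
    max_lag: int | None = None,
) -> MSDCurve:
    x = np.asarray(x, dtype=float) * pixel_size
    y = np.asarray(y, dtype=float) * pixel_size
    N = x.size
    if np.isfinite(x).sum() < 2:
        raise ValueError("trajectory needs at least 2 non-gap points")
    n_max = N - 1 if max_lag is None else min(max_lag, N - 1)
    lags = np.arange(1, n_max + 1)
    rho = np.full(n_max, np.nan)
    n_valid = np.zeros(n_max, dtype=int)
    for k, n in enumerate(lags):
        dx = x[n:] - x[:-n]
        dy = y[n:] - y[:-n]
        sq = dx * dx + dy * dy
        valid = np.isfinite(sq)
        n_valid[k] = int(valid.sum())
        if n_valid[k] > 0:
            rho[k] = float(sq[valid].mean())
    rel = np.array([qian_relative_error(int(n), N) for n in lags])
    return MSDCurve(
        lags=lags,
        taus=lags * dt,
        rho=rho,
        n_valid_pairs=n_valid,
        rel_error=rel,
        N=N,
        dt=dt,
    )


def fit_diffusion_coefficient(
    curve: MSDCurve, fit_lags: Iterable[int] = range(1, 5)
) -> DiffusionEstimate:
    """Fit rho(tau) = 4 D tau + b over the requested lags by OLS.

    Lags without a defined MSD value are dropped; at least two must remain.
    ``alpha`` is fit on ln rho vs ln tau over the same lags and is NaN when
    any rho there is non-positive (e.g. a perfectly stationary track).
    """
    wanted = np.array(sorted(set(int(n) for n in fit_lags)))
    idx = np.isin(curve.lags, wanted) & np.isfinite(curve.rho)
    taus = curve.taus[idx]
    rho = curve.rho[idx]
    used = tuple(int(n) for n in curve.lags[idx])
    if taus.size < 2:
        raise ValueError(f"need >= 2 defined lags to fit; have {taus.size}")
    slope, intercept = np.polyfit(taus, rho, 1)
    pred = slope * taus + intercept
    ss_res = float(((rho - pred) ** 2).sum())
    ss_tot = float(((rho - rho.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    if np.all(rho > 0):
        alpha = float(np.polyfit(np.log(taus), np.log(rho), 1)[0])
    else:
        alpha = math.nan
    return DiffusionEstimate(
        D=float(slope) / 4.0,
        intercept=float(intercept),
        fit_lags=used,
        alpha=alpha,
        r_squared=r2,
        negative_slope=bool(slope < 0),
    )
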