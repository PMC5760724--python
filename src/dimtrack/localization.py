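"""Sub-pixel spot localization: centroid, 2D Gaussian fit, background and SNR.

The spot model is an elliptical 2D Gaussian without rotation,

    I(x, y) = A * exp(-(x - x_c)^2 / (2 w_x^2) - (y - y_c)^2 / (2 w_y^2)),

fit to background-subtracted intensities. The Gaussian fit is performed by
log-linearization: ln I is quadratic in x and y, so the five parameters are
recovered from a weighted linear least-squares fit of ln I against
[1, x, y, x^2, y^2] with weights equal to the squared background-subtracted
intensity (bright pixels, whose log-transformed noise is smallest, dominate).
This "weighted overdetermined regression" is exact for noiseless data and a
standard fast estimator for well-sampled spots.

The integrated spot intensity is the analytic Gaussian integral
2*pi*A*w_x*w_y. The centroid alternative uses the intensity-weighted mean
pixel position and reports intensity as the background-corrected window sum.

SNR follows the convention (mean signal - mean background) / std background.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import ScanRegion

__all__ = [
    "GaussianFit",
    "CentroidResult",
    "SnrMeasurement",
    "NoSignalError",
    "GaussianFitError",
    "estimate_background",
    "localize_centroid",
    "fit_gaussian_2d",
    "compute_snr",
    "measure_snr",
    "window_bounds",
]


class NoSignalError(ValueError):
    """No positive intensity left in the window after background subtraction."""


class GaussianFitError(ValueError):
    """The Gaussian fit cannot be attempted (too few usable pixels)."""


@dataclass(frozen=True)
class GaussianFit:
    A: float
    x_c: float
    y_c: float
    w_x: float
    w_y: float
    integrated_intensity: float
    converged: bool


@dataclass(frozen=True)
class CentroidResult:
    x_c: float
    y_c: float
    intensity: float


@dataclass(frozen=True)
class SnrMeasurement:
    mu_sig: float
    mu_background: float
    sigma_background: float
    snr: float


def window_bounds(window_center: tuple[int, int], window_size: int) -> tuple[int, int, int, int]:
    """Inclusive (row_min, row_max, col_min, col_max) of a square window."""
    half = window_size // 2
    r, c = window_center
    return (r - half, r + half, c - half, c + half)


def _window_view(frame_image: np.ndarray, window_center: tuple[int, int], window_size: int):
    r0, r1, c0, c1 = window_bounds(window_center, window_size)
    if r0 < 0 or c0 < 0 or r1 >= frame_image.shape[0] or c1 >= frame_image.shape[1]:
        raise ValueError(
            f"window {window_size}x{window_size} at center {window_center} "
            f"does not fit inside image of shape {frame_image.shape}"
        )
    # slice before converting: callers may pass lazy/recording image proxies
    win = np.asarray(frame_image[r0 : r1 + 1, c0 : c1 + 1], dtype=float)
    return win, (r0, c0)


def estimate_background(
    frame_image: np.ndarray,
    region: ScanRegion,
    window_center: tuple[int, int],
    window_size: int,
) -> float:
    """Median intensity of the scan-region pixels outside the window.

    The median is robust to a second particle in the surround; if the window
    covers the whole region the median of the region itself is returned.
    """
    sub = np.asarray(frame_image[region.slices], dtype=float)
    if sub.size == 0:
        raise ValueError("empty scan region")
    r0, r1, c0, c1 = window_bounds(window_center, window_size)
    inside = np.zeros(sub.shape, dtype=bool)
    rr0 = max(r0 - region.row_min, 0)
    cc0 = max(c0 - region.col_min, 0)
    rr1 = min(r1 - region.row_min, sub.shape[0] - 1)
    cc1 = min(c1 - region.col_min, sub.shape[1] - 1)
    if rr0 <= rr1 and cc0 <= cc1:
        inside[rr0 : rr1 + 1, cc0 : cc1 + 1] = True
    surround = sub[~inside]
    if surround.size == 0:
        return float(np.median(sub))
    return float(np.median(surround))


def localize_centroid(
    frame_image: np.ndarray,
    window_center: tuple[int, int],
    window_size: int,
    background: float,
) -> CentroidResult:
    """Intensity-weighted centroid of the background-subtracted window.

    Negative background-subtracted pixels are clipped to zero (negative mass
    would pull the centroid outside the signal). The reported intensity is
    the raw window sum minus ``background`` times the window pixel count.
    """
    win, (r0, c0) = _window_view(frame_image, window_center, window_size)
    signal = np.clip(win - background, 0.0, None)
    total = signal.sum()
    if total <= 0:
        raise NoSignalError(
            f"no positive signal in window at {window_center} after background subtraction"
        )
    rows, cols = np.mgrid[r0 : r0 + win.shape[0], c0 : c0 + win.shape[1]]
    x_c = float((signal * cols).sum() / total)
    y_c = float((signal * rows).sum() / total)
    intensity = float(win.sum() - background * win.size)
    return CentroidResult(x_c=x_c, y_c=y_c, intensity=intensity)


def fit_gaussian_2d(
    frame_image: np.ndarray,
    window_center: tuple[int, int],
    window_size: int,
    background: float,
) -> GaussianFit:
    """Log-linearized weighted least-squares fit of an axis-aligned 2D Gaussian.

    Pixels that are non-positive after background subtraction are excluded
    (their logarithm is undefined); at least 6 usable pixels are required for
    the 5-parameter fit. If either recovered quadratic coefficient is
    non-negative the window has no peak along that axis: the result is
    flagged ``converged=False`` with the center taken from the centroid and
    amplitude/widths left as NaN.
    """
    win, (r0, c0) = _window_view(frame_image, window_center, window_size)
    signal = win - background
    mask = signal > 0
    if mask.sum() < 6:
        raise GaussianFitError(
            f"only {int(mask.sum())} positive pixels in window at {window_center}; need >= 6"
        )
    rows, cols = np.mgrid[r0 : r0 + win.shape[0], c0 : c0 + win.shape[1]]
    x = cols[mask].astype(float)
    y = rows[mask].astype(float)
    I = signal[mask]
    # weights = I^2  ->  scale each linear equation by I
    design = np.column_stack([np.ones_like(x), x, y, x * x, y * y]) * I[:, None]
    target = np.log(I) * I
    coef, *_ = np.linalg.lstsq(design, target, rcond=None)
    c0_, c1, c2, c3, c4 = coef
    bad = c3 >= 0 or c4 >= 0
    if not bad:
        # a fit centered outside the window is a noise artifact, not a peak
        x_c = -c1 / (2.0 * c3)
        y_c = -c2 / (2.0 * c4)
        r0_, r1_, c0b, c1b = window_bounds(window_center, window_size)
        bad = not (c0b - 0.5 <= x_c <= c1b + 0.5 and r0_ - 0.5 <= y_c <= r1_ + 0.5)
    if bad:
        fallback = localize_centroid(frame_image, window_center, window_size, background)
        return GaussianFit(
            A=math.nan,
            x_c=fallback.x_c,
            y_c=fallback.y_c,
            w_x=math.nan,
            w_y=math.nan,
            integrated_intensity=math.nan,
            converged=False,
        )
    w_x = math.sqrt(-1.0 / (2.0 * c3))
    w_y = math.sqrt(-1.0 / (2.0 * c4))
    A = math.exp(c0_ - c3 * x_c * x_c - c4 * y_c * y_c)
    return GaussianFit(
        A=float(A),
        x_c=float(x_c),
        y_c=float(y_c),
        w_x=float(w_x),
        w_y=float(w_y),
        integrated_intensity=float(2.0 * math.pi * A * w_x * w_y),
        converged=True,
    )


def compute_snr(
    frame_image: np.ndarray,
    signal_region: np.ndarray,
    background_region: np.ndarray,
) -> SnrMeasurement:
    """SNR = (mu_sig - mu_background) / sigma_background over two pixel sets.

    ``signal_region`` and ``background_region`` are boolean masks over the
    image; they must be non-empty and disjoint, and the background must have
    at least 2 pixels and non-zero spread.
    """
    img = np.asarray(frame_image, dtype=float)
    sig_mask = np.asarray(signal_region, dtype=bool)
    bg_mask = np.asarray(background_region, dtype=bool)
    if not sig_mask.any() or not bg_mask.any():
        raise ValueError("signal and background regions must be non-empty")
    if (sig_mask & bg_mask).any():
        raise ValueError("signal and background regions must be disjoint")
    bg = img[bg_mask]
    if bg.size < 2:
        raise ValueError("background region needs >= 2 pixels")
    mu_sig = float(img[sig_mask].mean())
    mu_bg = float(bg.mean())
    sigma_bg = float(bg.std(ddof=0))
    if sigma_bg == 0:
        raise ValueError("background standard deviation is zero; SNR undefined")
    return SnrMeasurement(
        mu_sig=mu_sig,
        mu_background=mu_bg,
        sigma_background=sigma_bg,
        snr=(mu_sig - mu_bg) / sigma_bg,
    )


def measure_snr(
    frame_image: np.ndarray,
    region: ScanRegion,
    window_center: tuple[int, int],
    window_size: int,
) -> SnrMeasurement:
    """SNR with the default geometry: signal = localization window,
    background = scan region minus window."""
    img = np.asarray(frame_image, dtype=float)
    r0, r1, c0, c1 = window_bounds(window_center, window_size)
    sig = np.zeros(img.shape, dtype=bool)
    sig[max(r0, 0) : r1 + 1, max(c0, 0) : c1 + 1] = True
    bg = region.mask(img.shape) & ~sig
    sig &= region.mask(img.shape)
    return compute_snr(img, sig, bg)
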