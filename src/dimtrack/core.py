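"""Core parameter and geometry types shared across the tracking pipeline.

Coordinate convention (used everywhere in this package): images are indexed
``[row, col]``; a particle position is ``(x, y)`` with ``x`` the sub-pixel
column coordinate and ``y`` the sub-pixel row coordinate; pixel centers sit
at integer coordinates; all indices are 0-based; rectangular regions include
both bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np

__all__ = [
    "TrackingConfig",
    "ScanRegion",
    "round_half_up",
    "LostParticleError",
]


class LostParticleError(ValueError):
    """The previous particle position lies entirely outside the image."""


def round_half_up(v: float) -> int:
    """Round to nearest integer, halves away from zero-independent (x.5 -> x+1).

    Used for every sub-pixel -> pixel conversion so the pixel chosen for a
    given coordinate never depends on banker's-rounding parity.
    """
    return int(np.floor(v + 0.5))


def _require_positive_odd(name: str, value: int) -> None:
    if not (isinstance(value, (int, np.integer)) and value > 0 and value % 2 == 1):
        raise ValueError(f"{name} must be a positive odd integer, got {value!r}")


@dataclass(frozen=True)
class TrackingConfig:
    """User-facing tracking parameters.

    Parameters
    ----------
    scan_rows, scan_cols:
        Height and width in pixels of the scan region centered on a
        particle's last position (typically 5-50 px). Must be odd so the
        region has an unambiguous center pixel.
    window_size:
        Side length in pixels of the square window whose mean intensity
        defines the local-maxima map and the localization footprint. Must be
        odd and no larger than either scan dimension.
    localization_method:
        ``"centroid"`` or ``"gaussian"`` sub-pixel localization.
    brightness_k:
        Detection threshold multiplier: a candidate window mean must exceed
        the local background level by ``brightness_k`` background standard
        deviations to count as a particle.
    min_separation:
        Minimum pixel distance between surviving candidates; two or more
        surviving candidates trigger the two-particle-overlap branch.
        Defaults to ``window_size``.
    frame_interval:
        Seconds between frames (default 0.1 s, i.e. 10
        frames per second).
    pixel_size:
        Micrometers per pixel.
    """

    scan_rows: int = 15
    scan_cols: int = 15
    window_size: int = 5
    localization_method: str = "gaussian"
    brightness_k: float = 2.0
    min_separation: int | None = None
    frame_interval: float = 0.1
    pixel_size: float = 0.1

    def __post_init__(self) -> None:
        _require_positive_odd("scan_rows", self.scan_rows)
        _require_positive_odd("scan_cols", self.scan_cols)
        _require_positive_odd("window_size", self.window_size)
        if self.window_size > min(self.scan_rows, self.scan_cols):
            raise ValueError(
                f"window_size ({self.window_size}) must not exceed "
                f"min(scan_rows, scan_cols) = {min(self.scan_rows, self.scan_cols)}"
            )
        if self.localization_method not in ("centroid", "gaussian"):
            raise ValueError(
                f"localization_method must be 'centroid' or 'gaussian', "
                f"got {self.localization_method!r}"
            )
        if self.brightness_k < 0:
            raise ValueError("brightness_k must be non-negative")
        if self.min_separation is None:
            object.__setattr__(self, "min_separation", self.window_size)
        if self.min_separation <= 0:
            raise ValueError("min_separation must be positive")
        if self.frame_interval <= 0 or self.pixel_size <= 0:
            raise ValueError("frame_interval and pixel_size must be positive")


@dataclass(frozen=True)
class ScanRegion:
    """Axis-aligned pixel rectangle, inclusive of both bounds."""

    row_min: int
    row_max: int
    col_min: int
    col_max: int
    center: Tuple[int, int] = field(default=None)  # (row, col)

    def __post_init__(self) -> None:
        if self.row_min > self.row_max or self.col_min > self.col_max:
            raise ValueError(f"degenerate region {self}")
        if self.center is None:
            object.__setattr__(
                self,
                "center",
                ((self.row_min + self.row_max) // 2, (self.col_min + self.col_max) // 2),
            )

    @property
    def shape(self) -> Tuple[int, int]:
        return (self.row_max - self.row_min + 1, self.col_max - self.col_min + 1)

    @property
    def slices(self) -> Tuple[slice, slice]:
        return (slice(self.row_min, self.row_max + 1), slice(self.col_min, self.col_max + 1))

    def contains(self, row: int, col: int) -> bool:
        return self.row_min <= row <= self.row_max and self.col_min <= col <= self.col_max

    def mask(self, image_shape: Tuple[int, int]) -> np.ndarray:
        m = np.zeros(image_shape, dtype=bool)
        m[self.slices] = True
        return m
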