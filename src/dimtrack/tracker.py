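"""Frame-by-frame hybrid tracking engine.

Unlike detect-then-link trackers, this engine advances each annotated
particle one frame at a time inside a small scan region centered on its last
known position. Each frame is resolved by one of three routes:

* exactly one local maximum in the scan region -> automatic sub-pixel
  localization (status ``detected``);
* no maximum bright enough -> an intervention request of kind
  ``no_maximum``; the policy answers ``stop``, ``manual`` or ``gap``;
* two or more maxima (particle overlap) -> an intervention request of kind
  ``overlap``; the policy answers ``manual``, ``pick_candidate`` or
  ``linear_motion`` (extrapolate the previous velocity and localize around
  the predicted position, status ``predicted``).

The policy object generalizes the interactive pop-up of a GUI tracker: it
may be a human at a prompt, a scripted decision table, a fixed automatic
rule, or the simulator's ground truth in tests. Every request/decision pair
is recorded so a run is fully auditable.

Local maxima are found on the window-mean map: the mean intensity of every
window_size x window_size square whose footprint lies inside the scan
region. A candidate must exceed the local background (median of the region
outside the brightest window) by ``brightness_k`` background standard
deviations, and candidates closer than ``min_separation`` pixels to a
brighter one are suppressed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import maximum_filter, uniform_filter

from .core import LostParticleError, ScanRegion, TrackingConfig, round_half_up
from .localization import (
    GaussianFitError,
    NoSignalError,
    estimate_background,
    fit_gaussian_2d,
    localize_centroid,
)

__all__ = [
    "TrackPoint",
    "Track",
    "Candidate",
    "InterventionRequest",
    "InterventionDecision",
    "InterventionRecord",
    "TrackingResult",
    "IllegalDecisionError",
    "define_scan_region",
    "detect_local_maxima",
    "predict_linear_motion",
    "step_frame",
    "track_movie",
    "STATUSES",
]

logger = logging.getLogger(__name__)

STATUSES = ("detected", "manual", "predicted", "gap", "stopped")

_LEGAL_ACTIONS = {
    "no_maximum": ("stop", "manual", "gap"),
    "overlap": ("manual", "linear_motion", "pick_candidate"),
}


class IllegalDecisionError(ValueError):
    """Policy returned an action not legal for the request kind."""


@dataclass(frozen=True)
class TrackPoint:
    frame: int
    x: float
    y: float
    intensity: float
    status: str

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")
        missing = [math.isnan(v) for v in (self.x, self.y, self.intensity)]
        if self.status == "gap" and not all(missing):
            raise ValueError("gap points must have NaN x, y and intensity")
        if self.status != "gap" and (missing[0] or missing[1]):
            raise ValueError(f"{self.status} points must have finite coordinates")

    @property
    def is_gap(self) -> bool:
        return self.status == "gap"


def gap_point(frame: int) -> TrackPoint:
    return TrackPoint(frame=frame, x=math.nan, y=math.nan, intensity=math.nan, status="gap")


@dataclass
class Track:
    track_id: int
    points: List[TrackPoint] = field(default_factory=list)

    @property
    def stopped(self) -> bool:
        return bool(self.points) and self.points[-1].status == "stopped"

    @property
    def last_frame(self) -> int:
        return self.points[-1].frame

    def last_position(self) -> Tuple[float, float]:
        """Most recent non-gap (x, y)."""
        for p in reversed(self.points):
            if not p.is_gap:
                return (p.x, p.y)
        raise ValueError(f"track {self.track_id} has no non-gap points")

    def nongap_points(self) -> List[TrackPoint]:
        return [p for p in self.points if not p.is_gap]

    def append(self, point: TrackPoint) -> None:
        if self.stopped:
            raise ValueError(f"track {self.track_id} is stopped")
        expected = self.points[-1].frame + 1 if self.points else 0
        if point.frame != expected:
            raise ValueError(
                f"track {self.track_id}: expected frame {expected}, got {point.frame}"
            )
        self.points.append(point)


@dataclass(frozen=True)
class Candidate:
    row: int
    col: int
    window_mean: float

    @property
    def xy(self) -> Tuple[float, float]:
        return (float(self.col), float(self.row))


@dataclass(frozen=True)
class InterventionRequest:
    kind: str  # "no_maximum" | "overlap"
    track_id: int
    frame: int
    scan_region: ScanRegion
    candidates: Tuple[Candidate, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in _LEGAL_ACTIONS:
            raise ValueError(f"unknown request kind {self.kind!r}")
        if self.kind == "no_maximum" and self.candidates:
            raise ValueError("no_maximum requests carry no candidates")
        if self.kind == "overlap" and len(self.candidates) < 2:
            raise ValueError("overlap requests need >= 2 candidates")


@dataclass(frozen=True)
class InterventionDecision:
    action: str  # stop | manual | gap | linear_motion | pick_candidate
    manual_position: Optional[Tuple[float, float]] = None
    candidate_index: Optional[int] = None

    def __post_init__(self) -> None:
        if self.action == "manual" and self.manual_position is None:
            raise ValueError("manual decisions require manual_position")
        if self.action == "pick_candidate" and self.candidate_index is None:
            raise ValueError("pick_candidate decisions require candidate_index")


@dataclass(frozen=True)
class InterventionRecord:
    request: InterventionRequest
    decision: InterventionDecision


@dataclass
class TrackingResult:
    tracks: List[Track]
    interventions: List[InterventionRecord] = field(default_factory=list)

    def __iter__(self):
        return iter(self.tracks)


def define_scan_region(
    prev_position: Tuple[float, float],
    config: TrackingConfig,
    image_shape: Tuple[int, int],
) -> ScanRegion:
    """Scan region of scan_rows x scan_cols centered on the previous position
    rounded to the nearest pixel, clipped to the image (clipping shrinks the
    region; the opposite edge never shifts)."""
    x, y = prev_position
    if not (math.isfinite(x) and math.isfinite(y)):
        raise LostParticleError(f"previous position {prev_position} is not finite")
    rows, cols = image_shape
    rc, cc = round_half_up(y), round_half_up(x)
    if not (0 <= rc < rows and 0 <= cc < cols):
        raise LostParticleError(
            f"previous position {prev_position} lies outside the {rows}x{cols} image"
        )
    hr, hc = config.scan_rows // 2, config.scan_cols // 2
    return ScanRegion(
        row_min=max(0, rc - hr),
        row_max=min(rows - 1, rc + hr),
        col_min=max(0, cc - hc),
        col_max=min(cols - 1, cc + hc),
        center=(rc, cc),
    )


def detect_local_maxima(
    frame_image: np.ndarray,
    region: ScanRegion,
    config: TrackingConfig,
) -> List[Candidate]:
    """Candidate particle positions inside the scan region.

    Returns window centers that are local maxima of the window-mean map,
    pass the brightness test, and survive non-maximum suppression at
    ``min_separation`` — brightest first. An empty list means "nothing
    bright enough".
    """
    w = config.window_size
    sub = np.asarray(frame_image[region.slices], dtype=float)
    H, W = sub.shape
    if H < w or W < w:
        return []
    half = w // 2
    wmean = uniform_filter(sub, size=w, mode="constant")[half : H - half, half : W - half]
    # local maxima (plateau-tolerant) of the window-mean map; maxima on the
    # border of the valid map have incomplete neighborhoods and are excluded
    # (cf. exclude_border in peak finders) unless the map is too small to
    # have an interior
    peaks = wmean >= maximum_filter(wmean, size=3, mode="constant", cval=-np.inf)
    if peaks.shape[0] >= 3:
        peaks[0, :] = peaks[-1, :] = False
    if peaks.shape[1] >= 3:
        peaks[:, 0] = peaks[:, -1] = False
    pr, pc = np.nonzero(peaks)
    if pr.size == 0:
        return []
    vals = wmean[pr, pc]
    # absolute image coordinates of the window centers
    abs_r = pr + region.row_min + half
    abs_c = pc + region.col_min + half
    # brightness test: background = region pixels outside the *brightest* window
    best = int(np.argmax(vals))
    r0 = abs_r[best] - half - region.row_min
    c0 = abs_c[best] - half - region.col_min
    inside = np.zeros(sub.shape, dtype=bool)
    inside[r0 : r0 + w, c0 : c0 + w] = True
    surround = sub[~inside]
    if surround.size == 0:
        return []
    bg_level = float(np.median(surround))
    bg_std = float(surround.std(ddof=0))
    keep = vals > bg_level + config.brightness_k * bg_std
    if not keep.any():
        return []
    abs_r, abs_c, vals = abs_r[keep], abs_c[keep], vals[keep]
    # deterministic ordering: brightness desc, then nearest the previous
    # position, then row-major
    ctr_r, ctr_c = region.center
    d2 = (abs_r - ctr_r) ** 2 + (abs_c - ctr_c) ** 2
    order = np.lexsort((abs_c, abs_r, d2, -vals))
    selected: List[Candidate] = []
    for i in order:
        r, c, v = int(abs_r[i]), int(abs_c[i]), float(vals[i])
        if all(
            (r - s.row) ** 2 + (c - s.col) ** 2 >= config.min_separation**2 for s in selected
        ):
            selected.append(Candidate(row=r, col=c, window_mean=v))
    return selected


def predict_linear_motion(track: Track, current_frame: int) -> Tuple[float, float]:
    """Extrapolate the previous velocity: p_last + v * (frame - frame_last),
    with v the displacement between the last two non-gap points divided by
    their frame difference (gaps in between are bridged)."""
    pts = track.nongap_points()
    if len(pts) < 2:
        raise ValueError(
            f"track {track.track_id} has fewer than 2 non-gap points; "
            "linear motion prediction unavailable — fall back to manual or gap"
        )
    p1, p2 = pts[-2], pts[-1]
    df = p2.frame - p1.frame
    vx = (p2.x - p1.x) / df
    vy = (p2.y - p1.y) / df
    dt = current_frame - p2.frame
    return (p2.x + vx * dt, p2.y + vy * dt)


def _clamp_window_center(
    position: Tuple[float, float], window_size: int, image_shape: Tuple[int, int]
) -> Tuple[int, int]:
    half = window_size // 2
    rows, cols = image_shape
    r = min(max(round_half_up(position[1]), half), rows - 1 - half)
    c = min(max(round_half_up(position[0]), half), cols - 1 - half)
    return (r, c)


def _localize(
    frame_image: np.ndarray,
    region: ScanRegion,
    position: Tuple[float, float],
    config: TrackingConfig,
    frame: int,
    status: str,
) -> TrackPoint:
    """Sub-pixel localization around an approximate position.

    Falls back from the Gaussian fit to the centroid when the fit is
    unusable; if even the centroid finds no signal (manual/predicted seeds on
    empty pixels), the seed position itself is kept with NaN intensity.
    """
    center = _clamp_window_center(position, config.window_size, frame_image.shape)
    background = estimate_background(frame_image, region, center, config.window_size)
    try:
        if config.localization_method == "gaussian":
            try:
                fit = fit_gaussian_2d(frame_image, center, config.window_size, background)
            except GaussianFitError:
                fit = None
            if fit is not None and fit.converged:
                return TrackPoint(
                    frame=frame,
                    x=fit.x_c,
                    y=fit.y_c,
                    intensity=fit.integrated_intensity,
                    status=status,
                )
        res = localize_centroid(frame_image, center, config.window_size, background)
        return TrackPoint(frame=frame, x=res.x_c, y=res.y_c, intensity=res.intensity, status=status)
    except NoSignalError:
        if status in ("manual", "predicted"):
            return TrackPoint(
                frame=frame,
                x=float(position[0]),
                y=float(position[1]),
                intensity=math.nan,
                status=status,
            )
        raise


def _apply_decision(
    track: Track,
    frame_image: np.ndarray,
    request: InterventionRequest,
    decision: InterventionDecision,
    config: TrackingConfig,
) -> TrackPoint:
    if decision.action not in _LEGAL_ACTIONS[request.kind]:
        raise IllegalDecisionError(
            f"action {decision.action!r} is not a legal response to a "
            f"{request.kind!r} request (track {request.track_id}, frame {request.frame})"
        )
    frame = request.frame
    region = request.scan_region
    if decision.action == "stop":
        x, y = track.last_position()
        return TrackPoint(frame=frame, x=x, y=y, intensity=math.nan, status="stopped")
    if decision.action == "gap":
        return gap_point(frame)
    if decision.action == "manual":
        return _localize(frame_image, region, decision.manual_position, config, frame, "manual")
    if decision.action == "pick_candidate":
        idx = decision.candidate_index
        if not (0 <= idx < len(request.candidates)):
            raise IllegalDecisionError(
                f"candidate_index {idx} out of range for {len(request.candidates)} candidates"
            )
        return _localize(
            frame_image, region, request.candidates[idx].xy, config, frame, "detected"
        )
    # linear_motion
    try:
        predicted = predict_linear_motion(track, frame)
    except ValueError:
        # not enough history: stay where we are (zero-velocity prediction)
        predicted = track.last_position()
    return _localize(frame_image, region, predicted, config, frame, "predicted")


def step_frame(
    track: Track,
    frame_image: np.ndarray,
    config: TrackingConfig,
    policy,
    frame: Optional[int] = None,
    log: Optional[List[InterventionRecord]] = None,
) -> TrackPoint:
    """Advance one track by one frame; appends and returns the new point."""
    if track.stopped:
        raise ValueError(f"track {track.track_id} is stopped")
    if frame is None:
        frame = track.last_frame + 1
    region = define_scan_region(track.last_position(), config, frame_image.shape)
    candidates = detect_local_maxima(frame_image, region, config)
    if len(candidates) == 1:
        try:
            point = _localize(frame_image, region, candidates[0].xy, config, frame, "detected")
            track.append(point)
            return point
        except NoSignalError:
            candidates = []
    if len(candidates) == 0:
        request = InterventionRequest(
            kind="no_maximum", track_id=track.track_id, frame=frame, scan_region=region
        )
    else:
        request = InterventionRequest(
            kind="overlap",
            track_id=track.track_id,
            frame=frame,
            scan_region=region,
            candidates=tuple(candidates),
        )
    decision = policy.decide(request)
    point = _apply_decision(track, frame_image, request, decision, config)
    if log is not None:
        log.append(InterventionRecord(request=request, decision=decision))
    track.append(point)
    return point


def track_movie(
    stack: np.ndarray,
    initial_positions: Sequence[Tuple[float, float]],
    config: TrackingConfig,
    policy,
) -> TrackingResult:
    """Track every annotated particle through the whole stack.

    Each initial (x, y) position seeds one track; the frame-0 point is
    localized around the annotation (status ``manual``). Particles are then
    advanced frame by frame in annotation order; stopped tracks are skipped.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3 or stack.shape[0] < 1:
        raise ValueError(f"stack must be (frames, rows, cols); got shape {stack.shape}")
    if len(initial_positions) == 0:
        raise ValueError("at least one initial position is required")
    n_frames, rows, cols = stack.shape
    tracks: List[Track] = []
    log: List[InterventionRecord] = []
    for i, (x, y) in enumerate(initial_positions):
        if not (0 <= round_half_up(x) < cols and 0 <= round_half_up(y) < rows):
            raise ValueError(f"initial position {i} at ({x}, {y}) is outside frame 0")
        region = define_scan_region((x, y), config, (rows, cols))
        track = Track(track_id=i)
        track.append(_localize(stack[0], region, (x, y), config, 0, "manual"))
        tracks.append(track)
    for f in range(1, n_frames):
        for track in tracks:
            if track.stopped:
                continue
            step_frame(track, stack[f], config, policy, frame=f, log=log)
        _warn_coincident(tracks, f, config)
    return TrackingResult(tracks=tracks, interventions=log)


def _warn_coincident(tracks: Sequence[Track], frame: int, config: TrackingConfig) -> None:
    fixes = []
    for t in tracks:
        if t.points and t.points[-1].frame == frame and not t.points[-1].is_gap:
            p = t.points[-1]
            if p.status != "stopped":
                fixes.append((t.track_id, p.x, p.y))
    for a in range(len(fixes)):
        for b in range(a + 1, len(fixes)):
            _, xa, ya = fixes[a]
            _, xb, yb = fixes[b]
            if (xa - xb) ** 2 + (ya - yb) ** 2 < config.min_separation**2:
                logger.warning(
                    "tracks %d and %d localized within %g px of each other at frame %d",
                    fixes[a][0],
                    fixes[b][0],
                    config.min_separation,
                    frame,
                )
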