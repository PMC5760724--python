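"""Intervention policies: who answers when the tracker is unsure.

A policy is any object with ``decide(request) -> InterventionDecision``.
Bundled policies:

* :class:`AutomaticPolicy` — fixed rules, no human: by default ``gap`` when
  nothing is bright enough and ``linear_motion`` on particle overlap.
* :class:`ScriptedPolicy` — decisions read from a table keyed by
  (frame, track_id); replays a previous interactive session or encodes a
  prepared analysis plan. Fully deterministic.
* :class:`OraclePolicy` — answers from simulator ground truth; test-only.
* :class:`InteractivePolicy` — minimal terminal prompt standing in for a
  GUI pop-up.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .simulate import GroundTruth
from .tracker import InterventionDecision, InterventionRequest

__all__ = [
    "AutomaticPolicy",
    "ScriptedPolicy",
    "OraclePolicy",
    "InteractivePolicy",
    "read_decisions",
    "write_decisions",
]

DECISION_COLUMNS = ["frame", "track_id", "action", "x", "y", "candidate_index"]


@dataclass
class AutomaticPolicy:
    no_maximum_action: str = "gap"       # "gap" or "stop"
    overlap_action: str = "linear_motion"  # "linear_motion" or "pick_candidate"

    def decide(self, request: InterventionRequest) -> InterventionDecision:
        if request.kind == "no_maximum":
            return InterventionDecision(action=self.no_maximum_action)
        if self.overlap_action == "pick_candidate":
            return InterventionDecision(action="pick_candidate", candidate_index=0)
        return InterventionDecision(action="linear_motion")


class ScriptedPolicy:
    """Replays decisions from a (frame, track_id)-keyed table.

    ``fallback`` (another policy) handles requests the script does not
    cover; without one, an uncovered request is an error.
    """

    def __init__(
        self,
        decisions: Dict[Tuple[int, int], InterventionDecision],
        fallback=None,
    ) -> None:
        self.decisions = dict(decisions)
        self.fallback = fallback

    def decide(self, request: InterventionRequest) -> InterventionDecision:
        key = (request.frame, request.track_id)
        if key in self.decisions:
            return self.decisions[key]
        if self.fallback is not None:
            return self.fallback.decide(request)
        raise KeyError(
            f"no scripted decision for track {request.track_id} at frame "
            f"{request.frame} ({request.kind}) and no fallback policy"
        )


class OraclePolicy:
    """Answers every request from simulator ground truth (test-only).

    When the true particle is invisible (blinked) a ``no_maximum`` request
    is answered with ``gap``; otherwise the true position is supplied as a
    manual click. Track ids map to particle indices via ``track_to_particle``
    (identity by default).
    """

    def __init__(self, truth: GroundTruth, track_to_particle: Optional[Dict[int, int]] = None):
        self.truth = truth
        self.track_to_particle = track_to_particle or {}

    def decide(self, request: InterventionRequest) -> InterventionDecision:
        p = self.track_to_particle.get(request.track_id, request.track_id)
        if request.kind == "no_maximum":
            if not self.truth.visible[p, request.frame]:
                return InterventionDecision(action="gap")
            x, y = self.truth.positions[p, request.frame]
            return InterventionDecision(action="manual", manual_position=(float(x), float(y)))
        x, y = self.truth.positions[p, request.frame]
        return InterventionDecision(action="manual", manual_position=(float(x), float(y)))


class InteractivePolicy:
    """Terminal prompt replacing a GUI pop-up; reads from stdin."""

    def __init__(self, input_fn=input, echo=print):
        self.input_fn = input_fn
        self.echo = echo

    def decide(self, request: InterventionRequest) -> InterventionDecision:
        self.echo(
            f"[track {request.track_id}, frame {request.frame}] {request.kind}; "
            f"candidates: {[(c.col, c.row) for c in request.candidates]}"
        )
        if request.kind == "no_maximum":
            options = "stop/manual/gap"
        else:
            options = "manual/linear_motion/pick_candidate"
        action = self.input_fn(f"action ({options}): ").strip()
        if action == "manual":
            x = float(self.input_fn("x: "))
            y = float(self.input_fn("y: "))
            return InterventionDecision(action="manual", manual_position=(x, y))
        if action == "pick_candidate":
            idx = int(self.input_fn("candidate index: "))
            return InterventionDecision(action="pick_candidate", candidate_index=idx)
        return InterventionDecision(action=action)


def read_decisions(path) -> Dict[Tuple[int, int], InterventionDecision]:
    """Load a scripted-decision CSV (columns frame, track_id, action, x, y,
    candidate_index; x/y blank unless action=manual)."""
    df = pd.read_csv(path)
    missing = [c for c in ("frame", "track_id", "action") if c not in df.columns]
    if missing:
        raise ValueError(f"decision file {path} lacks columns {missing}")
    out: Dict[Tuple[int, int], InterventionDecision] = {}
    for row in df.itertuples(index=False):
        action = str(row.action)
        manual = None
        cand = None
        if action == "manual":
            manual = (float(row.x), float(row.y))
        if action == "pick_candidate":
            cand = int(row.candidate_index)
        out[(int(row.frame), int(row.track_id))] = InterventionDecision(
            action=action, manual_position=manual, candidate_index=cand
        )
    return out


def write_decisions(decisions: Dict[Tuple[int, int], InterventionDecision], path) -> None:
    rows = []
    for (frame, track_id), d in sorted(decisions.items()):
        x, y = (d.manual_position if d.manual_position is not None else (math.nan, math.nan))
        rows.append(
            {
                "frame": frame,
                "track_id": track_id,
                "action": d.action,
                "x": x,
                "y": y,
                "candidate_index": d.candidate_index if d.candidate_index is not None else np.nan,
            }
        )
    pd.DataFrame(rows, columns=DECISION_COLUMNS).to_csv(path, index=False)
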