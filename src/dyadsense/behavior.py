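"""Rule-based per-window behavior classification: Engaged / Struggling / Waiting.

The classifier mirrors the decision logic a behavioral analyst applies when
annotating dyadic task video, expressed over four window-level channels:

* speech present        -> Engaged (talking participants are interacting);
* else controller input -> judged by object movement relative to the target:
  toward -> Engaged, away -> Struggling, stationary -> Waiting;
* else (no input)       -> judged by gaze: present -> Waiting (attending but
  idle), absent -> Struggling (disengaged and unsupported).

The function is total and deterministic over the 2x2x3x2 input grid;
movement is meaningful only while the controller is active and is forced to
"none" otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .eventlog import Window

__all__ = [
    "BEHAVIOR_STATES",
    "ENGAGED",
    "STRUGGLING",
    "WAITING",
    "MOVEMENT_EPSILON",
    "BehaviorWindowInput",
    "BehaviorTimeline",
    "classify_window",
    "movement_from_delta",
    "build_timeline",
]

ENGAGED = "Engaged"
STRUGGLING = "Struggling"
WAITING = "Waiting"
BEHAVIOR_STATES = (ENGAGED, STRUGGLING, WAITING)

MOVEMENTS = ("toward", "away", "none")

#: Dead-band on per-window object-distance change, in scene units.
MOVEMENT_EPSILON = 0.05


@dataclass(frozen=True)
class BehaviorWindowInput:
    speech_present: bool
    controller_active: bool
    movement: str = "none"
    gaze_present: bool = False

    def __post_init__(self) -> None:
        if self.movement not in MOVEMENTS:
            raise ValueError(f"movement must be one of {MOVEMENTS}")
        if not self.controller_active and self.movement != "none":
            # movement is only meaningful under controller input
            object.__setattr__(self, "movement", "none")


def classify_window(inp: BehaviorWindowInput) -> str:
    """Assign one behavior state to a window; total over all inputs."""
    if inp.speech_present:
        return ENGAGED
    if inp.controller_active:
        if inp.movement == "away":
            return STRUGGLING
        if inp.movement == "toward":
            return ENGAGED
        return WAITING
    return WAITING if inp.gaze_present else STRUGGLING


def movement_from_delta(delta: float,
                        epsilon: float = MOVEMENT_EPSILON) -> str:
    """Sign of the object-distance change, with a +-epsilon dead-band."""
    if delta < -epsilon:
        return "toward"
    if delta > epsilon:
        return "away"
    return "none"


@dataclass
class BehaviorTimeline:
    """One state per window for one participant."""

    player: str
    tick: float
    states: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        bad = [s for s in self.states if s not in BEHAVIOR_STATES]
        if bad:
            raise ValueError(f"unknown behavior states {sorted(set(bad))}")

    def __len__(self) -> int:
        return len(self.states)

    def window_start(self, index: int) -> float:
        return index * self.tick


def build_timeline(windows: Sequence[Window], tick: float = 1.0,
                   movement_epsilon: float = MOVEMENT_EPSILON,
                   smooth: bool = False) -> BehaviorTimeline:
    """Classify each window of one player's discretized session.

    ``smooth`` applies an optional width-3 majority filter; it is off by
    default so that downstream feedback timing stays exact.
    """
    player = windows[0].player if windows else "P1"
    states = []
    for w in windows:
        inp = BehaviorWindowInput(
            speech_present=w.speech_present,
            controller_active=w.controller_active,
            movement=(movement_from_delta(w.distance_delta, movement_epsilon)
                      if w.controller_active else "none"),
            gaze_present=w.gaze_present)
        states.append(classify_window(inp))
    if smooth and len(states) >= 3:
        smoothed = list(states)
        for i in range(1, len(states) - 1):
            trio = states[i - 1:i + 2]
            for s in BEHAVIOR_STATES:
                if trio.count(s) >= 2:
                    smoothed[i] = s
                    break
        states = smoothed
    return BehaviorTimeline(player=player, tick=tick, states=states)
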