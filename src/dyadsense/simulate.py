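"""Synthetic dyad-session generator with scripted ground truth.

A :class:`Scenario` scripts each participant as a sequence of behavior
states with durations; the generator renders those scripts into raw
multimodal records in the session-log schema, inverting the behavior
classifier's decision logic:

* Engaged    -> controller activity with the object's distance-to-target
  decreasing, task-directed gaze, and utterances arriving as an exponential
  process (speech occupies a small fraction of the interaction, as in real
  task dialogue);
* Waiting    -> gaze present but no controller input (or, optionally,
  controller input with a stationary object — both waiting signatures);
* Struggling -> controller activity with the distance increasing (or,
  optionally, total signal absence).

Noise knobs: independent gaze-sample dropout (default 5%, typical tracker
loss), Gaussian jitter on the distance trajectory, and the utterance rate.
Status records are emitted at 2 Hz so every window observes the distance
trend; gaze at 60 Hz, the display rate.  Given a seed the output is
byte-identical across runs.

Ground truth carries the scripted per-window timelines and the feedback
landmarks (prompt/escalation times) obtained by running the feedback
machine on those scripted timelines, enabling end-to-end recovery tests
against the raw-signal pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .behavior import BEHAVIOR_STATES, ENGAGED, STRUGGLING, WAITING, BehaviorTimeline
from .eventlog import DEFAULT_ROI_MAP, PLAYERS, EventRecord, SessionLog
from .feedback import FeedbackTrace, run_fsm

__all__ = ["Scenario", "GroundTruth", "simulate_session", "preset_scenarios"]

Script = Sequence[tuple[str, float]]

_UTTERANCE_TEMPLATES = (
    "Try moving it more to the right",
    "Okay",
    "What do you see?",
    "Mine says to attach the small piece first",
    "I think this one goes on top",
    "Yeah",
    "Can you pass me the blue piece?",
    "Let me try",
    "Good job",
    "Thanks",
    "And then backward",
    "I'm not sure about this one",
)

TASK_ROI = "task_object"
SOCIAL_ROI = "video_window"
TIME_ROI = "timer_bar"


@dataclass(frozen=True)
class Scenario:
    """Scripted dyad session plus rendering and noise parameters."""

    name: str = "scenario"
    scripts: Mapping[str, Script] = field(
        default_factory=lambda: {p: ((ENGAGED, 60.0),) for p in PLAYERS})
    task_events: tuple[float, ...] = ()
    piece_shares: Mapping[str, tuple[float, ...]] = field(default_factory=dict)
    gaze_dropout: float = 0.05
    utterance_rate: float = 0.1        # utterances/s while Engaged
    distance_drift: float = 0.5        # scene units/s
    distance_jitter: float = 0.02      # SD of Gaussian jitter per sample
    gaze_hz: float = 60.0
    status_hz: float = 2.0
    waiting_mode: str = "gaze"         # "gaze" | "controller"
    struggling_mode: str = "controller"  # "controller" | "absent"
    group: str = "training"
    seed: int = 0

    def __post_init__(self) -> None:
        for player, script in self.scripts.items():
            if player not in PLAYERS:
                raise ValueError(f"unknown player {player!r}")
            for state, dur in script:
                if state not in BEHAVIOR_STATES:
                    raise ValueError(f"unknown scripted state {state!r}")
                if dur <= 0:
                    raise ValueError("scripted durations must be positive")
        for rate in (self.gaze_dropout, self.utterance_rate,
                     self.distance_jitter):
            if rate < 0:
                raise ValueError("noise rates must be non-negative")
        if not 0 <= self.gaze_dropout <= 1:
            raise ValueError("gaze_dropout must lie in [0, 1]")
        if self.waiting_mode not in ("gaze", "controller"):
            raise ValueError(f"unknown waiting_mode {self.waiting_mode!r}")
        if self.struggling_mode not in ("controller", "absent"):
            raise ValueError(f"unknown struggling_mode {self.struggling_mode!r}")

    @property
    def length(self) -> float:
        return max((sum(d for _, d in script)
                    for script in self.scripts.values()), default=0.0)

    def scripted_timeline(self, player: str, tick: float = 1.0
                          ) -> BehaviorTimeline:
        """Expand a player's script to one state per window."""
        n = math.ceil(self.length / tick)
        states: list[str] = []
        bounds = []
        t = 0.0
        for state, dur in self.scripts.get(player, ()):
            bounds.append((t, t + dur, state))
            t += dur
        for k in range(n):
            mid = k * tick
            state = ENGAGED
            for lo, hi, s in bounds:
                if lo <= mid < hi:
                    state = s
                    break
            else:
                if bounds and mid >= bounds[-1][1]:
                    state = bounds[-1][2]
            states.append(state)
        return BehaviorTimeline(player=player, tick=tick, states=states)


@dataclass
class GroundTruth:
    scenario: Scenario
    timelines: dict[str, BehaviorTimeline]
    expected_trace: FeedbackTrace

    def state_onsets(self, player: str, state: str) -> list[float]:
        """Window-start times where the scripted state begins a new run."""
        tl = self.timelines[player]
        onsets = []
        prev = None
        for k, s in enumerate(tl.states):
            if s == state and prev != state:
                onsets.append(tl.window_start(k))
            prev = s
        return onsets


def _segment_bounds(script: Script) -> list[tuple[float, float, str]]:
    out, t = [], 0.0
    for state, dur in script:
        out.append((t, t + dur, state))
        t += dur
    return out


def simulate_session(scenario: Scenario, seed: int | None = None
                     ) -> tuple[SessionLog, GroundTruth]:
    """Render a scenario into a session log plus its ground truth."""
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    length = scenario.length
    records: list[EventRecord] = []
    n_steps = max(1, len(scenario.task_events))

    for player in PLAYERS:
        script = scenario.scripts.get(player, ((ENGAGED, length),))
        events: list[tuple[float, dict]] = []
        cur_dist = 1.0
        for t0, t1, state in _segment_bounds(script):
            dur = t1 - t0
            if state == ENGAGED:
                # Fresh headroom so the approach never bottoms out mid-segment.
                cur_dist = scenario.distance_drift * dur + 1.0
            active = 1 if (state == ENGAGED
                           or (state == WAITING
                               and scenario.waiting_mode == "controller")
                           or (state == STRUGGLING
                               and scenario.struggling_mode == "controller")
                           ) else 0
            # Status/controller channel.
            n_status = max(1, int(round(dur * scenario.status_hz)))
            for i in range(n_status):
                t = t0 + i / scenario.status_hz
                if t >= t1:
                    break
                if state == ENGAGED:
                    dist = cur_dist - scenario.distance_drift * (t - t0)
                elif state == STRUGGLING:
                    # Offset by one status interval so the retreat is visible
                    # from the segment's very first window.
                    dist = cur_dist + scenario.distance_drift * (
                        t - t0 + 1.0 / scenario.status_hz)
                else:
                    dist = cur_dist
                if scenario.distance_jitter:
                    dist += rng.normal(0.0, scenario.distance_jitter)
                dist = max(0.0, dist)
                omit_dist = (state == STRUGGLING
                             and scenario.struggling_mode == "absent")
                events.append((t, {"active_effort": active,
                                   "object_distance": None if omit_dist
                                   else round(dist, 4)}))
            if state == ENGAGED:
                cur_dist = max(0.0, cur_dist - scenario.distance_drift * dur)
            elif state == STRUGGLING:
                cur_dist = cur_dist + scenario.distance_drift * dur

            # Gaze channel: absent-mode struggling emits no signal at all.
            emit_gaze = not (state == STRUGGLING
                             and scenario.struggling_mode == "absent")
            if emit_gaze:
                n_gaze = int(dur * scenario.gaze_hz)
                for i in range(n_gaze):
                    t = t0 + i / scenario.gaze_hz
                    if t >= t1:
                        break
                    if scenario.gaze_dropout and rng.random() < scenario.gaze_dropout:
                        continue
                    block = int(t)
                    if state == WAITING and block % 7 == 6:
                        roi = TIME_ROI
                    elif state == ENGAGED and block % 11 == 10:
                        roi = SOCIAL_ROI
                    else:
                        roi = TASK_ROI
                    events.append((t, {
                        "gaze_x": round(float(960 + rng.normal(0, 40)), 1),
                        "gaze_y": round(float(540 + rng.normal(0, 40)), 1),
                        "focused_object": roi}))

            # Speech channel (Engaged only).
            if state == ENGAGED and scenario.utterance_rate > 0:
                t = t0 + rng.exponential(1.0 / scenario.utterance_rate)
                while t < t1:
                    events.append((t, {"transcribed_text":
                                       str(rng.choice(_UTTERANCE_TEMPLATES))}))
                    t += rng.exponential(1.0 / scenario.utterance_rate)

        # Piece-share events.
        for i, t in enumerate(scenario.piece_shares.get(player, ())):
            events.append((float(t), {"piece_shared": f"piece_{i + 1}",
                                      "__share__": True}))

        # Chronological fill of cumulative channels.
        events.sort(key=lambda e: e[0])
        shared = 0
        for t, payload in events:
            if payload.pop("__share__", False):
                shared += 1
            done = sum(1 for e in scenario.task_events if e <= t)
            score = round(100.0 * done / n_steps, 2)
            records.append(EventRecord(
                timestamp=round(t, 3), player=player,
                total_score=score, individual_score=score,
                shared_count=shared, game_duration=length, **payload))

    log = SessionLog(dyad_id=scenario.name, group=scenario.group,
                     records=records, roi_map=dict(DEFAULT_ROI_MAP),
                     session_length=length)
    timelines = {p: scenario.scripted_timeline(p) for p in PLAYERS}
    expected = run_fsm(timelines["P1"], timelines["P2"],
                       task_events=scenario.task_events)
    return log, GroundTruth(scenario, timelines, expected)


def preset_scenarios() -> dict[str, Scenario]:
    """Named scenarios, one per feedback-machine row plus a mixed session.

    The single-condition presets are noise-free because they pin exact
    prompt/escalation timing; ``mixed_session`` carries the default noise.
    """
    clean = dict(gaze_dropout=0.0, distance_jitter=0.0)
    presets = {
        "observe_baseline": Scenario(
            name="observe_baseline",
            scripts={"P1": ((ENGAGED, 120.0),), "P2": ((ENGAGED, 120.0),)},
            **clean),
        "redirect_case": Scenario(
            name="redirect_case",
            scripts={"P1": ((ENGAGED, 10.0), (WAITING, 90.0)),
                     "P2": ((ENGAGED, 100.0),)},
            **clean),
        "assist_case": Scenario(
            name="assist_case",
            scripts={"P1": ((ENGAGED, 10.0), (STRUGGLING, 90.0)),
                     "P2": ((ENGAGED, 100.0),)},
            **clean),
        "intervene_case": Scenario(
            name="intervene_case",
            scripts={"P1": ((ENGAGED, 10.0), (STRUGGLING, 80.0)),
                     "P2": ((ENGAGED, 10.0), (STRUGGLING, 80.0))},
            **clean),
        "positive_case": Scenario(
            name="positive_case",
            scripts={"P1": ((ENGAGED, 120.0),), "P2": ((ENGAGED, 120.0),)},
            task_events=(60.0,),
            piece_shares={"P1": (20.0, 45.0), "P2": (30.0,)},
            **clean),
        "mixed_session": Scenario(
            name="mixed_session",
            scripts={"P1": ((ENGAGED, 120.0), (WAITING, 40.0),
                            (ENGAGED, 60.0), (STRUGGLING, 40.0),
                            (ENGAGED, 60.0)),
                     "P2": ((ENGAGED, 160.0), (STRUGGLING, 40.0),
                            (ENGAGED, 120.0))},
            task_events=(90.0, 200.0, 300.0),
            piece_shares={"P1": (35.0, 95.0, 210.0), "P2": (60.0, 250.0)}),
    }
    return presets
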