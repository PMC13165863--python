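"""Rule-based feedback finite state machine over dyadic behavior timelines.

Five states — Observe, Redirect, Assist, Intervene, PositiveFeedback —
scaffold a collaborating dyad:

* Observe: both participants Engaged; no action.
* Redirect: one participant Waiting (none Struggling).  After the condition
  has persisted for the wait interval (30 s), the waiting participant and
  their partner each receive a complementary prompt; after a further
  interval (or when the whole dyad has gone idle) both are prompted to
  request help from the researcher.
* Assist: exactly one participant Struggling.  After 30 s both receive
  prompts; after a further 30 s the system automatically completes the
  current task step.
* Intervene: both Struggling.  Help-request prompts after 30 s, automatic
  step completion a further 30 s later.
* PositiveFeedback: entered instantaneously on step/task completion,
  delivers praise, then returns to Observe.

Prompts never fire before the triggering condition has held continuously
for the full wait interval; any change of the condition (including which
participant triggers it) resets the timer.  The 30 s delay gives the dyad
room to resolve breakdowns on its own before the system steps in.

The machine is formally the 5-tuple (states, dyad-state + task-event
inputs, transition function, initial state Observe, prompt/auto-completion
outputs) and is deterministic: identical inputs yield identical traces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .behavior import BEHAVIOR_STATES, ENGAGED, STRUGGLING, WAITING, BehaviorTimeline
from .eventlog import PLAYERS

__all__ = [
    "FSM_STATES",
    "WAIT_INTERVAL_S",
    "PROMPT_CATALOGUE",
    "PromptEvent",
    "FeedbackTrace",
    "resolve_dyad_state",
    "FeedbackFsm",
    "run_fsm",
]

OBSERVE = "Observe"
REDIRECT = "Redirect"
ASSIST = "Assist"
INTERVENE = "Intervene"
POSITIVE = "PositiveFeedback"
FSM_STATES = (OBSERVE, REDIRECT, ASSIST, INTERVENE, POSITIVE)

#: Continuous-condition interval before any prompt, and again before escalation.
WAIT_INTERVAL_S = 30.0

#: Editable prompt catalogue; template ids are stable keys, texts are defaults.
PROMPT_CATALOGUE: dict[str, str] = {
    "redirect.waiting": "Please wait for your partner to finish",
    "redirect.partner": "Your partner is waiting. Please update them on your progress.",
    "redirect.help_request": "Please request help from the researcher.",
    "assist.struggling": "Try asking your partner for advice.",
    "assist.partner": "Your partner seems to be struggling, please assist them.",
    "intervene.help_request": "Please request help from the researcher.",
    "positive.step": "Good job!",
    "positive.task": "Well done on working together to complete the task!",
    # Role-adapted check-in variants, keyed by recipient role.
    "redirect.partner.initiate": "Try initiating a conversation with your partner.",
    "redirect.partner.checkin": "Try checking in with your partner.",
}


@dataclass(frozen=True)
class PromptEvent:
    time: float
    recipient: str            # "P1", "P2", "both", or "researcher_request"
    template_id: str
    text: str


@dataclass
class FeedbackTrace:
    """Timestamped state trajectory plus emitted prompts and interventions."""

    states: list[tuple[float, str]] = field(default_factory=list)
    prompts: list[PromptEvent] = field(default_factory=list)
    auto_completions: list[float] = field(default_factory=list)

    def prompts_by_template(self, prefix: str) -> list[PromptEvent]:
        return [p for p in self.prompts if p.template_id.startswith(prefix)]


def resolve_dyad_state(s1: str, s2: str) -> tuple[str, tuple[str, ...]]:
    """Map a pair of behavior states to (FSM state, triggering players).

    Struggling dominates Waiting: a (Waiting, Struggling) dyad resolves to
    Assist, since the greater breakdown is addressed first; Intervene is
    reserved for mutual struggle.  A fully idle (Waiting, Waiting) dyad
    resolves to Redirect with both participants as triggers.
    """
    for s in (s1, s2):
        if s not in BEHAVIOR_STATES:
            raise ValueError(f"unknown behavior state {s!r}")
    if s1 == ENGAGED and s2 == ENGAGED:
        return OBSERVE, ()
    if s1 == STRUGGLING and s2 == STRUGGLING:
        return INTERVENE, PLAYERS
    if s1 == STRUGGLING:
        return ASSIST, ("P1",)
    if s2 == STRUGGLING:
        return ASSIST, ("P2",)
    waiting = tuple(p for p, s in zip(PLAYERS, (s1, s2)) if s == WAITING)
    return REDIRECT, waiting


def _partner(player: str) -> str:
    return "P2" if player == "P1" else "P1"


class FeedbackFsm:
    """Stepwise feedback machine; drive with :meth:`step` at nondecreasing times."""

    def __init__(self, wait_s: float = WAIT_INTERVAL_S,
                 catalogue: Mapping[str, str] | None = None) -> None:
        if wait_s <= 0:
            raise ValueError("wait interval must be positive")
        self.wait_s = wait_s
        self.catalogue = dict(PROMPT_CATALOGUE)
        if catalogue:
            self.catalogue.update(catalogue)
        self.state = OBSERVE
        self.trace = FeedbackTrace()
        self._condition: tuple[str, tuple[str, ...]] | None = None
        self._onset = 0.0
        self._prompt_time: float | None = None
        self._escalated = False
        self._last_t: float | None = None

    # -- internals ----------------------------------------------------------
    def _emit(self, t: float, recipient: str, template_id: str) -> None:
        self.trace.prompts.append(PromptEvent(
            t, recipient, template_id, self.catalogue[template_id]))

    def _reset_timer(self) -> None:
        self._condition = None
        self._prompt_time = None
        self._escalated = False

    def _stage_one(self, t: float, target: str,
                   trigger: tuple[str, ...]) -> None:
        if target == REDIRECT:
            if len(trigger) == 2:  # whole dyad idle -> straight to help request
                self._emit(t, "both", "redirect.help_request")
                self._escalated = True
            else:
                waiting = trigger[0]
                self._emit(t, waiting, "redirect.waiting")
                self._emit(t, _partner(waiting), "redirect.partner")
        elif target == ASSIST:
            struggling = trigger[0]
            self._emit(t, struggling, "assist.struggling")
            self._emit(t, _partner(struggling), "assist.partner")
        elif target == INTERVENE:
            self._emit(t, "both", "intervene.help_request")

    def _escalate(self, t: float, target: str) -> None:
        if target == REDIRECT:
            self._emit(t, "both", "redirect.help_request")
            self._escalated = True
        else:  # Assist or Intervene: complete the step for the dyad
            self.trace.auto_completions.append(t)
            self._reset_timer()
            self.state = OBSERVE

    # -- public -------------------------------------------------------------
    def step(self, dyad: tuple[str, str], t: float,
             task_event: bool = False) -> str:
        """Advance one tick given both participants' behavior states."""
        if self._last_t is not None and t < self._last_t:
            raise ValueError("step times must be nondecreasing")
        self._last_t = t

        if task_event:
            self.state = POSITIVE
            self._emit(t, "both", "positive.step")
            self._reset_timer()
            self.trace.states.append((t, self.state))
            return self.state

        target, trigger = resolve_dyad_state(*dyad)
        if target == OBSERVE:
            self._reset_timer()
            self.state = OBSERVE
        else:
            key = (target, trigger)
            if key != self._condition:
                self._condition = key
                self._onset = t
                self._prompt_time = None
                self._escalated = False
            self.state = target
            if self._prompt_time is None and t - self._onset >= self.wait_s:
                self._stage_one(t, target, trigger)
                self._prompt_time = t
            elif (self._prompt_time is not None and not self._escalated
                  and t - self._prompt_time >= self.wait_s):
                self._escalate(t, target)
        self.trace.states.append((t, self.state))
        return self.state


def run_fsm(timeline_a: BehaviorTimeline, timeline_b: BehaviorTimeline,
            task_events: Iterable[float] = (),
            wait_s: float = WAIT_INTERVAL_S,
            catalogue: Mapping[str, str] | None = None) -> FeedbackTrace:
    """Run the feedback machine over a dyad's aligned behavior timelines.

    Timelines must share tick and length.  Task events (step completions,
    in seconds) trigger PositiveFeedback in the window containing them.
    Empty timelines yield a trace holding only the initial Observe state.
    """
    if timeline_a.tick != timeline_b.tick:
        raise ValueError("timelines must share a tick")
    if len(timeline_a) != len(timeline_b):
        raise ValueError("timelines must share a length")
    fsm = FeedbackFsm(wait_s=wait_s, catalogue=catalogue)
    tick = timeline_a.tick
    events = sorted(task_events)
    n = len(timeline_a)
    if n == 0:
        fsm.trace.states.append((0.0, OBSERVE))
        return fsm.trace
    for k in range(n):
        t = k * tick
        has_event = any(t <= e < t + tick for e in events)
        fsm.step((timeline_a.states[k], timeline_b.states[k]), t,
                 task_event=has_event)
    return fsm.trace
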