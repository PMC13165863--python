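"""End-to-end session analysis: log -> features -> profiles (+ feedback trace)."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .behavior import MOVEMENT_EPSILON, BehaviorTimeline, build_timeline
from .dimensions import (CollaborationProfile, FeatureVector, extract_features,
                         score_dimensions)
from .eventlog import PLAYERS, SessionLog, Window, window_session
from .feedback import WAIT_INTERVAL_S, FeedbackTrace, run_fsm
from .gaze import (MIN_FIXATION_S, Fixation, GazeSummary, categorize_gaze,
                   detect_fixations, gaze_samples_from_log, summarize_gaze)
from .speech import (INITIATION_GAP_S, MAX_UTTERANCE_S, SILENCE_GAP_S,
                     Utterance, utterances_from_log)

__all__ = ["SessionAnalysis", "analyze_session"]


@dataclass
class SessionAnalysis:
    """All derived artifacts for one dyadic session."""

    log: SessionLog
    windows: dict[str, list[Window]]
    utterances: list[Utterance]
    fixations: list[Fixation]
    gaze_summaries: dict[str, GazeSummary]
    timelines: dict[str, BehaviorTimeline]
    features: dict[str, FeatureVector]
    profiles: dict[str, CollaborationProfile]
    trace: FeedbackTrace | None = None


def analyze_session(log: SessionLog, *, tick: float = 1.0,
                    min_fixation: float = MIN_FIXATION_S,
                    silence_gap: float = SILENCE_GAP_S,
                    max_utterance: float = MAX_UTTERANCE_S,
                    initiation_gap: float = INITIATION_GAP_S,
                    fsm_wait: float = WAIT_INTERVAL_S,
                    movement_epsilon: float = MOVEMENT_EPSILON,
                    normalization: str = "rate_per_minute",
                    task_events: tuple[float, ...] = (),
                    run_feedback: bool | None = None) -> SessionAnalysis:
    """Run the full analysis chain on a session log.

    The feedback machine runs only for training-group sessions (assessment
    sessions provide no prompts); pass ``run_feedback`` to override.
    """
    windows = window_session(log, tick)
    utterances = utterances_from_log(log, silence_gap, max_utterance,
                                     initiation_gap)
    fixations: list[Fixation] = []
    for player in PLAYERS:
        fixations.extend(categorize_gaze(
            detect_fixations(gaze_samples_from_log(log, player),
                             min_fixation, player=player),
            log.roi_map))
    gaze_summaries = summarize_gaze(fixations)
    timelines = {p: build_timeline(windows[p], tick, movement_epsilon)
                 for p in PLAYERS}
    features = extract_features(log, utterances, gaze_summaries, timelines,
                                tick)
    profiles = {p: score_dimensions(features[p], log.length, normalization,
                                    cohort=list(features.values())
                                    if normalization == "zscore" else None)
                for p in PLAYERS}
    trace = None
    if run_feedback if run_feedback is not None else log.group == "training":
        trace = run_fsm(timelines["P1"], timelines["P2"],
                        task_events=task_events, wait_s=fsm_wait)
    return SessionAnalysis(log, windows, utterances, fixations,
                           gaze_summaries, timelines, features, profiles,
                           trace)
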