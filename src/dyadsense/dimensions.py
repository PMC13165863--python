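"""Feature extraction and mapping onto the five dimensions of collaboration.

Multimodal features — initiations, dialogue-act counts, piece-sharing
events, active-effort windows and categorized gaze fixations — are pooled
into five operationalized constructs:

* Dialogue Management:        initiations + Acks, Neg, Conv dialogue acts
* Information Pooling:        pieces shared + Ques, Read, Inform acts
* Reciprocal Interaction:     active effort + Pos, Acks acts
* Task Division/Coordination: task-object fixations, pieces shared,
                              active effort, Inform acts
* Time Management:            timer-bar fixations only

The incidence of features in dimensions is frozen (``DIMENSION_FEATURES``);
everything else — the normalization (per-minute rates by default, optional
within-cohort z-scores) and the unweighted mean used to combine features —
is configuration.  Utterances labeled Out are transcription noise and are
excluded from every feature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .behavior import BehaviorTimeline, build_timeline
from .eventlog import PLAYERS, SessionLog, window_session
from .gaze import (GazeSummary, categorize_gaze, detect_fixations,
                   gaze_samples_from_log, summarize_gaze)
from .speech import DIALOGUE_ACTS, Utterance, utterances_from_log

__all__ = [
    "DIMENSIONS",
    "DIMENSION_FEATURES",
    "FeatureVector",
    "CollaborationProfile",
    "extract_features",
    "score_dimensions",
    "aggregate_dimension_effects",
    "profiles_frame",
]

DIMENSIONS = (
    "DialogueManagement",
    "InformationPooling",
    "ReciprocalInteraction",
    "TaskDivisionCoordination",
    "TimeManagement",
)

#: Frozen feature -> dimension incidence.
DIMENSION_FEATURES: dict[str, tuple[str, ...]] = {
    "DialogueManagement": ("initiations", "da_Acks", "da_Neg", "da_Conv"),
    "InformationPooling": ("piece_shared", "da_Ques", "da_Read", "da_Inform"),
    "ReciprocalInteraction": ("active_effort", "da_Pos", "da_Acks"),
    "TaskDivisionCoordination": ("gaze_task", "piece_shared",
                                 "active_effort", "da_Inform"),
    "TimeManagement": ("gaze_time",),
}


@dataclass
class FeatureVector:
    """Per-participant session features feeding the dimension scores."""

    player: str
    initiations: int = 0
    dialogue_acts: dict[str, int] = field(
        default_factory=lambda: {a: 0 for a in DIALOGUE_ACTS})
    piece_shared: int = 0
    active_effort: int = 0        # number of windows with controller activity
    gaze_task: int = 0
    gaze_social: int = 0
    gaze_time: int = 0
    task_score: float = 0.0
    individual_score: float = 0.0
    game_duration: float = 0.0

    def as_dict(self) -> dict[str, float]:
        d = {
            "initiations": self.initiations,
            "piece_shared": self.piece_shared,
            "active_effort": self.active_effort,
            "gaze_task": self.gaze_task,
            "gaze_social": self.gaze_social,
            "gaze_time": self.gaze_time,
            "task_score": self.task_score,
            "individual_score": self.individual_score,
            "game_duration": self.game_duration,
        }
        # Out is recorded but never used as an analysis feature.
        d.update({f"da_{a}": float(self.dialogue_acts.get(a, 0))
                  for a in DIALOGUE_ACTS if a != "Out"})
        return {k: float(v) for k, v in d.items()}


@dataclass
class CollaborationProfile:
    player: str
    scores: dict[str, float]
    provenance: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DIMENSION_FEATURES))
    normalization: str = "rate_per_minute"


def extract_features(log: SessionLog,
                     utterances: Sequence[Utterance] | None = None,
                     gaze_summaries: Mapping[str, GazeSummary] | None = None,
                     timelines: Mapping[str, BehaviorTimeline] | None = None,
                     tick: float = 1.0) -> dict[str, FeatureVector]:
    """Deterministically reduce session artifacts to one vector per player.

    Upstream artifacts (labeled utterances, gaze summaries, behavior
    timelines) are recomputed from the log with defaults when not given.
    """
    if utterances is None:
        utterances = utterances_from_log(log)
    windows = window_session(log, tick)
    if gaze_summaries is None:
        fixations = []
        for player in PLAYERS:
            fixations.extend(categorize_gaze(
                detect_fixations(gaze_samples_from_log(log, player),
                                 player=player),
                log.roi_map))
        gaze_summaries = summarize_gaze(fixations)
    if timelines is None:
        timelines = {p: build_timeline(windows[p], tick) for p in PLAYERS}

    out: dict[str, FeatureVector] = {}
    for player in PLAYERS:
        fv = FeatureVector(player)
        for u in utterances:
            if u.player != player:
                continue
            if u.is_initiation:
                fv.initiations += 1
            if u.label is not None:
                fv.dialogue_acts[u.label] = fv.dialogue_acts.get(u.label, 0) + 1
        recs = log.player_records(player)
        fv.piece_shared = sum(1 for r in recs if r.piece_shared)
        fv.active_effort = sum(1 for w in windows[player]
                               if w.controller_active)
        summary = gaze_summaries.get(player)
        if summary is not None:
            fv.gaze_task = summary.counts["task"]
            fv.gaze_social = summary.counts["social"]
            fv.gaze_time = summary.counts["time"]
        totals = [r.total_score for r in recs if r.total_score is not None]
        indivs = [r.individual_score for r in recs
                  if r.individual_score is not None]
        durs = [r.game_duration for r in recs if r.game_duration is not None]
        fv.task_score = totals[-1] if totals else 0.0
        fv.individual_score = indivs[-1] if indivs else 0.0
        fv.game_duration = durs[-1] if durs else log.length
        out[player] = fv
    return out


def _normalized(values: Mapping[str, float], session_length_s: float,
                normalization: str,
                cohort: Sequence[Mapping[str, float]] | None) -> dict[str, float]:
    if normalization == "rate_per_minute":
        minutes = max(session_length_s, 1e-9) / 60.0
        return {k: v / minutes for k, v in values.items()}
    if normalization == "zscore":
        if not cohort:
            raise ValueError("zscore normalization requires a cohort")
        out = {}
        for k, v in values.items():
            col = np.array([c[k] for c in cohort], dtype=float)
            sd = col.std(ddof=0)
            out[k] = 0.0 if sd == 0 else (v - col.mean()) / sd
        return out
    raise ValueError(f"unknown normalization {normalization!r}")


def score_dimensions(features: FeatureVector, session_length_s: float,
                     normalization: str = "rate_per_minute",
                     cohort: Sequence[FeatureVector] | None = None
                     ) -> CollaborationProfile:
    """Score the five dimensions as unweighted means of normalized features."""
    raw = features.as_dict()
    cohort_dicts = [c.as_dict() for c in cohort] if cohort else None
    norm = _normalized(raw, session_length_s, normalization, cohort_dicts)
    scores = {dim: float(np.mean([norm[f] for f in feats]))
              for dim, feats in DIMENSION_FEATURES.items()}
    return CollaborationProfile(features.player, scores,
                                normalization=normalization)


def aggregate_dimension_effects(feature_effects: Mapping[str, float]
                                ) -> dict[str, float]:
    """Per-dimension mean of the absolute effect sizes of constituent features.

    ``feature_effects`` maps feature names (as in ``DIMENSION_FEATURES``)
    to Cohen's d values; every dimension must have at least one constituent
    present.
    """
    out: dict[str, float] = {}
    for dim, feats in DIMENSION_FEATURES.items():
        ds = [abs(feature_effects[f]) for f in feats if f in feature_effects]
        if not ds:
            raise ValueError(f"no effect sizes for dimension {dim}")
        out[dim] = float(np.mean(ds))
    return out


def profiles_frame(profiles: Iterable[CollaborationProfile],
                   features: Mapping[str, FeatureVector] | None = None):
    """Tidy table: one row per player with dimension scores (+ raw features)."""
    import pandas as pd

    rows = []
    for prof in profiles:
        row: dict[str, object] = {"player": prof.player,
                                  "normalization": prof.normalization}
        row.update(prof.scores)
        if features and prof.player in features:
            row.update(features[prof.player].as_dict())
        rows.append(row)
    return pd.DataFrame(rows)
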