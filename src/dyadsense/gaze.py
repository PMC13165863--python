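"""Fixation detection and gaze categorization on ROI-labeled samples.

The eye-tracking channel reports, per sample, the name of the on-screen
object the participant is looking at (or nothing).  A fixation is a maximal
run of consecutive samples sharing one non-null ROI whose time span reaches
the minimum dwell threshold — 200 ms by default, the conventional boundary
between a fixation and shorter gaze events.  Detection is dwell-on-ROI, not
dispersion- or velocity-based: the tracker has already resolved gaze to
named objects, so run-length over labels is the faithful primitive.

Detected fixations are sorted into three categories: *task* (virtual task
objects), *social* (the partner's video-stream window), and *time* (the
timer bar).  Unmapped ROIs default to task.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .eventlog import GAZE_CATEGORIES, PLAYERS, SessionLog

__all__ = [
    "MIN_FIXATION_S",
    "Fixation",
    "GazeSummary",
    "detect_fixations",
    "categorize_gaze",
    "gaze_samples_from_log",
    "summarize_gaze",
]

#: Minimum dwell for a run of same-ROI samples to count as a fixation.
MIN_FIXATION_S = 0.200


@dataclass(frozen=True)
class Fixation:
    player: str
    roi: str
    start: float
    duration: float
    category: str = "task"


@dataclass
class GazeSummary:
    """Per-player fixation counts and total dwell per gaze category."""

    player: str
    counts: dict[str, int] = field(
        default_factory=lambda: {c: 0 for c in GAZE_CATEGORIES})
    dwell: dict[str, float] = field(
        default_factory=lambda: {c: 0.0 for c in GAZE_CATEGORIES})

    @property
    def count_total(self) -> int:
        return sum(self.counts.values())

    @property
    def dwell_total(self) -> float:
        return sum(self.dwell.values())


def detect_fixations(samples: Sequence[tuple[float, str | None]],
                     min_fixation: float = MIN_FIXATION_S, *,
                     player: str = "P1",
                     null_gap_samples: int = 1,
                     null_gap_s: float = 0.025,
                     break_gap_s: float = 0.1) -> list[Fixation]:
    """Detect fixations in one player's time-sorted ``(timestamp, roi)`` stream.

    A run's span is the time from its first to its last sample; runs whose
    span reaches ``min_fixation`` emit one fixation.  A short tracker
    dropout inside a run — at most ``null_gap_samples`` consecutive null
    samples, or a null stretch no longer than ``null_gap_s`` (whichever is
    larger) — does not break it.  A silent gap between samples longer than
    ``break_gap_s`` does, as does any sample on a different ROI.  Set
    ``null_gap_samples=0, null_gap_s=0`` and ``break_gap_s=inf`` for strict
    run-length semantics.
    """
    if min_fixation <= 0:
        raise ValueError("min_fixation must be positive")
    fixations: list[Fixation] = []
    roi: str | None = None         # ROI of the open run
    start = 0.0
    last_on = 0.0                  # last on-ROI sample time in the run
    last_t: float | None = None    # previous sample time (sortedness check)
    null_run = 0                   # consecutive nulls inside the open run
    null_since = 0.0               # time of last on-ROI sample before nulls

    def close() -> None:
        nonlocal roi
        if roi is not None and last_on - start >= min_fixation - 1e-12:
            fixations.append(Fixation(player, roi, start, last_on - start))
        roi = None

    for t, label in samples:
        if last_t is not None and t < last_t:
            raise ValueError(f"gaze samples not time-sorted at t={t}")
        if last_t is not None and roi is not None and t - last_t > break_gap_s:
            close()
        last_t = t
        if label is None:
            if roi is not None:
                null_run += 1
                tolerated = (null_run <= null_gap_samples
                             or t - null_since <= null_gap_s)
                if not tolerated:
                    close()
                    null_run = 0
            continue
        if roi == label:
            last_on = t
            null_run = 0
            null_since = t
        else:
            close()
            roi, start, last_on = label, t, t
            null_run = 0
            null_since = t
    close()
    return fixations


def categorize_gaze(fixations: Iterable[Fixation],
                    roi_map: Mapping[str, str] | None = None,
                    default: str = "task") -> list[Fixation]:
    """Resolve each fixation's ROI to a gaze category through ``roi_map``."""
    roi_map = roi_map or {}
    out = []
    for fx in fixations:
        cat = roi_map.get(fx.roi, default)
        if cat not in GAZE_CATEGORIES:
            raise ValueError(f"unknown gaze category {cat!r} for ROI {fx.roi!r}")
        out.append(Fixation(fx.player, fx.roi, fx.start, fx.duration, cat))
    return out


def summarize_gaze(fixations: Iterable[Fixation]) -> dict[str, GazeSummary]:
    """Aggregate categorized fixations into per-player count/dwell summaries."""
    summaries = {p: GazeSummary(p) for p in PLAYERS}
    for fx in fixations:
        s = summaries.setdefault(fx.player, GazeSummary(fx.player))
        s.counts[fx.category] += 1
        s.dwell[fx.category] += fx.duration
    return summaries


def gaze_samples_from_log(log: SessionLog, player: str
                          ) -> list[tuple[float, str | None]]:
    """Extract the (timestamp, focused-ROI) stream for one player.

    Records without a gaze point are not gaze samples and are skipped;
    records with a gaze point but no focused object are null-ROI samples.
    """
    return [(r.timestamp, r.focused_object)
            for r in log.player_records(player)
            if r.gaze_x is not None or r.gaze_y is not None]
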