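"""Session data model and I/O for synchronized dyadic multimodal event logs.

A session log is a single time-ordered stream of :class:`EventRecord` covering
both participants of a dyad.  Each record carries up to 15 fields sampled from
the sensing channels of a collaborative virtual environment: transcribed
speech, screen-space gaze points with the name of the focused on-screen
object, controller/task telemetry (scores, piece events, an active-effort
flag) and the distance of the manipulated object from its target.

Timestamps are elapsed session time.  On disk they are clock strings
(``HH:MM:SS`` with optional milliseconds); in memory they are seconds as
floats.  Two serializations are supported: CSV with a canonical header, and
JSON-lines with one record object per line.

Missing-data policy: rows that fail schema validation are dropped and
counted, never imputed.  A file where more than half the rows drop is
rejected outright, since that almost always means the wrong file was given.
"""

from __future__ import annotations

import csv
import json
import math
import re
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "PLAYERS",
    "SchemaError",
    "EventRecord",
    "SessionLog",
    "Window",
    "parse_timestamp",
    "format_timestamp",
    "read_session",
    "write_session",
    "merge_player_streams",
    "window_session",
]

PLAYERS = ("P1", "P2")

#: Gaze categories a focused object can resolve to.
GAZE_CATEGORIES = ("task", "social", "time")

#: Objects mapped to non-task gaze categories unless a session supplies its
#: own map; anything unlisted is task-related by default.
DEFAULT_ROI_MAP = {
    "video_window": "social",
    "partner_video": "social",
    "timer_bar": "time",
    "time_bar": "time",
}


class SchemaError(ValueError):
    """A record or file violates the session-log schema."""


_TS_RE = re.compile(r"^(\d{1,4}):([0-5]?\d):([0-5]?\d)(\.\d{1,3})?$")


def parse_timestamp(text: str, index: int | None = None) -> float:
    """Parse a ``HH:MM:SS`` or ``HH:MM:SS.mmm`` clock string into seconds.

    Whole-second inputs are valid but degrade sub-second resolution (e.g.
    the 200 ms fixation threshold cannot be expressed); millisecond
    precision is recommended for gaze streams.
    """
    m = _TS_RE.match(text.strip()) if isinstance(text, str) else None
    if m is None:
        where = "" if index is None else f" (record {index})"
        raise SchemaError(f"malformed timestamp {text!r}{where}")
    h, mi, s = int(m.group(1)), int(m.group(2)), int(m.group(3))
    ms = round(float(m.group(4)) * 1000) if m.group(4) else 0
    # integer-millisecond arithmetic keeps parse/format exact inverses
    return ((h * 3600 + mi * 60 + s) * 1000 + ms) / 1000.0


def format_timestamp(seconds: float) -> str:
    """Inverse of :func:`parse_timestamp`; millisecond precision."""
    if seconds < 0 or not math.isfinite(seconds):
        raise SchemaError(f"cannot format timestamp {seconds!r}")
    ms = round(seconds * 1000)
    h, rem = divmod(ms, 3_600_000)
    mi, rem = divmod(rem, 60_000)
    s, ms = divmod(rem, 1000)
    base = f"{h:02d}:{mi:02d}:{s:02d}"
    return base if ms == 0 else f"{base}.{ms:03d}"


@dataclass
class EventRecord:
    """One synchronized multimodal sample for one participant."""

    timestamp: float
    player: str
    transcribed_text: str | None = None
    gaze_x: float | None = None
    gaze_y: float | None = None
    focused_object: str | None = None
    total_score: float | None = None
    individual_score: float | None = None
    piece_at_target: str | None = None
    piece_shared: str | None = None
    shared_count: int = 0
    piece_selected: str | None = None
    active_effort: int = 0
    game_duration: float | None = None
    object_distance: float | None = None

    def validate(self, index: int | None = None) -> "EventRecord":
        where = "" if index is None else f" (record {index})"
        if not (isinstance(self.timestamp, (int, float)) and self.timestamp >= 0):
            raise SchemaError(f"timestamp must be non-negative{where}")
        if self.player not in PLAYERS:
            raise SchemaError(f"player must be one of {PLAYERS}{where}")
        if self.active_effort not in (0, 1):
            raise SchemaError(f"active_effort must be 0 or 1{where}")
        for name in ("total_score", "individual_score"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 100.0):
                raise SchemaError(f"{name} must lie in [0, 100]{where}")
        if self.shared_count < 0:
            raise SchemaError(f"shared_count must be non-negative{where}")
        if self.object_distance is not None and self.object_distance < 0:
            raise SchemaError(f"object_distance must be non-negative{where}")
        return self


FIELD_NAMES = tuple(f.name for f in fields(EventRecord))

# Case/punctuation-insensitive header aliases for the canonical columns.
_ALIASES = {
    "timestamp": "timestamp",
    "time": "timestamp",
    "player": "player",
    "playerlabel": "player",
    "transcribedtext": "transcribed_text",
    "text": "transcribed_text",
    "gazex": "gaze_x",
    "xgazepoint": "gaze_x",
    "gazey": "gaze_y",
    "ygazepoint": "gaze_y",
    "focusedobject": "focused_object",
    "totalscore": "total_score",
    "individualscore": "individual_score",
    "pieceattarget": "piece_at_target",
    "pieceshared": "piece_shared",
    "sharedcount": "shared_count",
    "pieceselected": "piece_selected",
    "activeeffort": "active_effort",
    "gameduration": "game_duration",
    "objectdistance": "object_distance",
}
_ALIASES.update({k.replace("_", ""): v for k, v in
                 ((f, f) for f in FIELD_NAMES)})

_FLOAT_FIELDS = {"gaze_x", "gaze_y", "total_score", "individual_score",
                 "game_duration", "object_distance"}
_INT_FIELDS = {"shared_count", "active_effort"}
_STR_FIELDS = {"transcribed_text", "focused_object", "piece_at_target",
               "piece_shared", "piece_selected"}

_PLAYER_NORM = {"p1": "P1", "player1": "P1", "1": "P1",
                "p2": "P2", "player2": "P2", "2": "P2"}


def _canon_header(name: str) -> str | None:
    return _ALIASES.get(re.sub(r"[^a-z0-9]", "", name.lower()))


def _record_from_mapping(row: Mapping[str, object], index: int) -> EventRecord:
    kwargs: dict[str, object] = {}
    for key, raw in row.items():
        name = _canon_header(str(key))
        if name is None:
            continue
        if raw is None or (isinstance(raw, str) and raw.strip() == ""):
            continue
        if name == "timestamp":
            kwargs[name] = raw if isinstance(raw, (int, float)) else \
                parse_timestamp(str(raw), index)
        elif name == "player":
            norm = _PLAYER_NORM.get(re.sub(r"\s+", "", str(raw).lower()))
            if norm is None:
                raise SchemaError(f"unknown player {raw!r} (record {index})")
            kwargs[name] = norm
        elif name in _FLOAT_FIELDS:
            try:
                kwargs[name] = float(raw)
            except (TypeError, ValueError):
                raise SchemaError(f"bad value for {name}: {raw!r} (record {index})")
        elif name in _INT_FIELDS:
            try:
                kwargs[name] = int(float(raw))
            except (TypeError, ValueError):
                raise SchemaError(f"bad value for {name}: {raw!r} (record {index})")
        else:
            kwargs[name] = str(raw)
    if "timestamp" not in kwargs or "player" not in kwargs:
        raise SchemaError(f"record {index} lacks timestamp or player")
    return EventRecord(**kwargs).validate(index)  # type: ignore[arg-type]


def _sort_key(rec: EventRecord, idx: int):
    # Deterministic tie-break: P1 before P2, then original order.
    return (rec.timestamp, PLAYERS.index(rec.player), idx)


@dataclass
class SessionLog:
    """A validated, time-sorted dyadic session.

    ``roi_map`` maps focused-object names to gaze categories
    (task / social / time); unmapped objects are task-related.
    """

    dyad_id: str = "dyad"
    group: str = "training"
    records: list[EventRecord] = field(default_factory=list)
    roi_map: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_ROI_MAP))
    session_length: float | None = None
    dropped_rows: int = 0

    def __post_init__(self) -> None:
        self.records = [r for _, r in sorted(
            ((i, r) for i, r in enumerate(self.records)),
            key=lambda pair: _sort_key(pair[1], pair[0]))]
        if self.session_length is None and self.records:
            self.session_length = math.ceil(self.records[-1].timestamp)

    @property
    def length(self) -> float:
        if self.session_length is not None:
            return self.session_length
        return self.records[-1].timestamp if self.records else 0.0

    def player_records(self, player: str) -> list[EventRecord]:
        return [r for r in self.records if r.player == player]

    def validate(self) -> "SessionLog":
        for cat in self.roi_map.values():
            if cat not in GAZE_CATEGORIES:
                raise SchemaError(f"unknown gaze category {cat!r}")
        last: dict[str, float] = {}
        shared: dict[str, int] = {}
        for i, rec in enumerate(self.records):
            rec.validate(i)
            if rec.timestamp < last.get(rec.player, 0.0):
                raise SchemaError(f"records not time-sorted at index {i}")
            last[rec.player] = rec.timestamp
            if rec.shared_count < shared.get(rec.player, 0):
                raise SchemaError(
                    f"shared_count decreases for {rec.player} at index {i}")
            shared[rec.player] = rec.shared_count
        return self

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SessionLog):
            return NotImplemented
        return (self.dyad_id, self.group, self.records, self.roi_map) == \
               (other.dyad_id, other.group, other.records, other.roi_map)


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt:
        return fmt
    suffix = path.suffix.lower()
    if suffix in (".jsonl", ".ndjson", ".json"):
        return "jsonl"
    return "csv"


def read_session(path: str | Path, fmt: str | None = None, *,
                 dyad_id: str | None = None, group: str = "training",
                 roi_map: Mapping[str, str] | None = None) -> SessionLog:
    """Read and validate a session file (CSV or JSON-lines).

    Invalid or corrupted rows are dropped and counted (``dropped_rows``);
    a file losing more than 50% of its rows raises :class:`SchemaError`.
    """
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt not in ("csv", "jsonl"):
        raise SchemaError(f"unknown format {fmt!r}")
    rows: list[Mapping[str, object]]
    with path.open("r", encoding="utf-8", newline="") as fh:
        if fmt == "csv":
            rows = list(csv.DictReader(fh))
        else:
            rows = []
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                try:
                    rows.append(json.loads(line))
                except json.JSONDecodeError:
                    rows.append({"__bad__": line})

    records: list[EventRecord] = []
    dropped = 0
    for i, row in enumerate(rows):
        try:
            records.append(_record_from_mapping(row, i))
        except SchemaError:
            dropped += 1
    if rows and dropped > len(rows) / 2:
        raise SchemaError(
            f"{dropped}/{len(rows)} rows invalid in {path.name}; "
            "this does not look like a session log")

    # Enforce monotone shared_count per player: a regressing row is corrupt.
    records.sort(key=lambda r: (r.timestamp, PLAYERS.index(r.player)))
    kept: list[EventRecord] = []
    running: dict[str, int] = {}
    for rec in records:
        if rec.shared_count < running.get(rec.player, 0):
            dropped += 1
            continue
        running[rec.player] = rec.shared_count
        kept.append(rec)

    return SessionLog(dyad_id=dyad_id or path.stem, group=group,
                      records=kept,
                      roi_map=dict(roi_map) if roi_map else dict(DEFAULT_ROI_MAP),
                      dropped_rows=dropped)


def _record_to_row(rec: EventRecord) -> dict[str, object]:
    row: dict[str, object] = {}
    for name in FIELD_NAMES:
        v = getattr(rec, name)
        if name == "timestamp":
            v = format_timestamp(v)
        row[name] = v
    return row


def write_session(log: SessionLog, path: str | Path,
                  fmt: str | None = None) -> Path:
    """Serialize a session to CSV or JSON-lines with canonical field names."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", encoding="utf-8", newline="") as fh:
        if fmt == "csv":
            writer = csv.DictWriter(fh, fieldnames=FIELD_NAMES)
            writer.writeheader()
            for rec in log.records:
                row = _record_to_row(rec)
                writer.writerow({k: ("" if v is None else v)
                                 for k, v in row.items()})
        elif fmt == "jsonl":
            for rec in log.records:
                row = {k: v for k, v in _record_to_row(rec).items()
                       if v is not None}
                fh.write(json.dumps(row) + "\n")
        else:
            raise SchemaError(f"unknown format {fmt!r}")
    return path


def merge_player_streams(a: Sequence[EventRecord], b: Sequence[EventRecord],
                         **log_kwargs) -> SessionLog:
    """Merge two single-player streams into one synchronized session.

    No records are lost; relative order within each player is preserved;
    equal timestamps sort P1 before P2.
    """
    for stream, label in ((a, "first"), (b, "second")):
        players = {r.player for r in stream}
        if len(players) > 1:
            raise SchemaError(f"{label} stream mixes players {sorted(players)}")
    pa = {r.player for r in a}
    pb = {r.player for r in b}
    if pa and pa == pb:
        raise SchemaError(f"both streams belong to {pa.pop()}")
    tagged = [(r.timestamp, PLAYERS.index(r.player), i, r)
              for i, r in enumerate(a)]
    tagged += [(r.timestamp, PLAYERS.index(r.player), i, r)
               for i, r in enumerate(b)]
    tagged.sort(key=lambda t: t[:3])
    return SessionLog(records=[t[3] for t in tagged], **log_kwargs)


@dataclass(frozen=True)
class Window:
    """Boolean channel summary of one half-open window [start, start+tick)."""

    player: str
    index: int
    start: float
    speech_present: bool
    controller_active: bool
    gaze_present: bool
    distance_delta: float


def window_session(log: SessionLog, tick: float = 1.0) -> dict[str, list[Window]]:
    """Discretize a session into per-player half-open windows.

    A record at exactly a boundary ``k*tick`` belongs to window ``k``.  The
    distance delta is the signed change of ``object_distance`` from the last
    observation before the window (or the window's first observation when
    there is none) to the last observation inside it; windows with no
    distance observations report 0.
    """
    if tick <= 0:
        raise ValueError("tick must be positive")
    n = max(1, math.ceil(log.length / tick)) if log.length > 0 else 0
    out: dict[str, list[Window]] = {}
    for player in PLAYERS:
        recs = log.player_records(player)
        if recs:
            n = max(n, int(recs[-1].timestamp // tick) + 1)
    for player in PLAYERS:
        buckets: dict[int, list[EventRecord]] = {}
        for rec in log.player_records(player):
            buckets.setdefault(int(rec.timestamp // tick), []).append(rec)
        windows: list[Window] = []
        prev_dist: float | None = None
        for k in range(n):
            group = buckets.get(k, [])
            speech = any(r.transcribed_text for r in group)
            controller = any(r.active_effort == 1 for r in group)
            gaze = any(r.gaze_x is not None or r.gaze_y is not None
                       for r in group)
            dists = [r.object_distance for r in group
                     if r.object_distance is not None]
            if dists:
                base = prev_dist if prev_dist is not None else dists[0]
                delta = dists[-1] - base
                prev_dist = dists[-1]
            else:
                delta = 0.0
            windows.append(Window(player, k, k * tick, speech, controller,
                                  gaze, delta))
        out[player] = windows
    return out
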