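"""Utterance segmentation, initiation counting, and dialogue-act labeling.

Transcribed speech arrives as timestamped word groups per participant.  A
segmenter groups them into utterances using silence detection (default gap
1 s, emulating a streaming speech-to-text service) with a hard 15 s cap on
utterance duration.  An utterance counts as an *initiation* if it opens the
session, follows at least 30 s of silence by either participant, or carries
a topic annotation that differs from the running topic.  No lexical topic
model is attempted: topic judgments in transcripts are human annotations,
and a heuristic would silently diverge from them, so unannotated
transcripts rely on the silence rule alone.

Each utterance receives exactly one of eight dialogue-act labels
(Acks, Neg, Pos, Ques, Read, Inform, Conv, Out) from a deterministic,
transparent rule cascade over editable lexicons — a fully auditable
stand-in for a trained classifier.  Inform is the residual class covering
action directives, descriptions and statements of opinion, which dominate
task-oriented dialogue; Out marks uninterpretable transcription noise and
is excluded from downstream analysis.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .eventlog import PLAYERS, SessionLog

__all__ = [
    "DIALOGUE_ACTS",
    "SILENCE_GAP_S",
    "MAX_UTTERANCE_S",
    "INITIATION_GAP_S",
    "Utterance",
    "segment_utterances",
    "count_initiations",
    "classify_dialogue_act",
    "label_utterances",
    "dialogue_act_frequencies",
    "utterances_from_log",
]

DIALOGUE_ACTS = ("Acks", "Neg", "Pos", "Ques", "Read", "Inform", "Conv", "Out")

SILENCE_GAP_S = 1.0      # inter-word gap that splits utterances
MAX_UTTERANCE_S = 15.0   # hard cap on single-utterance duration
INITIATION_GAP_S = 30.0  # dyad-wide silence that makes the next utterance an initiation


@dataclass
class Utterance:
    player: str
    start: float
    end: float
    text: str
    word_count: int
    is_initiation: bool = False
    topic_id: str | None = None
    label: str | None = None

    @property
    def duration(self) -> float:
        return self.end - self.start


def segment_utterances(words: Sequence[tuple[float, str]],
                       silence_gap: float = SILENCE_GAP_S,
                       max_utterance: float = MAX_UTTERANCE_S, *,
                       player: str = "P1") -> list[Utterance]:
    """Group one player's timestamped words into utterances.

    A new utterance starts when the gap since the previous word reaches
    ``silence_gap``, or when including the word would push the utterance's
    duration past ``max_utterance``.  Every word lands in exactly one
    utterance.
    """
    if silence_gap <= 0:
        raise ValueError("silence_gap must be positive")
    if max_utterance <= 0:
        raise ValueError("max_utterance must be positive")
    utterances: list[Utterance] = []
    cur: list[tuple[float, str]] = []

    def flush() -> None:
        if not cur:
            return
        text = " ".join(w for _, w in cur)
        utterances.append(Utterance(
            player=player, start=cur[0][0], end=cur[-1][0], text=text,
            word_count=max(1, len(re.findall(r"\S+", text)))))

    prev_t: float | None = None
    for t, word in words:
        if prev_t is not None and t < prev_t:
            raise ValueError("words must be time-sorted")
        if cur and (t - prev_t >= silence_gap or t - cur[0][0] > max_utterance):
            flush()
            cur = []
        cur.append((t, word))
        prev_t = t
    flush()
    return utterances


def count_initiations(utterances: Sequence[Utterance],
                      silence_threshold: float = INITIATION_GAP_S
                      ) -> dict[str, int]:
    """Flag initiations in a dyad-wide utterance sequence and count per player.

    The session's first utterance initiates; afterwards an utterance
    initiates iff the silence since the previous utterance by *either*
    player reaches ``silence_threshold``, or its topic annotation differs
    from the running topic.  Flags are written onto the utterances in place.
    """
    ordered = sorted(utterances, key=lambda u: (u.start, u.end))
    counts = {p: 0 for p in PLAYERS}
    prev_end: float | None = None
    topic: str | None = None
    for u in ordered:
        new_topic = u.topic_id is not None and u.topic_id != topic
        u.is_initiation = (prev_end is None
                           or u.start - prev_end >= silence_threshold
                           or new_topic)
        if u.topic_id is not None:
            topic = u.topic_id
        if u.is_initiation:
            counts[u.player] = counts.get(u.player, 0) + 1
        prev_end = u.end if prev_end is None else max(prev_end, u.end)
    return counts


# ---------------------------------------------------------------------------
# Dialogue-act rule cascade.  Rules are evaluated in a fixed order; the first
# match wins, and Inform is the residual class.  Lexicons are module-level so
# deployments can extend them.

CONV_PHRASES = ("thanks", "thank you", "sorry", "my bad", "you're welcome",
                "no problem", "hello", "hi there", "goodbye", "bye")

POS_PHRASES = ("well done", "good job", "great job", "nice job", "nice work",
               "good work", "great work", "nicely done", "awesome", "perfect")

INTERROGATIVES = frozenset((
    "what", "where", "when", "who", "whom", "whose", "why", "how", "which",
    "can", "could", "do", "does", "did", "is", "are", "was", "were", "will",
    "would", "should", "shall", "may", "might", "am", "have", "has",
))

READ_CUES = ("mine says", "it says", "instructions say", "instruction says",
             "the manual says", "manual says", "says to")

NEGATION_TOKENS = frozenset((
    "no", "not", "don't", "dont", "can't", "cant", "won't", "wont", "isn't",
    "isnt", "doesn't", "doesnt", "didn't", "didnt", "never", "nope",
))

NEG_PHRASES = ("oh no", "not sure", "confused")

ACK_PHRASES = frozenset((
    "okay", "ok", "yeah", "yea", "yep", "yup", "yes", "cool", "uh-huh",
    "uh huh", "mhm", "mm-hmm", "sure", "right", "alright", "all right",
    "i know", "you're right", "youre right", "got it", "sounds good",
    "fine", "exactly", "okay cool", "yeah okay",
))

# Function words whose unaccompanied presence marks an unparsable fragment.
_FUNCTION_WORDS = frozenset((
    "the", "a", "an", "it", "and", "or", "but", "then", "so", "of", "to",
    "in", "on", "at", "um", "uh", "er", "hm", "hmm", "oh", "is", "was",
))

# Past-tense reported speech ("it said an end then snow") appears in these
# transcripts only as garbled speech-to-text output; present-tense "says"
# cues remain instruction reading.
_REPORTED_NOISE = re.compile(r"\b(it|he|she|that) said\b")


def _tokens(text: str) -> list[str]:
    return re.findall(r"[a-z']+", text.lower())


def _contains_phrase(text: str, phrase: str) -> bool:
    return re.search(rf"\b{re.escape(phrase)}\b", text) is not None


def classify_dialogue_act(text: str) -> str:
    """Assign exactly one of the eight dialogue-act labels to an utterance."""
    if not isinstance(text, str) or not text.strip():
        raise ValueError("cannot classify empty utterance")
    norm = re.sub(r"\s+", " ", text.lower()).strip()
    toks = _tokens(norm)

    # 1. Conventional pleasantries.
    if any(norm.startswith(p) or _contains_phrase(norm, p)
           for p in CONV_PHRASES):
        return "Conv"
    # 2. Positive feedback to the partner.
    if any(_contains_phrase(norm, p) for p in POS_PHRASES):
        return "Pos"
    # 3. Questions: terminal "?" or interrogative/auxiliary opener.
    if norm.rstrip(".! ").endswith("?") or (toks and toks[0] in INTERROGATIVES):
        return "Ques"
    # 4. Reading task instructions aloud.
    if any(_contains_phrase(norm, c) for c in READ_CUES):
        return "Read"
    # 5. Disagreement / confusion: negation among the first three tokens.
    if any(t in NEGATION_TOKENS for t in toks[:3]) or \
            any(_contains_phrase(norm, p) for p in NEG_PHRASES):
        return "Neg"
    # 6. Short agreement tokens.
    if len(toks) <= 4 and " ".join(toks) in ACK_PHRASES:
        return "Acks"
    # 7. Uninterpretable noise: no alphabetic content, bare function-word
    #    fragments, or garbled reported speech.
    if not toks or all(t in _FUNCTION_WORDS for t in toks) or \
            _REPORTED_NOISE.search(norm):
        return "Out"
    # 8. Residual: descriptions, action directives, opinions.
    return "Inform"


def label_utterances(utterances: Iterable[Utterance]) -> list[Utterance]:
    """Label every utterance in place with its dialogue act."""
    out = list(utterances)
    for u in out:
        u.label = classify_dialogue_act(u.text)
    return out


def dialogue_act_frequencies(utterances: Iterable[Utterance]
                             ) -> dict[str, dict[str, int]]:
    """Per-player counts over all eight classes.

    Out is counted here but excluded from downstream feature extraction.
    """
    freqs: dict[str, dict[str, int]] = {
        p: {a: 0 for a in DIALOGUE_ACTS} for p in PLAYERS}
    for u in utterances:
        if u.label is None:
            raise ValueError(f"utterance at t={u.start} is unlabeled")
        freqs.setdefault(u.player, {a: 0 for a in DIALOGUE_ACTS})
        freqs[u.player][u.label] += 1
    return freqs


def utterances_from_log(log: SessionLog,
                        silence_gap: float = SILENCE_GAP_S,
                        max_utterance: float = MAX_UTTERANCE_S,
                        initiation_gap: float = INITIATION_GAP_S
                        ) -> list[Utterance]:
    """Full speech pass over a session: segment, flag initiations, label."""
    utterances: list[Utterance] = []
    for player in PLAYERS:
        words = [(r.timestamp, r.transcribed_text)
                 for r in log.player_records(player) if r.transcribed_text]
        utterances.extend(segment_utterances(
            words, silence_gap, max_utterance, player=player))
    utterances.sort(key=lambda u: (u.start, u.end))
    count_initiations(utterances, initiation_gap)
    return label_utterances(utterances)
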