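# Methods

## Data model

A session is a single time-sorted stream of per-participant records with up
to 15 fields: elapsed timestamp, player label (P1/P2), transcribed text,
gaze point (x, y) with the name of the focused on-screen object, total and
individual score (percent), piece-at-target / piece-shared /
piece-selected names, a cumulative shared count, a binary active-effort
flag, game duration, and the manipulated object's distance to its target
in scene units.  Timestamps are serialized as `HH:MM:SS[.mmm]`; the clock
dialect accepts whole seconds, but whole-second gaze streams cannot resolve
the 200 ms fixation threshold, so millisecond precision is recommended and
is what the simulator writes.  Parsing and formatting run through integer
milliseconds so the two are exact inverses.

Sorting ties at equal timestamps break P1-before-P2, then original file
order, so golden-file comparisons are deterministic.  Rows failing
validation (malformed timestamp, unknown player, scores outside [0, 100],
non-binary effort flag, a cumulative share count that regresses) are
dropped and counted — never imputed — and a file losing more than half its
rows is rejected as not being a session log.

Windowing is half-open: a record at exactly `k·tick` belongs to window
`k`.  The default tick is 1 s, fine enough for the 30 s feedback timers
while keeping timelines human-readable.  A window's object-distance delta
is taken from the last observation before the window to the last inside
it, so a 2 Hz status channel suffices to sign the movement.

## Behavior classification

The window classifier is the decision cascade described in the README,
total over its 24 input combinations.  Movement is the signed
distance-to-target change with a ±0.05 scene-unit dead band (`ε`), the
only distance signal the schema carries; the dead band absorbs jitter an
order of magnitude below typical drift (0.5 units/s in simulation) without
masking real motion.  Gaze "presence" means any valid gaze sample in the
window regardless of ROI, because the cascade tests attention, not target.
No smoothing is applied by default — hysteresis would shift feedback-timer
onsets — but a width-3 majority filter is available.

## Feedback machine

Dyad states map to machine states by a total priority order: both Engaged
→ Observe; both Struggling → Intervene; exactly one Struggling → Assist
(struggling dominates waiting, because the larger breakdown is addressed
first); otherwise any Waiting → Redirect, with a fully idle dyad treated
as the Redirect row's both-idle branch (its first action is the
help-request prompt).  Prompts require the triggering condition — state
*and* the identity of the triggering participant — to persist 30 s
continuously on the timeline clock; any change resets the timer.  A second
30 s escalates: Redirect issues the help request; Assist and Intervene
automatically complete the current step, after which the machine returns
to Observe with timers cleared.  Positive feedback on step/task completion
is instantaneous (one tick) before returning to Observe.  Prompt texts
live in an editable catalogue keyed by stable template ids, including
role-adapted check-in variants.  The 30 s interval balances autonomy
against support; it is a parameter (`--fsm-wait-s`) everywhere.

## Speech

Segmentation emulates a streaming transcription service: a new utterance
opens when the inter-word gap reaches the silence threshold (default 1.0 s
— the service behavior being emulated documents only the cap, so the gap
is configurable) or when extending would push the duration past 15 s.
An utterance initiates if it is the session's first, follows ≥ 30 s of
silence by *either* participant (the rule names silence, not
partner-specific silence), or carries a topic annotation differing from
the running topic.  No lexical topic model is attempted: topic judgments
in reference transcripts are human annotations, and a heuristic would
silently diverge, so unannotated transcripts rely on the silence rule
alone.

The dialogue-act classifier replaces a trained model with a fixed-order
rule cascade over editable lexicons: Conv pleasantries → Pos praise →
questions (terminal `?` or interrogative/auxiliary opener) → instruction
reading (present-tense "says" cues) → negation within the first three
tokens or confusion phrases → short agreement tokens (≤ 4 tokens in the
acknowledgment lexicon) → uninterpretable noise → Inform as the residual
class (action directives, descriptions, opinions — the dominant class in
task dialogue).  The noise rule needs more than "no alphabetic tokens":
real transcription garbage usually *is* alphabetic.  Two transparent cues
cover it: fragments made only of function words ("The."), and past-tense
reported speech ("it said an end then snow"), which in these transcripts
appears only as garbled recognizer output, while present-tense "it says…"
remains instruction reading.  Cascade order is itself a documented choice:
agreement outranks nothing above it, so "Okay but no" resolves Neg.  Out
utterances are counted but excluded from every downstream feature.

## Gaze

Fixations are maximal runs of same-ROI samples whose first-to-last span
reaches 200 ms.  Detection is dwell-over-labels rather than I-DT/I-VT,
because the tracker has already resolved gaze onto named objects.  One
dropped sample (or ≤ 25 ms of null labels, whichever is larger) inside a
run is bridged — tracker dropout is ubiquitous — while a silent gap over
100 ms or any different ROI breaks the run; all tolerances are parameters,
and strict run-length semantics (used by the brute-force oracle tests) is
one configuration away.  Categories: task (default for unmapped ROIs),
social (the partner-video window — "gaze at partner" is identified with
this window, since the partner is only visible there), and time (timer
bar).  Summaries report fixation counts and dwell, not raw sample counts.

## Dimensions of collaboration

The feature→dimension incidence is frozen (see `DIMENSION_FEATURES`);
everything else is configuration.  Dimension scores are unweighted means
of normalized constituent features; the default normalization is
per-minute rates (invariant to proportionally longer sessions), with
within-cohort z-scores available when comparing across dyads.  No claim is
made that scores are validated psychometric measurements.  For group
statistics both participant-level and dyad-level (summed) exports are
provided, since either unit of analysis is defensible.  Effect sizes
aggregate to dimensions as the arithmetic mean of the absolute Cohen's *d*
of constituent features.

## Statistics

Cohen's *d* uses (n−1)-weighted pooled SD (independent) or the SD of
differences (paired); Hedges' correction is optional and off by default.
Zero variance makes *d* and *t* undefined and raises rather than returning
a fabricated 0/∞.  t-tests and their mean-difference CIs are delegated to
scipy; Benjamini–Hochberg is implemented directly from the step-up
definition and cross-checked in tests against a brute-force oracle and
statsmodels.  (BH is *not* idempotent on general adjusted vectors — e.g.
(0.04, 0.04, 0.45, 0.7) re-adjusts to 0.08 at rank 2 — only tied vectors
are fixed points, and the tests assert exactly that.)

Post hoc power uses the noncentral *t* exactly: paired/one-sample
ncp = d·√n, df = n−1; two equal groups ncp = d·√(n/2), df = 2n−2;
two-sided power sums both rejection tails, so power(d=0) = α.  At very
large df the far tail can underflow to NaN in the numerics and is then
treated as 0, where it is genuinely negligible.  Conventions (two-sided,
α = 0.05, n in dyads) are parameters because published power figures
rarely state software or sidedness: at d = 1.00 with 6 per group the exact
two-sided value is 0.347 (reported elsewhere rounded to 0.35), while at
d = 1.92 with 6 pairs the exact value is 0.959 — comfortably above the
0.80 adequacy threshold, which is the only bound the tests pin, since no
standard convention reproduces a commonly quoted 0.93 exactly.

Linear mixed-effects models and MANOVA are standard fits, exposed only as
thin pass-throughs to statsmodels (`fit_mixed_model`, `fit_manova`); the
bespoke layer of this package is the d/CI/BH/power battery and the
dimension aggregation.

## Simulator

The generator renders scripted state sequences into raw signals by
inverting the classifier: Engaged segments emit 2 Hz controller records
with the distance falling at 0.5 units/s (reset to `drift·duration + 1` at
segment start so the approach never bottoms out), 60 Hz task-directed gaze
with occasional glances at the partner window, and utterances drawn from a
template list as an exponential process at 0.1/s — speech occupies a small
fraction of interaction time, matching observed task dialogue.  Waiting
emits gaze (task + periodic timer-bar glances) without controller input,
or optionally controller input with a stationary object; Struggling emits
controller input with the distance rising (offset by one status interval
so the retreat is visible from the segment's first window), or optionally
total signal absence.  Both alternate renderings exist so every branch of
the classifier is exercised.

Noise defaults: 5% independent gaze-sample dropout (typical tracker loss)
and 0.02-unit Gaussian distance jitter.  The five single-condition presets
(observe/redirect/assist/intervene/positive) are noise-free by design —
they validate exact prompt timing landmarks — while `mixed_session`
carries the default noise.  Ground truth includes the scripted per-window
timelines and the feedback landmarks obtained by running the machine on
those scripted timelines, so recovery tests compare the raw-signal path
against the script path end to end.

What the simulator does **not** emulate: real language (utterances are
templates, so dialogue-act *content* distributions are synthetic),
correlated gaze dropout, saccade dynamics, score trajectories tied to
actual task physics, or human response to prompts (scripts do not react to
feedback).  Passing recovery tests therefore show that the pipeline
inverts this generative model faithfully — boundary windows at segment
transitions are the known, tolerated exception — not that it would
reproduce human annotation on real recordings.

## Problem sizes and numerics

Tests and the acceptance script run sessions of 100–500 s (one to two
dyads, ≤ ~60 k records), chosen as representative desk-scale sizes;
property suites use bounded randomized inputs with fixed seeds
(hypothesis derandomized).  Floating-point guards: fixation spans compare
against the threshold with a 1e-12 slack; acceptance word streams are
constructed on exact decimal grids (`i·3/10`); timestamps round-trip
through integer milliseconds.  Degenerate inputs (empty streams, empty
timelines, zero-length sessions) return empty results rather than raising,
except where a statistic is genuinely undefined.
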