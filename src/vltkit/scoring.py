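"""Scoring of 15-word Verbal Learning Test (VLT) recall transcripts.

The VLT (a Dutch adaptation of the Rey Auditory Verbal Learning Test)
presents a fixed list of 15 unrelated monosyllabic nouns over five
immediate learning trials, followed by an unannounced delayed free-recall
trial and a 30-item yes/no recognition trial (15 targets intermixed with
15 foils).  A recall transcript is an ordered sequence of spoken tokens,
optionally time-stamped with onset seconds; it may originate from a
clinician's annotation ("clinical" rater) or from automatic speech
recognition ("asr" rater).

This module defines the session data model and turns raw transcripts into
:class:`ScoredTrial` objects: every recalled token is classified exactly
once as a first correct recall, a repetition of an already-recalled
target, or an intrusion (a token not on the list).  Matching is exact
after :func:`normalize_token` (case folding, punctuation stripping,
diacritic folding); no fuzzy or phonetic matching is attempted, so any
clinical-vs-ASR divergence is a property of the transcripts, not of the
scorer.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field
from typing import Mapping, Optional

__all__ = [
    "IMMEDIATE_TRIALS",
    "DELAYED_TRIAL",
    "TRIAL_LABELS",
    "WordList",
    "RecallEvent",
    "TrialTranscript",
    "RecognitionProbe",
    "RecognitionResponse",
    "SessionVariant",
    "Session",
    "ScoredTrial",
    "InvalidTokenError",
    "normalize_token",
    "score_trial",
    "score_recognition",
    "score_variant",
]

IMMEDIATE_TRIALS: tuple[str, ...] = ("T1", "T2", "T3", "T4", "T5")
DELAYED_TRIAL: str = "DELAYED"
TRIAL_LABELS: tuple[str, ...] = IMMEDIATE_TRIALS + (DELAYED_TRIAL,)

N_WORDS = 15

_PUNCT_RE = re.compile(r"[^\w\s]", flags=re.UNICODE)


class InvalidTokenError(ValueError):
    """Raised when a token is empty after normalization."""


def normalize_token(raw: str) -> str:
    """Normalize a recalled token for exact matching.

    Lowercases, folds diacritics (NFKD decomposition with combining marks
    removed), strips punctuation and surrounding whitespace.  Deterministic
    and idempotent.

    Raises
    ------
    InvalidTokenError
        If nothing is left after normalization (e.g. ``"??"``).
    """
    if not isinstance(raw, str) or not raw:
        raise InvalidTokenError(f"not a usable token: {raw!r}")
    s = unicodedata.normalize("NFKD", raw)
    s = "".join(ch for ch in s if not unicodedata.combining(ch))
    s = _PUNCT_RE.sub("", s).strip().lower()
    s = re.sub(r"\s+", " ", s)
    if not s:
        raise InvalidTokenError(f"token empty after normalization: {raw!r}")
    return s


@dataclass(frozen=True)
class WordList:
    """A 15-target VLT list with 15 recognition foils.

    Positions are 1-based presentation order (1..15).  Three parallel
    versions of the instrument exist; each is one ``WordList``.
    """

    list_id: str
    targets: tuple[str, ...]
    foils: tuple[str, ...]

    def __post_init__(self) -> None:
        norm_targets = tuple(normalize_token(w) for w in self.targets)
        norm_foils = tuple(normalize_token(w) for w in self.foils)
        if len(norm_targets) != N_WORDS:
            raise ValueError(
                f"word list {self.list_id!r}: expected {N_WORDS} targets, "
                f"got {len(norm_targets)}"
            )
        if len(set(norm_targets)) != N_WORDS:
            raise ValueError(f"word list {self.list_id!r}: duplicate targets after normalization")
        if len(norm_foils) != N_WORDS:
            raise ValueError(
                f"word list {self.list_id!r}: expected {N_WORDS} foils, got {len(norm_foils)}"
            )
        if set(norm_targets) & set(norm_foils):
            raise ValueError(f"word list {self.list_id!r}: foils overlap targets")
        object.__setattr__(self, "targets", norm_targets)
        object.__setattr__(self, "foils", norm_foils)

    @property
    def position_of(self) -> Mapping[str, int]:
        """Map normalized target word -> 1-based list position."""
        return {w: i + 1 for i, w in enumerate(self.targets)}


@dataclass(frozen=True)
class RecallEvent:
    """One spoken token with optional onset time (seconds from trial start)."""

    token: str
    onset_s: Optional[float] = None

    def __post_init__(self) -> None:
        if self.onset_s is not None and self.onset_s < 0:
            raise ValueError(f"negative onset {self.onset_s} for token {self.token!r}")


@dataclass(frozen=True)
class TrialTranscript:
    """Ordered recall events for one trial (T1..T5 or DELAYED)."""

    trial_label: str
    events: tuple[RecallEvent, ...] = ()

    def __post_init__(self) -> None:
        if self.trial_label not in TRIAL_LABELS:
            raise ValueError(
                f"unknown trial_label {self.trial_label!r}; expected one of {TRIAL_LABELS}"
            )
        onsets = [e.onset_s for e in self.events if e.onset_s is not None]
        if any(b < a for a, b in zip(onsets, onsets[1:])):
            raise ValueError(f"trial {self.trial_label}: onsets must be non-decreasing")


@dataclass(frozen=True)
class RecognitionProbe:
    word: str
    is_target: bool
    response_yes: bool


@dataclass(frozen=True)
class RecognitionResponse:
    """The 30-probe yes/no recognition sheet (15 targets + 15 foils)."""

    probes: tuple[RecognitionProbe, ...]

    def __post_init__(self) -> None:
        n_t = sum(p.is_target for p in self.probes)
        n_f = sum(not p.is_target for p in self.probes)
        if (n_t, n_f) != (N_WORDS, N_WORDS):
            raise ValueError(
                f"recognition sheet must have {N_WORDS} targets and {N_WORDS} foils, "
                f"got {n_t} targets / {n_f} foils"
            )


@dataclass(frozen=True)
class SessionVariant:
    """One rater's view of a session.

    Either token-level ``trials`` are present, or (for clinicians who
    recorded only scores) ``counts`` maps trial labels to correct counts;
    in the count-only case only count-level features are computable.
    """

    rater: str
    trials: tuple[TrialTranscript, ...] = ()
    recognition: Optional[RecognitionResponse] = None
    counts: Optional[Mapping[str, int]] = None

    def __post_init__(self) -> None:
        if self.rater not in ("clinical", "asr"):
            raise ValueError(f"rater must be 'clinical' or 'asr', got {self.rater!r}")
        labels = [t.trial_label for t in self.trials]
        if len(labels) != len(set(labels)):
            raise ValueError(f"duplicate trial labels in variant {self.rater!r}: {labels}")
        if not self.trials and self.counts is None:
            raise ValueError(f"variant {self.rater!r} carries neither transcripts nor counts")
        if self.counts is not None:
            for lab, c in self.counts.items():
                if lab not in TRIAL_LABELS:
                    raise ValueError(f"counts: unknown trial label {lab!r}")
                if not (0 <= int(c) <= N_WORDS):
                    raise ValueError(f"counts[{lab!r}] = {c} outside 0..{N_WORDS}")

    @property
    def has_transcripts(self) -> bool:
        return len(self.trials) > 0

    def trial(self, label: str) -> Optional[TrialTranscript]:
        for t in self.trials:
            if t.trial_label == label:
                return t
        return None


@dataclass(frozen=True)
class Session:
    """One participant's full VLT administration, one or two rater variants."""

    participant_id: str
    word_list: WordList
    variants: tuple[SessionVariant, ...]

    def __post_init__(self) -> None:
        if not self.variants:
            raise ValueError(f"session {self.participant_id}: at least one variant required")
        raters = [v.rater for v in self.variants]
        if len(raters) != len(set(raters)):
            raise ValueError(f"session {self.participant_id}: duplicate rater variants {raters}")

    def variant(self, rater: str) -> Optional[SessionVariant]:
        for v in self.variants:
            if v.rater == rater:
                return v
        return None

    def with_variant(self, variant: SessionVariant) -> "Session":
        others = tuple(v for v in self.variants if v.rater != variant.rater)
        return Session(self.participant_id, self.word_list, others + (variant,))


@dataclass(frozen=True)
class ScoredTrial:
    """Result of classifying every event of one trial transcript.

    ``within_10s_count`` is None when any first-correct event lacks an
    onset time (clinician-entered lists); it is never imputed.
    """

    trial_label: str
    correct_set: frozenset[int]
    first_recall_order: tuple[int, ...]
    repetitions: int
    intrusions: int
    within_10s_count: Optional[int]
    n_events: int

    @property
    def correct_count(self) -> int:
        return len(self.correct_set)


def score_trial(transcript: TrialTranscript, word_list: WordList) -> ScoredTrial:
    """Score one trial transcript against the target list.

    Each event is classified exactly once: first correct recall of a
    target, repetition of an already-recalled target, or intrusion.
    ``first_recall_order`` preserves output order of first correct recalls
    as 1-based list positions.
    """
    pos_of = word_list.position_of
    seen: set[int] = set()
    order: list[int] = []
    repetitions = 0
    intrusions = 0
    within_10s = 0
    timing_complete = True
    for ev in transcript.events:
        tok = normalize_token(ev.token)
        pos = pos_of.get(tok)
        if pos is None:
            intrusions += 1
        elif pos in seen:
            repetitions += 1
        else:
            seen.add(pos)
            order.append(pos)
            if ev.onset_s is None:
                timing_complete = False
            elif ev.onset_s <= 10.0:
                within_10s += 1
    return ScoredTrial(
        trial_label=transcript.trial_label,
        correct_set=frozenset(seen),
        first_recall_order=tuple(order),
        repetitions=repetitions,
        intrusions=intrusions,
        within_10s_count=within_10s if timing_complete else None,
        n_events=len(transcript.events),
    )


def score_recognition(resp: RecognitionResponse) -> tuple[int, int]:
    """Count recognition hits: (true positives, false positives).

    True positives are "yes" responses to targets; false positives are
    "yes" responses to foils.  Both lie in [0, 15].
    """
    tp = sum(p.response_yes and p.is_target for p in resp.probes)
    fp = sum(p.response_yes and not p.is_target for p in resp.probes)
    return tp, fp


def score_variant(session: Session, rater: str) -> dict[str, ScoredTrial]:
    """Score every transcript trial of a session variant.

    Returns a map trial_label -> ScoredTrial.  Empty for count-only
    variants (use ``variant.counts`` instead).

    Raises
    ------
    KeyError if the rater variant is absent from the session.
    """
    variant = session.variant(rater)
    if variant is None:
        raise KeyError(f"session {session.participant_id} has no {rater!r} variant")
    return {t.trial_label: score_trial(t, session.word_list) for t in variant.trials}
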