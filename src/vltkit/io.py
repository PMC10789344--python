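"""Session / word-list file formats and run metadata.

Sessions are stored as UTF-8 JSON, one file per session or a list of
session objects, under a versioned schema:

.. code-block:: json

    {
      "schema_version": "1",
      "participant_id": "P0001",
      "word_list_id": "synthetic-nl-a",
      "variants": [
        {
          "rater": "clinical",
          "trials": [
            {"trial_label": "T1",
             "events": [{"token": "boot", "onset_s": 1.4}, ...]},
            ...
          ],
          "recognition": {
            "probes": [{"word": "boot", "is_target": true, "response": true}, ...]
          }
        },
        {"rater": "asr", ...}
      ]
    }

A clinical variant may instead carry ``"counts": {"T1": 5, ...}`` when
only scores were recorded.  Word lists live in a JSON (or YAML) config
``{"lists": [{"list_id": ..., "targets": [15 words], "foils": [15 words]}]}``.
Validation errors name the offending field.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import yaml

from .scoring import (
    RecallEvent,
    RecognitionProbe,
    RecognitionResponse,
    Session,
    SessionVariant,
    TrialTranscript,
    WordList,
)

__all__ = [
    "SCHEMA_VERSION",
    "SessionFormatError",
    "load_wordlists",
    "load_bundled_wordlists",
    "read_sessions",
    "write_sessions",
    "session_to_dict",
    "session_from_dict",
]

SCHEMA_VERSION = "1"


class SessionFormatError(ValueError):
    """Session JSON does not conform to the schema; message names the field."""


def _require(obj: Mapping, key: str, where: str):
    if key not in obj:
        raise SessionFormatError(f"{where}: missing required field {key!r}")
    return obj[key]


# ---------------------------------------------------------------------------
# word lists


def _parse_wordlist(entry: Mapping, where: str) -> WordList:
    list_id = _require(entry, "list_id", where)
    targets = _require(entry, "targets", where)
    foils = _require(entry, "foils", where)
    try:
        return WordList(list_id=str(list_id), targets=tuple(targets), foils=tuple(foils))
    except ValueError as exc:
        raise SessionFormatError(f"{where}: {exc}") from exc


def load_wordlists(path: str | Path) -> list[WordList]:
    """Load word lists from a JSON or YAML config file."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    data = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
    lists = _require(data, "lists", str(path))
    return [_parse_wordlist(e, f"{path} lists[{i}]") for i, e in enumerate(lists)]


def load_bundled_wordlists() -> list[WordList]:
    """The three synthetic Dutch-style 15-word lists shipped with the package.

    The clinical instrument's proprietary lists are not redistributable;
    these stand-ins preserve the structure (15 unique monosyllabic-style
    targets + 15 disjoint foils, three parallel versions) only.
    """
    with resources.files("vltkit.data").joinpath("wordlists.json").open(
        "r", encoding="utf-8"
    ) as fh:
        data = json.load(fh)
    return [
        _parse_wordlist(e, f"bundled lists[{i}]") for i, e in enumerate(data["lists"])
    ]


# ---------------------------------------------------------------------------
# sessions


def session_to_dict(session: Session) -> dict:
    """Serialize a Session to the versioned JSON structure."""
    variants = []
    for v in session.variants:
        d: dict = {"rater": v.rater}
        if v.has_transcripts:
            d["trials"] = [
                {
                    "trial_label": t.trial_label,
                    "events": [
                        {"token": e.token, "onset_s": e.onset_s} for e in t.events
                    ],
                }
                for t in v.trials
            ]
        if v.counts is not None:
            d["counts"] = dict(v.counts)
        if v.recognition is not None:
            d["recognition"] = {
                "probes": [
                    {"word": p.word, "is_target": p.is_target, "response": p.response_yes}
                    for p in v.recognition.probes
                ]
            }
        variants.append(d)
    return {
        "schema_version": SCHEMA_VERSION,
        "participant_id": session.participant_id,
        "word_list_id": session.word_list.list_id,
        "variants": variants,
    }


def session_from_dict(data: Mapping, word_lists: Sequence[WordList]) -> Session:
    """Parse and validate one session object against the schema."""
    where = "session"
    version = _require(data, "schema_version", where)
    if str(version) != SCHEMA_VERSION:
        raise SessionFormatError(
            f"{where}: unsupported schema_version {version!r} (expected {SCHEMA_VERSION!r})"
        )
    pid = str(_require(data, "participant_id", where))
    where = f"session {pid}"
    wl_id = _require(data, "word_list_id", where)
    by_id = {wl.list_id: wl for wl in word_lists}
    if wl_id not in by_id:
        raise SessionFormatError(
            f"{where}: word_list_id {wl_id!r} not among loaded lists {sorted(by_id)}"
        )
    raw_variants = _require(data, "variants", where)
    if not raw_variants:
        raise SessionFormatError(f"{where}: variants must be non-empty")

    variants = []
    for vi, rv in enumerate(raw_variants):
        vwhere = f"{where} variants[{vi}]"
        rater = _require(rv, "rater", vwhere)
        trials = []
        for ti, rt in enumerate(rv.get("trials", [])):
            twhere = f"{vwhere} trials[{ti}]"
            label = _require(rt, "trial_label", twhere)
            events = []
            for ei, re_ in enumerate(rt.get("events", [])):
                token = _require(re_, "token", f"{twhere} events[{ei}]")
                onset = re_.get("onset_s")
                try:
                    events.append(
                        RecallEvent(token=str(token), onset_s=None if onset is None else float(onset))
                    )
                except ValueError as exc:
                    raise SessionFormatError(f"{twhere} events[{ei}]: {exc}") from exc
            try:
                trials.append(TrialTranscript(trial_label=str(label), events=tuple(events)))
            except ValueError as exc:
                raise SessionFormatError(f"{twhere}: {exc}") from exc
        recognition = None
        if rv.get("recognition") is not None:
            probes = []
            for pi_, rp in enumerate(_require(rv["recognition"], "probes", f"{vwhere} recognition")):
                pwhere = f"{vwhere} recognition probes[{pi_}]"
                probes.append(
                    RecognitionProbe(
                        word=str(_require(rp, "word", pwhere)),
                        is_target=bool(_require(rp, "is_target", pwhere)),
                        response_yes=bool(_require(rp, "response", pwhere)),
                    )
                )
            try:
                recognition = RecognitionResponse(probes=tuple(probes))
            except ValueError as exc:
                raise SessionFormatError(f"{vwhere} recognition: {exc}") from exc
        try:
            variants.append(
                SessionVariant(
                    rater=str(rater),
                    trials=tuple(trials),
                    recognition=recognition,
                    counts=rv.get("counts"),
                )
            )
        except ValueError as exc:
            raise SessionFormatError(f"{vwhere}: {exc}") from exc
    try:
        return Session(participant_id=pid, word_list=by_id[wl_id], variants=tuple(variants))
    except ValueError as exc:
        raise SessionFormatError(f"{where}: {exc}") from exc


def read_sessions(path: str | Path, word_lists: Sequence[WordList]) -> list[Session]:
    """Read one or many sessions from a JSON file (object or list)."""
    path = Path(path)
    data = json.loads(path.read_text(encoding="utf-8"))
    items = data if isinstance(data, list) else [data]
    return [session_from_dict(d, word_lists) for d in items]


def write_sessions(sessions: Iterable[Session], path: str | Path) -> None:
    """Write sessions to a UTF-8 JSON file (list of session objects)."""
    path = Path(path)
    payload = [session_to_dict(s) for s in sessions]
    path.write_text(
        json.dumps(payload if len(payload) != 1 else payload[0], indent=1, ensure_ascii=False),
        encoding="utf-8",
    )
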