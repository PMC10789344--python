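import numpy as np
import pandas as pd
import pytest

from vltkit.cohort import calibrate_defaults, simulate_cohort
from vltkit.features import build_feature_table
from vltkit.scoring import (
    RecallEvent,
    RecognitionProbe,
    RecognitionResponse,
    TrialTranscript,
    WordList,
)


@pytest.fixture(scope="session")
def toy_list() -> WordList:
    targets = [
        "boot", "zon", "kat", "brood", "stoel", "muur", "vis", "lamp",
        "boek", "touw", "kaas", "berg", "hond", "raam", "zout",
    ]
    foils = [
        "deur", "tuin", "melk", "schoen", "bril", "klok", "mes", "jas",
        "bloem", "trein", "glas", "steen", "vuur", "zand", "bed",
    ]
    return WordList(list_id="toy", targets=tuple(targets), foils=tuple(foils))


def make_trial(label, tokens, onsets=None):
    if onsets is None:
        onsets = [None] * len(tokens)
    return TrialTranscript(
        trial_label=label,
        events=tuple(RecallEvent(token=t, onset_s=o) for t, o in zip(tokens, onsets)),
    )


def make_recognition(target_yes, foil_yes, word_list):
    probes = []
    for i, w in enumerate(word_list.targets):
        probes.append(RecognitionProbe(word=w, is_target=True, response_yes=i < target_yes))
    for i, w in enumerate(word_list.foils):
        probes.append(RecognitionProbe(word=w, is_target=False, response_yes=i < foil_yes))
    return RecognitionResponse(probes=tuple(probes))


@pytest.fixture(scope="session")
def default_cohort():
    """Paper-sized cohort (69 SCD, 56 MCI, 13 dementia) at the shipped defaults."""
    sessions, metadata = simulate_cohort(calibrate_defaults(seed=20240102))
    return sessions, metadata


@pytest.fixture(scope="session")
def default_feature_tables(default_cohort):
    sessions, metadata = default_cohort
    return {
        "asr": build_feature_table(sessions, "asr"),
        "clinical": build_feature_table(sessions, "clinical"),
        "metadata": metadata,
    }
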