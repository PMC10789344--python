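"""Process-score feature catalog for scored VLT sessions.

Beyond the three clinical totals (total immediate recall, delayed recall,
recognition count) a word-list learning session carries rich process
information: serial-position effects (primacy / midlist / recency),
learning slopes across the five immediate trials, trial-to-trial recall
consistency (constancy learning index, gained/lost access, savings),
output organization (serial clustering, subjective organization as
chance-corrected pair frequency), and recall timing (words produced in
the first 10 seconds of a trial).  This module computes the full named
catalog from a scored session and assembles per-cohort feature tables.

Missing-data contract: any feature whose inputs are unavailable (e.g.
token-level features for a count-only clinical variant, timing features
without onsets) is reported as NaN, never zero-filled.  Downstream
imputation is an explicit classifier-side step.

Feature definitions
-------------------
overall/early/late learning slope
    Least-squares slope of correct count against trial index over trials
    1–5, 1–3 and 3–5 respectively.
peak_learning_slope
    Largest single-trial gain max_t (c_{t+1} - c_t).
constancy_learning_index
    sum_t |C_t ∩ C_{t+1}| / sum_t |C_t| over consecutive immediate
    trials; 1.0 when recall sets are perfectly stable.
savings
    delayed_recall / trial-5 recall (consolidation; NaN when c5 = 0).
serial_clusters_trial_t
    Number of adjacent output pairs whose list positions are consecutive
    in presentation order (forward chaining by default).
subjective_organization_trial_t  (pair frequency, PF)
    O - 2c(c-1)/(h*k) for trials t, t+1, where O counts unordered word
    pairs output adjacently in both trials (either order), h and k are
    the two recall counts and c the common-item count; the subtracted
    term is the expected O under random output order, so PF has mean ~0
    under chance organization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .scoring import (
    DELAYED_TRIAL,
    IMMEDIATE_TRIALS,
    N_WORDS,
    ScoredTrial,
    Session,
    score_recognition,
    score_variant,
)

__all__ = [
    "SerialRegions",
    "FeatureVector",
    "compute_count_features",
    "compute_serial_position_features",
    "compute_slope_features",
    "compute_consistency_features",
    "compute_organization_features",
    "compute_features",
    "build_feature_table",
    "feature_catalog",
    "least_squares_slope",
    "pair_frequency",
    "serial_cluster_count",
]

NaN = float("nan")


@dataclass(frozen=True)
class SerialRegions:
    """Serial-position regions partitioning list positions 1..15.

    Defaults follow the standard 15-item RAVLT process-score convention:
    primacy 1–4, midlist 5–11, recency 12–15.
    """

    primacy: frozenset[int] = frozenset(range(1, 5))
    midlist: frozenset[int] = frozenset(range(5, 12))
    recency: frozenset[int] = frozenset(range(12, 16))

    def __post_init__(self) -> None:
        all_pos = set(self.primacy) | set(self.midlist) | set(self.recency)
        n = len(self.primacy) + len(self.midlist) + len(self.recency)
        if all_pos != set(range(1, N_WORDS + 1)) or n != N_WORDS:
            raise ValueError("regions must be disjoint and partition positions 1..15")
        object.__setattr__(self, "primacy", frozenset(self.primacy))
        object.__setattr__(self, "midlist", frozenset(self.midlist))
        object.__setattr__(self, "recency", frozenset(self.recency))

    def items(self) -> Iterable[tuple[str, frozenset[int]]]:
        yield "primacy", self.primacy
        yield "midlist", self.midlist
        yield "recency", self.recency


@dataclass
class FeatureVector:
    """Named process-score features for one session variant."""

    participant_id: str
    rater: str
    values: dict[str, float] = field(default_factory=dict)

    @property
    def missing_mask(self) -> dict[str, bool]:
        return {k: isinstance(v, float) and math.isnan(v) for k, v in self.values.items()}

    def to_series(self) -> pd.Series:
        s = pd.Series(self.values, dtype=float)
        s.name = self.participant_id
        return s


# ---------------------------------------------------------------------------
# helpers


def least_squares_slope(x: Sequence[float], y: Sequence[float]) -> float:
    """Closed-form least-squares slope: sum((x-x̄)(y-ȳ)) / sum((x-x̄)²)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    denom = float(np.sum(xc * xc))
    if denom == 0.0:
        return NaN
    return float(np.sum(xc * (y - y.mean())) / denom)


def serial_cluster_count(order: Sequence[int], bidirectional: bool = False) -> int:
    """Count adjacent output pairs in consecutive list order.

    ``order`` is a first-recall order of 1-based list positions.  A pair
    (a, b) of successive outputs is a serial cluster when b = a + 1
    (forward chaining); with ``bidirectional`` also when b = a - 1.
    """
    n = 0
    for a, b in zip(order, order[1:]):
        if b == a + 1 or (bidirectional and b == a - 1):
            n += 1
    return n


def _adjacent_pairs(order: Sequence[int]) -> set[frozenset[int]]:
    return {frozenset((a, b)) for a, b in zip(order, order[1:]) if a != b}


def pair_frequency(order_1: Sequence[int], order_2: Sequence[int]) -> float:
    """Chance-corrected subjective organization PF between two trials.

    PF = O - 2c(c-1)/(h*k) with O the number of unordered item pairs
    recalled adjacently in both trials (either order), h = |trial 1
    recall|, k = |trial 2 recall|, c = common items.  NaN when h*k = 0.
    """
    h, k = len(order_1), len(order_2)
    if h == 0 or k == 0:
        return NaN
    c = len(set(order_1) & set(order_2))
    observed = len(_adjacent_pairs(order_1) & _adjacent_pairs(order_2))
    expected = 2.0 * c * (c - 1) / (h * k)
    return observed - expected


def _counts_by_trial(session: Session, rater: str) -> dict[str, float]:
    """Per-trial correct counts from transcripts or the count-only fallback."""
    variant = session.variant(rater)
    if variant is None:
        raise KeyError(f"session {session.participant_id} has no {rater!r} variant")
    out: dict[str, float] = {}
    if variant.has_transcripts:
        for lab, st in score_variant(session, rater).items():
            out[lab] = float(st.correct_count)
    elif variant.counts is not None:
        out = {lab: float(c) for lab, c in variant.counts.items()}
    return out


# ---------------------------------------------------------------------------
# feature operations


def compute_count_features(session: Session, rater: str) -> dict[str, float]:
    """Count-level features: per-trial counts, totals, recognition,
    repetitions, intrusions and first-10-seconds counts.

    Works for count-only clinical variants (token-level entries NaN).
    """
    variant = session.variant(rater)
    if variant is None:
        raise KeyError(f"session {session.participant_id} has no {rater!r} variant")
    counts = _counts_by_trial(session, rater)
    scored = score_variant(session, rater) if variant.has_transcripts else {}

    f: dict[str, float] = {}
    for i, lab in enumerate(IMMEDIATE_TRIALS, start=1):
        f[f"immediate_count_trial_{i}"] = counts.get(lab, NaN)
    imm = [f[f"immediate_count_trial_{i}"] for i in range(1, 6)]
    f["total_immediate_recall"] = sum(imm) if not any(math.isnan(v) for v in imm) else NaN
    f["delayed_recall"] = counts.get(DELAYED_TRIAL, NaN)

    if variant.recognition is not None:
        tp, fp = score_recognition(variant.recognition)
        f["recognition_true_positives"] = float(tp)
        f["recognition_false_positives"] = float(fp)
    else:
        f["recognition_true_positives"] = NaN
        f["recognition_false_positives"] = NaN

    def per_trial(name: str, getter) -> None:
        vals = []
        for i, lab in enumerate(IMMEDIATE_TRIALS, start=1):
            st = scored.get(lab)
            v = getter(st) if st is not None else NaN
            v = NaN if v is None else float(v)
            f[f"{name}_trial_{i}"] = v
            vals.append(v)
        st = scored.get(DELAYED_TRIAL)
        v = getter(st) if st is not None else NaN
        f[f"{name}_delayed"] = NaN if v is None else float(v)
        f[f"total_{name}"] = sum(vals) if not any(math.isnan(v) for v in vals) else NaN

    per_trial("repetitions", lambda st: st.repetitions)
    per_trial("intrusions", lambda st: st.intrusions)
    per_trial("within_10s_count", lambda st: st.within_10s_count)
    if not math.isnan(f["total_within_10s_count"]) and f["total_immediate_recall"] > 0:
        f["within_10s_fraction"] = f["total_within_10s_count"] / f["total_immediate_recall"]
    else:
        f["within_10s_fraction"] = NaN
    return f


def compute_serial_position_features(
    session: Session, rater: str, regions: SerialRegions | None = None
) -> dict[str, float]:
    """Region (primacy/midlist/recency) recall counts and proportions.

    Requires token-level transcripts; all-NaN for count-only variants.
    Naming follows the instrument's reporting convention, e.g.
    ``immediate_midlist_items_trial_3``, ``immediate_total_midlist_items``,
    ``delayed_recall_recency_items``.
    """
    regions = regions or SerialRegions()
    variant = session.variant(rater)
    if variant is None:
        raise KeyError(f"session {session.participant_id} has no {rater!r} variant")
    scored = score_variant(session, rater) if variant.has_transcripts else {}

    f: dict[str, float] = {}
    for rname, rset in regions.items():
        total = 0.0
        have_all = True
        for i, lab in enumerate(IMMEDIATE_TRIALS, start=1):
            st = scored.get(lab)
            if st is None:
                f[f"immediate_{rname}_items_trial_{i}"] = NaN
                f[f"immediate_{rname}_proportion_trial_{i}"] = NaN
                have_all = False
                continue
            n = len(st.correct_set & rset)
            f[f"immediate_{rname}_items_trial_{i}"] = float(n)
            f[f"immediate_{rname}_proportion_trial_{i}"] = n / len(rset)
            total += n
        f[f"immediate_total_{rname}_items"] = total if have_all else NaN
        f[f"immediate_total_{rname}_proportion"] = (
            total / (5 * len(rset)) if have_all else NaN
        )
        std = scored.get(DELAYED_TRIAL)
        if std is None:
            f[f"delayed_recall_{rname}_items"] = NaN
            f[f"delayed_recall_{rname}_proportion"] = NaN
        else:
            n = len(std.correct_set & rset)
            f[f"delayed_recall_{rname}_items"] = float(n)
            f[f"delayed_recall_{rname}_proportion"] = n / len(rset)
    return f


def compute_slope_features(counts: Sequence[float]) -> dict[str, float]:
    """Learning-slope features from the five immediate correct counts.

    All slope features are NaN if any of the five counts is missing.
    """
    counts = [float(c) for c in counts]
    if len(counts) != 5:
        raise ValueError(f"expected 5 immediate counts, got {len(counts)}")
    if any(math.isnan(c) for c in counts):
        return {
            "overall_learning_slope": NaN,
            "early_learning_slope": NaN,
            "late_learning_slope": NaN,
            "peak_learning_slope": NaN,
            "simple_gain": NaN,
        }
    return {
        "overall_learning_slope": least_squares_slope([1, 2, 3, 4, 5], counts),
        "early_learning_slope": least_squares_slope([1, 2, 3], counts[:3]),
        "late_learning_slope": least_squares_slope([3, 4, 5], counts[2:]),
        "peak_learning_slope": max(b - a for a, b in zip(counts, counts[1:])),
        "simple_gain": counts[4] - counts[0],
    }


def compute_consistency_features(
    scored: Mapping[str, ScoredTrial]
) -> dict[str, float]:
    """Trial-to-trial consistency: constancy index, gained/lost access, savings."""
    f: dict[str, float] = {}
    sets: list[Optional[frozenset[int]]] = [
        scored[lab].correct_set if lab in scored else None for lab in IMMEDIATE_TRIALS
    ]
    have_all = all(s is not None for s in sets)

    overlap_num = 0.0
    overlap_den = 0.0
    total_gained = 0.0
    total_lost = 0.0
    for t in range(4):
        a, b = sets[t], sets[t + 1]
        if a is None or b is None:
            f[f"gained_trial_{t + 1}_to_{t + 2}"] = NaN
            f[f"lost_trial_{t + 1}_to_{t + 2}"] = NaN
            continue
        f[f"gained_trial_{t + 1}_to_{t + 2}"] = float(len(b - a))
        f[f"lost_trial_{t + 1}_to_{t + 2}"] = float(len(a - b))
        overlap_num += len(a & b)
        overlap_den += len(a)
        total_gained += len(b - a)
        total_lost += len(a - b)
    if have_all:
        f["total_gained"] = total_gained
        f["total_lost"] = total_lost
        f["constancy_learning_index"] = overlap_num / overlap_den if overlap_den > 0 else NaN
    else:
        f["total_gained"] = NaN
        f["total_lost"] = NaN
        f["constancy_learning_index"] = NaN

    t5 = scored.get(IMMEDIATE_TRIALS[-1])
    dl = scored.get(DELAYED_TRIAL)
    if t5 is not None and dl is not None and t5.correct_count > 0:
        f["savings"] = dl.correct_count / t5.correct_count
    else:
        f["savings"] = NaN
    return f


def compute_organization_features(
    scored: Mapping[str, ScoredTrial], bidirectional_clusters: bool = False
) -> dict[str, float]:
    """Output-order organization: serial clustering and pair-frequency SO."""
    f: dict[str, float] = {}
    total_sc = 0.0
    have_all = True
    for i, lab in enumerate(IMMEDIATE_TRIALS, start=1):
        st = scored.get(lab)
        if st is None:
            f[f"serial_clusters_trial_{i}"] = NaN
            have_all = False
            continue
        sc = serial_cluster_count(st.first_recall_order, bidirectional_clusters)
        f[f"serial_clusters_trial_{i}"] = float(sc)
        total_sc += sc
    f["total_serial_clusters"] = total_sc if have_all else NaN

    total_pf = 0.0
    pf_ok = True
    for t in range(4):
        a = scored.get(IMMEDIATE_TRIALS[t])
        b = scored.get(IMMEDIATE_TRIALS[t + 1])
        if a is None or b is None:
            pf = NaN
        else:
            pf = pair_frequency(a.first_recall_order, b.first_recall_order)
        f[f"subjective_organization_trial_{t + 1}_to_{t + 2}"] = pf
        if math.isnan(pf):
            pf_ok = False
        else:
            total_pf += pf
    f["total_subjective_organization"] = total_pf if pf_ok else NaN
    return f


def compute_features(
    session: Session,
    rater: str,
    regions: SerialRegions | None = None,
    bidirectional_clusters: bool = False,
) -> FeatureVector:
    """Compute the full feature catalog for one session variant."""
    variant = session.variant(rater)
    if variant is None:
        raise KeyError(f"session {session.participant_id} has no {rater!r} variant")
    values = compute_count_features(session, rater)
    values.update(compute_serial_position_features(session, rater, regions))
    values.update(
        compute_slope_features([values[f"immediate_count_trial_{i}"] for i in range(1, 6)])
    )
    scored = score_variant(session, rater) if variant.has_transcripts else {}
    values.update(compute_consistency_features(scored))
    values.update(compute_organization_features(scored, bidirectional_clusters))
    # fixed catalog order
    ordered = {name: values[name] for name in feature_catalog()}
    return FeatureVector(session.participant_id, rater, ordered)


def feature_catalog() -> tuple[str, ...]:
    """Stable ordering of every named feature in the catalog."""
    names: list[str] = []
    names += [f"immediate_count_trial_{i}" for i in range(1, 6)]
    names += ["total_immediate_recall", "delayed_recall"]
    names += ["recognition_true_positives", "recognition_false_positives"]
    for base in ("repetitions", "intrusions", "within_10s_count"):
        names += [f"{base}_trial_{i}" for i in range(1, 6)]
        names += [f"{base}_delayed", f"total_{base}"]
    names += ["within_10s_fraction"]
    for rname in ("primacy", "midlist", "recency"):
        names += [f"immediate_{rname}_items_trial_{i}" for i in range(1, 6)]
        names += [f"immediate_{rname}_proportion_trial_{i}" for i in range(1, 6)]
        names += [
            f"immediate_total_{rname}_items",
            f"immediate_total_{rname}_proportion",
            f"delayed_recall_{rname}_items",
            f"delayed_recall_{rname}_proportion",
        ]
    names += [
        "overall_learning_slope",
        "early_learning_slope",
        "late_learning_slope",
        "peak_learning_slope",
        "simple_gain",
    ]
    names += [f"gained_trial_{t}_to_{t + 1}" for t in range(1, 5)]
    names += [f"lost_trial_{t}_to_{t + 1}" for t in range(1, 5)]
    names += ["total_gained", "total_lost", "constancy_learning_index", "savings"]
    names += [f"serial_clusters_trial_{i}" for i in range(1, 6)]
    names += ["total_serial_clusters"]
    names += [f"subjective_organization_trial_{t}_to_{t + 1}" for t in range(1, 5)]
    names += ["total_subjective_organization"]
    return tuple(names)


def build_feature_table(
    sessions: Iterable[Session],
    rater: str,
    regions: SerialRegions | None = None,
    metadata: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Assemble a participants × features table for one rater.

    Columns follow :func:`feature_catalog`; ``metadata`` (indexed by
    participant_id) is joined on the left when given.  Duplicate
    participant ids raise.
    """
    rows = []
    ids = []
    for s in sessions:
        fv = compute_features(s, rater, regions)
        if s.participant_id in ids:
            raise ValueError(f"duplicate participant_id {s.participant_id!r}")
        ids.append(s.participant_id)
        rows.append(fv.to_series())
    if not rows:
        raise ValueError("no sessions given")
    table = pd.DataFrame(rows)
    table.index.name = "participant_id"
    if metadata is not None:
        table = metadata.join(table, how="right")
        table.index.name = "participant_id"
    return table


def feature_dictionary() -> dict[str, dict[str, str]]:
    """Sidecar data dictionary: feature name -> description and range."""
    d: dict[str, dict[str, str]] = {}
    for name in feature_catalog():
        if name.startswith("immediate_count"):
            desc, rng = "correct words on an immediate learning trial", "0..15"
        elif name == "total_immediate_recall":
            desc, rng = "sum of correct words over trials 1-5", "0..75"
        elif name == "delayed_recall":
            desc, rng = "correct words at the delayed free-recall trial", "0..15"
        elif "recognition" in name:
            desc, rng = "yes responses on the 30-probe recognition sheet", "0..15"
        elif "slope" in name or name == "simple_gain":
            desc, rng = "learning-curve slope/gain across immediate trials", "-14..14"
        elif "subjective_organization" in name:
            desc, rng = "chance-corrected pair-frequency organization", "unbounded"
        elif "serial_clusters" in name:
            desc, rng = "adjacent outputs in consecutive list order", "0..14 per trial"
        elif name == "constancy_learning_index":
            desc, rng = "consecutive-trial recall-set overlap ratio", "0..1"
        elif name == "savings":
            desc, rng = "delayed recall / trial-5 recall", "0..~2"
        elif "proportion" in name or "fraction" in name:
            desc, rng = "region/timing count as a proportion", "0..1"
        elif "within_10s" in name:
            desc, rng = "first-correct recalls with onset <= 10 s", "0..15 per trial"
        elif "gained" in name or "lost" in name:
            desc, rng = "items gained/lost between consecutive trials", "0..15"
        elif "repetitions" in name or "intrusions" in name:
            desc, rng = "re-recalls of recalled targets / off-list tokens", ">=0"
        else:
            desc, rng = "serial-position region recall count", "0..region size"
        d[name] = {"description": desc, "range": rng}
    return d
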