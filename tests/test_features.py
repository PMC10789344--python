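"""Process-score feature catalog: counts, regions, slopes, consistency,
organization, and the feature-table assembly."""

import math

import numpy as np
import pytest

from vltkit.features import (
    SerialRegions,
    build_feature_table,
    compute_consistency_features,
    compute_count_features,
    compute_features,
    compute_organization_features,
    compute_serial_position_features,
    compute_slope_features,
    feature_catalog,
    least_squares_slope,
    pair_frequency,
    serial_cluster_count,
)
from vltkit.scoring import ScoredTrial, Session, SessionVariant

from .conftest import make_recognition, make_trial


def _session(toy_list, trials, rater="clinical", recognition=None, counts=None):
    variant = SessionVariant(
        rater=rater, trials=tuple(trials), recognition=recognition, counts=counts
    )
    return Session(participant_id="p1", word_list=toy_list, variants=(variant,))


def _scored(label, order, total_events=None):
    order = tuple(order)
    return ScoredTrial(
        trial_label=label,
        correct_set=frozenset(order),
        first_recall_order=order,
        repetitions=0,
        intrusions=0,
        within_10s_count=None,
        n_events=total_events or len(order),
    )


class TestCountFeatures:
    def test_all_trials_empty(self, toy_list):
        trials = [make_trial(lab, []) for lab in ("T1", "T2", "T3", "T4", "T5")]
        f = compute_count_features(_session(toy_list, trials), "clinical")
        assert f["total_immediate_recall"] == 0

    def test_count_only_variant_summation(self, toy_list):
        counts = {"T1": 5, "T2": 7, "T3": 8, "T4": 9, "T5": 10, "DELAYED": 8}
        f = compute_count_features(_session(toy_list, [], counts=counts), "clinical")
        assert f["total_immediate_recall"] == 39
        assert f["delayed_recall"] == 8
        # token-level features unavailable -> missing, never zero
        assert math.isnan(f["repetitions_trial_1"])

    def test_consistent_with_trial_scoring(self, toy_list):
        trials = [
            make_trial("T1", ["kat", "kat", "xyz", "boot"]),
            *[make_trial(lab, ["zon"]) for lab in ("T2", "T3", "T4", "T5")],
        ]
        f = compute_count_features(
            _session(toy_list, trials, recognition=make_recognition(12, 2, toy_list)),
            "clinical",
        )
        assert f["immediate_count_trial_1"] == 2
        assert f["total_immediate_recall"] == 6
        assert f["repetitions_trial_1"] == 1
        assert f["intrusions_trial_1"] == 1
        assert f["recognition_true_positives"] == 12
        assert f["recognition_false_positives"] == 2


class TestSerialPositionFeatures:
    def test_hand_intersections(self, toy_list):
        # recall positions {1,2,8,15}: primacy 2, midlist 1, recency 1
        tokens = [toy_list.targets[p - 1] for p in (1, 2, 8, 15)]
        trials = [make_trial("T1", tokens)]
        f = compute_serial_position_features(_session(toy_list, trials), "clinical")
        assert f["immediate_primacy_items_trial_1"] == 2
        assert f["immediate_midlist_items_trial_1"] == 1
        assert f["immediate_recency_items_trial_1"] == 1
        assert f["immediate_midlist_proportion_trial_1"] == pytest.approx(1 / 7)

    def test_full_recall_saturates_midlist(self, toy_list):
        trials = [make_trial("T3", list(toy_list.targets))]
        f = compute_serial_position_features(_session(toy_list, trials), "clinical")
        assert f["immediate_midlist_items_trial_3"] == 7

    def test_empty_recall_zero_regions(self, toy_list):
        f = compute_serial_position_features(
            _session(toy_list, [make_trial("T2", [])]), "clinical"
        )
        for r in ("primacy", "midlist", "recency"):
            assert f[f"immediate_{r}_items_trial_2"] == 0

    def test_count_only_variant_gives_missing(self, toy_list):
        f = compute_serial_position_features(
            _session(toy_list, [], counts={"T1": 5}), "clinical"
        )
        assert math.isnan(f["immediate_midlist_items_trial_1"])

    def test_region_partition_enforced(self):
        with pytest.raises(ValueError, match="partition"):
            SerialRegions(primacy=frozenset({1, 2}), midlist=frozenset({2, 3}),
                          recency=frozenset(range(4, 16)))


class TestSlopeFeatures:
    def test_exact_linear_counts(self):
        f = compute_slope_features([3, 5, 7, 9, 11])
        assert f["overall_learning_slope"] == pytest.approx(2.0)
        assert f["peak_learning_slope"] == 2
        assert f["simple_gain"] == 8

    def test_constant_counts(self):
        f = compute_slope_features([5, 5, 5, 5, 5])
        for k in ("overall_learning_slope", "early_learning_slope", "late_learning_slope"):
            assert f[k] == 0

    def test_against_normal_equations_oracle(self):
        counts = [2, 6, 7, 7, 10]
        t = np.array([1, 2, 3, 4, 5], dtype=float)

        def ls_slope(x, y):
            x, y = np.asarray(x, float), np.asarray(y, float)
            a = np.vstack([x, np.ones_like(x)]).T
            return float(np.linalg.solve(a.T @ a, a.T @ y)[0])

        f = compute_slope_features(counts)
        assert f["overall_learning_slope"] == pytest.approx(ls_slope(t, counts), abs=1e-12)
        assert f["early_learning_slope"] == pytest.approx(ls_slope(t[:3], counts[:3]), abs=1e-12)
        assert f["late_learning_slope"] == pytest.approx(ls_slope(t[2:], counts[2:]), abs=1e-12)

    def test_missing_trial_propagates(self):
        f = compute_slope_features([3, float("nan"), 7, 9, 11])
        assert all(math.isnan(v) for v in f.values())


class TestConsistencyFeatures:
    def test_identical_sets_full_constancy(self):
        scored = {lab: _scored(lab, (1, 2, 3)) for lab in ("T1", "T2", "T3", "T4", "T5")}
        f = compute_consistency_features(scored)
        assert f["constancy_learning_index"] == 1.0
        assert f["total_gained"] == 0
        assert f["total_lost"] == 0

    def test_disjoint_sets_zero_constancy(self):
        sets = [(1,), (2,), (3,), (4,), (5,)]
        scored = {
            lab: _scored(lab, s) for lab, s in zip(("T1", "T2", "T3", "T4", "T5"), sets)
        }
        assert compute_consistency_features(scored)["constancy_learning_index"] == 0.0

    def test_hand_computed_overlap_ratio(self):
        sets = [(1, 2), (2, 3, 4), (2, 3, 4), (2, 3, 4), (2, 3, 4)]
        scored = {
            lab: _scored(lab, s) for lab, s in zip(("T1", "T2", "T3", "T4", "T5"), sets)
        }
        f = compute_consistency_features(scored)
        assert f["constancy_learning_index"] == pytest.approx(10 / 11)
        assert f["gained_trial_1_to_2"] == 2
        assert f["lost_trial_1_to_2"] == 1

    def test_savings(self):
        scored = {lab: _scored(lab, (1, 2, 3, 4)) for lab in ("T1", "T2", "T3", "T4", "T5")}
        scored["DELAYED"] = _scored("DELAYED", (1, 2))
        assert compute_consistency_features(scored)["savings"] == pytest.approx(0.5)

    def test_savings_missing_when_trial5_zero(self):
        scored = {lab: _scored(lab, ()) for lab in ("T1", "T2", "T3", "T4", "T5")}
        scored["DELAYED"] = _scored("DELAYED", (1,))
        assert math.isnan(compute_consistency_features(scored)["savings"])


class TestOrganizationFeatures:
    def test_list_order_recall_maximal_chaining(self):
        assert serial_cluster_count(tuple(range(1, 16))) == 14

    def test_forward_only_by_default(self):
        assert serial_cluster_count((3, 2, 1)) == 0
        assert serial_cluster_count((3, 2, 1), bidirectional=True) == 2

    def test_pf_degenerate_missing(self):
        assert math.isnan(pair_frequency((), ()))

    def test_pf_hand_enumeration(self):
        # shared adjacent pair {2,3} (opposite orders); h=k=4, c=|{2,3,4}|=3
        # -> O=1, PF = 1 - 2*3*2/16 = 0.25
        assert pair_frequency((1, 2, 3, 4), (3, 2, 4, 8)) == pytest.approx(0.25)

    def test_pf_chance_correction_zero_mean_under_permutation(self):
        """Under random output order within fixed recall sets, E[PF] = 0."""
        rng = np.random.default_rng(42)
        set_a = np.array([1, 2, 3, 4, 5, 6, 7, 8])
        set_b = np.array([3, 4, 5, 6, 7, 8, 9, 10])
        vals = []
        for _ in range(4000):
            vals.append(
                pair_frequency(rng.permutation(set_a), rng.permutation(set_b))
            )
        vals = np.asarray(vals)
        se = vals.std(ddof=1) / math.sqrt(len(vals))
        assert abs(vals.mean()) < 3 * se

    def test_total_serial_clusters_sums_trials(self):
        scored = {
            "T1": _scored("T1", (1, 2, 5)),   # 1 cluster
            "T2": _scored("T2", (4, 5, 6)),   # 2 clusters
            "T3": _scored("T3", (9, 3, 1)),   # 0
            "T4": _scored("T4", (7, 8)),      # 1
            "T5": _scored("T5", ()),          # 0
        }
        f = compute_organization_features(scored)
        assert f["total_serial_clusters"] == 4


class TestFeatureTable:
    def test_catalog_size_and_required_names(self):
        cat = feature_catalog()
        assert len(cat) >= 60
        required = {
            "delayed_recall", "immediate_midlist_items_trial_3",
            "delayed_recall_midlist_items", "late_learning_slope",
            "immediate_total_midlist_items", "immediate_count_trial_5",
            "total_immediate_recall", "immediate_count_trial_4",
            "delayed_recall_recency_items", "immediate_count_trial_3",
        }
        assert required <= set(cat)

    def test_table_shape_and_order(self, default_cohort):
        sessions, meta = default_cohort
        tab = build_feature_table(sessions[:10], "asr")
        assert list(tab.columns) == list(feature_catalog())
        assert tab.shape == (10, len(feature_catalog()))

    def test_duplicate_participants_rejected(self, default_cohort):
        sessions, _ = default_cohort
        with pytest.raises(ValueError, match="duplicate"):
            build_feature_table([sessions[0], sessions[0]], "asr")

    def test_region_counts_sum_to_trial_counts(self, default_cohort):
        """Region decomposition identity on every simulated session/trial."""
        sessions, _ = default_cohort
        for s in sessions:
            fv = compute_features(s, "asr").values
            for t in range(1, 6):
                total = sum(
                    fv[f"immediate_{r}_items_trial_{t}"]
                    for r in ("primacy", "midlist", "recency")
                )
                assert total == fv[f"immediate_count_trial_{t}"]

    def test_total_immediate_is_sum_of_trials(self, default_feature_tables):
        tab = default_feature_tables["asr"]
        trials = sum(tab[f"immediate_count_trial_{i}"] for i in range(1, 6))
        assert np.allclose(tab["total_immediate_recall"], trials)
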