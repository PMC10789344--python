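"""Synthetic cohort generator: limit cases, monotonicity, determinism,
ASR-miss mechanism."""

import math
from dataclasses import replace

import numpy as np
import pytest

from vltkit.cohort import (
    AsrNoiseParams,
    DUMMY_INTRUSION_VOCAB,
    GroupParams,
    apply_asr_noise,
    calibrate_defaults,
    simulate_cohort,
    simulate_session,
)
from vltkit.features import build_feature_table, compute_features
from vltkit.io import load_bundled_wordlists, session_to_dict
from vltkit.reliability import icc_a_k
from vltkit.scoring import score_variant


def base_params(**kw) -> GroupParams:
    defaults = dict(
        alpha=-0.5, beta=0.4, pi=0.5, rho=0.3, sigma_u=0.8, theta=0.8, eps=0.05,
        dprime=2.5, crit=1.0, order_mix=0.5, gap_mu=0.26, gap_sigma=0.55,
        intrusion_rate=0.3, repetition_rate=0.3,
    )
    defaults.update(kw)
    return GroupParams(**defaults)


@pytest.fixture(scope="module")
def wl():
    return load_bundled_wordlists()[0]


class TestSimulateSession:
    def test_floor_limit_no_immediate_recall(self, wl):
        """alpha -> -inf: immediate trials empty; delayed ~ Binomial(15, eps)."""
        rng = np.random.default_rng(0)
        params = base_params(alpha=-40.0, pi=0.0, rho=0.0, sigma_u=0.0, eps=0.2,
                            intrusion_rate=0.0, repetition_rate=0.0)
        delayed_counts = []
        for _ in range(300):
            s = simulate_session(params, 0.0, wl, rng)
            scored = score_variant(s, "clinical")
            for lab in ("T1", "T2", "T3", "T4", "T5"):
                assert scored[lab].correct_count == 0
            delayed_counts.append(scored["DELAYED"].correct_count)
        mean = np.mean(delayed_counts)
        se = np.std(delayed_counts, ddof=1) / math.sqrt(len(delayed_counts))
        assert abs(mean - 15 * 0.2) < 3 * se + 1e-9

    def test_flat_learning_binomial_expectation(self, wl):
        """beta = pi = rho = u = 0: E[count per trial] = 15*logistic(alpha)."""
        rng = np.random.default_rng(1)
        alpha = -0.3
        params = base_params(alpha=alpha, beta=0.0, pi=0.0, rho=0.0, sigma_u=0.0,
                            intrusion_rate=0.0, repetition_rate=0.0)
        expected = 15 / (1 + math.exp(-alpha))
        counts = []
        for _ in range(2000):
            s = simulate_session(params, 0.0, wl, rng)
            counts.extend(
                st.correct_count
                for lab, st in score_variant(s, "clinical").items()
                if lab != "DELAYED"
            )
        mean = np.mean(counts)
        se = np.std(counts, ddof=1) / math.sqrt(len(counts))
        assert abs(mean - expected) < 3 * se

    def test_pure_list_order_maximal_chaining_at_saturation(self, wl):
        """order_mix=1, no order noise, saturated recall: clusters = count-1."""
        rng = np.random.default_rng(2)
        params = base_params(alpha=40.0, sigma_u=0.0, order_mix=1.0, order_noise=0.0,
                            intrusion_rate=0.0, repetition_rate=0.0)
        s = simulate_session(params, 0.0, wl, rng)
        fv = compute_features(s, "clinical").values
        for t in range(1, 6):
            assert fv[f"serial_clusters_trial_{t}"] == fv[f"immediate_count_trial_{t}"] - 1 == 14

    def test_onsets_increasing_and_positive(self, wl):
        rng = np.random.default_rng(3)
        s = simulate_session(base_params(), 0.5, wl, rng)
        for trial in s.variant("clinical").trials:
            onsets = [e.onset_s for e in trial.events]
            assert all(o > 0 for o in onsets)
            assert all(b > a for a, b in zip(onsets, onsets[1:]))

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError, match="theta"):
            base_params(theta=1.3)

    def test_intrusion_vocab_disjoint_from_all_lists(self):
        lists = load_bundled_wordlists()
        all_words = set()
        for l in lists:
            all_words |= set(l.targets) | set(l.foils)
        assert not (set(DUMMY_INTRUSION_VOCAB) & all_words)


class TestAsrNoise:
    def test_zero_miss_identical_counts_and_perfect_icc(self, wl):
        rng = np.random.default_rng(4)
        noise = AsrNoiseParams(base_miss=0.0, fast_gap_s=1.0, fast_miss=0.0)
        totals_c, totals_a = [], []
        for i in range(30):
            s = simulate_session(base_params(intrusion_rate=0.5), rng.normal(0, 0.8), wl, rng,
                                 participant_id=f"p{i}")
            s = apply_asr_noise(s, noise, rng)
            fc = compute_features(s, "clinical").values
            fa = compute_features(s, "asr").values
            totals_c.append(fc["total_immediate_recall"])
            totals_a.append(fa["total_immediate_recall"])
            assert fa["total_intrusions"] == 0  # ASR never registers intrusions
        np.testing.assert_array_equal(totals_c, totals_a)
        assert icc_a_k(totals_c, totals_a).icc == 1.0

    def test_total_miss_empties_asr(self, wl):
        rng = np.random.default_rng(5)
        s = simulate_session(base_params(), 0.0, wl, rng)
        s = apply_asr_noise(s, AsrNoiseParams(base_miss=1.0, fast_miss=1.0), rng)
        fa = compute_features(s, "asr").values
        assert fa["total_immediate_recall"] == 0
        assert fa["delayed_recall"] == 0

    def test_fast_speech_misses_grow_with_clinical_count(self, wl):
        """With fast_miss >> base_miss, the clinical-ASR difference trends
        upward with the clinical count (the count-dependent agreement
        pattern): higher-ability speakers produce more sub-threshold gaps."""
        rng = np.random.default_rng(6)
        noise = AsrNoiseParams(base_miss=0.02, fast_gap_s=1.2, fast_miss=0.6)
        counts, diffs = [], []
        for i in range(500):
            u = rng.normal(0, 1.0)
            s = simulate_session(base_params(intrusion_rate=0.0), u, wl, rng,
                                 participant_id=f"p{i}")
            s = apply_asr_noise(s, noise, rng)
            c = compute_features(s, "clinical").values["total_immediate_recall"]
            a = compute_features(s, "asr").values["total_immediate_recall"]
            counts.append(c)
            diffs.append(c - a)
        corr = np.corrcoef(counts, diffs)[0, 1]
        assert corr > 0.3

    def test_params_ordering_enforced(self):
        with pytest.raises(ValueError):
            AsrNoiseParams(base_miss=0.5, fast_miss=0.1)


class TestSimulateCohort:
    def test_seed_determinism_byte_for_byte(self):
        cfg = calibrate_defaults(n_scd=8, n_mci=6, n_dementia=2, seed=321)
        s1, m1 = simulate_cohort(cfg)
        s2, m2 = simulate_cohort(cfg)
        assert [session_to_dict(a) for a in s1] == [session_to_dict(b) for b in s2]
        assert m1.equals(m2)

    def test_metadata_columns_complete(self, default_cohort):
        _, meta = default_cohort
        for col in ("group", "label", "age", "sex", "education", "mmse", "cdr_sob",
                    "z_svf", "z_rbmt_delayed"):
            assert col in meta.columns
        assert set(meta["group"]) == {"SCD", "MCI", "dementia"}
        assert meta["label"].value_counts()[0] == 69

    def test_beta_increases_total_recall(self):
        means = []
        for beta in (0.1, 0.3, 0.5):
            cfg = calibrate_defaults(n_scd=120, n_mci=0, n_dementia=0, seed=99)
            cfg = replace(cfg, scd=replace(cfg.scd, beta=beta))
            sessions, _ = simulate_cohort(cfg)
            tab = build_feature_table(sessions, "clinical")
            means.append(tab["total_immediate_recall"].mean())
        assert means[0] < means[1] < means[2]

    def test_theta_increases_savings(self):
        means = []
        for theta in (0.3, 0.6, 0.9):
            cfg = calibrate_defaults(n_scd=120, n_mci=0, n_dementia=0, seed=98)
            cfg = replace(cfg, scd=replace(cfg.scd, theta=theta, theta_u_loading=0.0))
            sessions, _ = simulate_cohort(cfg)
            tab = build_feature_table(sessions, "clinical")
            means.append(tab["savings"].mean())
        assert means[0] < means[1] < means[2]

    def test_savings_recovers_retention_probability(self):
        """With eps = 0 and no ability-coupling, mean savings ~ theta ± 0.05."""
        theta = 0.65
        cfg = calibrate_defaults(n_scd=500, n_mci=0, n_dementia=0, seed=97)
        cfg = replace(
            cfg,
            scd=replace(cfg.scd, theta=theta, eps=0.0, theta_u_loading=0.0),
            asr=AsrNoiseParams(base_miss=0.0, fast_miss=0.0),
        )
        sessions, _ = simulate_cohort(cfg)
        tab = build_feature_table(sessions, "clinical")
        assert abs(tab["savings"].mean() - theta) < 0.05
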