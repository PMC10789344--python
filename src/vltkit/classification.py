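"""Diagnostic classification of SCD vs MCI/dementia.

Model family: for each VLT subtest (immediate, delayed, recognition, or
the full set of the three clinical totals) three nested tiers are fit —

    tier 1  the subtest's clinical total score(s) only,
    tier 2  tier 1 + age,
    tier 3  tier 2 + the full process-score feature catalog,

each an extremely-randomized-trees ensemble evaluated by leave-one-out
cross-validation (LOOCV): every participant is scored by a model trained
on all others, with median imputation of missing features fitted inside
each training fold.  Discrimination is summarized by the ROC AUC with
DeLong confidence intervals, paired DeLong tests between tiers, and the
F1 of the impaired class at a fixed 0.5 probability threshold.

The DeLong method estimates the variance of the midrank AUC (and the
covariance of two AUCs computed on the same sample) from per-observation
structural components, enabling Wald CIs and paired AUC-difference tests
without resampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import ExtraTreesClassifier
from sklearn.impute import SimpleImputer
from sklearn.metrics import f1_score

__all__ = [
    "SUBTESTS",
    "CORE_COLUMNS",
    "ModelSpec",
    "RocModelResult",
    "loocv_scores",
    "roc_auc_delong",
    "delong_paired_test",
    "f1_at_threshold",
    "run_model_family",
]

SUBTESTS: tuple[str, ...] = ("immediate", "delayed", "recognition", "full")

CORE_COLUMNS: dict[str, tuple[str, ...]] = {
    "immediate": ("total_immediate_recall",),
    "delayed": ("delayed_recall",),
    "recognition": ("recognition_true_positives",),
    "full": ("total_immediate_recall", "delayed_recall", "recognition_true_positives"),
}


@dataclass(frozen=True)
class ModelSpec:
    """One model of the subtest × tier family.

    ``tier``: 1 = core score only, 2 = + age, 3 = + age + all features.
    Hyperparameters default to 500 trees with sklearn's default split
    rules and a fixed seed; they are recorded in run metadata.
    """

    subtest_core: str
    tier: int
    name: str = ""
    n_estimators: int = 500
    random_seed: int = 1234
    age_column: str = "age"
    imputation: str = "median"

    def __post_init__(self) -> None:
        if self.subtest_core not in SUBTESTS:
            raise ValueError(f"unknown subtest {self.subtest_core!r}")
        if self.tier not in (1, 2, 3):
            raise ValueError(f"tier must be 1, 2 or 3, got {self.tier}")
        if not self.name:
            object.__setattr__(self, "name", f"{self.subtest_core}_model{self.tier}")

    def predictor_columns(self, feature_columns: Sequence[str]) -> list[str]:
        cols = list(CORE_COLUMNS[self.subtest_core])
        if self.tier >= 2:
            cols.append(self.age_column)
        if self.tier == 3:
            cols += [c for c in feature_columns if c not in cols and c != self.age_column]
        return cols


@dataclass(frozen=True)
class RocModelResult:
    """LOOCV scores and ROC summary for one model specification."""

    model: ModelSpec
    scores: np.ndarray
    labels: np.ndarray
    auc: float
    ci_low: float
    ci_high: float
    auc_variance: float
    f1: float
    n_positive: int
    n_negative: int


def loocv_scores(
    table: pd.DataFrame,
    labels: Sequence[int],
    spec: ModelSpec,
    feature_columns: Optional[Sequence[str]] = None,
) -> np.ndarray:
    """Leave-one-out predicted probabilities of the impaired class.

    For every sample, an ExtraTrees ensemble is trained on all other
    samples (median imputation fitted on the training fold only) and the
    held-out sample's probability of class 1 is emitted.  Deterministic
    given ``spec.random_seed``.
    """
    y = np.asarray(labels, dtype=int)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if len(y) != len(table):
        raise ValueError("labels length must match table")
    cols = spec.predictor_columns(
        feature_columns if feature_columns is not None else table.columns
    )
    missing_cols = [c for c in cols if c not in table.columns]
    if missing_cols:
        raise ValueError(f"predictor columns absent from table: {missing_cols}")
    x = table[cols].to_numpy(dtype=float)
    n = len(y)
    if np.sum(y == 1) < 2 or np.sum(y == 0) < 2:
        raise ValueError("need >= 2 samples per class")

    scores = np.empty(n, dtype=float)
    idx = np.arange(n)
    for i in range(n):
        train = idx != i
        y_tr = y[train]
        if len(np.unique(y_tr)) < 2:
            raise ValueError(f"training fold for sample {i} is single-class")
        imputer = SimpleImputer(strategy=spec.imputation, keep_empty_features=True)
        x_tr = imputer.fit_transform(x[train])
        x_te = imputer.transform(x[i : i + 1])
        clf = ExtraTreesClassifier(
            n_estimators=spec.n_estimators, random_state=spec.random_seed
        )
        clf.fit(x_tr, y_tr)
        pos = int(np.where(clf.classes_ == 1)[0][0])
        scores[i] = clf.predict_proba(x_te)[0, pos]
    return scores


# ---------------------------------------------------------------------------
# DeLong machinery


def _delong_components(scores: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and per-observation structural components (V10, V01)."""
    x = scores[labels == 1]
    y = scores[labels == 0]
    m, n = len(x), len(y)
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    tx = stats.rankdata(x)
    ty = stats.rankdata(y)
    tz = stats.rankdata(np.concatenate([x, y]))
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    auc = float(v10.mean())
    return auc, v10, v01


def _auc_variance(v10: np.ndarray, v01: np.ndarray) -> float:
    m, n = len(v10), len(v01)
    s10 = float(np.var(v10, ddof=1)) if m > 1 else 0.0
    s01 = float(np.var(v01, ddof=1)) if n > 1 else 0.0
    return s10 / m + s01 / n


def roc_auc_delong(
    scores: Sequence[float],
    labels: Sequence[int],
    alpha: float = 0.05,
) -> tuple[float, float, float, float]:
    """Midrank AUC with a DeLong variance and Wald CI.

    Returns ``(auc, ci_low, ci_high, variance)``.  Constant score
    vectors carry no ranking information: AUC 0.5 with a zero-variance
    warning.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(s) != len(y):
        raise ValueError("scores and labels differ in length")
    if np.all(s == s[0]):
        warnings.warn(
            "constant scores: AUC 0.5 with zero variance", RuntimeWarning, stacklevel=2
        )
        return 0.5, float("nan"), float("nan"), 0.0
    auc, v10, v01 = _delong_components(s, y)
    var = _auc_variance(v10, v01)
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(var)
    return auc, max(0.0, auc - half), min(1.0, auc + half), var


def delong_paired_test(
    scores_1: Sequence[float],
    scores_2: Sequence[float],
    labels: Sequence[int],
) -> float:
    """Two-sided p-value for the difference of two correlated AUCs.

    Both score vectors must be computed on the same samples with the
    same labels.  Identical score vectors give p = 1.
    """
    s1 = np.asarray(scores_1, dtype=float)
    s2 = np.asarray(scores_2, dtype=float)
    y = np.asarray(labels, dtype=int)
    if not (len(s1) == len(s2) == len(y)):
        raise ValueError("scores and labels must share length")
    auc1, v10_1, v01_1 = _delong_components(s1, y)
    auc2, v10_2, v01_2 = _delong_components(s2, y)
    m, n = len(v10_1), len(v01_1)
    var1 = _auc_variance(v10_1, v01_1)
    var2 = _auc_variance(v10_2, v01_2)
    cov = 0.0
    if m > 1:
        cov += float(np.cov(v10_1, v10_2, ddof=1)[0, 1]) / m
    if n > 1:
        cov += float(np.cov(v01_1, v01_2, ddof=1)[0, 1]) / n
    var_diff = var1 + var2 - 2 * cov
    diff = auc1 - auc2
    if var_diff <= 1e-16:
        return 1.0 if abs(diff) < 1e-12 else 0.0
    z = diff / np.sqrt(var_diff)
    return float(2 * stats.norm.sf(abs(z)))


def f1_at_threshold(
    scores: Sequence[float],
    labels: Sequence[int],
    threshold: float = 0.5,
) -> float:
    """F1 of the impaired (positive) class at a fixed probability threshold."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    pred = (s >= threshold).astype(int)
    if pred.sum() == 0:
        warnings.warn(
            "no positive predictions at threshold; F1 = 0", RuntimeWarning, stacklevel=2
        )
        return 0.0
    return float(f1_score(y, pred, pos_label=1, zero_division=0))


def _evaluate(
    table: pd.DataFrame,
    y: np.ndarray,
    spec: ModelSpec,
    feature_columns: Sequence[str],
    threshold: float,
) -> RocModelResult:
    scores = loocv_scores(table, y, spec, feature_columns)
    auc, lo, hi, var = roc_auc_delong(scores, y)
    f1 = f1_at_threshold(scores, y, threshold)
    return RocModelResult(
        model=spec,
        scores=scores,
        labels=y.copy(),
        auc=auc,
        ci_low=lo,
        ci_high=hi,
        auc_variance=var,
        f1=f1,
        n_positive=int(np.sum(y == 1)),
        n_negative=int(np.sum(y == 0)),
    )


def run_model_family(
    table: pd.DataFrame,
    labels: Sequence[int],
    feature_columns: Sequence[str],
    n_estimators: int = 500,
    random_seed: int = 1234,
    threshold: float = 0.5,
    exclude_mask: Optional[Sequence[bool]] = None,
    subtests: Sequence[str] = SUBTESTS,
) -> tuple[dict[str, RocModelResult], pd.DataFrame]:
    """Fit the 4-subtest × 3-tier model family, with paired DeLong tests.

    ``table`` must contain the core score columns, an ``age`` column and
    the feature columns.  ``exclude_mask`` (e.g. participants with
    dementia) triggers a sensitivity rerun on the remaining samples,
    reported with a ``_sens`` suffix.  Returns the result map and a tidy
    summary table with one row per model.
    """
    y = np.asarray(labels, dtype=int)
    results: dict[str, RocModelResult] = {}
    rows = []

    def _family(tab: pd.DataFrame, yy: np.ndarray, suffix: str) -> None:
        for subtest in subtests:
            fam: dict[int, RocModelResult] = {}
            for tier in (1, 2, 3):
                spec = ModelSpec(
                    subtest_core=subtest,
                    tier=tier,
                    n_estimators=n_estimators,
                    random_seed=random_seed,
                )
                res = _evaluate(tab, yy, spec, feature_columns, threshold)
                fam[tier] = res
                results[spec.name + suffix] = res
            for lo_t, hi_t in ((1, 2), (1, 3), (2, 3)):
                p = delong_paired_test(fam[hi_t].scores, fam[lo_t].scores, yy)
                rows_p[(subtest + suffix, lo_t, hi_t)] = p
            for tier in (1, 2, 3):
                res = fam[tier]
                rows.append(
                    {
                        "model": res.model.name + suffix,
                        "subtest": subtest,
                        "tier": tier,
                        "sensitivity": suffix == "_sens",
                        "auc": res.auc,
                        "ci_low": res.ci_low,
                        "ci_high": res.ci_high,
                        "f1": res.f1,
                        "n_positive": res.n_positive,
                        "n_negative": res.n_negative,
                        "p_vs_tier1": rows_p.get((subtest + suffix, 1, tier), np.nan),
                        "p_vs_tier2": rows_p.get((subtest + suffix, 2, tier), np.nan),
                    }
                )

    rows_p: dict[tuple, float] = {}
    _family(table, y, "")
    if exclude_mask is not None:
        keep = ~np.asarray(exclude_mask, dtype=bool)
        _family(table.loc[keep], y[keep], "_sens")
    return results, pd.DataFrame(rows)
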