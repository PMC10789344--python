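"""Univariate group comparisons, effect sizes, and correlation structure.

Because most process scores are heavily skewed, group differences between
SCD and MCI/dementia are tested with the Mann-Whitney U test.  The effect
size is the standardized statistic converted to

    r = |Z| / sqrt(N),

with Z the tie-corrected normal approximation of U (no continuity
correction) and N the combined sample size actually available for the
feature.  U/(n_a * n_b) is the probability that a random draw from group
A exceeds one from group B — the univariate ROC AUC — so the ranking
table carries both r and the AUC for each feature.

The correlation analysis reproduces a clinical heatmap: Pearson
correlations between process scores and external cognitive measures on
case-wise-complete rows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EffectSizeResult",
    "CorrelationMatrix",
    "mann_whitney_z",
    "effect_size_r_from_z",
    "effect_size_ranking",
    "correlation_heatmap",
    "demographic_comparisons",
]


@dataclass(frozen=True)
class EffectSizeResult:
    """Mann-Whitney comparison of one feature between two groups."""

    feature: str
    u: float
    z: float
    p: float
    r: float
    n: int
    n_a: int
    n_b: int
    univariate_auc: float


@dataclass(frozen=True)
class CorrelationMatrix:
    """Pearson correlation matrix on case-wise-complete rows."""

    variables: tuple[str, ...]
    r: pd.DataFrame
    p: pd.DataFrame
    n_complete: int


def effect_size_r_from_z(z: float, n: int) -> float:
    """Convert a standardized test statistic to the r effect size |Z|/sqrt(N)."""
    if n <= 0:
        raise ValueError("N must be positive")
    return abs(z) / np.sqrt(n)


def mann_whitney_z(
    group_a: Sequence[float],
    group_b: Sequence[float],
    feature: str = "",
) -> EffectSizeResult:
    """Mann-Whitney U with tie-corrected normal approximation.

    U counts pairs where a group-A value exceeds a group-B value (ties
    count 1/2), computed through midranks.  Z = (U - n_a n_b / 2) / sigma
    with the tie-corrected variance and no continuity correction, so its
    sign is positive when group A tends to exceed group B.  The p-value
    is two-sided; r = |Z|/sqrt(n_a + n_b).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    n_a, n_b = len(a), len(b)
    if n_a < 2 or n_b < 2:
        raise ValueError(f"need >= 2 values per group, got {n_a} and {n_b}")
    n = n_a + n_b
    combined = np.concatenate([a, b])
    ranks = stats.rankdata(combined)
    u = float(ranks[:n_a].sum() - n_a * (n_a + 1) / 2)

    mu = n_a * n_b / 2.0
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (n * (n - 1))
    sigma2 = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        z = 0.0
        p = 1.0
    else:
        z = (u - mu) / np.sqrt(sigma2)
        p = 2 * stats.norm.sf(abs(z))
    return EffectSizeResult(
        feature=feature,
        u=u,
        z=float(z),
        p=float(p),
        r=effect_size_r_from_z(z, n),
        n=n,
        n_a=n_a,
        n_b=n_b,
        univariate_auc=u / (n_a * n_b),
    )


def effect_size_ranking(
    feature_table: pd.DataFrame,
    labels: Sequence,
    positive_label,
    features: Optional[Sequence[str]] = None,
    top_k: Optional[int] = None,
) -> pd.DataFrame:
    """Rank features by the r effect size for positive vs rest.

    Group A is the positive (impaired) group, so Z is negative for
    features on which impaired participants score lower.  Besides the
    orientation-bearing ``univariate_auc`` = U/(n_a n_b), the table
    reports ``discrimination_auc`` = max(AUC, 1 - AUC), the direction-free
    separability of the feature.  Per-feature N is reported explicitly
    since missing values differ between features.
    """
    y = np.asarray(labels)
    if len(y) != len(feature_table):
        raise ValueError("labels length must match feature table")
    mask_a = y == positive_label
    cols = list(features) if features is not None else [
        c for c in feature_table.columns if pd.api.types.is_numeric_dtype(feature_table[c])
    ]
    rows = []
    for c in cols:
        vals = feature_table[c].to_numpy(dtype=float)
        a = vals[mask_a]
        b = vals[~mask_a]
        a = a[~np.isnan(a)]
        b = b[~np.isnan(b)]
        if len(a) < 2 or len(b) < 2:
            continue
        res = mann_whitney_z(a, b, feature=c)
        rows.append(
            {
                "feature": c,
                "U": res.u,
                "Z": res.z,
                "p": res.p,
                "effect_size": res.r,
                "N": res.n,
                "n_a": res.n_a,
                "n_b": res.n_b,
                "univariate_auc": res.univariate_auc,
                "discrimination_auc": max(res.univariate_auc, 1 - res.univariate_auc),
            }
        )
    out = pd.DataFrame(rows).sort_values("effect_size", ascending=False, ignore_index=True)
    if top_k is not None:
        out = out.head(top_k)
    return out


def correlation_heatmap(
    table: pd.DataFrame,
    variables: Optional[Sequence[str]] = None,
    min_complete: int = 3,
) -> CorrelationMatrix:
    """Pearson correlations with case-wise deletion.

    Rows with any missing value across the selected variables are
    dropped (case-wise deletion), matching how clinical heatmaps report
    a single complete-case N.  With fewer than ``min_complete`` complete
    rows all entries are NaN.
    """
    cols = list(variables) if variables is not None else [
        c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])
    ]
    sub = table[cols].dropna()
    n = len(sub)
    k = len(cols)
    r = pd.DataFrame(np.full((k, k), np.nan), index=cols, columns=cols)
    p = pd.DataFrame(np.full((k, k), np.nan), index=cols, columns=cols)
    if n >= min_complete:
        for i, ci in enumerate(cols):
            r.iloc[i, i] = 1.0
            p.iloc[i, i] = 0.0
            for j in range(i + 1, k):
                cj = cols[j]
                if sub[ci].nunique() < 2 or sub[cj].nunique() < 2:
                    continue
                rr, pp = stats.pearsonr(sub[ci], sub[cj])
                r.iloc[i, j] = r.iloc[j, i] = rr
                p.iloc[i, j] = p.iloc[j, i] = pp
    return CorrelationMatrix(tuple(cols), r, p, n)


def demographic_comparisons(
    metadata: pd.DataFrame,
    labels: Sequence,
    positive_label,
    continuous: Sequence[str] = (),
    categorical: Sequence[str] = (),
) -> pd.DataFrame:
    """Baseline-table group comparisons: Welch t-tests for continuous
    variables and chi-square tests for categorical ones.

    Convenience only; the primary effect-size machinery is
    :func:`effect_size_ranking`.
    """
    y = np.asarray(labels)
    mask = y == positive_label
    rows = []
    for c in continuous:
        a = metadata.loc[mask, c].dropna()
        b = metadata.loc[~mask, c].dropna()
        t, p = stats.ttest_ind(a, b, equal_var=False)
        rows.append(
            {
                "variable": c,
                "test": "t",
                "group_a_mean": a.mean(),
                "group_a_sd": a.std(ddof=1),
                "group_b_mean": b.mean(),
                "group_b_sd": b.std(ddof=1),
                "statistic": float(t),
                "p": float(p),
            }
        )
    for c in categorical:
        tab = pd.crosstab(metadata[c], mask)
        chi2, p, _, _ = stats.chi2_contingency(tab)
        rows.append(
            {
                "variable": c,
                "test": "chi2",
                "group_a_mean": np.nan,
                "group_a_sd": np.nan,
                "group_b_mean": np.nan,
                "group_b_sd": np.nan,
                "statistic": float(chi2),
                "p": float(p),
            }
        )
    return pd.DataFrame(rows)
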