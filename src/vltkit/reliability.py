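"""Clinical-vs-ASR agreement statistics.

The agreement between a clinician's score and the automatically derived
(ASR) score for the same measure is quantified with the intraclass
correlation for a two-way model with absolute agreement on the mean of
k = 2 ratings, ICC(A,k).  With MS_rows (between-subject), MS_cols
(between-rater) and MS_error mean squares from the two-way ANOVA
without replication,

    ICC(A,k) = (MS_rows - MS_error) / (MS_rows + (MS_cols - MS_error)/n)

Absolute agreement penalizes systematic rater offsets through the
MS_cols term, which is the right behaviour when the ASR systematically
misses words.  Confidence intervals use the McGraw & Wong F-based
procedure for the single-rating coefficient, stepped up to the k-rating
scale.  Difference summaries (mean/min/max clinical - ASR difference,
counts above a threshold) and per-subgroup ICCs support sensitivity
analyses by diagnosis and by trial.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ICCResult",
    "DifferenceSummary",
    "icc_a_k",
    "difference_summary",
    "subgroup_icc",
    "reliability_report",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ICCResult:
    """ICC(A,k) estimate with CI and the underlying ANOVA mean squares."""

    icc: float
    ci_low: float
    ci_high: float
    n_subjects: int
    k_raters: int
    ms_rows: float
    ms_cols: float
    ms_error: float
    measure: str = ""


@dataclass(frozen=True)
class DifferenceSummary:
    """Summary of per-participant clinical - ASR differences."""

    mean_diff: float
    min_diff: float
    max_diff: float
    threshold: float
    count_exceeding: int
    fraction_exceeding: float
    n: int


def _two_way_mean_squares(data: np.ndarray) -> tuple[float, float, float]:
    """Mean squares of the two-way ANOVA without replication.

    ``data`` is an n_subjects × k_raters matrix.
    """
    n, k = data.shape
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    # grand mean as the mean of column means: keeps the column and
    # interaction sums of squares exactly zero for duplicated columns
    grand = float(col_means.mean())
    ss_rows = k * float(np.sum((row_means - grand) ** 2))
    ss_cols = n * float(np.sum((col_means - grand) ** 2))
    resid = data - row_means[:, None] - col_means[None, :] + grand
    ss_error = float(np.sum(resid**2))
    ms_rows = ss_rows / (n - 1)
    ms_cols = ss_cols / (k - 1)
    ms_error = ss_error / ((n - 1) * (k - 1))
    return ms_rows, ms_cols, ms_error


def icc_a_k(
    value_clinical: Sequence[float],
    value_asr: Sequence[float],
    alpha: float = 0.05,
    measure: str = "",
) -> ICCResult:
    """ICC(A,k): two-way model, absolute agreement, mean of k = 2 ratings.

    Pairs with a missing side are excluded listwise.  Requires >= 3
    complete pairs.  With zero between-subject variance the ICC is
    undefined; 0.0 is returned with a degenerate-variance warning.
    """
    a = np.asarray(value_clinical, dtype=float)
    b = np.asarray(value_asr, dtype=float)
    if a.shape != b.shape:
        raise ValueError("clinical and asr vectors differ in length")
    keep = ~(np.isnan(a) | np.isnan(b))
    data = np.column_stack([a[keep], b[keep]])
    n, k = data.shape
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, got {n}")

    msr, msc, mse = _two_way_mean_squares(data)
    denom = msr + (msc - mse) / n
    if denom <= 0 or (msr == 0 and mse == 0 and msc == 0):
        warnings.warn(
            "degenerate variance structure (no between-subject variance); ICC set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
        return ICCResult(0.0, float("nan"), float("nan"), n, k, msr, msc, mse, measure)
    icc_k = (msr - mse) / denom

    if mse == 0.0 and msc == 0.0:
        # raters agree exactly on every subject: estimate and CI are 1
        return ICCResult(1.0, 1.0, 1.0, n, k, msr, msc, mse, measure)

    # McGraw & Wong F-based interval for the single-rating ICC(A,1),
    # stepped up to k ratings.  When MS_error = 0 with a non-zero rater
    # effect (e.g. an exact constant offset) the F-ratio MS_cols/MS_error
    # diverges; the interval formulas below are evaluated in that limit,
    # where the Satterthwaite df tends to k - 1.
    icc_1 = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    if mse == 0.0:
        v = float(k - 1)
    else:
        fj = msc / mse
        vn = (k - 1) * (n - 1) * (k * icc_1 * fj + n * (1 + (k - 1) * icc_1) - k * icc_1) ** 2
        vd = (n - 1) * k**2 * icc_1**2 * fj**2 + (n * (1 + (k - 1) * icc_1) - k * icc_1) ** 2
        v = vn / vd
    f_u = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_l = stats.f.ppf(1 - alpha / 2, v, n - 1)
    l1 = n * (msr - f_u * mse) / (f_u * (k * msc + (k * n - k - n) * mse) + n * msr)
    u1 = n * (f_l * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_l * msr)
    ci_low = l1 * k / (1 + l1 * (k - 1))
    ci_high = u1 * k / (1 + u1 * (k - 1))
    ci_low = min(ci_low, icc_k)
    ci_high = max(ci_high, icc_k)
    return ICCResult(icc_k, ci_low, ci_high, n, k, msr, msc, mse, measure)


def difference_summary(
    value_clinical: Sequence[float],
    value_asr: Sequence[float],
    threshold: float = 14.0,
) -> DifferenceSummary:
    """Summarize clinical - ASR differences.

    ``threshold`` flags participants for whom the ASR missed more than
    that many words (default 14, the reported immediate-recall cut; use
    4 for delayed recall).
    """
    a = np.asarray(value_clinical, dtype=float)
    b = np.asarray(value_asr, dtype=float)
    keep = ~(np.isnan(a) | np.isnan(b))
    d = a[keep] - b[keep]
    if d.size == 0:
        raise ValueError("no complete pairs")
    count = int(np.sum(d > threshold))
    return DifferenceSummary(
        mean_diff=float(d.mean()),
        min_diff=float(d.min()),
        max_diff=float(d.max()),
        threshold=threshold,
        count_exceeding=count,
        fraction_exceeding=count / d.size,
        n=int(d.size),
    )


def subgroup_icc(
    pairs: pd.DataFrame,
    group_col: str,
    clinical_col: str = "value_clinical",
    asr_col: str = "value_asr",
    min_n: int = 3,
    alpha: float = 0.05,
) -> dict[str, ICCResult]:
    """ICC(A,k) per subgroup (diagnosis labels, trial labels, ...).

    Groups with fewer than ``min_n`` complete pairs are skipped with a
    log entry.
    """
    out: dict[str, ICCResult] = {}
    for g, sub in pairs.groupby(group_col, sort=False):
        complete = sub[[clinical_col, asr_col]].dropna()
        if len(complete) < min_n:
            logger.warning(
                "subgroup %r skipped: %d complete pairs (< %d)", g, len(complete), min_n
            )
            continue
        out[str(g)] = icc_a_k(
            complete[clinical_col], complete[asr_col], alpha=alpha, measure=str(g)
        )
    return out


def reliability_report(
    measures: Mapping[str, pd.DataFrame],
    thresholds: Optional[Mapping[str, float]] = None,
    group_col: Optional[str] = None,
) -> pd.DataFrame:
    """One row per measure (× subgroup): ICC, CI, n and difference summary.

    ``measures`` maps measure name -> DataFrame with ``value_clinical``
    and ``value_asr`` columns (plus ``group_col`` for subgroup rows).
    """
    thresholds = thresholds or {}
    rows = []

    def _row(measure: str, subgroup: str, df: pd.DataFrame) -> Optional[dict]:
        complete = df[["value_clinical", "value_asr"]].dropna()
        if len(complete) < 3:
            logger.warning("measure %s / %s: too few pairs", measure, subgroup)
            return None
        res = icc_a_k(complete["value_clinical"], complete["value_asr"], measure=measure)
        ds = difference_summary(
            complete["value_clinical"], complete["value_asr"], thresholds.get(measure, 14.0)
        )
        return {
            "measure": measure,
            "subgroup": subgroup,
            "n": res.n_subjects,
            "n_excluded": len(df) - len(complete),
            "icc": res.icc,
            "ci_low": res.ci_low,
            "ci_high": res.ci_high,
            "mean_diff": ds.mean_diff,
            "min_diff": ds.min_diff,
            "max_diff": ds.max_diff,
            "count_exceeding": ds.count_exceeding,
            "fraction_exceeding": ds.fraction_exceeding,
        }

    for measure, df in measures.items():
        r = _row(measure, "all", df)
        if r:
            rows.append(r)
        if group_col is not None and group_col in df.columns:
            for g, sub in df.groupby(group_col, sort=False):
                r = _row(measure, str(g), sub)
                if r:
                    rows.append(r)
    return pd.DataFrame(rows)
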