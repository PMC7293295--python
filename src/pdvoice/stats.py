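"""Paired ON/OFF group statistics: t-tests, Bonferroni ranking, partial correlation.

The design is within-subject, so every feature is compared with a paired
t-test on the per-subject ON-OFF differences (positive t means the ON state
has the greater mean).  Features are ranked by ascending p-value, with
Bonferroni control of the family-wise error over the task's feature set.
Partial correlations among the top features describe how the feature pattern
covaries within each state once the other features are regressed out.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .errors import ParameterError

__all__ = [
    "TestResult",
    "paired_ttest",
    "bonferroni_mask",
    "rank_features",
    "partial_correlation",
    "paired_arrays",
]

META_COLUMNS = ("subject", "task", "state")


@dataclass
class TestResult:
    """Paired-test summary for one feature."""

    feature: str
    t_statistic: float
    p_value: float
    df: int
    significant: bool = False
    degenerate: bool = False


def paired_ttest(on_values, off_values, feature: str = "") -> TestResult:
    """Two-sided paired t-test of ON vs OFF (d = on - off, df = n - 1).

    Zero-variance differences yield a degenerate result that ranking skips.
    """
    on = np.asarray(on_values, dtype=np.float64)
    off = np.asarray(off_values, dtype=np.float64)
    if on.shape != off.shape or on.ndim != 1:
        raise ParameterError("paired vectors must be 1-D and equal length")
    n = on.size
    if n < 3:
        raise ParameterError("need at least 3 pairs")
    d = on - off
    if np.std(d, ddof=1) == 0.0:
        return TestResult(feature, float("nan"), float("nan"), n - 1, degenerate=True)
    t, p = sstats.ttest_rel(on, off)
    return TestResult(feature, float(t), float(p), n - 1)


def bonferroni_mask(p_values, alpha: float = 0.05) -> np.ndarray:
    """Boolean mask of p < alpha/m over the m supplied p-values."""
    p = np.asarray(p_values, dtype=np.float64)
    if p.size < 1:
        raise ParameterError("need at least one p-value")
    return p < alpha / p.size


def paired_arrays(
    table: pd.DataFrame, task: str, feature: str
) -> tuple[np.ndarray, np.ndarray]:
    """Aligned (on, off) value arrays for one feature, dropping incomplete pairs."""
    sub = table[table["task"] == task].pivot(index="subject", columns="state", values=feature)
    sub = sub.dropna()
    if not {"ON", "OFF"} <= set(sub.columns):
        raise ParameterError(f"both states required for task {task!r}")
    return sub["ON"].to_numpy(), sub["OFF"].to_numpy()


def rank_features(
    table: pd.DataFrame, task: str, alpha: float = 0.05
) -> list[TestResult]:
    """Per-feature paired tests for one task, ranked by ascending p-value.

    Ties break by descending |t|, then by feature name.  Significance is
    Bonferroni-corrected over all non-degenerate features of the task
    (missing values drop a subject pairwise for that feature only).
    Degenerate (zero-variance) features are appended after the ranking.
    """
    features = [c for c in table.columns if c not in META_COLUMNS]
    results, degenerate = [], []
    for feature in features:
        on, off = paired_arrays(table, task, feature)
        if on.size < 3:
            degenerate.append(
                TestResult(feature, float("nan"), float("nan"), max(on.size - 1, 0), degenerate=True)
            )
            continue
        res = paired_ttest(on, off, feature)
        (degenerate if res.degenerate else results).append(res)
    m = len(results)
    if m:
        mask = bonferroni_mask([r.p_value for r in results], alpha)
        for r, sig in zip(results, mask):
            r.significant = bool(sig)
    results.sort(key=lambda r: (r.p_value, -abs(r.t_statistic), r.feature))
    return results + degenerate


def partial_correlation(X) -> np.ndarray:
    """k x k partial-correlation matrix from the inverse correlation matrix.

    partial_ij = -P_ij / sqrt(P_ii P_jj) with P the precision of the
    correlation matrix; the diagonal is 1.  Raises on singular input and
    suggests adding a ridge.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2:
        raise ParameterError("X must be an n x k matrix")
    n, k = X.shape
    if n < k + 2:
        raise ParameterError(f"need n >= k + 2 observations (got n={n}, k={k})")
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0.0):
        raise ParameterError("degenerate (constant) column in X")
    corr = np.corrcoef(X, rowvar=False)
    try:
        precision = np.linalg.inv(corr)
    except np.linalg.LinAlgError as exc:
        raise ParameterError(
            "singular correlation matrix; consider adding a small ridge "
            "(corr + eps*I) or dropping a collinear feature"
        ) from exc
    d = np.sqrt(np.diag(precision))
    partial = -precision / np.outer(d, d)
    np.fill_diagonal(partial, 1.0)
    return partial
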