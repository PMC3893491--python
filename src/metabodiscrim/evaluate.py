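"""ROC/AUC machinery, whole-pipeline permutation significance, paired DeLong
AUC comparisons and box-plot style distribution summaries.

AUC is the tie-corrected (midrank) Mann-Whitney statistic, identical to the
trapezoidal area under the empirical ROC curve.  The permutation test treats
the *entire* analysis — confound screening plus cross-validated stepwise
model building — as the unit being tested: case labels are shuffled at fixed
group proportions and the whole procedure is re-run on each permuted dataset,
so the empirical null accounts for all selection steps.
"""

from __future__ import annotations

import logging
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

from .datatypes import DeLongComparison, PermutationResult, ROCResult

logger = logging.getLogger(__name__)


def _split_scores(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    cases = scores[labels == 1]
    controls = scores[labels == 0]
    if len(cases) == 0 or len(controls) == 0:
        raise ValueError("both classes must be present")
    return cases, controls


def auc(scores, labels) -> float:
    """Midrank Mann-Whitney AUC of ``scores`` against binary ``labels``.

    Equals the probability that a random case scores above a random control,
    counting ties as 1/2.
    """
    cases, controls = _split_scores(scores, labels)
    n1, n0 = len(cases), len(controls)
    ranks = stats.rankdata(np.concatenate([cases, controls]))
    return float((ranks[:n1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def roc(scores, labels) -> ROCResult:
    """Empirical ROC curve with its (midrank) AUC."""
    cases, controls = _split_scores(scores, labels)
    fpr, tpr, thr = _sk_roc_curve(np.asarray(labels, dtype=int), np.asarray(scores, dtype=float))
    return ROCResult(
        thresholds=thr,
        fpr=fpr,
        tpr=tpr,
        auc=auc(scores, labels),
        n_cases=len(cases),
        n_controls=len(controls),
    )


def sens_spec(scores, labels, threshold: float = 0.5, rule: str = "half") -> tuple[float, float]:
    """Sensitivity and specificity of thresholded scores.

    ``rule='half'`` classifies at the fixed probability cutoff (default 0.5);
    ``rule='youden'`` picks the cutoff maximizing sensitivity+specificity-1
    over the observed scores.
    """
    cases, controls = _split_scores(scores, labels)
    if rule == "youden":
        cand = np.unique(np.concatenate([cases, controls]))
        best, threshold = -np.inf, 0.5
        for c in cand:
            j = np.mean(cases >= c) + np.mean(controls < c) - 1.0
            if j > best:
                best, threshold = j, c
    elif rule != "half":
        raise ValueError(f"unknown threshold rule {rule!r}")
    sens = float(np.mean(cases >= threshold))
    spec = float(np.mean(controls < threshold))
    return sens, spec


def _placements(cases: np.ndarray, controls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong structural components (placement values) for one score vector."""
    m, n = len(cases), len(controls)
    all_ranks = stats.rankdata(np.concatenate([cases, controls]))
    case_ranks = stats.rankdata(cases)
    control_ranks = stats.rankdata(controls)
    v10 = (all_ranks[:m] - case_ranks) / n  # P(case_i > random control)
    v01 = 1.0 - (all_ranks[m:] - control_ranks) / m  # P(random case > control_j)
    return v10, v01


def delong_test(scores1, scores2, labels, label1: str = "1", label2: str = "2") -> DeLongComparison:
    """Paired DeLong test for the difference of two correlated AUCs.

    Both score vectors must be computed on the same samples.  The variance of
    the AUC difference is assembled from the empirical covariance of the
    per-sample placement values, scaled by the case and control counts; the
    z statistic is referred to the standard normal.
    """
    scores1 = np.asarray(scores1, dtype=float)
    scores2 = np.asarray(scores2, dtype=float)
    if scores1.shape != scores2.shape:
        raise ValueError("score vectors must have the same length")
    labels = np.asarray(labels, dtype=float)
    mask = labels == 1
    c1, k1 = scores1[mask], scores1[~mask]
    c2, k2 = scores2[mask], scores2[~mask]
    if len(c1) == 0 or len(k1) == 0:
        raise ValueError("both classes must be present")
    m, n = len(c1), len(k1)
    a1, a2 = auc(scores1, labels), auc(scores2, labels)
    v10 = np.vstack(
        [_placements(c1, k1)[0], _placements(c2, k2)[0]]
    )  # (2, m)
    v01 = np.vstack([_placements(c1, k1)[1], _placements(c2, k2)[1]])  # (2, n)
    s10 = np.cov(v10) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(v01) if n > 1 else np.zeros((2, 2))
    var_diff = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    var_diff = max(float(var_diff), 0.0)
    diff = a1 - a2
    if var_diff == 0.0:
        z = 0.0
        p = 1.0 if diff == 0.0 else 0.0
    else:
        z = diff / np.sqrt(var_diff)
        p = 2.0 * stats.norm.sf(abs(z))
    return DeLongComparison(
        label1=label1,
        label2=label2,
        auc1=a1,
        auc2=a2,
        var_diff=var_diff,
        z=float(z),
        pvalue=float(p),
    )


def delong_variance(scores, labels) -> float:
    """DeLong variance of a single AUC (used by the jackknife cross-check)."""
    cases, controls = _split_scores(scores, labels)
    v10, v01 = _placements(cases, controls)
    m, n = len(cases), len(controls)
    var10 = np.var(v10, ddof=1) if m > 1 else 0.0
    var01 = np.var(v01, ddof=1) if n > 1 else 0.0
    return float(var10 / m + var01 / n)


def bonferroni(pvalues: Sequence[float], alpha: float = 0.05) -> tuple[list, float]:
    """Bonferroni family control: flags ``p < alpha / m`` and returns the
    adjusted alpha.  An empty list yields no flags."""
    pvalues = list(pvalues)
    m = len(pvalues)
    if m == 0:
        return [], alpha
    for p in pvalues:
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"p-value out of range: {p}")
    thr = alpha / m
    return [p < thr for p in pvalues], thr


def permute_labels(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Shuffle case status while preserving the group proportions exactly."""
    return rng.permutation(np.asarray(y))


def permutation_test(
    statistic: Callable[[np.ndarray], float],
    y,
    n_permutations: int = 1000,
    seed: Optional[int] = None,
    fail_value: float = 0.5,
) -> PermutationResult:
    """Whole-pipeline permutation significance.

    Parameters
    ----------
    statistic : callable
        Maps a label vector to the scalar model-fit statistic (by convention
        the mean testing AUC of the re-run screen + stepwise-CV pipeline).
        Called once on the observed labels and once per permutation.
    y : array-like of {0,1}
        Observed case/control labels; permutations preserve the proportions.
    n_permutations : int
        Number of permuted datasets (B).
    seed : int, optional
    fail_value : float
        Statistic recorded for a permutation on which the pipeline fails
        (e.g. every feature screened out); logged, not raised.

    Returns
    -------
    PermutationResult with empirical ``p = (1 + #{null >= observed}) / (B + 1)``.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be at least 1")
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    observed = float(statistic(y))
    null = np.empty(n_permutations)
    failures = 0
    for b in range(n_permutations):
        yb = permute_labels(y, rng)
        try:
            null[b] = float(statistic(yb))
        except Exception as exc:  # pragma: no cover - defensive
            logger.warning("permutation %d failed: %s", b, exc)
            null[b] = fail_value
            failures += 1
    return PermutationResult(
        n_permutations=n_permutations,
        observed=observed,
        null_statistics=null,
        n_failures=failures,
    )


def distribution_summary(values, convention: str = "median") -> dict:
    """Median, quartiles and outliers of one group's values.

    ``convention='median'`` flags outliers farther than 1.5 x IQR from the
    *median* (the definition used for the box plots here, which is stricter
    than the usual Tukey fences); ``convention='tukey'`` uses the standard
    fences at the quartiles.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise ValueError("empty group")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    if convention == "median":
        lo, hi = med - 1.5 * iqr, med + 1.5 * iqr
    elif convention == "tukey":
        lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    else:
        raise ValueError(f"unknown convention {convention!r}")
    outliers = v[(v < lo) | (v > hi)]
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "iqr": float(iqr),
        "fence_low": float(lo),
        "fence_high": float(hi),
        "outliers": outliers.tolist(),
        "n": int(v.size),
    }


def distribution_summary_by_group(values, groups, convention: str = "median") -> dict:
    """Per-group :func:`distribution_summary`, keyed by group label."""
    import pandas as pd

    s = pd.Series(np.asarray(values, dtype=float))
    g = pd.Series(np.asarray(groups))
    out = {}
    for label, idx in g.groupby(g).groups.items():
        out[label] = distribution_summary(s.loc[idx].to_numpy(), convention=convention)
    return out
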