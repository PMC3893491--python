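"""Platform-specific normalization and transformation.

The GC-TOF platform reports a feature only if it was detected in at least 50%
of the samples of a study design group, and intensities are normalized to the
per-sample sum of the known (identified) metabolites.  The LC-ECA platform
reports concentrations relative to a pooled central CSF sample taken as
100%.  Metabolite values are then natural-log transformed to improve
normality before any model building; remaining missing values are imputed
with half the feature's minimum observed value so that logistic regression
sees complete rows.

Each step exists both as a scikit-learn transformer operating on a
sample-by-feature DataFrame and as a function operating on a
:class:`~metabodiscrim.datatypes.FeatureMatrix` (returning the transformed
matrix plus a :class:`~metabodiscrim.datatypes.PreprocessReport`).
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .datatypes import FeatureMatrix, PreprocessReport


# ---------------------------------------------------------------------------
# transformers


class DetectionFilter(BaseEstimator, TransformerMixin):
    """Drop features detected in fewer than ``threshold`` of the samples of
    every study design group.

    Parameters
    ----------
    threshold : float, default 0.5
        Minimum non-missing fraction.
    rule : {"any", "all"}, default "any"
        "any" keeps a feature whose detection fraction reaches the threshold
        in at least one group (so case-only signals survive); "all" requires
        it in every group.
    """

    def __init__(self, threshold: float = 0.5, rule: str = "any"):
        self.threshold = threshold
        self.rule = rule

    def fit(self, X: pd.DataFrame, y=None):
        if y is None:
            raise ValueError("DetectionFilter requires group labels y")
        X = pd.DataFrame(X)
        groups = pd.Series(np.asarray(y), index=X.index)
        if groups.isna().any():
            raise ValueError("group labels contain missing values")
        fracs = {}
        for g, idx in groups.groupby(groups).groups.items():
            sub = X.loc[idx]
            if len(sub) == 0:
                raise ValueError(f"empty group {g!r}")
            fracs[g] = sub.notna().mean(axis=0)
        frac_df = pd.DataFrame(fracs)  # feature x group
        if self.rule == "any":
            keep = (frac_df >= self.threshold).any(axis=1)
        elif self.rule == "all":
            keep = (frac_df >= self.threshold).all(axis=1)
        else:
            raise ValueError(f"unknown rule {self.rule!r}")
        self.detection_fractions_ = frac_df
        self.kept_features_ = list(X.columns[keep.to_numpy()])
        self.dropped_features_ = {
            f: frac_df.loc[f].to_dict() for f in X.columns[~keep.to_numpy()]
        }
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "kept_features_")
        return pd.DataFrame(X)[self.kept_features_]


class SumNormalizer(BaseEstimator, TransformerMixin):
    """Divide each sample by its summed intensity over the known metabolites.

    Stateless per sample: the divisor is computed from the row being
    transformed (it is a per-sample scaling, not a learned parameter), so the
    known-feature values of every sample sum to 1 afterwards (over the
    non-missing entries entering the divisor).
    """

    def __init__(self, known_features: Optional[list] = None):
        self.known_features = known_features

    def fit(self, X: pd.DataFrame, y=None):
        X = pd.DataFrame(X)
        known = list(X.columns) if self.known_features is None else [
            f for f in self.known_features if f in X.columns
        ]
        if not known:
            raise ValueError("no known features available for sum normalization")
        self.known_features_ = known
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "known_features_")
        X = pd.DataFrame(X)
        divisors = X[self.known_features_].sum(axis=1, skipna=True)
        bad = divisors[~(divisors > 0)].index.tolist()
        if bad:
            raise ValueError(f"zero or undefined known-feature sum for sample(s): {bad}")
        self.divisors_ = divisors
        return X.div(divisors, axis=0)


class PoolRelativeScaler(BaseEstimator, TransformerMixin):
    """Express values as percent of a pooled reference sample (pool = 100)."""

    def __init__(self, pool_reference: Optional[pd.Series] = None):
        self.pool_reference = pool_reference

    def fit(self, X: pd.DataFrame, y=None):
        X = pd.DataFrame(X)
        if self.pool_reference is None:
            raise ValueError("pool_reference is required")
        pool = pd.Series(self.pool_reference).reindex(X.columns)
        missing = pool[pool.isna()].index.tolist()
        if missing:
            raise ValueError(f"missing pool_reference for feature(s): {missing}")
        nonpos = pool[pool <= 0].index.tolist()
        if nonpos:
            raise ValueError(f"non-positive pool_reference for feature(s): {nonpos}")
        self.pool_reference_ = pool.astype(float)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "pool_reference_")
        return pd.DataFrame(X).div(self.pool_reference_, axis=1) * 100.0


class LogTransformer(BaseEstimator, TransformerMixin):
    """Natural-log transform, optionally imputing missing values first.

    ``impute='half_min'`` replaces each feature's missing entries with half
    its minimum observed value (learned at fit time) before taking logs;
    ``impute=None`` leaves missingness in place.
    """

    def __init__(self, impute: Optional[str] = "half_min"):
        self.impute = impute

    def fit(self, X: pd.DataFrame, y=None):
        X = pd.DataFrame(X)
        if self.impute not in (None, "half_min"):
            raise ValueError(f"unknown imputation {self.impute!r}")
        if self.impute == "half_min":
            mins = X.min(axis=0, skipna=True)
            empty = mins[mins.isna()].index.tolist()
            if empty:
                raise ValueError(f"feature(s) with no observed values: {empty}")
            self.fill_values_ = mins / 2.0
        else:
            self.fill_values_ = None
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "fill_values_")
        X = pd.DataFrame(X).astype(float)
        if self.fill_values_ is not None:
            X = X.fillna(self.fill_values_)
        nonpos = X.le(0).any(axis=0)
        if nonpos.any():
            bad = list(X.columns[nonpos.to_numpy()])
            raise ValueError(f"non-positive values; cannot log-transform feature(s): {bad}")
        return np.log(X)


# ---------------------------------------------------------------------------
# FeatureMatrix-level operations


def detection_filter(
    matrix: FeatureMatrix, groups, threshold: float = 0.5, rule: str = "any"
) -> tuple[FeatureMatrix, PreprocessReport]:
    """Apply the per-group detection rule; returns the filtered matrix and a
    report listing each dropped feature with its per-group detection fractions."""
    filt = DetectionFilter(threshold=threshold, rule=rule).fit(matrix.values, groups)
    out = FeatureMatrix(
        matrix.platform,
        filt.transform(matrix.values),
        matrix.known.loc[filt.kept_features_],
        None if matrix.pool_reference is None else matrix.pool_reference.loc[filt.kept_features_],
    )
    report = PreprocessReport(
        platform=matrix.platform,
        transform=f"detection_filter(threshold={threshold}, rule={rule!r})",
        features_dropped=filt.dropped_features_,
    )
    return out, report


def sum_normalize(matrix: FeatureMatrix) -> tuple[FeatureMatrix, PreprocessReport]:
    """Normalize each sample to its summed known-metabolite intensity."""
    known = list(matrix.feature_ids[matrix.known.to_numpy()])
    norm = SumNormalizer(known_features=known).fit(matrix.values)
    values = norm.transform(matrix.values)
    out = FeatureMatrix(matrix.platform, values, matrix.known, matrix.pool_reference)
    report = PreprocessReport(
        platform=matrix.platform,
        transform="sum_normalize(known)",
        divisors=norm.divisors_,
    )
    return out, report


def relative_to_pool(matrix: FeatureMatrix) -> tuple[FeatureMatrix, PreprocessReport]:
    """Scale to percent of the pooled central CSF reference (pool = 100)."""
    if matrix.pool_reference is None:
        raise ValueError("matrix has no pool_reference")
    scaler = PoolRelativeScaler(pool_reference=matrix.pool_reference).fit(matrix.values)
    out = FeatureMatrix(
        matrix.platform, scaler.transform(matrix.values), matrix.known, matrix.pool_reference
    )
    report = PreprocessReport(platform=matrix.platform, transform="relative_to_pool")
    return out, report


def log_transform(
    matrix: FeatureMatrix, impute: Optional[str] = None
) -> tuple[FeatureMatrix, PreprocessReport]:
    """Natural-log transform; missingness preserved unless ``impute`` is set."""
    tr = LogTransformer(impute=impute).fit(matrix.values)
    out = FeatureMatrix(
        matrix.platform, tr.transform(matrix.values), matrix.known, matrix.pool_reference
    )
    report = PreprocessReport(
        platform=matrix.platform, transform=f"log_transform(impute={impute!r})"
    )
    return out, report


def qq_normality_diagnostic(values, plot_path: Optional[str] = None) -> float:
    """Correlation between sample order statistics and normal quantiles.

    Uses probability points ``(i - 0.5) / n``.  A value near 1 indicates the
    sample is consistent with a normal shape; heavy tails pull it down.
    Optionally writes a quantile-quantile plot to ``plot_path``.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    n = v.size
    if n < 3:
        raise ValueError("need at least 3 non-missing values")
    if np.ptp(v) == 0:
        raise ValueError("constant input: correlation undefined")
    order = np.sort(v)
    probs = (np.arange(1, n + 1) - 0.5) / n
    theo = stats.norm.ppf(probs)
    r = float(np.corrcoef(order, theo)[0, 1])
    if plot_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(4, 4))
        ax.scatter(theo, order, s=8)
        ax.set_xlabel("standard normal quantiles")
        ax.set_ylabel("sample quantiles")
        ax.set_title(f"QQ plot (r = {r:.4f})")
        fig.tight_layout()
        fig.savefig(plot_path, dpi=100)
        plt.close(fig)
    return r
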