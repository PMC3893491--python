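"""Univariate tests and the confound screen.

Demographic and drug-use covariates are compared between diagnostic groups
with Fisher's exact test (categorical) and two-sample t tests (continuous).
Metabolite features are then filtered before model building: for every drug
class itself associated with diagnosis, any metabolite associated with that
drug's use (Kruskal-Wallis, p < alpha) is removed, and likewise any
metabolite associated with the ApoE risk group (E3/E4 and E4/E4 high risk).
This filter is deliberately conservative — treatment is nearly exclusive to
cases, so drug-response metabolites can masquerade as disease markers.
Protein analytes are never screened.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .datatypes import DRUG_CLASSES, ScreenReport


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 count table.

    The two-sided p sums hypergeometric probabilities of all tables with the
    observed margins whose probability does not exceed the observed table's.

    Returns ``(pvalue, odds_ratio)`` with the conditional (sample) odds ratio.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if not np.issubdtype(t.dtype, np.integer):
        if not np.allclose(t, np.round(t)):
            raise ValueError("counts must be integers")
        t = np.round(t).astype(int)
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
        raise ValueError("both margins must be positive")
    odds, p = stats.fisher_exact(t, alternative="two-sided")
    return float(p), float(odds)


def two_sample_t(x, y, equal_var: bool = False) -> tuple[float, float, float]:
    """Two-sample t test; Welch (unequal variance) by default.

    Returns ``(t, df, pvalue)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x, y = x[~np.isnan(x)], y[~np.isnan(y)]
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 non-missing values")
    if np.var(x) == 0 and np.var(y) == 0 and np.mean(x) == np.mean(y):
        return 0.0, float(len(x) + len(y) - 2), 1.0
    res = stats.ttest_ind(x, y, equal_var=equal_var)
    return float(res.statistic), float(res.df), float(res.pvalue)


def kruskal_wallis(values, groups) -> tuple[float, float]:
    """Kruskal-Wallis H test (midranks, tie-corrected), chi-square p.

    Returns ``(H, pvalue)``.  With all values identical the tie correction
    degenerates; H is taken as 0 by convention.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    samples = [values[groups == g] for g in pd.unique(groups)]
    samples = [s[~np.isnan(s)] for s in samples]
    if len(samples) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(s) == 0 for s in samples):
        raise ValueError("every group needs at least 1 value")
    allv = np.concatenate(samples)
    if np.ptp(allv) == 0:
        return 0.0, 1.0
    h, p = stats.kruskal(*samples)
    return float(h), float(p)


def kruskal_wallis_matrix(values: np.ndarray, flag: np.ndarray) -> np.ndarray:
    """Two-group Kruskal-Wallis p-values for every column of ``values``.

    Vectorized midrank computation with per-column tie correction; used to
    screen hundreds of metabolites against a drug flag in one pass.  Agrees
    with :func:`kruskal_wallis` column by column.
    """
    V = np.asarray(values, dtype=float)
    flag = np.asarray(flag, dtype=bool)
    n, F = V.shape
    n1 = int(flag.sum())
    n2 = n - n1
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    ranks = stats.rankdata(V, axis=0)
    r1 = ranks[flag].mean(axis=0)
    r2 = ranks[~flag].mean(axis=0)
    mid = (n + 1) / 2.0
    h = 12.0 / (n * (n + 1)) * (n1 * (r1 - mid) ** 2 + n2 * (r2 - mid) ** 2)
    # tie correction per column
    Vs = np.sort(V, axis=0)
    has_ties = (np.diff(Vs, axis=0) == 0).any(axis=0)
    if has_ties.any():
        corr = np.ones(F)
        for j in np.flatnonzero(has_ties):
            _, counts = np.unique(V[:, j], return_counts=True)
            corr[j] = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
        with np.errstate(divide="ignore", invalid="ignore"):
            h = np.where(corr > 0, h / corr, 0.0)
    return stats.chi2.sf(h, df=1)


def pearson_correlation(x, y) -> tuple[float, float]:
    """Pearson r with the t-transform p on n-2 degrees of freedom.

    Returns ``(r, pvalue)``; pairs with a missing member are dropped.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    mask = ~(np.isnan(x) | np.isnan(y))
    x, y = x[mask], y[mask]
    if len(x) < 3:
        raise ValueError("need at least 3 paired non-missing values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: correlation undefined")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def cohort_characteristics(cohort: pd.DataFrame) -> pd.DataFrame:
    """Demographics/clinical comparison table between diagnostic groups.

    Continuous covariates (age, education, MMSE) by Welch t test; sex, race
    and the seven drug-class flags by Fisher's exact test.
    """
    case = cohort["diagnosis"].isin(["AD", "case", 1, True])
    rows = []
    for col in ("age", "education", "mmse"):
        t, df, p = two_sample_t(cohort.loc[case, col], cohort.loc[~case, col])
        rows.append({"covariate": col, "test": "t", "statistic": t, "pvalue": p})
    cat_cols = []
    if "sex" in cohort:
        cat_cols.append(("sex", cohort["sex"].isin(["M", "male", 1, True])))
    if "race" in cohort:
        top = cohort["race"].mode().iloc[0]
        cat_cols.append(("race", cohort["race"] == top))
    for drug in DRUG_CLASSES:
        if drug in cohort:
            cat_cols.append((drug, cohort[drug].astype(bool)))
    for name, flag in cat_cols:
        tab = [
            [int((flag & case).sum()), int((~flag & case).sum())],
            [int((flag & ~case).sum()), int((~flag & ~case).sum())],
        ]
        try:
            p, odds = fisher_exact_2x2(tab)
            stat = odds
        except ValueError:
            p, stat = np.nan, np.nan
        rows.append({"covariate": name, "test": "fisher", "statistic": stat, "pvalue": p})
    return pd.DataFrame(rows)


class ConfoundScreen(BaseEstimator, TransformerMixin):
    """Remove features associated with disease-linked drug use or ApoE risk.

    Fitting identifies the drug classes associated with diagnosis (Fisher
    exact, p < alpha), tests every non-protected feature against each such
    drug's flag and against the ApoE risk grouping (two-group Kruskal-Wallis)
    and marks any feature with any p < alpha for removal.  Drugs whose flag
    is constant across the cohort are skipped with a warning.

    Parameters
    ----------
    drug_flags : DataFrame of booleans, samples x drug classes.
    apoe_risk : array-like of booleans (high risk), or None to skip.
    alpha : float, default 0.05 — nominal screening level.
    protected : sequence of feature IDs never removed (protein analytes).
    union_drugs : bool, default False
        Test against the union ("any qualifying drug") flag instead of each
        drug separately.

    Attributes
    ----------
    report_ : ScreenReport
    kept_features_ : feature IDs surviving the screen (protected included).
    """

    def __init__(
        self,
        drug_flags: Optional[pd.DataFrame] = None,
        apoe_risk=None,
        alpha: float = 0.05,
        protected: Sequence[str] = (),
        union_drugs: bool = False,
    ):
        self.drug_flags = drug_flags
        self.apoe_risk = apoe_risk
        self.alpha = alpha
        self.protected = protected
        self.union_drugs = union_drugs

    def fit(self, X: pd.DataFrame, y=None):
        if y is None:
            raise ValueError("ConfoundScreen requires diagnosis labels y")
        X = pd.DataFrame(X)
        y = np.asarray(pd.Series(y).isin(["AD", "case", 1, True]), dtype=bool)
        protected = [f for f in self.protected if f in X.columns]
        testable = [f for f in X.columns if f not in set(protected)]
        V = np.asarray(X[testable], dtype=float)

        drug_rows = []
        qualifying = []
        skipped = []
        if self.drug_flags is not None:
            flags = pd.DataFrame(self.drug_flags).astype(bool)
            for drug in flags.columns:
                f = flags[drug].to_numpy()
                if f.all() or (~f).all():
                    skipped.append(drug)
                    warnings.warn(f"drug flag {drug!r} is constant; skipped in screen")
                    continue
                tab = [
                    [int((f & y).sum()), int((~f & y).sum())],
                    [int((f & ~y).sum()), int((~f & ~y).sum())],
                ]
                p, odds = fisher_exact_2x2(tab)
                drug_rows.append(
                    {"covariate": drug, "test": "fisher", "statistic": odds, "pvalue": p}
                )
                if p < self.alpha:
                    qualifying.append(drug)
        else:
            flags = None

        removed: dict[str, str] = {}
        drug_p = {}
        if flags is not None and qualifying and testable:
            if self.union_drugs:
                union = flags[qualifying].any(axis=1).to_numpy()
                drug_p["any_qualifying_drug"] = kruskal_wallis_matrix(V, union)
            else:
                for drug in qualifying:
                    drug_p[drug] = kruskal_wallis_matrix(V, flags[drug].to_numpy())
            for pvec in drug_p.values():
                for f, p in zip(testable, pvec):
                    if p < self.alpha and f not in removed:
                        removed[f] = "drug"
        drug_pvalues = pd.DataFrame(drug_p, index=testable)

        if self.apoe_risk is not None and testable:
            risk = np.asarray(pd.Series(self.apoe_risk), dtype=bool)
            apoe_p = pd.Series(kruskal_wallis_matrix(V, risk), index=testable)
            for f, p in apoe_p.items():
                if p < self.alpha and f not in removed:
                    removed[f] = "apoe"
        else:
            apoe_p = pd.Series(np.nan, index=testable)

        self.report_ = ScreenReport(
            covariate_tests=pd.DataFrame(drug_rows),
            disease_associated_drugs=qualifying,
            drug_pvalues=drug_pvalues,
            apoe_pvalues=apoe_p,
            removed=removed,
            skipped_drugs=skipped,
            alpha=self.alpha,
        )
        self.kept_features_ = [f for f in X.columns if f not in removed]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "kept_features_")
        return pd.DataFrame(X)[self.kept_features_]


def screen_confounds(
    features: pd.DataFrame,
    diagnosis,
    drug_flags: Optional[pd.DataFrame] = None,
    apoe_risk=None,
    alpha: float = 0.05,
    protected: Sequence[str] = (),
    union_drugs: bool = False,
) -> tuple[ScreenReport, pd.DataFrame]:
    """Functional wrapper over :class:`ConfoundScreen`.

    Returns the screen report and the reduced feature table.
    """
    screen = ConfoundScreen(
        drug_flags=drug_flags,
        apoe_risk=apoe_risk,
        alpha=alpha,
        protected=protected,
        union_drugs=union_drugs,
    ).fit(features, diagnosis)
    return screen.report_, screen.transform(features)
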