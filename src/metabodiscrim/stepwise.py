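"""Forward stepwise logistic regression under BIC, with cross-validation
consistency selection.

The model-building engine works in two layers:

* :class:`StepwiseLogisticBIC` — a scikit-learn classifier that runs a
  forward-only stepwise search: starting from the intercept-only model, each
  step fits every single-feature addition and accepts the one with the lowest
  BIC, provided it is strictly lower than the current model's BIC.
* :class:`ConsistencyStepwiseCV` — repeats the stepwise search on every 4/5
  training split of a stratified K-fold partition, records per-fold training
  and held-out testing AUC and which variables each fold selected, and takes
  as the final variable set those selected in a majority of folds (with a
  maximal-count fallback).  The final model is refit on all samples for
  coefficient reporting, but the headline AUC remains the cross-validated
  mean *testing* AUC.

Confound screening is expected to have happened before these estimators see
the data; it is deliberately not re-run inside the folds (see the
whole-pipeline permutation test for how significance accounts for the full
procedure).
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from .datatypes import CVRun, LogisticModel, ModelSummary
from .evaluate import auc, sens_spec
from .logistic import fit_logistic, scan_candidates


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=float)
    return pd.DataFrame(X, columns=[f"x{j}" for j in range(X.shape[1])])


def _check_y(y) -> np.ndarray:
    y = np.asarray(y)
    if y.dtype.kind in "OUSb":
        # map two labels to 0/1 by sorted order
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValueError("y must have exactly two classes")
        y = (y == classes[1]).astype(float)
    y = np.asarray(y, dtype=float)
    if not np.isin(np.unique(y), (0.0, 1.0)).all():
        raise ValueError("y must be binary")
    return y


def forward_stepwise_bic(
    X_pool: pd.DataFrame,
    y,
    max_features: Optional[int] = None,
    tol: float = 1e-8,
) -> LogisticModel:
    """Forward stepwise search over a candidate pool, scored by BIC.

    Ties in BIC are broken deterministically by feature-ID order.  Candidate
    fits flagged for separation are skipped.  An empty pool returns the
    intercept-only model.
    """
    X_pool = _as_frame(X_pool)
    y = _check_y(y)
    n = len(y)
    logn = np.log(n)
    features = sorted(X_pool.columns)
    M = np.asarray(X_pool[features], dtype=float)
    if np.isnan(M).any():
        raise ValueError("candidate pool contains missing values; impute or filter first")
    # search on centered columns (log-likelihood and BIC are invariant; the
    # working intercept stays O(1), see fit_logistic); refit at original scale
    M = M - M.mean(axis=0)
    Xc = pd.DataFrame(M, columns=features)

    current = fit_logistic(None, y)
    selected: list[int] = []  # column indices into `features`
    remaining = list(range(len(features)))
    if max_features is None:
        max_features = len(features)
    while remaining and len(selected) < max_features:
        S = np.column_stack([np.ones(n)] + [M[:, j] for j in selected])
        beta0 = np.concatenate([[current.intercept], list(current.coef.values())])
        C = M[:, remaining]
        # the scan only ranks candidates by BIC; a looser gradient tolerance
        # suffices (log-likelihood error is quadratic in the gradient) and the
        # accepted model is polished to full tolerance below
        ll, beta, ok = scan_candidates(S, C, y, beta0, tol=max(tol, 1e-5))
        k_new = len(selected) + 2  # intercept + selected + candidate
        bics = -2.0 * ll + k_new * logn
        bics[~ok] = np.inf
        best = int(np.argmin(bics))  # first minimum = lowest feature ID (sorted order)
        if not np.isfinite(bics[best]) or bics[best] >= current.bic:
            break
        j = remaining[best]
        selected.append(j)
        remaining.pop(best)
        b = beta[best]
        current = LogisticModel(
            intercept=float(b[0]),
            coef={features[i]: float(v) for i, v in zip(selected, b[1:])},
            loglik=float(ll[best]),
            n=n,
        )
        # polish the accepted model to full tolerance
        current = fit_logistic(Xc, y, features=[features[i] for i in selected], tol=tol)
    if selected:
        current = fit_logistic(X_pool, y, features=[features[i] for i in selected], tol=tol)
    return current


def make_folds(y, n_splits: int = 5, seed: Optional[int] = None) -> np.ndarray:
    """Stratified K-fold assignment: one fold index per sample.

    Class proportions per fold are within one sample of the overall
    proportion.  Seeded and reproducible.
    """
    y = _check_y(y)
    counts = np.bincount(y.astype(int))
    if (counts < n_splits).any():
        raise ValueError(f"each class must have at least {n_splits} samples")
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    assignment = np.empty(len(y), dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros((len(y), 1)), y)):
        assignment[test_idx] = fold
    return assignment


def consistency_select(selection_counts: dict, n_splits: int = 5, threshold: int = 3) -> list:
    """Variables selected in at least ``threshold`` folds; if none reach the
    threshold, fall back to the feature(s) with the maximal nonzero count
    (ties retained jointly)."""
    counts = {f: c for f, c in selection_counts.items() if c > 0}
    if not counts:
        return []
    hit = sorted(f for f, c in counts.items() if c >= threshold)
    if hit:
        return hit
    top = max(counts.values())
    return sorted(f for f, c in counts.items() if c == top)


class StepwiseLogisticBIC(BaseEstimator, ClassifierMixin):
    """Forward stepwise logistic regression classifier scored by BIC.

    Parameters
    ----------
    max_features : int or None
        Cap on the number of variables entered; None means no cap.
    tol : float
        Gradient tolerance of the IRLS fits.

    Attributes
    ----------
    selected_features_ : list of feature IDs entered, in entry order of ID.
    model_ : LogisticModel with coefficients, log-likelihood and BIC.
    bic_ : float
    classes_ : ndarray of the two class labels.
    """

    def __init__(self, max_features: Optional[int] = None, tol: float = 1e-8):
        self.max_features = max_features
        self.tol = tol

    def fit(self, X, y):
        X = _as_frame(X)
        yv = _check_y(y)
        self.classes_ = np.unique(np.asarray(y))
        self.n_features_in_ = X.shape[1]
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.model_ = forward_stepwise_bic(X, yv, max_features=self.max_features, tol=self.tol)
        self.selected_features_ = sorted(self.model_.coef)
        self.bic_ = self.model_.bic
        return self

    def decision_function(self, X):
        check_is_fitted(self, "model_")
        return self.model_.linear_predictor(_as_frame(X))

    def predict_proba(self, X):
        check_is_fitted(self, "model_")
        p1 = self.model_.predict_proba(_as_frame(X))
        return np.column_stack([1 - p1, p1])

    def predict(self, X):
        p = self.predict_proba(X)[:, 1]
        return self.classes_[(p >= 0.5).astype(int)]


class ConsistencyStepwiseCV(BaseEstimator, ClassifierMixin):
    """Stepwise-BIC model building under stratified K-fold cross-validation
    with consistency-based final variable selection.

    Parameters
    ----------
    n_splits : int, default 5
        Number of cross-validation folds.
    consistency_threshold : int, default 3
        Minimum number of folds a variable must be selected in (majority of
        5); if no variable reaches it, the maximal-count variables are taken.
    random_state : int or None
        Seed for the fold partition.
    threshold_rule : {"half", "youden"}
        Classification cutoff on pooled out-of-fold probabilities used for
        the reported sensitivity/specificity.

    Attributes
    ----------
    cv_run_ : CVRun — folds, per-fold models, train/test AUCs, selection counts.
    selected_features_ : consistency-selected variable set.
    mean_test_auc_ : float — average held-out AUC across folds (the headline
        discrimination estimate; the full-data refit's apparent AUC is not
        reported).
    final_model_ : LogisticModel refit on all samples over the selected set
        (ridge-stabilized for reporting if it separates).
    oof_proba_ : pooled out-of-fold predicted probabilities.
    sensitivity_, specificity_ : at the chosen cutoff on oof_proba_.
    """

    def __init__(
        self,
        n_splits: int = 5,
        consistency_threshold: int = 3,
        random_state: Optional[int] = None,
        max_features: Optional[int] = None,
        threshold_rule: str = "half",
    ):
        self.n_splits = n_splits
        self.consistency_threshold = consistency_threshold
        self.random_state = random_state
        self.max_features = max_features
        self.threshold_rule = threshold_rule

    def fit(self, X, y):
        X = _as_frame(X)
        yv = _check_y(y)
        self.classes_ = np.unique(np.asarray(y))
        self.n_features_in_ = X.shape[1]
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        folds = make_folds(yv, self.n_splits, self.random_state)
        counts = {f: 0 for f in X.columns}
        fold_models, train_aucs, test_aucs = [], [], []
        oof = np.full(len(yv), np.nan)
        for fold in range(self.n_splits):
            test_mask = folds == fold
            Xtr, ytr = X.loc[~test_mask], yv[~test_mask]
            Xte, yte = X.loc[test_mask], yv[test_mask]
            model = forward_stepwise_bic(Xtr, ytr, max_features=self.max_features)
            fold_models.append(model)
            for f in model.coef:
                counts[f] += 1
            ptr = model.predict_proba(Xtr)
            pte = model.predict_proba(Xte)
            train_aucs.append(auc(ptr, ytr))
            test_aucs.append(auc(pte, yte))
            oof[test_mask] = pte
        self.cv_run_ = CVRun(
            fold_assignment=folds,
            fold_models=fold_models,
            train_aucs=train_aucs,
            test_aucs=test_aucs,
            selection_counts=counts,
            oof_proba=oof,
        )
        self.selected_features_ = consistency_select(
            counts, self.n_splits, self.consistency_threshold
        )
        self.mean_test_auc_ = self.cv_run_.mean_test_auc
        self.oof_proba_ = oof
        self.sensitivity_, self.specificity_ = sens_spec(oof, yv, rule=self.threshold_rule)
        final = fit_logistic(X, yv, features=self.selected_features_)
        if final.separated:
            # tiny ridge stabilizes reported coefficients only
            final = fit_logistic(X, yv, features=self.selected_features_, ridge=1e-6)
            final.separated = True
        self.final_model_ = final
        return self

    def summary(self, label: str = "") -> ModelSummary:
        check_is_fitted(self, "cv_run_")
        return ModelSummary(
            label=label,
            selected_features=list(self.selected_features_),
            mean_test_auc=self.mean_test_auc_,
            sensitivity=self.sensitivity_,
            specificity=self.specificity_,
            final_model=self.final_model_,
            cv_run=self.cv_run_,
        )

    def decision_function(self, X):
        check_is_fitted(self, "final_model_")
        return self.final_model_.linear_predictor(_as_frame(X))

    def predict_proba(self, X):
        check_is_fitted(self, "final_model_")
        p1 = self.final_model_.predict_proba(_as_frame(X))
        return np.column_stack([1 - p1, p1])

    def predict(self, X):
        p = self.predict_proba(X)[:, 1]
        return self.classes_[(p >= 0.5).astype(int)]


def cross_validated_selection(
    X_pool,
    y,
    n_splits: int = 5,
    seed: Optional[int] = None,
    consistency_threshold: int = 3,
) -> CVRun:
    """Functional wrapper over :class:`ConsistencyStepwiseCV`; returns the CVRun."""
    est = ConsistencyStepwiseCV(
        n_splits=n_splits, consistency_threshold=consistency_threshold, random_state=seed
    ).fit(X_pool, y)
    return est.cv_run_


def fit_final_model(
    X, y, selected: Sequence[str], label: str = "", cv_run: Optional[CVRun] = None
) -> tuple[LogisticModel, ModelSummary]:
    """Refit on all samples over the consistency set, for coefficient reporting.

    The summary's AUC is the cross-validated mean testing AUC (0.5 when no
    CVRun or empty set), never the refit's apparent AUC.
    """
    X = _as_frame(X)
    yv = _check_y(y)
    selected = sorted(selected)
    model = fit_logistic(X, yv, features=selected)
    if model.separated:
        model = fit_logistic(X, yv, features=selected, ridge=1e-6)
        model.separated = True
    if cv_run is not None:
        oof = cv_run.oof_proba
        sens, spec = sens_spec(oof, yv)
        mean_auc = cv_run.mean_test_auc
    elif selected:
        sens = spec = float("nan")
        mean_auc = float("nan")
    else:
        sens, spec, mean_auc = 0.5, 0.5, 0.5
    if not selected and cv_run is None:
        mean_auc, sens, spec = 0.5, 0.5, 0.5
    summary = ModelSummary(
        label=label,
        selected_features=list(selected),
        mean_test_auc=mean_auc,
        sensitivity=sens,
        specificity=spec,
        final_model=model,
        cv_run=cv_run,
    )
    return model, summary
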