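"""Logistic fitting, BIC bookkeeping, forward stepwise search and
cross-validation consistency selection."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from itertools import combinations

from metabodiscrim.datatypes import LogisticModel
from metabodiscrim.logistic import bic, fit_logistic, scan_candidates
from metabodiscrim.stepwise import (
    ConsistencyStepwiseCV,
    StepwiseLogisticBIC,
    consistency_select,
    forward_stepwise_bic,
    make_folds,
)


def logistic_data(rng, n=78, p=5, beta=None, intercept=0.0):
    X = pd.DataFrame(rng.standard_normal((n, p)), columns=[f"f{j:02d}" for j in range(p)])
    eta = intercept + (0 if beta is None else X.to_numpy() @ np.asarray(beta))
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    if y.sum() in (0, n):
        y[:2] = [0, 1]
    return X, y


class TestFitLogistic:
    def test_intercept_only_closed_form(self):
        m = fit_logistic(None, np.r_[np.ones(5), np.zeros(5)])
        assert np.isclose(m.intercept, 0.0, atol=1e-8)
        assert np.isclose(m.loglik, 10 * np.log(0.5), atol=1e-10)
        assert np.isclose(m.bic, -2 * 10 * np.log(0.5) + np.log(10), atol=1e-8)

    def test_intercept_only_unbalanced_closed_form(self):
        y = np.r_[np.ones(40), np.zeros(38)]
        m = fit_logistic(None, y)
        expected_ll = 40 * np.log(40 / 78) + 38 * np.log(38 / 78)
        assert np.isclose(m.loglik, expected_ll, atol=1e-10)
        assert np.isclose(m.bic, -2 * expected_ll + np.log(78), atol=1e-8)

    def test_matches_statsmodels_oracle(self, rng):
        for _ in range(5):
            X, y = logistic_data(rng, n=60, p=3, beta=[1.0, -0.5, 0.0])
            ours = fit_logistic(X, y)
            ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
            assert np.isclose(ours.loglik, ref.llf, atol=1e-8)
            assert np.isclose(ours.intercept, ref.params.iloc[0], atol=1e-6)
            assert np.allclose(list(ours.coef.values()), ref.params.iloc[1:], atol=1e-6)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic(None, np.ones(10))

    def test_perfect_separation_flagged(self, rng):
        X = pd.DataFrame({"x": rng.standard_normal(40)})
        y = (X["x"] > 0).astype(float)
        m = fit_logistic(X, y)
        assert m.separated

    def test_null_likelihood_ratio_behaviour(self, rng):
        """With y independent of X, the fitted log-likelihood rarely improves
        on the intercept-only model by more than a chi2-scale amount."""
        ok = 0
        for _ in range(40):
            X, y = logistic_data(rng, n=78, p=1)
            m0 = fit_logistic(None, y)
            m1 = fit_logistic(X, y)
            ok += (m1.loglik - m0.loglik) < 2.0  # LRT/2 < 2 ~ chi2(1) < 4
        assert ok >= 35

    def test_bic_identity(self):
        m = LogisticModel(intercept=0.1, coef={"a": 1.0, "b": 2.0}, loglik=-20.0, n=50)
        assert np.isclose(bic(m), 40.0 + 3 * np.log(50))
        m2 = LogisticModel(intercept=0.1, coef={"a": 1.0, "b": 2.0, "c": 0.0}, loglik=-20.0, n=50)
        assert np.isclose(m2.bic - m.bic, np.log(50))


class TestScan:
    def test_scan_matches_individual_fits(self, rng):
        X, y = logistic_data(rng, n=50, p=8, beta=[1.5] + [0] * 7)
        base = fit_logistic(None, y)
        ll, beta, ok = scan_candidates(
            np.ones((50, 1)), X.to_numpy(), y, np.array([base.intercept])
        )
        for j, col in enumerate(X.columns):
            ref = fit_logistic(X, y, features=[col])
            if ok[j] and not ref.separated:
                assert np.isclose(ll[j], ref.loglik, atol=1e-5)


def exhaustive_best_bic(X, y, max_size=None):
    """Independent oracle: best BIC over all subsets."""
    cols = list(X.columns)
    best = fit_logistic(None, y).bic
    best_set = frozenset()
    max_size = len(cols) if max_size is None else max_size
    for k in range(1, max_size + 1):
        for sub in combinations(cols, k):
            m = fit_logistic(X, y, features=list(sub))
            if not m.separated and m.bic < best - 1e-9:
                best, best_set = m.bic, frozenset(sub)
    return best, best_set


class TestForwardStepwise:
    def test_empty_pool_returns_intercept_only(self):
        m = forward_stepwise_bic(pd.DataFrame(index=range(10)), np.r_[np.ones(5), np.zeros(5)])
        assert m.coef == {}

    def test_agrees_with_exhaustive_search_on_small_pools(self, rng):
        """With one strong signal among 6 candidates, the greedy forward path
        finds the globally best-BIC subset in nearly all replicates."""
        agree = 0
        reps = 40
        for _ in range(reps):
            X, y = logistic_data(rng, n=60, p=6, beta=[2.0, 0, 0, 0, 0, 0])
            fwd = forward_stepwise_bic(X, y)
            _, best_set = exhaustive_best_bic(X, y)
            agree += frozenset(fwd.coef) == best_set
        assert agree / reps >= 0.95

    def test_null_selectivity_matches_closed_form(self, rng):
        """Intercept-only rate with 20 null candidates at n=78 is governed by
        the max of ~independent chi2(1) likelihood-ratio statistics versus the
        ln(n) BIC penalty: P(all chi2 < ln 78) = (1 - P(chi2 > 4.356))^20 ~ 0.47."""
        from scipy import stats

        reps = 80
        none_selected = 0
        for _ in range(reps):
            X, y = logistic_data(rng, n=78, p=20)
            m = forward_stepwise_bic(X, y)
            none_selected += len(m.coef) == 0
        expected = (1 - stats.chi2.sf(np.log(78), df=1)) ** 20
        half = 2.576 * np.sqrt(expected * (1 - expected) / reps)
        assert abs(none_selected / reps - expected) < half + 0.05

    def test_recovers_planted_pair_among_nulls(self, rng):
        hits = 0
        reps = 20
        for _ in range(reps):
            X, y = logistic_data(rng, n=78, p=30, beta=[1.5, 1.5] + [0] * 28)
            m = forward_stepwise_bic(X, y)
            hits += {"f00", "f01"} <= set(m.coef)
        assert hits / reps > 0.5

    def test_row_and_column_order_invariance(self, rng):
        X, y = logistic_data(rng, n=60, p=8, beta=[1.5, -1.0] + [0] * 6)
        m1 = forward_stepwise_bic(X, y)
        perm = rng.permutation(60)
        cols = list(rng.permutation(X.columns))
        m2 = forward_stepwise_bic(X.iloc[perm][cols], y[perm])
        assert set(m1.coef) == set(m2.coef)
        assert np.isclose(m1.bic, m2.bic, atol=1e-6)


class TestFolds:
    def test_stratification_arithmetic(self):
        y = np.r_[np.ones(40), np.zeros(38)]
        folds = make_folds(y, 5, seed=3)
        for f in range(5):
            mask = folds == f
            assert y[mask].sum() == 8
            assert (~y[mask].astype(bool)).sum() in (7, 8)

    def test_partition_and_determinism(self):
        y = np.r_[np.ones(20), np.zeros(20)]
        f1 = make_folds(y, 5, seed=9)
        f2 = make_folds(y, 5, seed=9)
        assert (f1 == f2).all()
        assert set(f1) == set(range(5))
        assert len(f1) == 40

    def test_small_class_rejected(self):
        with pytest.raises(ValueError):
            make_folds(np.r_[np.ones(3), np.zeros(20)], 5, seed=0)


class TestConsistencySelect:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ({"A": 5, "B": 5, "C": 1}, ["A", "B"]),
            ({"A": 0, "B": 0}, []),
            ({"A": 2, "B": 2, "C": 1}, ["A", "B"]),  # maximal-count fallback
            ({"A": 3, "B": 2}, ["A"]),
        ],
    )
    def test_rules(self, counts, expected):
        assert consistency_select(counts, 5, 3) == expected


class TestConsistencyStepwiseCV:
    def test_planted_signal_reaches_full_consistency(self, rng):
        """Two strong planted features are selected by every fold's stepwise
        model (5/5 cross-validation consistency) in most replicates."""
        full = 0
        reps = 10
        for i in range(reps):
            X, y = logistic_data(rng, n=78, p=20, beta=[2.0, 2.0] + [0] * 18)
            est = ConsistencyStepwiseCV(random_state=i).fit(X, y)
            counts = est.cv_run_.selection_counts
            full += counts["f00"] == 5 and counts["f01"] == 5
        assert full / reps > 0.5

    def test_training_auc_exceeds_testing_auc_on_average(self, rng):
        tr, te = [], []
        for i in range(8):
            X, y = logistic_data(rng, n=78, p=15, beta=[1.0] + [0] * 14)
            est = ConsistencyStepwiseCV(random_state=i).fit(X, y)
            tr += est.cv_run_.train_aucs
            te += est.cv_run_.test_aucs
        assert np.mean(tr) > np.mean(te)

    def test_pure_noise_pool_tests_at_chance(self, rng):
        aucs = []
        for i in range(15):
            X, y = logistic_data(rng, n=78, p=10)
            est = ConsistencyStepwiseCV(random_state=i).fit(X, y)
            aucs.append(est.mean_test_auc_)
        se = np.std(aucs, ddof=1) / np.sqrt(len(aucs))
        assert abs(np.mean(aucs) - 0.5) < 3 * max(se, 0.02)

    def test_final_refit_signs_match_planted_effects(self, rng):
        good = 0
        reps = 12
        for i in range(reps):
            X, y = logistic_data(rng, n=78, p=10, beta=[2.0, -2.0] + [0] * 8)
            est = ConsistencyStepwiseCV(random_state=i).fit(X, y)
            c = est.final_model_.coef
            good += c.get("f00", 0) > 0 and c.get("f01", 1) < 0
        assert good / reps >= 0.75

    def test_empty_selection_gives_chance_summary(self):
        """A constant-probability model has AUC 0.5 by the midrank convention."""
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.standard_normal((40, 1)), columns=["f"])
        y = np.r_[np.ones(20), np.zeros(20)]
        # force intercept-only by offering no informative candidates at cap 0
        est = ConsistencyStepwiseCV(random_state=0, max_features=0).fit(X, y)
        assert est.selected_features_ == []
        assert np.isclose(est.mean_test_auc_, 0.5)

    def test_sklearn_clone_and_get_params(self):
        from sklearn.base import clone

        est = ConsistencyStepwiseCV(n_splits=4, random_state=7)
        params = est.get_params()
        assert params["n_splits"] == 4
        est2 = clone(est)
        assert est2.get_params() == params

    def test_stepwise_classifier_predicts(self, rng):
        X, y = logistic_data(rng, n=60, p=5, beta=[2.0, 0, 0, 0, 0])
        est = StepwiseLogisticBIC().fit(X, y)
        proba = est.predict_proba(X)
        assert proba.shape == (60, 2)
        assert np.allclose(proba.sum(axis=1), 1.0)
        assert (est.predict(X) == (proba[:, 1] >= 0.5)).mean() == 1.0
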