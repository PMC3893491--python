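"""Univariate tests against hand computations and brute-force oracles, and
the drug/ApoE confound screen."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from metabodiscrim import GeneratorConfig, generate_cohort
from metabodiscrim.datatypes import DRUG_CLASSES
from metabodiscrim.univariate import (
    ConfoundScreen,
    cohort_characteristics,
    fisher_exact_2x2,
    kruskal_wallis,
    kruskal_wallis_matrix,
    pearson_correlation,
    screen_confounds,
    two_sample_t,
)


def fisher_p_by_enumeration(table):
    """Independent oracle: sum hypergeometric probabilities over the support."""
    a, b = table[0]
    c, d = table[1]
    r1, c1, n = a + b, a + c, a + b + c + d
    rv = stats.hypergeom(n, r1, c1)
    p_obs = rv.pmf(a)
    support = np.arange(max(0, c1 - (n - r1)), min(r1, c1) + 1)
    probs = rv.pmf(support)
    return float(probs[probs <= p_obs * (1 + 1e-9)].sum())


class TestFisher:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ([[6, 34], [0, 38]], 0.026),  # memantine use by diagnosis
            ([[1, 39], [5, 33]], 0.104),  # corticosteroids
            ([[12, 28], [8, 30]], 0.441),  # antidepressants
            ([[5, 35], [5, 33]], 1.00),  # anxiolytics
            ([[5, 5], [5, 5]], 1.0),
        ],
    )
    def test_known_tables(self, table, expected):
        p, _ = fisher_exact_2x2(table)
        assert np.isclose(p, expected, rtol=0, atol=5e-4 if expected < 1 else 1e-12)

    def test_matches_hypergeometric_enumeration(self, rng):
        for _ in range(60):
            t = rng.integers(0, 16, size=(2, 2))
            if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
                continue
            p, _ = fisher_exact_2x2(t)
            assert np.isclose(p, fisher_p_by_enumeration(t), atol=1e-10)

    @pytest.mark.parametrize("bad", [[[1, -1], [2, 3]], [[0.5, 1], [2, 3]], [[0, 0], [1, 2]]])
    def test_invalid_tables_rejected(self, bad):
        with pytest.raises(ValueError):
            fisher_exact_2x2(bad)


class TestTwoSampleT:
    def test_identical_vectors(self):
        t, df, p = two_sample_t([1, 2, 3], [1, 2, 3])
        assert t == 0.0 and p == 1.0

    def test_welch_hand_computation(self):
        t, df, p = two_sample_t([1, 2, 3], [2, 3, 4])
        assert np.isclose(abs(t), 1.224745, atol=1e-5)
        assert np.isclose(df, 4.0)
        assert np.isclose(p, 0.2879, atol=1e-3)

    def test_shift_invariance(self, rng):
        x, y = rng.random(10), rng.random(12)
        t1, _, _ = two_sample_t(x, y)
        t2, _, _ = two_sample_t(x + 5.0, y + 5.0)
        assert np.isclose(t1, t2)

    def test_insufficient_data(self):
        with pytest.raises(ValueError):
            two_sample_t([1.0], [1, 2, 3])


class TestKruskalWallis:
    def test_hand_computation(self):
        h, p = kruskal_wallis([1, 2, 3, 4, 5, 6], [0, 0, 0, 1, 1, 1])
        assert np.isclose(h, 3.857142857, atol=1e-6)
        assert np.isclose(p, 0.0495, atol=1e-3)

    def test_all_identical_values(self):
        h, p = kruskal_wallis([2, 2, 2, 2], [0, 0, 1, 1])
        assert h == 0.0 and p == 1.0

    def test_single_group_errors(self):
        with pytest.raises(ValueError):
            kruskal_wallis([1, 2, 3], [0, 0, 0])

    def test_equals_squared_mann_whitney_z(self, rng):
        """Two-group H equals the square of the standardized Mann-Whitney
        statistic on untied data."""
        for _ in range(10):
            x = rng.standard_normal(8)
            y = rng.standard_normal(11)
            h, _ = kruskal_wallis(np.r_[x, y], np.r_[np.zeros(8), np.ones(11)])
            u = stats.mannwhitneyu(x, y).statistic
            m, n = 8, 11
            z = (u - m * n / 2) / np.sqrt(m * n * (m + n + 1) / 12)
            assert np.isclose(h, z**2, atol=1e-8)

    def test_monotone_transform_invariance(self, rng):
        v = rng.standard_normal(20)
        g = np.r_[np.zeros(9), np.ones(11)]
        h1, _ = kruskal_wallis(v, g)
        h2, _ = kruskal_wallis(np.exp(v), g)
        assert np.isclose(h1, h2)

    def test_matrix_version_matches_scipy(self, rng):
        V = rng.standard_normal((25, 8))
        V[:, 3] = np.round(V[:, 3])  # introduce ties in one column
        flag = rng.random(25) < 0.4
        pvec = kruskal_wallis_matrix(V, flag)
        for j in range(8):
            h, p = stats.kruskal(V[flag, j], V[~flag, j])
            assert np.isclose(pvec[j], p, atol=1e-10)


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        r, _ = pearson_correlation(x, 2 * x + 1)
        assert np.isclose(r, 1.0)
        r, _ = pearson_correlation(x, -x)
        assert np.isclose(r, -1.0)

    def test_constant_errors(self):
        with pytest.raises(ValueError):
            pearson_correlation(np.ones(5), np.arange(5.0))

    def test_null_calibration(self):
        rng = np.random.default_rng(77)
        rejections = sum(
            pearson_correlation(rng.standard_normal(78), rng.standard_normal(78))[1] < 0.05
            for _ in range(500)
        )
        half = 2.576 * np.sqrt(0.05 * 0.95 / 500)
        assert abs(rejections / 500 - 0.05) < half + 1e-12


class TestCohortCharacteristics:
    def test_table_structure(self, small_cohort):
        cohort, _, _ = small_cohort
        tab = cohort_characteristics(cohort)
        assert set(tab["covariate"]) >= {"age", "education", "mmse", "memantine", "statin"}
        assert tab["pvalue"].dropna().between(0, 1).all()
        # MMSE is the most separated covariate by construction
        mmse_p = tab.loc[tab["covariate"] == "mmse", "pvalue"].iloc[0]
        assert mmse_p < 1e-6


def _log_metabolites(cohort, mats):
    from metabodiscrim.pipeline import preprocess_matrices

    logs, _ = preprocess_matrices(cohort, mats)
    return pd.concat([logs["ECA"].reset_index(drop=True), logs["GCTOF"].reset_index(drop=True)], axis=1)


class TestConfoundScreen:
    def test_confounded_features_removed_with_power(self):
        """Features shifted in users of case-exclusive drugs are removed with
        high power.  Power is bounded by each drug's user count: features tied
        to the cholinesterase inhibitor (15 users) are removed almost surely,
        those tied to memantine (6 users) in ~4 of 5 cohorts (rank-test power
        at a 2-SD shift with 6 vs 72 samples, established by simulation)."""
        hits8 = 0
        total = 0
        removed_by_drug = {"cholinesterase_inhibitor": [0, 0], "memantine": [0, 0]}
        for seed in range(20):
            cfg = GeneratorConfig(
                seed=seed, n_eca=20, n_eca_known=6,
                n_signal=0, n_drug_confounded=10, drug_effect=2.0, n_apoe_linked=0,
            )
            cohort, mats, truth = generate_cohort(cfg)
            X = _log_metabolites(cohort, mats)
            report, _ = screen_confounds(
                X, cohort["diagnosis"], cohort[list(DRUG_CLASSES)],
                apoe_risk=cohort["apoe_risk"],
            )
            removed = set(report.removed)
            confounded = truth.drug_confounded_features
            hits8 += len(set(confounded) & removed) >= 8
            total += 1
            for f, d in confounded.items():
                removed_by_drug[d][1] += 1
                removed_by_drug[d][0] += f in removed
        assert hits8 / total >= 0.8
        chei = removed_by_drug["cholinesterase_inhibitor"]
        mem = removed_by_drug["memantine"]
        assert chei[0] / chei[1] >= 0.9
        assert mem[0] / mem[1] >= 0.6

    def test_null_removal_rate_near_alpha(self):
        """With no planted effects and drug-free controls/cases, removals are
        chance-level: about alpha per test per feature."""
        n_removed = 0
        n_possible = 0
        for seed in range(15):
            cfg = GeneratorConfig(
                seed=seed, n_eca=40, n_eca_known=10, n_gctof=0, n_gctof_known=0,
                n_signal=0, n_drug_confounded=0, n_apoe_linked=0,
            ).without_drugs()
            cohort, mats, _ = generate_cohort(cfg)
            X = _log_metabolites(cohort, mats)
            report, _ = screen_confounds(
                X, cohort["diagnosis"], cohort[list(DRUG_CLASSES)],
                apoe_risk=cohort["apoe_risk"],
            )
            # only the ApoE screen runs (all drug flags constant)
            assert report.disease_associated_drugs == []
            n_removed += len(report.removed)
            n_possible += X.shape[1]
        rate = n_removed / n_possible
        half = 2.576 * np.sqrt(0.05 * 0.95 / n_possible)
        assert abs(rate - 0.05) < half + 0.01

    def test_zero_drug_prevalence_skips_all_drugs(self, rng):
        cfg = GeneratorConfig(
            seed=2, n_eca=8, n_eca_known=3, n_gctof=10, n_gctof_known=5,
            n_drug_confounded=0, n_apoe_linked=0,
        ).without_drugs()
        cohort, mats, _ = generate_cohort(cfg)
        X = _log_metabolites(cohort, mats)
        with pytest.warns(UserWarning, match="constant"):
            report, _ = screen_confounds(
                X, cohort["diagnosis"], cohort[list(DRUG_CLASSES)],
                apoe_risk=cohort["apoe_risk"],
            )
        assert set(report.skipped_drugs) == set(DRUG_CLASSES)
        assert report.n_removed_drug == 0

    def test_protected_features_never_removed(self, small_cohort):
        cohort, mats, _ = small_cohort
        from metabodiscrim.pipeline import preprocess_matrices

        logs, _ = preprocess_matrices(cohort, mats)
        X = pd.concat([df.reset_index(drop=True) for df in logs.values()], axis=1)
        protected = list(logs["PROTEIN"].columns)
        screen = ConfoundScreen(
            drug_flags=cohort[list(DRUG_CLASSES)],
            apoe_risk=cohort["apoe_risk"],
            protected=protected,
        ).fit(X, cohort["diagnosis"])
        assert not set(protected) & set(screen.report_.removed)
        assert set(protected) <= set(screen.kept_features_)

    def test_removal_set_invariant_to_feature_order(self, small_cohort):
        cohort, mats, _ = small_cohort
        X = _log_metabolites(cohort, mats)
        kwargs = dict(
            drug_flags=cohort[list(DRUG_CLASSES)], apoe_risk=cohort["apoe_risk"]
        )
        r1, _ = screen_confounds(X, cohort["diagnosis"], **kwargs)
        shuffled = X[list(np.random.default_rng(0).permutation(X.columns))]
        r2, _ = screen_confounds(shuffled, cohort["diagnosis"], **kwargs)
        assert set(r1.removed) == set(r2.removed)
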