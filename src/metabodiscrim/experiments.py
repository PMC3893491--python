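"""Replicated study-scale experiments: oracle cross-checks, null calibration
of the whole-pipeline permutation test, and planted-signal recovery.

These functions define the package's standard validation experiments at the
problem sizes described in the methods note; the acceptance script and the
acceptance tests both call them.
"""

from __future__ import annotations

from itertools import combinations
from typing import Optional

import numpy as np
import pandas as pd

from .datatypes import DRUG_CLASSES
from .evaluate import auc, delong_variance
from .logistic import fit_logistic
from .pipeline import RunConfig, ScreenCache, analyze_pool, preprocess_matrices, run_all
from .stepwise import forward_stepwise_bic
from .synthetic import GeneratorConfig, generate_cohort
from .univariate import fisher_exact_2x2

#: observed drug-use counts of the cohort demographics table
#: (users among 40 cases, users among 38 controls)
TABLE1_DRUG_COUNTS = {
    "memantine": (6, 0),
    "corticosteroid": (1, 5),
    "antidepressant": (12, 8),
    "anxiolytic": (5, 5),
}


def fisher_table1_pvalues() -> dict:
    """Two-sided Fisher's exact p-values of the drug-use contingency tables."""
    out = {}
    for drug, (cases, controls) in TABLE1_DRUG_COUNTS.items():
        table = [[cases, 40 - cases], [controls, 38 - controls]]
        p, _ = fisher_exact_2x2(table)
        out[drug] = p
    return out


# ---------------------------------------------------------------------------
# oracle cross-checks


def auc_vs_concordance(n_instances: int = 30, seed: int = 0) -> float:
    """Max |midrank AUC - brute-force pairwise concordance| over random
    small instances with ties."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        n1, n0 = rng.integers(3, 12, 2)
        scores = np.round(rng.random(n1 + n0), 1)
        labels = np.r_[np.ones(n1), np.zeros(n0)]
        cases, controls = scores[: n1], scores[n1:]
        brute = sum(
            1.0 if c > k else (0.5 if c == k else 0.0) for c in cases for k in controls
        ) / (n1 * n0)
        worst = max(worst, abs(auc(scores, labels) - brute))
    return worst


def fisher_vs_enumeration(n_instances: int = 60, seed: int = 0) -> float:
    """Max |Fisher p - hypergeometric-enumeration p| on random tables with
    margins at most 30."""
    from scipy import stats

    rng = np.random.default_rng(seed)
    worst = 0.0
    done = 0
    while done < n_instances:
        t = rng.integers(0, 16, size=(2, 2))
        if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
            continue
        a, b = t[0]
        c, d = t[1]
        rv = stats.hypergeom(a + b + c + d, a + b, a + c)
        p_obs = rv.pmf(a)
        support = np.arange(max(0, (a + c) - (c + d)), min(a + b, a + c) + 1)
        probs = rv.pmf(support)
        oracle = float(probs[probs <= p_obs * (1 + 1e-9)].sum())
        p, _ = fisher_exact_2x2(t)
        worst = max(worst, abs(p - oracle))
        done += 1
    return worst


def stepwise_vs_exhaustive(n_replicates: int = 40, seed: int = 0) -> float:
    """Fraction of small-pool replicates (6 candidates, one strong signal,
    n=60) where the greedy forward-BIC subset equals the global best-BIC
    subset found by exhaustive search."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_replicates):
        X = pd.DataFrame(
            rng.standard_normal((60, 6)), columns=[f"f{j}" for j in range(6)]
        )
        eta = 2.0 * X["f0"]
        y = (rng.random(60) < 1 / (1 + np.exp(-eta))).astype(float)
        if y.sum() in (0, 60):
            continue
        fwd = forward_stepwise_bic(X, y)
        best, best_set = fit_logistic(None, y).bic, frozenset()
        for k in range(1, 7):
            for sub in combinations(X.columns, k):
                m = fit_logistic(X, y, features=list(sub))
                if not m.separated and m.bic < best - 1e-9:
                    best, best_set = m.bic, frozenset(sub)
        agree += frozenset(fwd.coef) == best_set
    return agree / n_replicates


def delong_vs_jackknife(n_instances: int = 5, n: int = 100, seed: int = 0) -> float:
    """Max relative difference between the DeLong variance of one AUC and the
    delete-one jackknife variance."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        labels = np.r_[np.ones(n // 2), np.zeros(n - n // 2)]
        scores = rng.standard_normal(n) + 0.8 * labels
        v_delong = delong_variance(scores, labels)
        thetas = np.array(
            [auc(np.delete(scores, i), np.delete(labels, i)) for i in range(n)]
        )
        v_jack = (n - 1) / n * np.sum((thetas - thetas.mean()) ** 2)
        worst = max(worst, abs(v_delong - v_jack) / v_jack)
    return worst


# ---------------------------------------------------------------------------
# whole-pipeline experiments


def calibration_config(seed: int) -> GeneratorConfig:
    """Null cohort for permutation-calibration runs: full sample size, no
    planted effects anywhere, a reduced feature panel (the permutation p-value
    is a rank among exchangeable re-runs, so its null distribution does not
    depend on the panel width)."""
    return GeneratorConfig(
        seed=seed,
        n_eca=15,
        n_eca_known=5,
        n_gctof=25,
        n_gctof_known=10,
        n_signal=0,
        n_drug_confounded=0,
        n_apoe_linked=0,
        protein_effects={"abeta42": 0.0, "ttau": 0.0, "ptau": 0.0},
    )


def recovery_config(seed: int) -> GeneratorConfig:
    """Recovery cohort: the full 370-metabolite panel with two planted ECA
    signals at a 2-SD shift and no drug use (case-exclusive treatment would
    make disease markers drug-associated by construction, and the screen
    would — correctly — remove them)."""
    return GeneratorConfig(seed=seed).without_drugs()


def _pipeline_pvalue(
    gen: GeneratorConfig,
    pool: str,
    n_permutations: int,
    seed: int,
):
    """Run screen + stepwise-CV on one cohort and return its summary with the
    whole-pipeline permutation p attached."""
    cohort, mats, truth = generate_cohort(gen)
    y = (cohort["diagnosis"] == "AD").to_numpy()
    logs, _ = preprocess_matrices(cohort, mats)
    platform_cols = {p: list(df.columns) for p, df in logs.items()}
    X_all = pd.concat([df.reset_index(drop=True) for df in logs.values()], axis=1)
    metab = pd.concat(
        [logs[p].reset_index(drop=True) for p in ("ECA", "GCTOF") if p in logs], axis=1
    )
    cache = ScreenCache(
        metab, cohort[list(DRUG_CLASSES)].astype(bool), cohort["apoe_risk"].to_numpy()
    )
    summary, perm = analyze_pool(
        X_all,
        y,
        pool,
        platform_cols,
        cache,
        seed=seed,
        n_permutations=n_permutations,
    )
    return summary, perm, truth


def null_calibration(
    n_replicates: int = 100, n_permutations: int = 99, seed: int = 0, pool: str = "P|M|E"
) -> dict:
    """Type-I error of the full artifact: on cohorts with no true effects the
    permutation p should be uniform, rejecting at the nominal 5% rate."""
    rng = np.random.default_rng(seed)
    pvalues = []
    for _ in range(n_replicates):
        gen = calibration_config(int(rng.integers(2**31 - 1)))
        summary, perm, _ = _pipeline_pvalue(
            gen, pool, n_permutations, int(rng.integers(2**31 - 1))
        )
        pvalues.append(summary.permutation_p)
    pvalues = np.asarray(pvalues)
    return {
        "pvalues": pvalues,
        "rejection_rate": float(np.mean(pvalues < 0.05)),
        "n_replicates": n_replicates,
        "n_permutations": n_permutations,
    }


def recovery_study(
    n_replicates: int = 50, n_permutations: int = 24, seed: int = 0, pool: str = "E|M"
) -> dict:
    """Planted-pair recovery through the whole pipeline: two 2-SD ECA signals
    among 370 metabolites at n=78."""
    rng = np.random.default_rng(seed)
    exact = 0
    significant = 0
    aucs = []
    for _ in range(n_replicates):
        gen = recovery_config(int(rng.integers(2**31 - 1)))
        summary, perm, truth = _pipeline_pvalue(
            gen, pool, n_permutations, int(rng.integers(2**31 - 1))
        )
        exact += summary.selected_features == sorted(truth.signal_features)
        significant += summary.permutation_p is not None and summary.permutation_p < 0.05
        aucs.append(summary.mean_test_auc)
    return {
        "exact_pair_rate": exact / n_replicates,
        "significant_rate": significant / n_replicates,
        "mean_test_auc": float(np.mean(aucs)),
        "n_replicates": n_replicates,
        "n_permutations": n_permutations,
    }


def structural_run(seed: int = 0, n_permutations: int = 0, out_dir: Optional[str] = None) -> dict:
    """Default six-pool analysis on the standard synthetic cohort."""
    cfg = RunConfig(
        generator=GeneratorConfig(seed=seed),
        pools=("E", "M", "P", "P|E", "P|M", "P|M|E"),
        n_permutations=n_permutations,
        seed=seed,
        out_dir=out_dir,
        make_plots=out_dir is not None,
    )
    return run_all(cfg)
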