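"""End-to-end orchestration: generate/load -> preprocess -> screen ->
stepwise-CV model building -> permutation and DeLong evaluation.

A *pool* is a combination of data types offered to the stepwise search,
labelled as in the summary tables: ``E`` (LC-ECA metabolites), ``M`` (GC-TOF
metabolites), ``P`` (protein panel), and unions such as ``P|M|E``.  The
default run covers the six combinations E, M, P, P|E, P|M, P|M|E.

The whole-pipeline permutation test re-runs the confound screen and the
cross-validated stepwise search on every permuted label vector.  Because the
metabolite-vs-drug and metabolite-vs-ApoE association tests do not involve
the case labels, their p-values are computed once and cached; only the
drug-vs-diagnosis step (which decides *which* drug screens apply) is
recomputed per permutation — an exact, order-of-magnitude-faster
reformulation of re-running the screen from scratch.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import DRUG_CLASSES, FeatureMatrix, ModelSummary, PermutationResult
from .evaluate import auc, bonferroni, delong_test, distribution_summary_by_group, sens_spec
from .preprocess import detection_filter, log_transform, relative_to_pool, sum_normalize
from .stepwise import ConsistencyStepwiseCV, make_folds
from .synthetic import GeneratorConfig, generate_cohort
from .univariate import (
    cohort_characteristics,
    fisher_exact_2x2,
    kruskal_wallis_matrix,
)

logger = logging.getLogger(__name__)

DEFAULT_POOLS = ("E", "M", "P", "P|E", "P|M", "P|M|E")


@dataclass
class RunConfig:
    """Configuration of a full analysis run."""

    generator: Optional[GeneratorConfig] = None
    input_dir: Optional[str] = None
    pools: Sequence[str] = DEFAULT_POOLS
    n_splits: int = 5
    n_permutations: int = 199
    alpha: float = 0.05
    seed: int = 0
    out_dir: Optional[str] = None
    detection_threshold: float = 0.5
    detection_rule: str = "any"
    impute: str = "half_min"
    screen_in_permutation: bool = True
    threshold_rule: str = "half"
    make_plots: bool = True

    def __post_init__(self):
        if not self.pools:
            raise ValueError("at least one pool must be requested")
        for label in self.pools:
            for part in label.split("|"):
                if part not in ("E", "M", "P"):
                    raise ValueError(f"invalid pool label {label!r}")


def preprocess_matrices(
    cohort: pd.DataFrame,
    matrices: Dict[str, FeatureMatrix],
    detection_threshold: float = 0.5,
    detection_rule: str = "any",
    impute: str = "half_min",
) -> tuple[Dict[str, pd.DataFrame], list]:
    """Platform-appropriate normalization, then natural-log transform.

    GC-TOF: per-group detection filter, sum-normalization to the known
    metabolites, log with half-minimum imputation of residual missingness.
    ECA: percent-of-pool scaling, log.  Proteins: log.
    Returns log-scale DataFrames per platform plus the preprocess reports.
    """
    groups = cohort["diagnosis"].to_numpy()
    out: Dict[str, pd.DataFrame] = {}
    reports = []
    for platform, mat in matrices.items():
        m = mat
        if m.values.shape[1] == 0:
            out[platform] = m.values
            continue
        if platform == "GCTOF":
            m, rep = detection_filter(m, groups, detection_threshold, detection_rule)
            reports.append(rep)
            m, rep = sum_normalize(m)
            reports.append(rep)
            m, rep = log_transform(m, impute=impute)
        elif platform == "ECA":
            if m.pool_reference is not None:
                m, rep = relative_to_pool(m)
                reports.append(rep)
            m, rep = log_transform(m, impute=impute)
        else:
            m, rep = log_transform(m, impute=impute)
        reports.append(rep)
        out[platform] = m.values
    return out, reports


class ScreenCache:
    """Precomputed confound screen, reusable across label permutations.

    The Kruskal-Wallis p-values of every metabolite against each drug flag
    and against the ApoE risk group are label-free; which drug screens apply
    (drugs associated with diagnosis at p < alpha) is the only label-
    dependent part and is recomputed per call.
    """

    def __init__(
        self,
        metabolites: pd.DataFrame,
        drug_flags: pd.DataFrame,
        apoe_risk,
        alpha: float = 0.05,
    ):
        self.features = list(metabolites.columns)
        self.alpha = alpha
        V = np.asarray(metabolites, dtype=float)
        self.drug_flags = {}
        self.drug_pvalues = {}
        self.skipped_drugs = []
        for drug in drug_flags.columns:
            f = drug_flags[drug].to_numpy(dtype=bool)
            if f.all() or (~f).all():
                self.skipped_drugs.append(drug)
                continue
            self.drug_flags[drug] = f
            self.drug_pvalues[drug] = kruskal_wallis_matrix(V, f)
        risk = np.asarray(apoe_risk, dtype=bool)
        self.apoe_pvalues = (
            kruskal_wallis_matrix(V, risk) if 0 < risk.sum() < len(risk) else None
        )

    def qualifying_drugs(self, y: np.ndarray) -> List[str]:
        y = np.asarray(y, dtype=bool)
        out = []
        for drug, f in self.drug_flags.items():
            tab = [
                [int((f & y).sum()), int((~f & y).sum())],
                [int((f & ~y).sum()), int((~f & ~y).sum())],
            ]
            p, _ = fisher_exact_2x2(tab)
            if p < self.alpha:
                out.append(drug)
        return out

    def removed(self, y: np.ndarray) -> Dict[str, str]:
        """Feature -> removal reason for the given label vector."""
        removed: Dict[str, str] = {}
        for drug in self.qualifying_drugs(y):
            for f, p in zip(self.features, self.drug_pvalues[drug]):
                if p < self.alpha and f not in removed:
                    removed[f] = "drug"
        if self.apoe_pvalues is not None:
            for f, p in zip(self.features, self.apoe_pvalues):
                if p < self.alpha and f not in removed:
                    removed[f] = "apoe"
        return removed

    def kept(self, y: np.ndarray) -> List[str]:
        removed = self.removed(y)
        return [f for f in self.features if f not in removed]


def _pool_columns(label: str, platform_cols: Dict[str, List[str]], kept: List[str]) -> List[str]:
    keep = set(kept)
    cols: List[str] = []
    for part in label.split("|"):
        src = {"E": "ECA", "M": "GCTOF", "P": "PROTEIN"}[part]
        for c in platform_cols[src]:
            if src == "PROTEIN" or c in keep:  # proteins are never screened
                cols.append(c)
    return cols


def analyze_pool(
    X_all: pd.DataFrame,
    y: np.ndarray,
    label: str,
    platform_cols: Dict[str, List[str]],
    cache: ScreenCache,
    n_splits: int = 5,
    seed: Optional[int] = None,
    n_permutations: int = 0,
    screen_in_permutation: bool = True,
    threshold_rule: str = "half",
    consistency_threshold: int = 3,
) -> tuple[ModelSummary, Optional[PermutationResult]]:
    """Screen + stepwise-CV one pool; optionally attach a permutation p."""
    kept_obs = cache.kept(y)

    def run(yv: np.ndarray, fold_seed: int, kept: List[str]):
        cols = _pool_columns(label, platform_cols, kept)
        if not cols:
            return None
        est = ConsistencyStepwiseCV(
            n_splits=n_splits,
            consistency_threshold=consistency_threshold,
            random_state=fold_seed,
            threshold_rule=threshold_rule,
        )
        est.fit(X_all[cols], yv)
        return est

    rng = np.random.default_rng(seed)
    fold_seed = int(rng.integers(2**31 - 1))
    est = run(y, fold_seed, kept_obs)
    if est is None:
        summary = ModelSummary(label, [], 0.5, 0.5, 0.5)
        return summary, None
    summary = est.summary(label)

    perm = None
    if n_permutations > 0:
        null = np.empty(n_permutations)
        failures = 0
        for b in range(n_permutations):
            yb = rng.permutation(y)
            kept_b = cache.kept(yb) if screen_in_permutation else kept_obs
            fs = int(rng.integers(2**31 - 1))
            try:
                est_b = run(yb, fs, kept_b)
                null[b] = 0.5 if est_b is None else est_b.mean_test_auc_
            except Exception as exc:
                logger.warning("pool %s permutation %d failed: %s", label, b, exc)
                null[b] = 0.5
                failures += 1
        perm = PermutationResult(
            n_permutations=n_permutations,
            observed=summary.mean_test_auc,
            null_statistics=null,
            n_failures=failures,
        )
        summary.permutation_p = perm.pvalue
    return summary, perm


def run_all(config: RunConfig) -> dict:
    """Execute the full analysis for every requested pool; return the bundle.

    The bundle is a plain JSON-serializable dict: configuration echo (with
    all seeds), the demographics comparison table, the screening report, one
    model summary per pool (consistency-selected variables, mean testing
    AUC, sensitivity, specificity, permutation p), the pairwise DeLong
    matrix with its Bonferroni mask, and per-stage wall times.
    """
    t0 = time.time()
    timings = {}
    if config.input_dir is not None:
        from .io import read_cohort

        cohort, matrices, truth = read_cohort(config.input_dir)
    else:
        gen = config.generator or GeneratorConfig(seed=config.seed)
        cohort, matrices, truth = generate_cohort(gen)
    y = cohort["diagnosis"].isin(["AD", "case", 1, True]).to_numpy()
    timings["load"] = time.time() - t0

    t = time.time()
    table1 = cohort_characteristics(cohort)
    logs, prep_reports = preprocess_matrices(
        cohort,
        matrices,
        detection_threshold=config.detection_threshold,
        detection_rule=config.detection_rule,
        impute=config.impute,
    )
    platform_cols = {p: list(df.columns) for p, df in logs.items()}
    X_all = pd.concat([df.reset_index(drop=True) for df in logs.values()], axis=1)
    metab = pd.concat(
        [logs[p].reset_index(drop=True) for p in ("ECA", "GCTOF") if p in logs], axis=1
    )
    timings["preprocess"] = time.time() - t

    t = time.time()
    cache = ScreenCache(
        metab,
        cohort[list(DRUG_CLASSES)].astype(bool),
        cohort["apoe_risk"].to_numpy(),
        alpha=config.alpha,
    )
    removed = cache.removed(y)
    if cache.skipped_drugs:
        logger.warning("constant drug flags skipped: %s", cache.skipped_drugs)
    timings["screen"] = time.time() - t

    t = time.time()
    rng = np.random.default_rng(config.seed)
    summaries: List[ModelSummary] = []
    oof_scores: Dict[str, np.ndarray] = {}
    for label in config.pools:
        pool_seed = int(rng.integers(2**31 - 1))
        summary, _ = analyze_pool(
            X_all,
            y,
            label,
            platform_cols,
            cache,
            n_splits=config.n_splits,
            seed=pool_seed,
            n_permutations=config.n_permutations,
            screen_in_permutation=config.screen_in_permutation,
            threshold_rule=config.threshold_rule,
        )
        summaries.append(summary)
        if summary.cv_run is not None:
            oof_scores[label] = summary.cv_run.oof_proba
        logger.info(
            "pool %s: AUC=%.3f selected=%s p=%s",
            label,
            summary.mean_test_auc,
            summary.selected_features,
            summary.permutation_p,
        )
    timings["models"] = time.time() - t

    t = time.time()
    comparisons = []
    labels = [s.label for s in summaries if s.label in oof_scores]
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            comparisons.append(
                delong_test(
                    oof_scores[labels[i]], oof_scores[labels[j]], y, labels[i], labels[j]
                )
            )
    flags, adj_alpha = bonferroni([c.pvalue for c in comparisons], alpha=config.alpha)
    for c, f in zip(comparisons, flags):
        c.significant = bool(f)
    timings["delong"] = time.time() - t

    # Figure-1 analogue: distribution of the top consistency-selected features
    top_features = []
    for s in summaries:
        for f in s.selected_features:
            if f not in top_features:
                top_features.append(f)
    distributions = {
        f: distribution_summary_by_group(X_all[f].to_numpy(), cohort["diagnosis"].to_numpy())
        for f in top_features[:6]
    }

    bundle = {
        "config": {
            "pools": list(config.pools),
            "n_splits": config.n_splits,
            "n_permutations": config.n_permutations,
            "alpha": config.alpha,
            "seed": config.seed,
            "detection_threshold": config.detection_threshold,
            "detection_rule": config.detection_rule,
            "impute": config.impute,
            "screen_in_permutation": config.screen_in_permutation,
            "threshold_rule": config.threshold_rule,
            "generator": None if config.generator is None else vars(config.generator).copy(),
        },
        "n_cases": int(y.sum()),
        "n_controls": int((~y).sum()),
        "table1": table1.to_dict(orient="records"),
        "preprocess": [r.to_dict() for r in prep_reports],
        "screen": {
            "disease_associated_drugs": cache.qualifying_drugs(y),
            "skipped_drugs": cache.skipped_drugs,
            "removed": removed,
            "n_removed_drug": sum(1 for r in removed.values() if r == "drug"),
            "n_removed_apoe": sum(1 for r in removed.values() if r == "apoe"),
            "n_remaining": len(cache.features) - len(removed),
        },
        "models": [s.to_dict() for s in summaries],
        "delong": [c.to_dict() for c in comparisons],
        "bonferroni_alpha": adj_alpha,
        "distributions": distributions,
        "truth": None if truth is None else truth.to_dict(),
        "timings": timings,
    }
    if "generator" in bundle["config"] and bundle["config"]["generator"] is not None:
        g = bundle["config"]["generator"]
        g["drug_prevalence"] = {k: list(v) for k, v in g["drug_prevalence"].items()}

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "bundle.json").write_text(json.dumps(bundle, indent=1, default=float))
        (out / "report.md").write_text(render_report(bundle))
        _write_model_table(summaries, out / "model_summary.tsv")
        if config.make_plots and top_features:
            _boxplots(X_all, cohort["diagnosis"], top_features[:6], out / "top_features.png")
    return bundle


def _write_model_table(summaries: List[ModelSummary], path: Path) -> None:
    pd.DataFrame(
        [
            {
                "label": s.label,
                "selected": ";".join(s.selected_features) or "(intercept-only)",
                "mean_test_auc": s.mean_test_auc,
                "sensitivity": s.sensitivity,
                "specificity": s.specificity,
                "permutation_p": s.permutation_p,
            }
            for s in summaries
        ]
    ).to_csv(path, sep="\t", index=False)


def _boxplots(X: pd.DataFrame, diagnosis: pd.Series, features: List[str], path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groups = sorted(diagnosis.unique())
    fig, axes = plt.subplots(1, len(features), figsize=(2.2 * len(features), 3.2), squeeze=False)
    for ax, f in zip(axes[0], features):
        data = [X.loc[(diagnosis == g).to_numpy(), f].dropna() for g in groups]
        ax.boxplot(data, tick_labels=groups)
        ax.set_title(f, fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def render_report(bundle: dict) -> str:
    """Human-readable Markdown mirror of the bundle (no new computation)."""
    lines = ["# Discrimination analysis report", ""]
    lines.append(f"Cohort: {bundle['n_cases']} cases / {bundle['n_controls']} controls.")
    lines.append("")
    lines.append("## Demographics and clinical covariates")
    lines.append("")
    lines.append("| covariate | test | statistic | p |")
    lines.append("|---|---|---|---|")
    for row in bundle["table1"]:
        stat = row["statistic"]
        stat_s = "" if stat is None or (isinstance(stat, float) and np.isnan(stat)) else f"{stat:.3f}"
        lines.append(f"| {row['covariate']} | {row['test']} | {stat_s} | {row['pvalue']:.3g} |")
    s = bundle["screen"]
    lines.append("")
    lines.append("## Confound screen")
    lines.append("")
    lines.append(
        f"Drugs associated with diagnosis: {', '.join(s['disease_associated_drugs']) or 'none'}."
    )
    if s["skipped_drugs"]:
        lines.append(f"Skipped (constant flag): {', '.join(s['skipped_drugs'])}.")
    lines.append(
        f"Removed {s['n_removed_drug']} drug-associated and {s['n_removed_apoe']} "
        f"ApoE-associated metabolites; {s['n_remaining']} remain."
    )
    lines.append("")
    lines.append("## Model summaries")
    lines.append("")
    lines.append("| pool | selected variables | mean testing AUC | sensitivity | specificity | permutation p |")
    lines.append("|---|---|---|---|---|---|")
    for m in bundle["models"]:
        sel = ", ".join(m["selected_features"]) or "(intercept-only)"
        p = m["permutation_p"]
        lines.append(
            f"| {m['label']} | {sel} | {m['mean_test_auc']:.3f} | {m['sensitivity']:.3f} "
            f"| {m['specificity']:.3f} | {'' if p is None else format(p, '.4g')} |"
        )
    lines.append("")
    lines.append("## Pairwise DeLong comparisons")
    lines.append("")
    lines.append(
        f"Bonferroni-adjusted alpha: {bundle['bonferroni_alpha']:.4g} "
        f"({len(bundle['delong'])} pairs). Significant pairs flagged with *."
    )
    lines.append("")
    lines.append("| pair | AUC1 | AUC2 | z | p | |")
    lines.append("|---|---|---|---|---|---|")
    for c in bundle["delong"]:
        mark = "*" if c["significant"] else ""
        lines.append(
            f"| {c['label1']} vs {c['label2']} | {c['auc1']:.3f} | {c['auc2']:.3f} "
            f"| {c['z']:.2f} | {c['pvalue']:.3g} | {mark} |"
        )
    lines.append("")
    return "\n".join(lines)
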