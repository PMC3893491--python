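"""Shared containers for cohort tables, feature matrices and analysis results.

Samples are rows, features are columns, throughout.  Feature values live in a
plain :class:`pandas.DataFrame`; :class:`FeatureMatrix` adds the per-platform
annotation (known/unknown status, the pooled-CSF reference used by the
electrochemical-array platform) that the preprocessing steps need.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

#: platform codes: LC electrochemical array, GC time-of-flight MS, immunoassay panel
PLATFORMS = ("ECA", "GCTOF", "PROTEIN")

#: drug-class flag columns expected in a cohort table
DRUG_CLASSES = (
    "antidepressant",
    "antipsychotic",
    "anxiolytic",
    "corticosteroid",
    "cholinesterase_inhibitor",
    "memantine",
    "statin",
)

#: genotypes coded as high ApoE risk
APOE_HIGH_RISK = ("E3/E4", "E4/E4")

COHORT_COLUMNS = (
    "sample_id",
    "diagnosis",
    "age",
    "sex",
    "race",
    "education",
    "mmse",
    *DRUG_CLASSES,
    "apoe_genotype",
    "apoe_risk",
)


@dataclass
class FeatureMatrix:
    """A sample-by-feature table of relative concentrations for one platform.

    Parameters
    ----------
    platform : {"ECA", "GCTOF", "PROTEIN"}
    values : DataFrame
        Rows indexed by sample_id, columns are feature IDs.  Entries are
        strictly positive where present; NaN encodes a missing measurement.
    known : Series of bool, indexed by feature ID
        Whether the feature is an identified compound.
    pool_reference : Series of float, optional
        Per-feature intensity of the pooled central CSF sample (ECA only);
        the platform reports concentrations relative to this pool (= 100 %).
    """

    platform: str
    values: pd.DataFrame
    known: pd.Series
    pool_reference: Optional[pd.Series] = None

    def __post_init__(self):
        if self.platform not in PLATFORMS:
            raise ValueError(f"unknown platform {self.platform!r}")
        if not self.values.index.is_unique:
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample_id(s): {dups}")
        if not self.values.columns.is_unique:
            dups = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate feature ID(s): {dups}")
        self.known = self.known.reindex(self.values.columns).astype(bool)
        if self.pool_reference is not None:
            self.pool_reference = self.pool_reference.reindex(self.values.columns).astype(float)

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.columns

    def copy(self) -> "FeatureMatrix":
        return FeatureMatrix(
            self.platform,
            self.values.copy(),
            self.known.copy(),
            None if self.pool_reference is None else self.pool_reference.copy(),
        )


@dataclass
class SyntheticTruth:
    """Ground truth of a generated cohort, for recovery tests."""

    signal_features: list
    drug_confounded_features: dict  # feature ID -> drug class
    apoe_features: list
    effects: dict  # feature ID -> signed standardized shift on the log scale

    def to_dict(self) -> dict:
        return {
            "signal_features": list(self.signal_features),
            "drug_confounded_features": dict(self.drug_confounded_features),
            "apoe_features": list(self.apoe_features),
            "effects": {k: float(v) for k, v in self.effects.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticTruth":
        return cls(
            signal_features=list(d["signal_features"]),
            drug_confounded_features=dict(d["drug_confounded_features"]),
            apoe_features=list(d["apoe_features"]),
            effects={k: float(v) for k, v in d["effects"].items()},
        )


@dataclass
class PreprocessReport:
    """What a preprocessing step did: dropped features, transform, divisors."""

    platform: str
    transform: str
    features_dropped: dict = field(default_factory=dict)  # ID -> per-group detection fractions
    divisors: Optional[pd.Series] = None  # per-sample normalization divisor (GC-TOF)

    def to_dict(self) -> dict:
        return {
            "platform": self.platform,
            "transform": self.transform,
            "features_dropped": {
                k: {g: float(f) for g, f in v.items()} for k, v in self.features_dropped.items()
            },
            "divisors": None if self.divisors is None else {k: float(v) for k, v in self.divisors.items()},
        }


@dataclass
class ScreenReport:
    """Outcome of the confound screen (drug and ApoE association filters)."""

    covariate_tests: pd.DataFrame  # Table-1 analogue: covariate, test, statistic, p
    disease_associated_drugs: list
    drug_pvalues: pd.DataFrame  # feature x drug, Kruskal-Wallis p-values
    apoe_pvalues: pd.Series  # feature -> Kruskal-Wallis p vs ApoE risk group
    removed: dict  # feature ID -> reason ("drug" or "apoe"); union counted once
    skipped_drugs: list = field(default_factory=list)
    alpha: float = 0.05

    @property
    def n_removed_drug(self) -> int:
        return sum(1 for r in self.removed.values() if r == "drug")

    @property
    def n_removed_apoe(self) -> int:
        return sum(1 for r in self.removed.values() if r == "apoe")

    def kept(self, feature_ids) -> list:
        return [f for f in feature_ids if f not in self.removed]

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "disease_associated_drugs": list(self.disease_associated_drugs),
            "skipped_drugs": list(self.skipped_drugs),
            "removed": dict(self.removed),
            "n_removed_drug": self.n_removed_drug,
            "n_removed_apoe": self.n_removed_apoe,
            "covariate_tests": self.covariate_tests.to_dict(orient="records"),
        }


@dataclass
class LogisticModel:
    """A fitted binary logistic regression with its BIC bookkeeping.

    ``bic = -2 L + k ln(n)`` where ``k`` counts the intercept.
    """

    intercept: float
    coef: dict  # feature ID -> coefficient
    loglik: float
    n: int
    separated: bool = False
    converged: bool = True
    ridge: float = 0.0

    @property
    def k(self) -> int:
        return 1 + len(self.coef)

    @property
    def bic(self) -> float:
        return -2.0 * self.loglik + self.k * np.log(self.n)

    def linear_predictor(self, X: pd.DataFrame) -> np.ndarray:
        eta = np.full(len(X), self.intercept, dtype=float)
        for f, b in self.coef.items():
            eta += b * np.asarray(X[f], dtype=float)
        return eta

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        from scipy.special import expit

        return expit(self.linear_predictor(X))

    def to_dict(self) -> dict:
        return {
            "intercept": float(self.intercept),
            "coef": {k: float(v) for k, v in self.coef.items()},
            "loglik": float(self.loglik),
            "n": int(self.n),
            "k": self.k,
            "bic": float(self.bic),
            "separated": bool(self.separated),
            "converged": bool(self.converged),
        }


@dataclass
class CVRun:
    """Per-fold stepwise models and their train/test discrimination."""

    fold_assignment: np.ndarray  # fold index per sample
    fold_models: list  # LogisticModel per fold
    train_aucs: list
    test_aucs: list
    selection_counts: dict  # feature ID -> number of folds selecting it
    oof_proba: np.ndarray  # pooled out-of-fold predicted probabilities

    @property
    def n_splits(self) -> int:
        return len(self.fold_models)

    @property
    def mean_test_auc(self) -> float:
        return float(np.mean(self.test_aucs))

    def to_dict(self) -> dict:
        return {
            "fold_assignment": self.fold_assignment.tolist(),
            "fold_models": [m.to_dict() for m in self.fold_models],
            "train_aucs": [float(a) for a in self.train_aucs],
            "test_aucs": [float(a) for a in self.test_aucs],
            "selection_counts": {k: int(v) for k, v in self.selection_counts.items()},
        }


@dataclass
class ModelSummary:
    """One data-type combination's row of the model-fit summary table."""

    label: str  # e.g. "E", "M", "P", "P|E", "P|M", "P|M|E"
    selected_features: list
    mean_test_auc: float
    sensitivity: float
    specificity: float
    permutation_p: Optional[float] = None
    final_model: Optional[LogisticModel] = None
    cv_run: Optional[CVRun] = None

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "selected_features": list(self.selected_features),
            "mean_test_auc": float(self.mean_test_auc),
            "sensitivity": float(self.sensitivity),
            "specificity": float(self.specificity),
            "permutation_p": None if self.permutation_p is None else float(self.permutation_p),
            "final_model": None if self.final_model is None else self.final_model.to_dict(),
            "cv_run": None if self.cv_run is None else self.cv_run.to_dict(),
        }


@dataclass
class ROCResult:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    n_cases: int
    n_controls: int


@dataclass
class PermutationResult:
    """Empirical null of the pipeline statistic under label permutation."""

    n_permutations: int
    observed: float
    null_statistics: np.ndarray
    n_failures: int = 0

    @property
    def pvalue(self) -> float:
        # add-one convention: p is never 0
        b = int(np.sum(self.null_statistics >= self.observed))
        return (1.0 + b) / (self.n_permutations + 1.0)

    def to_dict(self) -> dict:
        return {
            "n_permutations": int(self.n_permutations),
            "observed": float(self.observed),
            "pvalue": float(self.pvalue),
            "n_failures": int(self.n_failures),
        }


@dataclass
class DeLongComparison:
    label1: str
    label2: str
    auc1: float
    auc2: float
    var_diff: float
    z: float
    pvalue: float
    significant: Optional[bool] = None  # after Bonferroni masking

    def to_dict(self) -> dict:
        return {
            "label1": self.label1,
            "label2": self.label2,
            "auc1": float(self.auc1),
            "auc2": float(self.auc2),
            "var_diff": float(self.var_diff),
            "z": float(self.z),
            "pvalue": float(self.pvalue),
            "significant": self.significant,
        }
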