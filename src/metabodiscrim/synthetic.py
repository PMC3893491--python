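"""Synthetic case-control CSF cohort generator.

Emulates the statistical structure of a two-platform CSF metabolomics study
of Alzheimer's disease (AD) cases versus cognitively normal (CN) controls:

* ~40 cases / ~38 controls with demographics, MMSE, seven drug-class flags
  (AD treatment drugs nearly exclusive to cases) and ApoE genotype;
* an LC electrochemical-array (ECA) platform of 71 metabolites (24 known)
  reported relative to a pooled reference sample;
* a GC-TOF platform of 299 metabolites with sum-normalizable intensities and
  missing-completely-at-random dropout;
* a 3-analyte protein panel (Abeta42 shifted down in cases, tau up).

Feature intensities are log-normal: log-scale values are a feature baseline
plus standardized effects plus unit-variance Gaussian noise (optionally
equicorrelated), then exponentiated.  Planted disease signals live on the
ECA platform; drug-confounded and ApoE-linked features on GC-TOF.  The
ground truth of every planted effect is returned for recovery testing.

Drug flags are assigned by deterministic rounding of prevalence x group size
(so the demographic margins reproduce exactly), with a random choice of
*which* samples carry each flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .datatypes import APOE_HIGH_RISK, DRUG_CLASSES, FeatureMatrix, SyntheticTruth

#: Table-1-patterned drug prevalence (case rate, control rate)
DEFAULT_DRUG_PREVALENCE: Dict[str, Tuple[float, float]] = {
    "antidepressant": (0.30, 0.2105),
    "antipsychotic": (0.05, 0.0),
    "anxiolytic": (0.125, 0.132),
    "corticosteroid": (0.025, 0.132),
    "cholinesterase_inhibitor": (0.375, 0.0),
    "memantine": (0.15, 0.0),
    "statin": (0.20, 0.263),
}

PROTEIN_IDS = ("abeta42", "ttau", "ptau")

#: genotype frequencies; high-risk (E3/E4 + E4/E4) mass = 0.35 in both groups
_APOE_GENOTYPES = ("E2/E2", "E2/E3", "E2/E4", "E3/E3", "E3/E4", "E4/E4")
_APOE_FREQS = (0.01, 0.10, 0.03, 0.51, 0.29, 0.06)


class ConfigurationError(ValueError):
    """Raised for an internally inconsistent generator configuration."""


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic cohort; defaults are the study's conditions."""

    n_cases: int = 40
    n_controls: int = 38
    n_eca: int = 71
    n_eca_known: int = 24
    n_gctof: int = 299
    n_gctof_known: int = 130
    n_protein: int = 3
    n_signal: int = 2
    signal_effect: float = 2.0
    n_drug_confounded: int = 10
    drug_effect: float = 2.0
    n_apoe_linked: int = 2
    apoe_effect: float = 2.0
    drug_prevalence: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_DRUG_PREVALENCE)
    )
    missing_rate_gctof: float = 0.10
    protein_effects: Dict[str, float] = field(
        default_factory=lambda: {"abeta42": -1.5, "ttau": 1.5, "ptau": 1.5}
    )
    feature_correlation: float = 0.0  # equicorrelation of the log-scale noise
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_cases": self.n_cases,
            "n_controls": self.n_controls,
            "n_eca": self.n_eca,
            "n_eca_known": self.n_eca_known,
            "n_gctof": self.n_gctof,
            "n_gctof_known": self.n_gctof_known,
            "n_protein": self.n_protein,
            "n_signal": self.n_signal,
            "n_drug_confounded": self.n_drug_confounded,
            "n_apoe_linked": self.n_apoe_linked,
        }
        for name, v in counts.items():
            if v < 0:
                raise ConfigurationError(f"{name} must be >= 0, got {v}")
        if self.n_eca_known > self.n_eca:
            raise ConfigurationError("n_eca_known exceeds n_eca")
        if self.n_gctof_known > self.n_gctof:
            raise ConfigurationError("n_gctof_known exceeds n_gctof")
        if self.n_signal > self.n_eca:
            raise ConfigurationError("n_signal exceeds the ECA feature count")
        if self.n_drug_confounded + self.n_apoe_linked > self.n_gctof:
            raise ConfigurationError("confounded + ApoE-linked features exceed GC-TOF count")
        if self.n_signal + self.n_drug_confounded + self.n_apoe_linked > self.n_eca + self.n_gctof:
            raise ConfigurationError("planted features exceed total metabolite count")
        if not (0.0 <= self.missing_rate_gctof < 1.0):
            raise ConfigurationError("missing_rate_gctof must be in [0, 1)")
        if not (0.0 <= self.feature_correlation < 1.0):
            raise ConfigurationError("feature_correlation must be in [0, 1)")
        for drug, (rc, rk) in self.drug_prevalence.items():
            if not (0.0 <= rc <= 1.0 and 0.0 <= rk <= 1.0):
                raise ConfigurationError(f"prevalence for {drug!r} must be rates in [0, 1]")

    def without_drugs(self) -> "GeneratorConfig":
        """Copy with every drug prevalence zeroed (confound-free cohort)."""
        import dataclasses

        return dataclasses.replace(
            self, drug_prevalence={d: (0.0, 0.0) for d in self.drug_prevalence}
        )


def _assign_flags(n_group: int, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Deterministic rounding of prevalence x group size; random carriers."""
    k = int(round(rate * n_group))
    flag = np.zeros(n_group, dtype=bool)
    if k > 0:
        flag[rng.choice(n_group, size=min(k, n_group), replace=False)] = True
    return flag


def _noise(rng: np.random.Generator, n: int, p: int, rho: float) -> np.ndarray:
    z = rng.standard_normal((n, p))
    if rho > 0:
        shared = rng.standard_normal((n, 1))
        z = np.sqrt(1 - rho) * z + np.sqrt(rho) * shared
    return z


def generate_cohort(
    config: Optional[GeneratorConfig] = None,
) -> tuple[pd.DataFrame, Dict[str, FeatureMatrix], SyntheticTruth]:
    """Generate a cohort table, one FeatureMatrix per platform, and the truth.

    The same config (same seed) always yields identical output.
    """
    cfg = config or GeneratorConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n_case, n_ctrl = cfg.n_cases, cfg.n_controls
    n = n_case + n_ctrl
    case = np.concatenate([np.ones(n_case, dtype=bool), np.zeros(n_ctrl, dtype=bool)])

    sample_id = [f"S{i + 1:03d}" for i in range(n)]
    age = np.round(rng.normal(69.0, 9.4, n), 1)
    sex = np.where(rng.random(n) < 0.30, "M", "F")
    race = np.where(rng.random(n) < 0.85, "Caucasian", "Other")
    education = np.clip(np.round(np.where(case, rng.normal(14.8, 3.6, n), rng.normal(16.6, 3.0, n))), 6, 24)
    mmse = np.clip(
        np.round(np.where(case, rng.normal(19.9, 7.7, n), rng.normal(29.2, 1.3, n))), 0, 30
    )

    flags = {}
    for drug in DRUG_CLASSES:
        rc, rk = cfg.drug_prevalence.get(drug, (0.0, 0.0))
        f = np.zeros(n, dtype=bool)
        f[:n_case] = _assign_flags(n_case, rc, rng)
        f[n_case:] = _assign_flags(n_ctrl, rk, rng)
        flags[drug] = f

    genotype = rng.choice(_APOE_GENOTYPES, size=n, p=_APOE_FREQS)
    apoe_risk = np.isin(genotype, APOE_HIGH_RISK)

    cohort = pd.DataFrame(
        {
            "sample_id": sample_id,
            "diagnosis": np.where(case, "AD", "CN"),
            "age": age,
            "sex": sex,
            "race": race,
            "education": education,
            "mmse": mmse,
            **flags,
            "apoe_genotype": genotype,
            "apoe_risk": apoe_risk,
        }
    )

    # --- feature matrices -------------------------------------------------
    eca_ids = [f"E{j + 1:03d}" for j in range(cfg.n_eca)]
    gctof_ids = [f"M{j + 1:03d}" for j in range(cfg.n_gctof)]
    protein_ids = list(PROTEIN_IDS[: cfg.n_protein]) + [
        f"protein_{j}" for j in range(max(0, cfg.n_protein - len(PROTEIN_IDS)))
    ]

    effects: Dict[str, float] = {}

    # planted disease signals live among the unknown ECA features
    unknown_eca = eca_ids[cfg.n_eca_known :] or eca_ids
    if cfg.n_signal > len(unknown_eca):
        signal_ids = [str(f) for f in rng.choice(eca_ids, size=cfg.n_signal, replace=False)]
    else:
        signal_ids = [str(f) for f in rng.choice(unknown_eca, size=cfg.n_signal, replace=False)]
    for f in signal_ids:
        effects[f] = cfg.signal_effect

    # drug-confounded + ApoE-linked features live on GC-TOF, disjoint
    gct_pick = rng.choice(
        gctof_ids, size=cfg.n_drug_confounded + cfg.n_apoe_linked, replace=False
    )
    drug_conf_ids = [str(f) for f in gct_pick[: cfg.n_drug_confounded]]
    apoe_ids = [str(f) for f in gct_pick[cfg.n_drug_confounded :]]
    # confounded features attach to the disease-treatment drugs that have users
    ad_drugs = [d for d in ("cholinesterase_inhibitor", "memantine") if flags[d].any()]
    if not ad_drugs:
        ad_drugs = [d for d in DRUG_CLASSES if flags[d].any()]
    drug_map: Dict[str, str] = {}
    for i, f in enumerate(drug_conf_ids):
        if ad_drugs:
            drug = ad_drugs[i % len(ad_drugs)]
            drug_map[f] = drug
            effects[f] = cfg.drug_effect
    for f in apoe_ids:
        effects[f] = cfg.apoe_effect

    def build_logs(ids, baseline_sd=0.5):
        base = rng.normal(0.0, baseline_sd, len(ids))
        logs = base[None, :] + _noise(rng, n, len(ids), cfg.feature_correlation)
        return base, logs

    eca_base, eca_logs = build_logs(eca_ids)
    for f in signal_ids:
        eca_logs[case, eca_ids.index(f)] += cfg.signal_effect

    gct_base, gct_logs = build_logs(gctof_ids)
    for f, drug in drug_map.items():
        gct_logs[flags[drug], gctof_ids.index(f)] += cfg.drug_effect
    for f in apoe_ids:
        gct_logs[apoe_risk, gctof_ids.index(f)] += cfg.apoe_effect

    prot_base, prot_logs = build_logs(protein_ids)
    for i, f in enumerate(protein_ids):
        eff = cfg.protein_effects.get(f, 0.0)
        effects[f] = eff
        prot_logs[case, i] += eff

    eca_values = pd.DataFrame(np.exp(eca_logs), index=sample_id, columns=eca_ids)
    gct_values = pd.DataFrame(np.exp(gct_logs), index=sample_id, columns=gctof_ids)
    prot_values = pd.DataFrame(np.exp(prot_logs), index=sample_id, columns=protein_ids)

    if cfg.missing_rate_gctof > 0:
        miss = rng.random(gct_values.shape) < cfg.missing_rate_gctof
        gct_values = gct_values.mask(miss)

    matrices = {
        "ECA": FeatureMatrix(
            "ECA",
            eca_values,
            known=pd.Series(
                [j < cfg.n_eca_known for j in range(cfg.n_eca)], index=eca_ids
            ),
            pool_reference=pd.Series(np.exp(eca_base), index=eca_ids),
        ),
        "GCTOF": FeatureMatrix(
            "GCTOF",
            gct_values,
            known=pd.Series(
                [j < cfg.n_gctof_known for j in range(cfg.n_gctof)], index=gctof_ids
            ),
        ),
        "PROTEIN": FeatureMatrix(
            "PROTEIN",
            prot_values,
            known=pd.Series(True, index=protein_ids),
        ),
    }

    truth = SyntheticTruth(
        signal_features=sorted(signal_ids),
        drug_confounded_features=drug_map,
        apoe_features=sorted(apoe_ids),
        effects=effects,
    )
    return cohort, matrices, truth
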