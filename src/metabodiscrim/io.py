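"""Delimited-text serialization of cohorts and feature matrices.

Layout of a cohort directory::

    cohort.tsv          per-sample metadata (fixed column names)
    features_<P>.tsv    sample-by-feature table per platform; first column
                        sample_id, header row of feature IDs; empty cell =
                        missing measurement
    annotations.tsv     per-feature sidecar: feature_id, platform,
                        known_flag, pool_reference
    truth.json          ground truth of a synthetic cohort (optional)

Floats are written with 17 significant digits so the round trip is lossless.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .datatypes import COHORT_COLUMNS, DRUG_CLASSES, FeatureMatrix, SyntheticTruth

_FLOAT_FMT = "%.17g"


class ParseError(ValueError):
    """Malformed table: duplicate IDs or non-numeric cells."""


def write_cohort(
    cohort: pd.DataFrame,
    matrices: Dict[str, FeatureMatrix],
    path,
    truth: Optional[SyntheticTruth] = None,
) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    cohort.to_csv(path / "cohort.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
    ann_rows = []
    for platform, mat in matrices.items():
        df = mat.values.copy()
        df.insert(0, "sample_id", df.index)
        df.to_csv(
            path / f"features_{platform}.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
        )
        for f in mat.feature_ids:
            ann_rows.append(
                {
                    "feature_id": f,
                    "platform": platform,
                    "known_flag": bool(mat.known[f]),
                    "pool_reference": (
                        "" if mat.pool_reference is None else mat.pool_reference[f]
                    ),
                }
            )
    pd.DataFrame(ann_rows).to_csv(
        path / "annotations.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
    )
    if truth is not None:
        (path / "truth.json").write_text(json.dumps(truth.to_dict(), indent=1))
    return path


def _check_unique(values, what: str, where: str):
    s = pd.Series(values)
    dup = s[s.duplicated()].unique().tolist()
    if dup:
        raise ParseError(f"duplicate {what}(s) in {where}: {dup}")


def read_cohort(path) -> tuple[pd.DataFrame, Dict[str, FeatureMatrix], Optional[SyntheticTruth]]:
    path = Path(path)
    cohort = pd.read_csv(path / "cohort.tsv", sep="\t")
    missing_cols = [c for c in COHORT_COLUMNS if c not in cohort.columns]
    if missing_cols:
        raise ParseError(f"cohort.tsv missing column(s): {missing_cols}")
    _check_unique(cohort["sample_id"], "sample_id", "cohort.tsv")
    for drug in DRUG_CLASSES:
        cohort[drug] = cohort[drug].astype(bool)
    cohort["apoe_risk"] = cohort["apoe_risk"].astype(bool)

    ann = pd.read_csv(path / "annotations.tsv", sep="\t")
    _check_unique(ann["feature_id"], "feature_id", "annotations.tsv")
    matrices: Dict[str, FeatureMatrix] = {}
    for fp in sorted(path.glob("features_*.tsv")):
        platform = fp.stem.split("_", 1)[1]
        df = pd.read_csv(fp, sep="\t")
        _check_unique(df["sample_id"], "sample_id", fp.name)
        df = df.set_index("sample_id")
        df.index.name = None
        for col in df.columns:
            try:
                df[col] = pd.to_numeric(df[col])
            except (ValueError, TypeError) as exc:
                raise ParseError(f"non-numeric cell in {fp.name}, column {col!r}") from exc
        sub = ann[ann["platform"] == platform].set_index("feature_id")
        known = sub["known_flag"].reindex(df.columns)
        if known.isna().any():
            missing = known[known.isna()].index.tolist()
            raise ParseError(f"features without annotation in {fp.name}: {missing}")
        pool = sub["pool_reference"].reindex(df.columns)
        pool = None if pool.isna().all() else pool.astype(float)
        matrices[platform] = FeatureMatrix(platform, df, known.astype(bool), pool)

    truth = None
    tfile = path / "truth.json"
    if tfile.exists():
        truth = SyntheticTruth.from_dict(json.loads(tfile.read_text()))
    return cohort, matrices, truth
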