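"""Reading and writing the cohort CSV datasets.

Two tables describe a cohort:

``mothers.csv`` — one row per mother/child pair: spot-urine metabolite
concentrations in ug/L (raw scale, with the literal token ``<LOD`` in
cells below the limit of detection), urinary creatinine (mg/dL),
collection date, and all baseline covariates.

``visits.csv`` — one row per (subject, visit in 1..3): age in months,
weight (kg), bioimpedance fat mass (kg, empty when the outcome is
missing), height (m), physical activity (0/1, may be empty) and the
outcome-missing indicator.

Internally a censored concentration is stored as the pair
``(conc_<code> = raw LOD placeholder, cens_<code> = True)``; the
placeholder value is never used directly in modeling.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .registry import MetaboliteSpec, SchemaError

__all__ = ["read_mothers", "write_mothers", "read_visits", "write_visits"]

logger = logging.getLogger(__name__)

LOD_TOKEN = "<LOD"

#: Covariates that must be present for every mother.
_REQUIRED_MOTHER_COLS = [
    "subject_id", "creatinine", "collection_date", "race_ethnicity",
    "maternal_age", "education", "work_status", "smoking", "prepreg_bmi",
    "maternal_height", "first_preg_weight", "gestational_age",
    "birth_weight", "child_sex",
]
#: Covariates that may be missing (imputed inside the MCMC).
_OPTIONAL_MOTHER_COLS = ["last_preg_weight", "breastfed"]

_VISIT_COLS = ["subject_id", "visit", "age_months", "weight", "fat_mass",
               "height", "active", "outcome_missing"]


def read_mothers(path: str | Path,
                 registry: list[MetaboliteSpec]) -> pd.DataFrame:
    """Read a mother-level CSV against a metabolite registry.

    Every metabolite column must match a registry code; cells holding the
    token ``<LOD`` become censored entries (flag set, raw-LOD placeholder
    stored). Rows missing any required covariate are rejected; only
    ``last_preg_weight`` and ``breastfed`` may be empty.
    """
    codes = [s.code for s in registry]
    # read everything as text: float() below round-trips repr-written
    # values exactly, which pandas' fast float parser does not guarantee
    df = pd.read_csv(path, dtype=str)
    missing = set(_REQUIRED_MOTHER_COLS) - set(df.columns)
    if missing:
        raise SchemaError(f"mothers file missing columns: {sorted(missing)}")
    conc_cols = [c for c in df.columns
                 if c not in _REQUIRED_MOTHER_COLS + _OPTIONAL_MOTHER_COLS]
    unknown = set(conc_cols) - set(codes)
    if unknown:
        raise SchemaError(f"unknown metabolite codes: {sorted(unknown)}")
    absent = set(codes) - set(conc_cols)
    if absent:
        raise SchemaError(f"registry metabolites absent from file: "
                          f"{sorted(absent)}")

    def exact_float(series):
        return series.map(lambda v: np.nan if pd.isna(v) or v == ""
                          else float(v))

    out = df[["subject_id", "collection_date"]].copy()
    for c in _REQUIRED_MOTHER_COLS:
        if c not in ("subject_id", "collection_date"):
            out[c] = exact_float(df[c])
    out = out[_REQUIRED_MOTHER_COLS]
    for c in ("race_ethnicity", "education", "work_status", "smoking",
              "child_sex"):
        out[c] = out[c].astype(int)
    for c in _OPTIONAL_MOTHER_COLS:
        out[c] = exact_float(df[c]) if c in df else np.nan

    lod = {s.code: s.lod for s in registry}
    for code in codes:  # keep registry column order
        raw = df[code].str.strip()
        cens = raw == LOD_TOKEN
        vals = raw.where(~cens, "nan").map(float)
        if (vals <= 0).any():
            raise ValueError(f"non-positive concentration for {code}")
        out[f"conc_{code}"] = vals.where(~cens, lod[code]).astype(float)
        out[f"cens_{code}"] = cens.to_numpy()

    if out["subject_id"].duplicated().any():
        raise ValueError("duplicate subject_id in mothers file")
    if (out["creatinine"] <= 0).any():
        raise ValueError("creatinine must be > 0")
    req = out[_REQUIRED_MOTHER_COLS].drop(columns=["subject_id",
                                                   "collection_date"])
    if req.isna().any().any():
        bad = req.columns[req.isna().any()].tolist()
        raise ValueError(f"required covariates missing: {bad}")
    for c in ("education", "work_status", "smoking", "child_sex"):
        if not out[c].isin([0, 1]).all():
            raise ValueError(f"{c} must be binary 0/1")
    if not out["breastfed"].dropna().isin([0, 1]).all():
        raise ValueError("breastfed must be binary 0/1 where observed")
    out["collection_date"] = pd.to_datetime(out["collection_date"],
                                            format="ISO8601")
    return out


def write_mothers(df: pd.DataFrame, path: str | Path,
                  registry: list[MetaboliteSpec]) -> None:
    """Write a mothers DataFrame; censored cells become ``<LOD`` tokens."""
    codes = [s.code for s in registry]
    out = df[_REQUIRED_MOTHER_COLS + _OPTIONAL_MOTHER_COLS].copy()
    out["collection_date"] = pd.to_datetime(
        out["collection_date"]).dt.strftime("%Y-%m-%d")
    for code in codes:
        vals = df[f"conc_{code}"].map(repr)
        out[code] = vals.where(~df[f"cens_{code}"], LOD_TOKEN)
    out.to_csv(path, index=False)


def read_visits(path: str | Path,
                known_subjects: set[str] | None = None) -> pd.DataFrame:
    """Read the child-visit CSV.

    Enforces one row per (subject, visit), ``fat_mass < weight`` where
    observed, and consistency between ``fat_mass`` presence and the
    ``outcome_missing`` indicator. Subjects not in ``known_subjects``
    (when given) are flagged with a warning, not dropped.
    """
    raw = pd.read_csv(path, dtype=str)
    missing = set(_VISIT_COLS) - set(raw.columns)
    if missing:
        raise SchemaError(f"visits file missing columns: {sorted(missing)}")
    df = raw[["subject_id"]].copy()
    for c in _VISIT_COLS[1:]:
        df[c] = raw[c].map(lambda v: np.nan if pd.isna(v) or v == ""
                           else float(v))
    for c in ("visit", "outcome_missing"):
        df[c] = df[c].astype("Int64" if df[c].isna().any() else int)
    if df.empty:
        logger.warning("visits file %s is empty", path)
        return df
    if df.duplicated(subset=["subject_id", "visit"]).any():
        raise ValueError("duplicate (subject_id, visit) rows")
    if not df["visit"].isin([1, 2, 3]).all():
        raise ValueError("visit must be in 1..3")
    obs = df["fat_mass"].notna()
    if ((df.loc[obs, "fat_mass"] < 0)
            | (df.loc[obs, "fat_mass"] >= df.loc[obs, "weight"])).any():
        raise ValueError("fat_mass must satisfy 0 <= fat_mass < weight")
    if not (df["outcome_missing"].astype(int) == (~obs).astype(int)).all():
        raise ValueError("outcome_missing inconsistent with fat_mass presence")
    if not df["active"].dropna().isin([0, 1]).all():
        raise ValueError("active must be binary 0/1 where observed")
    if known_subjects is not None:
        orphans = set(df["subject_id"]) - known_subjects
        if orphans:
            logger.warning("visits reference unknown subjects: %s",
                           sorted(orphans)[:5])
    return df


def write_visits(df: pd.DataFrame, path: str | Path) -> None:
    df[_VISIT_COLS].to_csv(path, index=False)
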