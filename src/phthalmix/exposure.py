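"""Deterministic exposure transformations.

Covers every preprocessing step applied to urinary metabolite
concentrations before modeling: analytical-standard correction factors,
exclusion of dilute samples, LOD/sqrt(2) substitution for descriptive
tables, geometric-mean descriptives, the DEHP molar sum, creatinine
correction, standardization, and tertile coding.

Units: concentrations ug/L; creatinine mg/dL; the DEHP molar sum umol/L;
creatinine-corrected values ug/g (umol/g for the DEHP sum).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .registry import DEHP_CODES, MetaboliteSpec

__all__ = [
    "ExposureMatrix",
    "StandardizationConstants",
    "apply_correction_factors",
    "exclude_dilute",
    "substitute_lod_sqrt2",
    "descriptive_table",
    "molar_sum_dehp",
    "creatinine_correct",
    "standardize_exposure",
    "standardize_covariate",
    "ExposureStandardizer",
    "TwoSDScaler",
    "TertileEncoder",
    "tertile_categorize",
]


@dataclasses.dataclass
class ExposureMatrix:
    """Corrected concentrations for one cohort, column order = registry order.

    ``values[i, j]`` is the corrected concentration (ug/L) of metabolite
    ``codes[j]`` for subject ``subject_id[i]``; where ``censored[i, j]``
    the stored value is the corrected-LOD placeholder and is never used
    directly in modeling.
    """

    subject_id: np.ndarray
    codes: list[str]
    values: np.ndarray
    censored: np.ndarray
    lods: np.ndarray  # corrected LODs, ug/L
    creatinine: np.ndarray  # mg/dL

    @property
    def n(self) -> int:
        return len(self.subject_id)

    def column(self, code: str) -> np.ndarray:
        return self.values[:, self.codes.index(code)]


def apply_correction_factors(mothers: pd.DataFrame,
                             registry: list[MetaboliteSpec]) -> ExposureMatrix:
    """Scale raw concentrations and LODs by each metabolite's correction
    factor (MBzP and MEP in the default registry; factor 1.0 elsewhere)."""
    codes = [s.code for s in registry]
    vals = np.column_stack(
        [mothers[f"conc_{s.code}"].to_numpy(float) * s.correction_factor
         for s in registry])
    cens = np.column_stack(
        [mothers[f"cens_{s.code}"].to_numpy(bool) for s in registry])
    if not (vals[~cens] > 0).all():
        raise ValueError("observed concentrations must be > 0")
    lods = np.array([s.corrected_lod for s in registry])
    return ExposureMatrix(
        subject_id=mothers["subject_id"].to_numpy(),
        codes=codes, values=vals, censored=cens, lods=lods,
        creatinine=mothers["creatinine"].to_numpy(float),
    )


def exclude_dilute(mothers: pd.DataFrame, threshold_mg_dl: float = 10.0
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop dilute urine samples (creatinine strictly below the threshold).

    Returns ``(kept, excluded)``; exclusion is strict ``<`` so a sample at
    exactly 10 mg/dL is kept.
    """
    if mothers["creatinine"].isna().any():
        raise ValueError("creatinine must be present")
    mask = mothers["creatinine"] < threshold_mg_dl
    return (mothers.loc[~mask].reset_index(drop=True),
            mothers.loc[mask].reset_index(drop=True))


def substitute_lod_sqrt2(matrix: ExposureMatrix) -> ExposureMatrix:
    """Replace censored cells by corrected LOD / sqrt(2) (descriptives only).

    Observed cells are untouched; the returned matrix keeps the censor
    flags so downstream code can still tell which cells were imputed.
    """
    vals = matrix.values.copy()
    lod_grid = np.broadcast_to(matrix.lods, vals.shape)
    vals[matrix.censored] = lod_grid[matrix.censored] / np.sqrt(2.0)
    return dataclasses.replace(matrix, values=vals)


def descriptive_table(matrix: ExposureMatrix,
                      registry: list[MetaboliteSpec] | None = None
                      ) -> pd.DataFrame:
    """Per-metabolite descriptives on an LOD/sqrt(2)-completed matrix.

    Columns: percent detected, geometric mean ``exp(mean(ln x))``,
    minimum, 25th/75th percentile (linear interpolation between order
    statistics), maximum. When a registry is given, a ``SumDEHP`` row
    (umol/L) computed from the completed component values is appended.
    """
    rows = {}
    cols = {code: matrix.values[:, j] for j, code in enumerate(matrix.codes)}
    detected = {code: 100.0 * (1 - matrix.censored[:, j].mean())
                for j, code in enumerate(matrix.codes)}
    if registry is not None:
        comp = np.column_stack([cols[c] for c in DEHP_CODES])
        cols["SumDEHP"] = molar_sum_dehp(comp, registry)
        detected["SumDEHP"] = np.nan
    for code, x in cols.items():
        rows[code] = {
            "percent_detected": detected[code],
            "geometric_mean": float(np.exp(np.mean(np.log(x)))),
            "min": float(np.min(x)),
            "p25": float(np.percentile(x, 25)),
            "p75": float(np.percentile(x, 75)),
            "max": float(np.max(x)),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "metabolite"
    return out


def molar_sum_dehp(values: np.ndarray,
                   registry: list[MetaboliteSpec]) -> np.ndarray:
    """Molar sum of the four DEHP metabolites, umol/L.

    ``values`` has one column per DEHP code in ``DEHP_CODES`` order
    (ug/L); each column is divided by its molecular weight (ug/umol) and
    the quotients summed.
    """
    mw = {s.code: s.mol_weight for s in registry if s.group == "DEHP"}
    if set(mw) != set(DEHP_CODES):
        raise ValueError("registry must define the four DEHP metabolites")
    values = np.asarray(values, float)
    if values.ndim == 1:
        values = values[None, :]
        return float((values / np.array([mw[c] for c in DEHP_CODES])).sum())
    return (values / np.array([mw[c] for c in DEHP_CODES])).sum(axis=1)


def creatinine_correct(conc: np.ndarray, creatinine: np.ndarray) -> np.ndarray:
    """Creatinine-corrected concentration: ug/L divided by g/L creatinine.

    100 mg/dL = 1 g/L, so the result is conc / (creatinine * 0.01) in
    ug/g (umol/g when ``conc`` is the DEHP molar sum in umol/L).
    """
    creatinine = np.asarray(creatinine, float)
    if np.any(creatinine <= 0):
        raise ValueError("creatinine must be > 0")
    return np.asarray(conc, float) / (creatinine * 0.01)


@dataclasses.dataclass(frozen=True)
class StandardizationConstants:
    """Frozen mean/SD pairs used to standardize exposures and covariates.

    Exposures are standardized as ``(ln x - mu) / sd``; continuous
    covariates as ``(x - mu) / (2 sd)`` so one unit is a 2-SD change,
    comparable to a binary covariate flip. Constants are computed once
    from the LOD/sqrt(2)-completed data and never updated during MCMC.
    """

    exposure: dict[str, tuple[float, float]]
    covariate: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for d in (self.exposure, self.covariate):
            for name, (_, sd) in d.items():
                if not sd > 0:
                    raise ValueError(f"SD for {name} must be > 0")


def standardize_exposure(ln_value: np.ndarray, mu: float, sd: float
                         ) -> np.ndarray:
    """(ln x - mu) / sd with frozen constants."""
    if not sd > 0:
        raise ValueError("sd must be > 0")
    return (np.asarray(ln_value, float) - mu) / sd


def standardize_covariate(value: np.ndarray, mu: float, sd: float
                          ) -> np.ndarray:
    """(x - mu) / (2 sd): one unit equals a 2-SD change."""
    if not sd > 0:
        raise ValueError("sd must be > 0")
    return (np.asarray(value, float) - mu) / (2.0 * sd)


class ExposureStandardizer(TransformerMixin, BaseEstimator):
    """Transformer freezing per-column ln-scale means and SDs.

    ``fit`` consumes a completed concentration matrix (n, k), stores
    ``mu_``/``sd_`` of the natural logs; ``transform`` maps new
    concentrations to standardized ln z-scores with the frozen constants.
    """

    def fit(self, X, y=None):
        ln = np.log(np.asarray(X, float))
        self.mu_ = ln.mean(axis=0)
        self.sd_ = ln.std(axis=0, ddof=1)
        if np.any(self.sd_ <= 0):
            raise ValueError("degenerate (constant) exposure column")
        return self

    def transform(self, X):
        return (np.log(np.asarray(X, float)) - self.mu_) / self.sd_


class TwoSDScaler(TransformerMixin, BaseEstimator):
    """Covariate scaler dividing centred values by twice the SD."""

    def fit(self, X, y=None):
        X = np.asarray(X, float)
        self.mu_ = X.mean(axis=0)
        self.sd_ = X.std(axis=0, ddof=1)
        if np.any(self.sd_ <= 0):
            raise ValueError("degenerate (constant) covariate column")
        return self

    def transform(self, X):
        return (np.asarray(X, float) - self.mu_) / (2.0 * self.sd_)


class TertileEncoder(TransformerMixin, BaseEstimator):
    """Tertile coder with cut points frozen on the analysis sample.

    ``fit`` stores the 1/3 and 2/3 empirical quantiles (linear
    interpolation between order statistics) of each column; ``transform``
    returns integer categories in {1, 2, 3}, values exactly at a cut
    point falling in the lower tertile. ``indicators`` expands categories
    to the second- and third-tertile dummy pair used in regression.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, float)
        if X.ndim == 1:
            X = X[:, None]
        self.q_ = np.quantile(X, [1 / 3, 2 / 3], axis=0)
        if np.any(self.q_[0] >= self.q_[1]):
            raise ValueError("degenerate tertiles: cut points coincide")
        return self

    def transform(self, X):
        X = np.asarray(X, float)
        squeeze = X.ndim == 1
        if squeeze:
            X = X[:, None]
        cat = 1 + (X > self.q_[0]).astype(int) + (X > self.q_[1]).astype(int)
        return cat[:, 0] if squeeze else cat

    @staticmethod
    def indicators(categories: np.ndarray) -> np.ndarray:
        cat = np.asarray(categories)
        return np.column_stack([(cat == 2).astype(float),
                                (cat == 3).astype(float)])


def tertile_categorize(values: np.ndarray) -> np.ndarray:
    """One-shot tertile categories for an analysis-sample vector."""
    return TertileEncoder().fit(values).transform(values)
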