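"""Outcome and derived-covariate construction.

Percent fat mass from bioimpedance fat mass and weight, BMI, LMS-based
age/sex-standardized z-scores, adequacy of gestational weight gain
against expected gain, and the binary physical-activity classification.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

__all__ = [
    "percent_fat_mass",
    "bmi",
    "lms_zscore",
    "IOMParams",
    "gwg_adequacy",
    "gwg_category",
    "gwg_ratio",
    "classify_activity",
    "build_outcomes",
]


def percent_fat_mass(fat_kg, weight_kg):
    """(fat mass / weight) x 100, in percent."""
    fat = np.asarray(fat_kg, float)
    wt = np.asarray(weight_kg, float)
    obs = ~np.isnan(fat)
    if np.any(fat[obs] < 0) or np.any(fat[obs] >= wt[obs]):
        raise ValueError("fat mass must satisfy 0 <= fat < weight")
    return fat / wt * 100.0


def bmi(weight_kg, height_m):
    """Body-mass index, kg/m^2."""
    ht = np.asarray(height_m, float)
    if np.any(ht <= 0):
        raise ValueError("height must be > 0")
    return np.asarray(weight_kg, float) / ht**2


def lms_zscore(x, L, M, S):
    """LMS z-score: ((x/M)^L - 1)/(L*S), or ln(x/M)/S when L == 0."""
    x, L, M, S = (np.asarray(v, float) for v in (x, L, M, S))
    if np.any(M <= 0) or np.any(S <= 0):
        raise ValueError("M and S must be > 0")
    t = np.log(x / M)
    Lsafe = np.where(L == 0, 1.0, L)
    with np.errstate(divide="ignore", invalid="ignore"):
        # expm1 keeps the L -> 0 limit numerically continuous
        z = np.where(L == 0, t / S, np.expm1(Lsafe * t) / (Lsafe * S))
    return z


@dataclasses.dataclass(frozen=True)
class IOMParams:
    """Operationalized 2009 IOM gestational weight-gain recommendations.

    Expected gain = ``base_gain`` (first-trimester total, kg) plus the
    BMI-class weekly rate (kg/wk) applied beyond week 13. Rates are the
    recommended-range midpoints for underweight (< 18.5), normal
    (18.5-24.9), overweight (25-29.9) and obese (>= 30) prepregnancy BMI.
    """

    base_gain: float = 2.0
    rate_under: float = 0.51
    rate_normal: float = 0.42
    rate_over: float = 0.28
    rate_obese: float = 0.22

    def weekly_rate(self, prepreg_bmi) -> np.ndarray:
        b = np.asarray(prepreg_bmi, float)
        return np.select(
            [b < 18.5, b < 25.0, b < 30.0],
            [self.rate_under, self.rate_normal, self.rate_over],
            default=self.rate_obese)

    def expected_gain(self, prepreg_bmi, gestational_age_wk) -> np.ndarray:
        wk = np.asarray(gestational_age_wk, float)
        return self.base_gain + self.weekly_rate(prepreg_bmi) * np.maximum(
            0.0, wk - 13.0)


def gwg_ratio(last_weight, prepreg_weight, gestational_age_wk, prepreg_bmi,
              iom: IOMParams | None = None) -> np.ndarray:
    """Observed / expected gestational weight gain x 100 (percent)."""
    iom = iom or IOMParams()
    observed = np.asarray(last_weight, float) - np.asarray(prepreg_weight,
                                                           float)
    expected = iom.expected_gain(prepreg_bmi, gestational_age_wk)
    return observed / expected * 100.0


def gwg_category(ratio):
    """Category for an adequacy ratio in percent: ``less`` (< 86),
    ``recommended`` (86-120, endpoints inclusive), ``more`` (> 120)."""
    ratio = np.asarray(ratio, float)
    return np.select([ratio < 86.0, ratio <= 120.0],
                     ["less", "recommended"], default="more")


def gwg_adequacy(last_weight, prepreg_weight, gestational_age_wk, prepreg_bmi,
                 iom: IOMParams | None = None):
    """Adequacy ratio (percent) and category (see :func:`gwg_category`)."""
    ratio = gwg_ratio(last_weight, prepreg_weight, gestational_age_wk,
                      prepreg_bmi, iom)
    cat = gwg_category(ratio)
    if np.isscalar(last_weight) or np.ndim(ratio) == 0:
        return float(ratio), str(cat)
    return ratio, cat


_ACTIVE = "active most of the time"
_INACTIVE = {"active some of the time", "some of the time", "hardly at all"}


def classify_activity(raw_response):
    """1 iff the caretaker reported 'active most of the time'; missing
    responses propagate as NaN for in-MCMC imputation."""
    def one(r):
        if r is None or (isinstance(r, float) and np.isnan(r)):
            return np.nan
        r = str(r).strip().lower()
        if r == _ACTIVE:
            return 1.0
        if r in _INACTIVE:
            return 0.0
        raise ValueError(f"unrecognized activity response: {r!r}")

    if isinstance(raw_response, (list, tuple, np.ndarray, pd.Series)):
        return np.array([one(r) for r in raw_response])
    return one(raw_response)


def build_outcomes(visits: pd.DataFrame, mothers: pd.DataFrame,
                   lms: pd.DataFrame | None = None) -> pd.DataFrame:
    """Assemble the outcome table keyed by (subject, visit).

    Adds percent fat mass, BMI, and (when an LMS reference is supplied)
    the age/sex-standardized BMI z-score looked up at the nearest
    reference age for the child's sex.
    """
    out = visits.merge(mothers[["subject_id", "child_sex"]], on="subject_id")
    out["pct_fat"] = percent_fat_mass(out["fat_mass"], out["weight"])
    out["bmi"] = bmi(out["weight"], out["height"])
    if lms is not None:
        zs = np.full(len(out), np.nan)
        for sex, grp in out.groupby("child_sex"):
            ref = lms[lms["sex"] == sex]
            if ref.empty:
                continue
            idx = np.abs(ref["age_months"].to_numpy()[None, :]
                         - grp["age_months"].to_numpy()[:, None]).argmin(axis=1)
            r = ref.iloc[idx]
            zs[grp.index] = lms_zscore(grp["bmi"], r["L"].to_numpy(),
                                       r["M"].to_numpy(), r["S"].to_numpy())
        out["bmi_z"] = zs
    return out[["subject_id", "visit", "age_months", "pct_fat", "bmi"]
               + (["bmi_z"] if lms is not None else [])]
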