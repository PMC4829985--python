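"""Assembly of the analysis dataset and fixed-effect design matrix.

This module turns the raw cohort tables into the frozen numeric
structures the Gibbs sampler operates on: the fixed-effect design with
its column groups (exposures, demographic covariates, raw-power
polynomial expansions), the frozen standardization constants, the
censored-cell imputation parameters, the covariate-imputation submodel
designs, and — for selection-model fits — the missingness design over
the full three-visit grid.

Standardization constants are computed once from the LOD/sqrt(2)-
completed data and never updated inside the MCMC, keeping the design
stable across iterations.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import exposure as xp
from .outcomes import IOMParams, percent_fat_mass
from .registry import DEHP_CODES, MetaboliteSpec

__all__ = ["ModelSpec", "MCMCSettings", "SelectionSpec", "AnalysisData",
           "build_analysis_data", "DEFAULT_EXPOSURES"]

DEFAULT_EXPOSURES = ("MEP", "MnBP", "MiBP", "MCPP", "MBzP", "SumDEHP")

_DEFAULT_POLY = {"maternal_age": 3, "prepreg_bmi": 2, "gwg_adequacy": 3,
                 "ln_creatinine": 2}


@dataclasses.dataclass
class MCMCSettings:
    burn_in: int = 10_000
    iterations: int = 50_000
    chains: int = 2
    thin: int = 1
    seed: int = 0

    def validate(self) -> None:
        if self.burn_in < 0 or self.iterations <= 0:
            raise ValueError("burn_in >= 0 and iterations > 0 required")
        if self.chains < 1 or self.thin < 1:
            raise ValueError("chains >= 1 and thin >= 1 required")


@dataclasses.dataclass
class ModelSpec:
    """Configuration of one outcome-model fit.

    ``tau_*`` are prior *precisions*: a coefficient prior is
    ``N(0, 1/tau)``. Defaults reproduce the primary analysis: shrinkage
    tau = 1/16 on standardized exposures, 1/64 on covariates, 1 on
    imputation-submodel coefficients.
    """

    exposure_coding: str = "continuous"  # continuous | tertile
    exposures: tuple[str, ...] = DEFAULT_EXPOSURES
    interaction: str = "none"  # none | sex
    tau_exposure: float = 1.0 / 16.0
    tau_covariate: float = 1.0 / 64.0
    tau_imputation: float = 1.0
    poly_degrees: dict[str, int] = dataclasses.field(
        default_factory=lambda: dict(_DEFAULT_POLY))
    creatinine_covariate: bool | None = None  # None = auto by coding
    variance_prior: tuple = ("inverse_gamma", 0.001, 0.001)
    random_intercept: bool = True
    outcome: str = "pct_fat"  # pct_fat | bmi_z
    mcmc: MCMCSettings = dataclasses.field(default_factory=MCMCSettings)

    def validate(self) -> None:
        if self.exposure_coding not in ("continuous", "tertile"):
            raise ValueError("exposure_coding must be continuous or tertile")
        if self.interaction not in ("none", "sex"):
            raise ValueError("interaction must be none or sex")
        for t in (self.tau_exposure, self.tau_covariate, self.tau_imputation):
            if not t > 0:
                raise ValueError("prior precisions must be > 0")
        if any(d < 1 for d in self.poly_degrees.values()):
            raise ValueError("polynomial degrees must be >= 1")
        if self.exposure_coding == "tertile" and self.creatinine_covariate:
            raise ValueError(
                "tertile models use creatinine-corrected concentrations and "
                "must not include natural log creatinine as a covariate")
        self.mcmc.validate()

    @property
    def use_creatinine(self) -> bool:
        if self.creatinine_covariate is None:
            return self.exposure_coding == "continuous"
        return self.creatinine_covariate


@dataclasses.dataclass
class SelectionSpec:
    """Configuration of the MNAR selection (missingness) model."""

    covariates: tuple[str, ...] = ("maternal_age", "race_ethnicity",
                                   "prepreg_bmi", "gwg_adequacy",
                                   "child_sex", "age_months")
    extra_covariates: tuple[str, ...] = ()
    tau_selection: float = 2.0
    chains: int = 10

    def validate(self) -> None:
        if not self.tau_selection > 0:
            raise ValueError("tau_selection must be > 0")
        if self.chains < 2:
            raise ValueError("selection model requires >= 2 chains")
        allowed = {"smoking", "breastfed", "education", "work_status",
                   "birth_weight"}
        bad = set(self.extra_covariates) - allowed
        if bad:
            raise ValueError(f"unsupported selection covariates: {bad}")


def _std2(x: np.ndarray) -> tuple[np.ndarray, float, float]:
    mu = float(np.nanmean(x))
    sd = float(np.nanstd(x, ddof=1))
    if not sd > 0:
        raise ValueError("constant covariate cannot be standardized")
    return (x - mu) / (2.0 * sd), mu, sd


@dataclasses.dataclass
class AnalysisData:
    """Frozen numeric inputs for the sampler (see module docstring)."""

    # children and rows
    subject_ids: np.ndarray
    child_idx: np.ndarray
    y0: np.ndarray            # outcome per row, NaN where missing
    obs_mask: np.ndarray
    sex_child: np.ndarray
    sex_row: np.ndarray
    # fixed-effect design
    X0: np.ndarray
    col_names: list[str]
    prior_prec: np.ndarray
    exposure_cols: dict[str, list[int]]
    interaction_cols: dict[str, list[int]]
    breastfed_col: int | None
    active_col: int | None
    gwg_cols: list[int]
    # censored-exposure machinery (corrected ln scale)
    codes: list[str]
    ln_conc0: np.ndarray      # (m, k) ln corrected conc, completed
    censored: np.ndarray
    ln_lod: np.ndarray
    imp_mu: np.ndarray
    imp_sd: np.ndarray
    exp_std: dict[str, tuple[float, float]]
    mol_weight: np.ndarray    # aligned with DEHP_CODES
    dehp_pos: np.ndarray      # column positions of DEHP codes
    # gestational-weight-gain machinery
    prepreg_weight: np.ndarray
    expected_gain: np.ndarray
    gwg_std: tuple[float, float]
    W0: np.ndarray            # last pregnancy weight kg, NaN missing
    miss_W: np.ndarray
    W_std: tuple[float, float]
    # covariate-imputation submodels
    A_W: np.ndarray
    A_B: np.ndarray
    gwg_col_B: int
    B0: np.ndarray
    miss_B: np.ndarray
    A_A: np.ndarray
    active0: np.ndarray
    miss_A: np.ndarray
    # selection design (None for MAR fits)
    Z0: np.ndarray | None = None
    z_names: list[str] | None = None
    gwg_col_Z: int | None = None
    breastfed_col_Z: int | None = None
    y_center: float = 0.0
    spec: ModelSpec | None = None

    @property
    def m(self) -> int:
        return len(self.subject_ids)

    @property
    def n_rows(self) -> int:
        return len(self.y0)

    @property
    def p(self) -> int:
        return self.X0.shape[1]

    def gwg_ratio(self, W: np.ndarray) -> np.ndarray:
        return (W - self.prepreg_weight) / self.expected_gain * 100.0

    def gwg_z(self, W: np.ndarray) -> np.ndarray:
        mu, sd = self.gwg_std
        return (self.gwg_ratio(W) - mu) / (2.0 * sd)


def _expand_grid(visits: pd.DataFrame, mothers: pd.DataFrame,
                 visit_ages_yr=(4.9, 6.1, 7.8)) -> pd.DataFrame:
    """Full (subject x visit) grid for selection-model fits.

    Children absent from the visit table contribute rows at the
    visit-schedule mean ages with the outcome missing.
    """
    full = pd.MultiIndex.from_product(
        [mothers["subject_id"], [1, 2, 3]],
        names=["subject_id", "visit"]).to_frame(index=False)
    out = full.merge(visits, on=["subject_id", "visit"], how="left")
    sched = {v: a * 12.0 for v, a in zip((1, 2, 3), visit_ages_yr)}
    fill = out["age_months"].isna()
    out.loc[fill, "age_months"] = out.loc[fill, "visit"].map(sched)
    out["outcome_missing"] = out["fat_mass"].isna().astype(int)
    return out


def build_analysis_data(mothers: pd.DataFrame, visits: pd.DataFrame,
                        registry: list[MetaboliteSpec], spec: ModelSpec,
                        selection: SelectionSpec | None = None,
                        iom: IOMParams | None = None) -> AnalysisData:
    """Prepare one cohort for fitting.

    MAR fits keep observed-outcome rows of children with at least one
    follow-up visit; selection fits keep the full three-visit grid over
    all mothers with measured exposures.
    """
    spec.validate()
    if selection is not None:
        selection.validate()
    iom = iom or IOMParams()

    mothers, _ = xp.exclude_dilute(mothers)
    # canonical child ordering: visit rows are grouped per child below
    mothers = mothers.sort_values("subject_id").reset_index(drop=True)

    if selection is None:
        obs = visits[visits["outcome_missing"] == 0]
        keep = mothers["subject_id"].isin(set(obs["subject_id"]))
        mothers = mothers.loc[keep].reset_index(drop=True)
        vrows = obs[obs["subject_id"].isin(set(mothers["subject_id"]))]
        vrows = vrows.sort_values(["subject_id", "visit"]).reset_index(
            drop=True)
    else:
        vrows = _expand_grid(visits, mothers).sort_values(
            ["subject_id", "visit"]).reset_index(drop=True)
    if vrows.empty:
        raise ValueError("no analysis rows")
    if selection is not None and vrows["outcome_missing"].all():
        raise ValueError("all outcomes missing")

    matrix = xp.apply_correction_factors(mothers, registry)
    completed = xp.substitute_lod_sqrt2(matrix)
    codes = matrix.codes
    k = len(codes)
    m = matrix.n

    sid_to_idx = {s: i for i, s in enumerate(mothers["subject_id"])}
    child_idx = vrows["subject_id"].map(sid_to_idx).to_numpy(int)

    # outcome per row
    if spec.outcome == "pct_fat":
        y0 = percent_fat_mass(vrows["fat_mass"], vrows["weight"])
        y0 = np.asarray(y0, float)
    else:
        raise ValueError(f"unsupported outcome {spec.outcome!r}")
    obs_mask = ~np.isnan(y0)

    # frozen censored-cell imputation parameters from observed values
    ln_obs = np.log(matrix.values)
    imp_mu = np.empty(k)
    imp_sd = np.empty(k)
    for j in range(k):
        vals = ln_obs[~matrix.censored[:, j], j]
        if len(vals) < 2:
            raise ValueError(f"too few observed values for {codes[j]}")
        imp_mu[j] = vals.mean()
        imp_sd[j] = vals.std(ddof=1)
    ln_lod = np.log(matrix.lods)

    # frozen exposure standardization constants from completed data
    ln_comp = np.log(completed.values)
    mol_weight = np.array([s.mol_weight for c in DEHP_CODES
                           for s in registry if s.code == c])
    dehp_pos = np.array([codes.index(c) for c in DEHP_CODES])
    ln_sum = np.log((completed.values[:, dehp_pos] / mol_weight).sum(axis=1))
    exp_std: dict[str, tuple[float, float]] = {}
    for name in spec.exposures:
        v = ln_sum if name == "SumDEHP" else ln_comp[:, codes.index(name)]
        exp_std[name] = (float(v.mean()), float(v.std(ddof=1)))
        if not exp_std[name][1] > 0:
            raise ValueError(f"degenerate exposure {name}")

    # mother-level covariates
    sex_child = mothers["child_sex"].to_numpy(float)
    race = mothers["race_ethnicity"].to_numpy(int)
    race_black = (race == 1).astype(float)
    race_hisp = (race == 2).astype(float)
    z_mage, *_ = _std2(mothers["maternal_age"].to_numpy(float))
    z_bmi, *_ = _std2(mothers["prepreg_bmi"].to_numpy(float))
    z_height, *_ = _std2(mothers["maternal_height"].to_numpy(float))
    z_birthw, *_ = _std2(mothers["birth_weight"].to_numpy(float))
    z_gestage, *_ = _std2(mothers["gestational_age"].to_numpy(float))
    z_firstw, *_ = _std2(mothers["first_preg_weight"].to_numpy(float))
    days = (pd.to_datetime(mothers["collection_date"])
            - pd.to_datetime(mothers["collection_date"]).min()
            ).dt.days.to_numpy(float)
    z_date, *_ = _std2(days)
    ln_creat = np.log(mothers["creatinine"].to_numpy(float))
    z_creat, *_ = _std2(ln_creat)

    # gestational weight gain: ratio as a function of last pregnancy weight
    prepreg_weight = (mothers["prepreg_bmi"]
                      * mothers["maternal_height"] ** 2).to_numpy(float)
    expected = np.asarray(iom.expected_gain(
        mothers["prepreg_bmi"], mothers["gestational_age"]), float)
    W0 = mothers["last_preg_weight"].to_numpy(float)
    miss_W = np.flatnonzero(np.isnan(W0))
    W_obs = W0[~np.isnan(W0)]
    if len(W_obs) < 2:
        raise ValueError("too few observed last pregnancy weights")
    W_std = (float(W_obs.mean()), float(W_obs.std(ddof=1)))
    ratio_obs = (W_obs - prepreg_weight[~np.isnan(W0)]) \
        / expected[~np.isnan(W0)] * 100.0
    gwg_std = (float(ratio_obs.mean()), float(ratio_obs.std(ddof=1)))

    B0 = mothers["breastfed"].to_numpy(float)
    miss_B = np.flatnonzero(np.isnan(B0))

    # row-level covariates
    sex_row = sex_child[child_idx]
    z_age_row, *_ = _std2(vrows["age_months"].to_numpy(float))
    active0 = vrows["active"].to_numpy(float)
    miss_A = np.flatnonzero(np.isnan(active0))

    # --- fixed-effect design ---------------------------------------
    cols: list[np.ndarray] = []
    names: list[str] = []
    prec: list[float] = []
    exposure_cols: dict[str, list[int]] = {}
    interaction_cols: dict[str, list[int]] = {}

    def add(col, name, tau):
        cols.append(np.asarray(col, float))
        names.append(name)
        prec.append(tau)
        return len(names) - 1

    add(np.ones(len(vrows)), "intercept", spec.tau_covariate)

    if spec.exposure_coding == "continuous":
        for name in spec.exposures:
            mu, sd = exp_std[name]
            v = ln_sum if name == "SumDEHP" \
                else np.log(completed.values[:, codes.index(name)])
            zc = (v - mu) / sd
            exposure_cols[name] = [add(zc[child_idx], name,
                                       spec.tau_exposure)]
    else:
        creat = completed.creatinine
        for name in spec.exposures:
            if name == "SumDEHP":
                conc = (completed.values[:, dehp_pos] / mol_weight).sum(axis=1)
            else:
                conc = completed.values[:, codes.index(name)]
            cc = xp.creatinine_correct(conc, creat)
            cat = xp.tertile_categorize(cc)
            ind = xp.TertileEncoder.indicators(cat)
            exposure_cols[name] = [
                add(ind[child_idx, 0], f"{name}_T2", spec.tau_exposure),
                add(ind[child_idx, 1], f"{name}_T3", spec.tau_exposure)]

    add(sex_row, "sex", spec.tau_covariate)
    add(z_age_row, "age", spec.tau_covariate)
    add(sex_row * z_age_row, "sex:age", spec.tau_covariate)
    add(race_black[child_idx], "race_black", spec.tau_covariate)
    add(race_hisp[child_idx], "race_hispanic", spec.tau_covariate)
    add(mothers["education"].to_numpy(float)[child_idx], "education",
        spec.tau_covariate)
    add(mothers["work_status"].to_numpy(float)[child_idx], "work_status",
        spec.tau_covariate)
    add(mothers["smoking"].to_numpy(float)[child_idx], "smoking",
        spec.tau_covariate)
    B_init = np.where(np.isnan(B0), float(np.nanmean(B0) >= 0.5), B0)
    breastfed_col = add(B_init[child_idx], "breastfed", spec.tau_covariate)
    A_init = np.where(np.isnan(active0),
                      float(np.nanmean(active0) >= 0.5), active0)
    active_col = add(A_init, "active", spec.tau_covariate)
    add(z_height[child_idx], "height", spec.tau_covariate)
    for d in range(1, spec.poly_degrees.get("maternal_age", 3) + 1):
        add(z_mage[child_idx] ** d, f"maternal_age^{d}", spec.tau_covariate)
    for d in range(1, spec.poly_degrees.get("prepreg_bmi", 2) + 1):
        add(z_bmi[child_idx] ** d, f"prepreg_bmi^{d}", spec.tau_covariate)
    W_init = W0.copy()
    W_init[miss_W] = W_std[0]
    gwg_mu, gwg_sd = gwg_std
    zg = ((W_init - prepreg_weight) / expected * 100.0 - gwg_mu) / (2 * gwg_sd)
    gwg_cols = []
    for d in range(1, spec.poly_degrees.get("gwg_adequacy", 3) + 1):
        gwg_cols.append(add(zg[child_idx] ** d, f"gwg^{d}",
                            spec.tau_covariate))
    if spec.use_creatinine:
        for d in range(1, spec.poly_degrees.get("ln_creatinine", 2) + 1):
            add(z_creat[child_idx] ** d, f"ln_creatinine^{d}",
                spec.tau_covariate)
    add(z_date[child_idx], "collection_date", spec.tau_covariate)

    if spec.interaction == "sex":
        for name, idxs in exposure_cols.items():
            interaction_cols[name] = [
                add(sex_row * cols[j], f"sex:{names[j]}", spec.tau_exposure)
                for j in idxs]
        if spec.use_creatinine:
            add(sex_row * z_creat[child_idx], "sex:ln_creatinine",
                spec.tau_covariate)

    X0 = np.column_stack(cols)

    # --- covariate-imputation submodel designs ----------------------
    A_W = np.column_stack([
        np.ones(m), mothers["education"], race_black, race_hisp, sex_child,
        mothers["smoking"], mothers["work_status"], z_mage, z_birthw,
        z_height, z_gestage, z_firstw, z_bmi]).astype(float)
    A_B_cols = [np.ones(m), mothers["education"].to_numpy(float), race_black,
                race_hisp, sex_child, mothers["smoking"].to_numpy(float),
                mothers["work_status"].to_numpy(float), z_mage, zg,
                z_bmi, z_birthw]
    gwg_col_B = 8
    A_B = np.column_stack(A_B_cols)
    A_A = np.column_stack([
        np.ones(len(vrows)), race_black[child_idx], race_hisp[child_idx],
        z_bmi[child_idx], mothers["smoking"].to_numpy(float)[child_idx],
        z_age_row, z_birthw[child_idx], sex_row]).astype(float)

    # --- selection design -------------------------------------------
    Z0 = z_names_out = gwg_col_Z = breastfed_col_Z = None
    if selection is not None:
        zcols, z_names_out = [], []
        pool = {
            "maternal_age": z_mage[child_idx],
            "race_ethnicity": None,  # handled as two indicators below
            "prepreg_bmi": z_bmi[child_idx],
            "gwg_adequacy": zg[child_idx],
            "child_sex": sex_row,
            "age_months": z_age_row,
            "smoking": mothers["smoking"].to_numpy(float)[child_idx],
            "education": mothers["education"].to_numpy(float)[child_idx],
            "work_status": mothers["work_status"].to_numpy(float)[child_idx],
            "birth_weight": z_birthw[child_idx],
            "breastfed": B_init[child_idx],
        }
        for name in tuple(selection.covariates) + tuple(
                selection.extra_covariates):
            if name == "race_ethnicity":
                zcols += [race_black[child_idx], race_hisp[child_idx]]
                z_names_out += ["race_black", "race_hispanic"]
            else:
                zcols.append(pool[name])
                z_names_out.append(name)
        Z0 = np.column_stack(zcols)
        gwg_col_Z = (z_names_out.index("gwg_adequacy")
                     if "gwg_adequacy" in z_names_out else None)
        breastfed_col_Z = (z_names_out.index("breastfed")
                           if "breastfed" in z_names_out else None)

    return AnalysisData(
        subject_ids=mothers["subject_id"].to_numpy(),
        child_idx=child_idx, y0=y0, obs_mask=obs_mask,
        sex_child=sex_child, sex_row=sex_row,
        X0=X0, col_names=names, prior_prec=np.asarray(prec),
        exposure_cols=exposure_cols, interaction_cols=interaction_cols,
        breastfed_col=breastfed_col, active_col=active_col,
        gwg_cols=gwg_cols,
        codes=codes, ln_conc0=np.log(completed.values),
        censored=matrix.censored, ln_lod=ln_lod,
        imp_mu=imp_mu, imp_sd=imp_sd, exp_std=exp_std,
        mol_weight=mol_weight, dehp_pos=dehp_pos,
        prepreg_weight=prepreg_weight, expected_gain=expected,
        gwg_std=gwg_std, W0=W0, miss_W=miss_W, W_std=W_std,
        A_W=A_W, A_B=A_B, gwg_col_B=gwg_col_B, B0=B0, miss_B=miss_B,
        A_A=A_A, active0=active0, miss_A=miss_A,
        Z0=Z0, z_names=z_names_out, gwg_col_Z=gwg_col_Z,
        breastfed_col_Z=breastfed_col_Z,
        y_center=float(np.mean(y0[obs_mask])), spec=spec,
    )
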