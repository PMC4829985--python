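"""Bayesian random-intercept mixed model with shrinkage priors.

The outcome model is

    y_ij = x_ij' beta + b_i + e_ij,   b_i ~ N(0, sigma_b^2),
                                      e_ij ~ N(0, sigma_e^2),

with independent null-centred normal priors N(0, 1/tau) on every fixed
effect: tau = 1/16 for standardized exposure coefficients (so a 1-SD
exposure shift is a priori within about +/- 1 outcome SD), tau = 1/64
for covariates, tau = 1 for imputation-submodel coefficients. Inference
is by a blocked Gibbs sampler with Metropolis steps for the logistic
pieces:

* censored ln concentrations are redrawn each sweep from a normal
  distribution truncated above at ln LOD, with frozen mean/SD taken
  from the observed (above-LOD) values; the DEHP molar sum is then
  recomputed from the current component values and restandardized with
  frozen constants;
* missing last pregnancy weight is drawn by independence Metropolis
  from its normal submodel, accepted against the outcome (and, where
  present, breastfeeding-submodel and selection-model) likelihood so the
  gestational-weight-gain polynomial feeds back correctly;
* missing breastfeeding and physical-activity indicators are drawn from
  their exact two-point full conditionals;
* fixed effects, random intercepts and variances use standard conjugate
  updates (inverse-gamma variance priors by default).
"""

from __future__ import annotations

import copy
import dataclasses

import numpy as np
from numpy import log1p
from scipy.special import ndtri
from sklearn.base import BaseEstimator

from .design import (AnalysisData, MCMCSettings, ModelSpec,
                     build_analysis_data)
from .registry import default_registry

__all__ = ["ParameterState", "GibbsSampler", "truncated_normal_below",
           "draw_coefficients", "impute_censored", "impute_covariates",
           "gibbs_sweep", "log_joint", "ShrinkageLMM"]

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


def _norm_logpdf(x, mu, sig2):
    return -0.5 * (x - mu) ** 2 / sig2 - 0.5 * np.log(sig2) - _LOG_SQRT_2PI


def _log_sigmoid(eta):
    return np.where(eta > 0, -log1p(np.exp(-eta)), eta - log1p(np.exp(eta)))


def _norm_cdf(x):
    from scipy.special import ndtr
    return ndtr(x)


def truncated_normal_below(mu, sd, upper, rng, size=None):
    """Draw N(mu, sd^2) truncated to (-inf, upper] by inverse-CDF.

    Vectorized over broadcastable ``mu``, ``sd``, ``upper``.
    """
    mu, sd, upper = np.broadcast_arrays(
        *(np.asarray(a, float) for a in (mu, sd, upper)))
    if np.any(sd <= 0):
        raise ValueError("sd must be > 0")
    p_up = _norm_cdf((upper - mu) / sd)
    shape = mu.shape if size is None else size
    u = rng.random(shape) * p_up
    u = np.clip(u, 1e-300, 1.0)
    return mu + sd * ndtri(u)


def draw_coefficients(X, y_adj, sig2_e, prior_prec, rng):
    """Conjugate draw of a Gaussian-likelihood coefficient block.

    Posterior precision is ``X'X / sig2_e + diag(prior_prec)``; with no
    rows (pure prior) the draw comes from N(0, 1/prior_prec).
    """
    p = len(prior_prec)
    prec = np.diag(np.asarray(prior_prec, float)).copy()
    rhs = np.zeros(p)
    if X is not None and len(X):
        prec += X.T @ X / sig2_e
        rhs = X.T @ y_adj / sig2_e
    L = np.linalg.cholesky(prec)
    mean = np.linalg.solve(prec, rhs)
    z = rng.standard_normal(p)
    return mean + np.linalg.solve(L.T, z)


@dataclasses.dataclass
class ParameterState:
    """Mutable sampler state; ``X`` (and ``Z``) hold the current design."""

    beta: np.ndarray
    b: np.ndarray
    sig2_e: float
    sig2_b: float
    ln_conc: np.ndarray
    W: np.ndarray
    B: np.ndarray
    active: np.ndarray
    theta_W: np.ndarray
    sig2_W: float
    theta_B: np.ndarray
    theta_A: np.ndarray
    u: np.ndarray
    sig2_u: float
    X: np.ndarray
    A_B: np.ndarray
    y: np.ndarray
    gamma: np.ndarray | None = None
    Z: np.ndarray | None = None

    def copy(self) -> "ParameterState":
        return copy.deepcopy(self)


def init_state(data: AnalysisData, rng: np.random.Generator
               ) -> ParameterState:
    y_obs = data.y0[data.obs_mask]
    var_y = float(np.var(y_obs)) if len(y_obs) > 1 else 1.0
    W = data.W0.copy()
    W[data.miss_W] = data.W_std[0]
    B = data.B0.copy()
    if len(data.miss_B):
        B[data.miss_B] = float(np.nanmean(data.B0) >= 0.5)
    active = data.active0.copy()
    if len(data.miss_A):
        active[data.miss_A] = float(np.nanmean(data.active0) >= 0.5)
    y = data.y0.copy()
    y[~data.obs_mask] = float(np.mean(y_obs))
    st = ParameterState(
        beta=np.zeros(data.p), b=np.zeros(data.m),
        sig2_e=max(var_y / 2.0, 1e-3), sig2_b=max(var_y / 2.0, 1e-3),
        ln_conc=data.ln_conc0.copy(), W=W, B=B, active=active,
        theta_W=np.zeros(data.A_W.shape[1]), sig2_W=1.0,
        theta_B=np.zeros(data.A_B.shape[1]),
        theta_A=np.zeros(data.A_A.shape[1]),
        u=np.zeros(data.m), sig2_u=1.0,
        X=data.X0.copy(), A_B=data.A_B.copy(), y=y,
        gamma=(np.zeros(2 + data.Z0.shape[1])
               if data.Z0 is not None else None),
        Z=(data.Z0.copy() if data.Z0 is not None else None),
    )
    return st


# ----------------------------------------------------------------------
# sweep components
# ----------------------------------------------------------------------

class GibbsSampler:
    """One-chain blocked Gibbs/Metropolis sampler.

    Parameters
    ----------
    data : AnalysisData
        Frozen design structures from :func:`build_analysis_data`.
    seed : int or numpy Generator state
        Chain seed.
    tau_selection : float, optional
        Prior precision for selection-model coefficients (MNAR fits).
    """

    def __init__(self, data: AnalysisData, seed, tau_selection: float = 2.0):
        self.data = data
        self.spec = data.spec
        self.tau_selection = tau_selection
        self.rng = np.random.default_rng(seed)
        self.state = init_state(data, self.rng)
        self._setup()

    # -- precomputed structures -------------------------------------
    def _setup(self):
        d = self.data
        # per-child contiguous row blocks (rows sorted by child)
        assert np.all(np.diff(d.child_idx) >= 0)
        self.starts = np.searchsorted(d.child_idx, np.arange(d.m))
        self.n_per_child = np.bincount(d.child_idx, minlength=d.m)
        self.rows_of_child = [
            np.arange(self.starts[i],
                      self.starts[i] + self.n_per_child[i])
            for i in range(d.m)]
        # censored cells
        ci, cj = np.nonzero(d.censored)
        self.cens_i, self.cens_j = ci, cj
        self.cens_mu = d.imp_mu[cj]
        self.cens_sd = d.imp_sd[cj]
        self.cens_up = d.ln_lod[cj]
        # which exposure columns need refreshing after imputation
        self.dyn_exposures = []
        if self.spec.exposure_coding == "continuous":
            for name, cols in d.exposure_cols.items():
                j = None if name == "SumDEHP" else d.codes.index(name)
                if name == "SumDEHP" or d.censored[:, j].any():
                    self.dyn_exposures.append((name, j, cols[0]))
        # Metropolis proposal factors for logistic blocks
        tau = self.spec.tau_imputation
        self.L_B = self._prop_chol(d.A_B, tau)
        self.L_A = self._prop_chol(d.A_A, tau)
        if d.Z0 is not None:
            W0 = np.column_stack([np.ones(d.n_rows),
                                  self.state.y - d.y_center, d.Z0])
            self.L_G = self._prop_chol(W0, self.tau_selection)
        self.mis_rows = np.flatnonzero(~d.obs_mask)

    @staticmethod
    def _prop_chol(A, tau):
        info = 0.25 * A.T @ A + tau * np.eye(A.shape[1])
        cov = np.linalg.inv(info)
        return np.linalg.cholesky(cov) * 2.4 / np.sqrt(A.shape[1])

    # -- checkpointing ----------------------------------------------
    def get_state(self) -> dict:
        return {"params": self.state.copy(),
                "rng": copy.deepcopy(self.rng.bit_generator.state)}

    def set_state(self, snapshot: dict) -> None:
        self.state = snapshot["params"].copy()
        self.rng.bit_generator.state = copy.deepcopy(snapshot["rng"])

    # -- exposure columns ---------------------------------------------
    def _exposure_value(self, name, j):
        d, st = self.data, self.state
        if name == "SumDEHP":
            conc = np.exp(st.ln_conc[:, d.dehp_pos])
            v = np.log((conc / d.mol_weight).sum(axis=1))
        else:
            v = st.ln_conc[:, j]
        mu, sd = d.exp_std[name]
        return (v - mu) / sd

    def refresh_exposure_columns(self):
        d, st = self.data, self.state
        for name, j, col in self.dyn_exposures:
            z = self._exposure_value(name, j)[d.child_idx]
            st.X[:, col] = z
            if name in d.interaction_cols:
                st.X[:, d.interaction_cols[name][0]] = d.sex_row * z

    def impute_censored(self):
        """Redraw censored cells from the frozen truncated normal and
        propagate through the exposure (and DEHP molar-sum) columns."""
        if not len(self.cens_i) or self.spec.exposure_coding == "tertile":
            return
        draws = truncated_normal_below(self.cens_mu, self.cens_sd,
                                       self.cens_up, self.rng)
        self.state.ln_conc[self.cens_i, self.cens_j] = draws
        self.refresh_exposure_columns()

    # -- outcome-model conjugate blocks -------------------------------
    def update_beta(self):
        d, st = self.data, self.state
        y_adj = st.y - st.b[d.child_idx]
        st.beta = draw_coefficients(st.X, y_adj, st.sig2_e, d.prior_prec,
                                    self.rng)

    def update_b(self):
        d, st = self.data, self.state
        if not self.spec.random_intercept:
            return
        resid = st.y - st.X @ st.beta
        sums = np.bincount(d.child_idx, weights=resid, minlength=d.m)
        prec = self.n_per_child / st.sig2_e + 1.0 / st.sig2_b
        mean = sums / st.sig2_e / prec
        st.b = mean + self.rng.standard_normal(d.m) / np.sqrt(prec)

    def _update_variance(self, ss, n, current):
        kind = self.spec.variance_prior[0]
        if kind == "inverse_gamma":
            a0, b0 = self.spec.variance_prior[1:3]
            return 1.0 / self.rng.gamma(a0 + 0.5 * n, 1.0 / (b0 + 0.5 * ss))
        if kind == "half_normal":
            # random-walk Metropolis on ln sigma against a half-normal
            # prior on sigma
            scale = self.spec.variance_prior[1]
            ln_s = 0.5 * np.log(current)
            ln_s_new = ln_s + 0.3 * self.rng.standard_normal()
            def logp(ls):
                s2 = np.exp(2 * ls)
                return (-0.5 * n * 2 * ls - 0.5 * ss / s2
                        - 0.5 * np.exp(2 * ls) / scale ** 2 + ls)
            if np.log(self.rng.random()) < logp(ln_s_new) - logp(ln_s):
                return float(np.exp(2 * ln_s_new))
            return current
        raise ValueError(f"unknown variance prior {kind!r}")

    def update_variances(self):
        d, st = self.data, self.state
        resid = st.y - st.X @ st.beta - st.b[d.child_idx]
        st.sig2_e = self._update_variance(float(resid @ resid), d.n_rows,
                                          st.sig2_e)
        if self.spec.random_intercept:
            st.sig2_b = self._update_variance(float(st.b @ st.b), d.m,
                                              st.sig2_b)

    # -- covariate-imputation submodels --------------------------------
    def _w_standardized(self):
        mu, sd = self.data.W_std
        return (self.state.W - mu) / sd

    def update_theta_W(self):
        d, st = self.data, self.state
        tau = self.spec.tau_imputation
        w = self._w_standardized()
        st.theta_W = draw_coefficients(d.A_W, w, st.sig2_W,
                                       np.full(d.A_W.shape[1], tau), self.rng)
        resid = w - d.A_W @ st.theta_W
        st.sig2_W = self._update_variance(float(resid @ resid), d.m,
                                          st.sig2_W)

    def _child_outcome_delta(self, i, d_eta):
        """Outcome log-likelihood change when the linear predictor of all
        rows of child ``i`` shifts by ``d_eta``."""
        d, st = self.data, self.state
        rows = self.rows_of_child[i]
        if not len(rows):
            return 0.0
        r = st.y[rows] - st.X[rows] @ st.beta - st.b[i]
        return float(np.sum(r * d_eta - 0.5 * d_eta ** 2) / st.sig2_e)

    def _apply_gwg(self, i, zg_new):
        d, st = self.data, self.state
        rows = self.rows_of_child[i]
        for k, col in enumerate(d.gwg_cols, start=1):
            st.X[rows, col] = zg_new ** k
        st.A_B[i, d.gwg_col_B] = zg_new
        if st.Z is not None and d.gwg_col_Z is not None:
            st.Z[rows, d.gwg_col_Z] = zg_new

    def impute_W(self):
        """Independence-Metropolis draw of each missing last pregnancy
        weight from its normal submodel, accepted against every
        likelihood term touched by the recomputed adequacy ratio."""
        d, st = self.data, self.state
        if not len(d.miss_W):
            return
        mu_w, sd_w = d.W_std
        for i in d.miss_W:
            mean_kg = mu_w + sd_w * float(d.A_W[i] @ st.theta_W)
            prop = self.rng.normal(mean_kg, sd_w * np.sqrt(st.sig2_W))
            zg_old = st.A_B[i, d.gwg_col_B]
            mu_g, s_g = d.gwg_std
            zg_new = ((prop - d.prepreg_weight[i]) / d.expected_gain[i]
                      * 100.0 - mu_g) / (2.0 * s_g)
            # outcome: only the gwg polynomial columns change
            bg = st.beta[d.gwg_cols]
            d_eta = float(
                sum(bg[k] * (zg_new ** (k + 1) - zg_old ** (k + 1))
                    for k in range(len(bg))))
            log_acc = self._child_outcome_delta(i, d_eta)
            # breastfeeding submodel term for this mother
            th_g = st.theta_B[d.gwg_col_B]
            eta_old = float(st.A_B[i] @ st.theta_B)
            eta_new = eta_old + th_g * (zg_new - zg_old)
            log_acc += float(
                st.B[i] * (eta_new - eta_old)
                + _log_sigmoid(-eta_new) - _log_sigmoid(-eta_old))
            # selection model term (MNAR)
            if st.Z is not None and d.gwg_col_Z is not None:
                rows = self.rows_of_child[i]
                g = st.gamma[2 + d.gwg_col_Z]
                eta_o = (st.gamma[0]
                         + st.gamma[1] * (st.y[rows] - d.y_center)
                         + st.Z[rows] @ st.gamma[2:])
                eta_n = eta_o + g * (zg_new - zg_old)
                R = (~d.obs_mask[rows]).astype(float)
                log_acc += float(np.sum(
                    R * (eta_n - eta_o)
                    + _log_sigmoid(-eta_n) - _log_sigmoid(-eta_o)))
            if np.log(self.rng.random()) < log_acc:
                st.W[i] = prop
                self._apply_gwg(i, zg_new)

    def impute_B(self):
        """Exact two-point draw of missing breastfeeding indicators."""
        d, st = self.data, self.state
        if d.breastfed_col is None:
            return
        for i in d.miss_B:
            eta_sub = float(st.A_B[i] @ st.theta_B)
            d_eta = st.beta[d.breastfed_col]  # effect of B: 0 -> 1
            rows = self.rows_of_child[i]
            cur = st.X[rows, d.breastfed_col]
            # outcome loglik difference (B=1 minus B=0)
            base = st.y[rows] - st.X[rows] @ st.beta - st.b[i] \
                + cur * d_eta  # residual with B=0
            ll_diff = float(np.sum(base * d_eta - 0.5 * d_eta ** 2)
                            / st.sig2_e)
            if st.Z is not None and d.breastfed_col_Z is not None:
                g = st.gamma[2 + d.breastfed_col_Z]
                eta0 = (st.gamma[0]
                        + st.gamma[1] * (st.y[rows] - d.y_center)
                        + st.Z[rows] @ st.gamma[2:]
                        - st.Z[rows, d.breastfed_col_Z] * g)
                R = (~d.obs_mask[rows]).astype(float)
                ll_diff += float(np.sum(
                    R * g + _log_sigmoid(-eta0 - g) - _log_sigmoid(-eta0)))
            logit1 = eta_sub + ll_diff
            newB = float(self.rng.random() < 1.0 / (1.0 + np.exp(-logit1)))
            st.B[i] = newB
            st.X[rows, d.breastfed_col] = newB
            if st.Z is not None and d.breastfed_col_Z is not None:
                st.Z[rows, d.breastfed_col_Z] = newB

    def _logistic_mh(self, theta, L, eta_fn, resp, prior_tau):
        prop = theta + L @ self.rng.standard_normal(len(theta))
        eta_old, eta_new = eta_fn(theta), eta_fn(prop)
        ll_old = float(np.sum(resp * eta_old + _log_sigmoid(-eta_old))) \
            - 0.5 * prior_tau * float(theta @ theta)
        ll_new = float(np.sum(resp * eta_new + _log_sigmoid(-eta_new))) \
            - 0.5 * prior_tau * float(prop @ prop)
        if np.log(self.rng.random()) < ll_new - ll_old:
            return prop, True
        return theta, False

    def update_theta_B(self):
        d, st = self.data, self.state
        st.theta_B, _ = self._logistic_mh(
            st.theta_B, self.L_B, lambda t: st.A_B @ t, st.B,
            self.spec.tau_imputation)

    def update_activity_submodel(self):
        d, st = self.data, self.state
        # coefficients
        st.theta_A, _ = self._logistic_mh(
            st.theta_A, self.L_A,
            lambda t: d.A_A @ t + st.u[d.child_idx], st.active,
            self.spec.tau_imputation)
        # random intercepts: componentwise vectorized random walk
        eta_fix = d.A_A @ st.theta_A
        u_new = st.u + 0.6 * self.rng.standard_normal(d.m)
        eta_old = eta_fix + st.u[d.child_idx]
        eta_prop = eta_fix + u_new[d.child_idx]
        ll_rows_old = st.active * eta_old + _log_sigmoid(-eta_old)
        ll_rows_new = st.active * eta_prop + _log_sigmoid(-eta_prop)
        delta = np.bincount(d.child_idx, weights=ll_rows_new - ll_rows_old,
                            minlength=d.m)
        delta += (st.u ** 2 - u_new ** 2) / (2.0 * st.sig2_u)
        accept = np.log(self.rng.random(d.m)) < delta
        st.u = np.where(accept, u_new, st.u)
        st.sig2_u = self._update_variance(float(st.u @ st.u), d.m, st.sig2_u)

    def impute_A(self):
        """Exact two-point draw of missing visit-level activity."""
        d, st = self.data, self.state
        if d.active_col is None or not len(d.miss_A):
            return
        rows = d.miss_A
        eta_sub = d.A_A[rows] @ st.theta_A + st.u[d.child_idx[rows]]
        d_eta = st.beta[d.active_col]
        cur = st.X[rows, d.active_col]
        base = (st.y[rows] - st.X[rows] @ st.beta
                - st.b[d.child_idx[rows]] + cur * d_eta)
        ll_diff = (base * d_eta - 0.5 * d_eta ** 2) / st.sig2_e
        logit1 = eta_sub + ll_diff
        newA = (self.rng.random(len(rows))
                < 1.0 / (1.0 + np.exp(-logit1))).astype(float)
        st.active[rows] = newA
        st.X[rows, d.active_col] = newA

    # -- selection model (MNAR) ---------------------------------------
    def _selection_eta(self, gamma, y):
        # the outcome is centred at the observed mean so the intercept
        # stays on the scale the tau = 2 prior anticipates; gamma[1]
        # remains the log-odds change per 1% fat mass
        st = self.state
        return (gamma[0] + gamma[1] * (y - self.data.y_center)
                + st.Z @ gamma[2:])

    def update_gamma(self):
        d, st = self.data, self.state
        R = (~d.obs_mask).astype(float)
        prop = st.gamma + self.L_G @ self.rng.standard_normal(len(st.gamma))
        eta_old = self._selection_eta(st.gamma, st.y)
        eta_new = self._selection_eta(prop, st.y)
        tau = self.tau_selection
        ll_old = float(np.sum(R * eta_old + _log_sigmoid(-eta_old))) \
            - 0.5 * tau * float(st.gamma @ st.gamma)
        ll_new = float(np.sum(R * eta_new + _log_sigmoid(-eta_new))) \
            - 0.5 * tau * float(prop @ prop)
        if np.log(self.rng.random()) < ll_new - ll_old:
            st.gamma = prop

    def update_y_mis(self):
        """Independence Metropolis for unobserved outcomes: propose from
        the Gaussian outcome full conditional, accept on the logistic
        selection ratio (rows have missing indicator = 1)."""
        d, st = self.data, self.state
        rows = self.mis_rows
        if not len(rows):
            return
        mu = st.X[rows] @ st.beta + st.b[d.child_idx[rows]]
        prop = mu + np.sqrt(st.sig2_e) * self.rng.standard_normal(len(rows))
        zg = st.Z[rows] @ st.gamma[2:]
        eta_old = (st.gamma[0] + st.gamma[1] * (st.y[rows] - d.y_center)
                   + zg)
        eta_new = (st.gamma[0] + st.gamma[1] * (prop - d.y_center) + zg)
        log_acc = _log_sigmoid(eta_new) - _log_sigmoid(eta_old)
        accept = np.log(self.rng.random(len(rows))) < log_acc
        st.y[rows] = np.where(accept, prop, st.y[rows])

    # -- one sweep ------------------------------------------------------
    def sweep(self):
        st = self.state
        self.impute_censored()
        self.update_theta_W()
        self.impute_W()
        self.update_theta_B()
        self.impute_B()
        self.update_activity_submodel()
        self.impute_A()
        self.update_beta()
        self.update_b()
        self.update_variances()
        if st.Z is not None:
            self.update_y_mis()
            self.update_gamma()
        if not np.isfinite(st.sig2_e) or not np.isfinite(st.beta).all():
            raise FloatingPointError("numerical overflow in sweep")

    # -- tracked output ------------------------------------------------
    @property
    def track_names(self) -> list[str]:
        names = list(self.data.col_names) + ["sigma2_e", "sigma2_b"]
        if self.state.gamma is not None:
            names += ["gamma0", "gamma_y"] + [f"gamma_{z}"
                                              for z in self.data.z_names]
        return names

    def snapshot(self) -> np.ndarray:
        st = self.state
        out = [st.beta, [st.sig2_e, st.sig2_b]]
        if st.gamma is not None:
            out.append(st.gamma)
        return np.concatenate([np.asarray(a, float) for a in out])

    def run(self, n_sweeps: int, collect: bool = True,
            thin: int = 1) -> np.ndarray | None:
        if collect:
            kept = n_sweeps // thin
            out = np.empty((kept, len(self.snapshot())))
            k = 0
            for it in range(n_sweeps):
                self.sweep()
                if (it + 1) % thin == 0:
                    out[k] = self.snapshot()
                    k += 1
            return out[:k]
        for _ in range(n_sweeps):
            self.sweep()
        return None


# ----------------------------------------------------------------------
# module-level operation wrappers (thin views over the sampler blocks)
# ----------------------------------------------------------------------

def impute_censored(sampler: GibbsSampler) -> np.ndarray:
    sampler.impute_censored()
    return sampler.state.ln_conc


def impute_covariates(sampler: GibbsSampler) -> ParameterState:
    sampler.update_theta_W()
    sampler.impute_W()
    sampler.update_theta_B()
    sampler.impute_B()
    sampler.update_activity_submodel()
    sampler.impute_A()
    return sampler.state


def gibbs_sweep(sampler: GibbsSampler) -> ParameterState:
    sampler.sweep()
    return sampler.state


# ----------------------------------------------------------------------
# joint density
# ----------------------------------------------------------------------

def log_joint(state: ParameterState, data: AnalysisData,
              tau_selection: float = 2.0) -> float:
    """Log posterior density (up to a constant) of a full state.

    Raises ``ValueError`` naming the offending component when a term is
    non-finite; returns ``-inf`` for support violations (a censored cell
    imputed above its LOD).
    """
    spec = data.spec
    parts = {}
    resid = state.y - state.X @ state.beta - state.b[data.child_idx]
    parts["outcome"] = float(np.sum(_norm_logpdf(resid, 0.0, state.sig2_e)))
    if spec.random_intercept:
        parts["random_intercepts"] = float(
            np.sum(_norm_logpdf(state.b, 0.0, state.sig2_b)))
    parts["beta_prior"] = float(np.sum(
        -0.5 * data.prior_prec * state.beta ** 2
        + 0.5 * np.log(data.prior_prec) - _LOG_SQRT_2PI))
    # censored cells: truncated normal with frozen parameters
    ci, cj = np.nonzero(data.censored)
    if len(ci):
        v = state.ln_conc[ci, cj]
        up = data.ln_lod[cj]
        if np.any(v > up):
            return -np.inf
        mu, sd = data.imp_mu[cj], data.imp_sd[cj]
        parts["censored"] = float(np.sum(
            _norm_logpdf(v, mu, sd ** 2)
            - np.log(_norm_cdf((up - mu) / sd))))
    # covariate submodels
    tau_i = spec.tau_imputation
    w = (state.W - data.W_std[0]) / data.W_std[1]
    parts["submodel_W"] = float(
        np.sum(_norm_logpdf(w - data.A_W @ state.theta_W, 0.0, state.sig2_W))
        - 0.5 * tau_i * state.theta_W @ state.theta_W)
    eta_B = state.A_B @ state.theta_B
    parts["submodel_B"] = float(
        np.sum(state.B * eta_B + _log_sigmoid(-eta_B))
        - 0.5 * tau_i * state.theta_B @ state.theta_B)
    eta_A = data.A_A @ state.theta_A + state.u[data.child_idx]
    parts["submodel_A"] = float(
        np.sum(state.active * eta_A + _log_sigmoid(-eta_A))
        - 0.5 * tau_i * state.theta_A @ state.theta_A
        + np.sum(_norm_logpdf(state.u, 0.0, state.sig2_u)))
    # variance priors
    if spec.variance_prior[0] == "inverse_gamma":
        a0, b0 = spec.variance_prior[1:3]
        vs = [state.sig2_e, state.sig2_W, state.sig2_u]
        if spec.random_intercept:
            vs.append(state.sig2_b)
        parts["variance_priors"] = float(
            sum(-(a0 + 1) * np.log(v) - b0 / v for v in vs))
    else:
        scale = spec.variance_prior[1]
        vs = [state.sig2_e, state.sig2_W, state.sig2_u]
        if spec.random_intercept:
            vs.append(state.sig2_b)
        parts["variance_priors"] = float(
            sum(-0.5 * v / scale ** 2 for v in vs))
    if state.gamma is not None:
        eta = state.gamma[0] \
            + state.gamma[1] * (state.y - data.y_center) \
            + state.Z @ state.gamma[2:]
        R = (~data.obs_mask).astype(float)
        parts["selection"] = float(
            np.sum(R * eta + _log_sigmoid(-eta))
            - 0.5 * tau_selection * state.gamma @ state.gamma)
    total = 0.0
    for name, v in parts.items():
        if not np.isfinite(v):
            raise ValueError(f"non-finite log-density component: {name}")
        total += v
    return total


# ----------------------------------------------------------------------
# estimator
# ----------------------------------------------------------------------

class ShrinkageLMM(BaseEstimator):
    """Scikit-learn style estimator for the shrinkage mixed model.

    ``fit(mothers, visits)`` prepares the cohort, runs the configured
    chains and stores posterior draws and summaries. Exposure
    coefficients are per SD of ln concentration (continuous coding) or
    tertile contrasts vs the lowest tertile (tertile coding).

    Attributes set by ``fit``: ``data_`` (frozen design), ``chains_``
    (draws, shape (chains, kept, params)), ``param_names_``,
    ``summary_`` (posterior summary DataFrame).
    """

    def __init__(self, exposure_coding="continuous",
                 exposures=tuple(("MEP", "MnBP", "MiBP", "MCPP", "MBzP",
                                  "SumDEHP")),
                 interaction="none", tau_exposure=1 / 16,
                 tau_covariate=1 / 64, tau_imputation=1.0,
                 creatinine_covariate=None, random_intercept=True,
                 variance_prior=("inverse_gamma", 0.001, 0.001),
                 outcome="pct_fat", burn_in=10_000, iterations=50_000,
                 chains=2, thin=1, seed=0):
        self.exposure_coding = exposure_coding
        self.exposures = exposures
        self.interaction = interaction
        self.tau_exposure = tau_exposure
        self.tau_covariate = tau_covariate
        self.tau_imputation = tau_imputation
        self.creatinine_covariate = creatinine_covariate
        self.random_intercept = random_intercept
        self.variance_prior = variance_prior
        self.outcome = outcome
        self.burn_in = burn_in
        self.iterations = iterations
        self.chains = chains
        self.thin = thin
        self.seed = seed

    def _model_spec(self) -> ModelSpec:
        return ModelSpec(
            exposure_coding=self.exposure_coding,
            exposures=tuple(self.exposures),
            interaction=self.interaction,
            tau_exposure=self.tau_exposure,
            tau_covariate=self.tau_covariate,
            tau_imputation=self.tau_imputation,
            creatinine_covariate=self.creatinine_covariate,
            random_intercept=self.random_intercept,
            variance_prior=self.variance_prior,
            outcome=self.outcome,
            mcmc=MCMCSettings(burn_in=self.burn_in,
                              iterations=self.iterations,
                              chains=self.chains, thin=self.thin,
                              seed=self.seed))

    def _build_data(self, mothers, visits, registry):
        return build_analysis_data(mothers, visits,
                                   registry or default_registry(),
                                   self._model_spec())

    def fit(self, mothers, visits, registry=None):
        from .inference import run_chains, summarize
        self.data_ = self._build_data(mothers, visits, registry)
        spec = self.data_.spec
        chains, names = run_chains(
            lambda seed: GibbsSampler(self.data_, seed), spec.mcmc)
        self.chains_ = chains
        self.param_names_ = names
        het = [f"sex:{n}" for cols in self.data_.interaction_cols.values()
               for n in (self.data_.col_names[c] for c in cols)]
        self.summary_ = summarize(chains, names, heterogeneity_names=het)
        return self

    def predict(self, mothers=None, visits=None):
        """Posterior-mean linear predictor for the training rows."""
        from sklearn.utils.validation import check_is_fitted
        check_is_fitted(self, "chains_")
        p = self.data_.p
        beta_mean = self.chains_.reshape(-1, self.chains_.shape[-1])[
            :, :p].mean(axis=0)
        return self.data_.X0 @ beta_mean
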