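"""Sampler building blocks: truncated-normal imputation, conjugate
draws, design construction, joint density, determinism, shrinkage."""

import numpy as np
import pytest
from scipy import stats

from phthalmix import (ModelSpec, ShrinkageLMM, TruthConfig,
                       build_analysis_data, log_joint, simulate_cohort)
from phthalmix.model import (GibbsSampler, draw_coefficients,
                             truncated_normal_below)
from phthalmix.registry import MetaboliteSpec


def lodless_registry(registry):
    """Registry clone with vanishing LODs: no censoring anywhere."""
    return [MetaboliteSpec(s.code, 1e-9, s.correction_factor, s.mol_weight,
                           s.group) for s in registry]


@pytest.fixture(scope="module")
def fitted_sampler(small_cohort, registry):
    mothers, visits, _ = small_cohort
    data = build_analysis_data(mothers, visits, registry, ModelSpec())
    s = GibbsSampler(data, seed=42)
    s.run(30, collect=False)
    return s


class TestTruncatedNormal:
    def test_support(self, rng):
        d = truncated_normal_below(1.0, 2.0, np.log(0.9), rng, size=5000)
        assert np.all(d <= np.log(0.9))

    def test_matches_rejection_oracle(self, rng):
        mu, sd, up = 1.8, 1.2, np.log(0.9)
        draws = truncated_normal_below(np.full(8000, mu), sd, up, rng)
        # rejection-sampling oracle
        pool = rng.normal(mu, sd, 400_000)
        oracle = pool[pool <= up][:8000]
        ks = stats.ks_2samp(draws, oracle).statistic
        assert ks < 0.03

    def test_untruncated_limit(self, rng):
        d = truncated_normal_below(0.5, 1.5, 1e6, rng, size=40_000)
        assert d.mean() == pytest.approx(0.5, abs=0.03)
        assert d.std() == pytest.approx(1.5, abs=0.03)

    def test_bad_sd(self, rng):
        with pytest.raises(ValueError):
            truncated_normal_below(0.0, 0.0, 1.0, rng)


class TestConjugateDraws:
    def test_prior_only_exposure_sd(self, rng):
        # tau = 1/16 precision convention: prior SD = 4
        draws = np.array([draw_coefficients(None, None, 1.0,
                                            np.array([1 / 16]), rng)[0]
                          for _ in range(40_000)])
        assert draws.std() == pytest.approx(4.0, rel=0.02)

    def test_matches_analytic_posterior(self, rng):
        X = rng.normal(size=(50, 2))
        beta = np.array([1.0, -2.0])
        y = X @ beta + rng.normal(0, 0.5, 50)
        prec = X.T @ X / 0.25 + np.eye(2) * 0.1
        mean = np.linalg.solve(prec, X.T @ y / 0.25)
        draws = np.array([draw_coefficients(X, y, 0.25,
                                            np.full(2, 0.1), rng)
                          for _ in range(4000)])
        np.testing.assert_allclose(draws.mean(axis=0), mean, atol=0.05)
        np.testing.assert_allclose(np.cov(draws.T),
                                   np.linalg.inv(prec), atol=0.02)


class TestDesign:
    def test_column_counts_by_mode(self, small_cohort, registry):
        mothers, visits, _ = small_cohort
        d = build_analysis_data(mothers, visits, registry, ModelSpec())
        # intercept + 6 exposures + sex/age/sex:age + 2 race + 3 binary +
        # breastfed + active + height + 3+2+3 polys + 2 creatinine + date
        assert d.p == 29
        di = build_analysis_data(mothers, visits, registry,
                                 ModelSpec(interaction="sex"))
        assert di.p == 29 + len(d.exposure_cols) + 1
        dt = build_analysis_data(mothers, visits, registry,
                                 ModelSpec(exposure_coding="tertile"))
        # two indicators per exposure, no creatinine terms
        assert all(len(c) == 2 for c in dt.exposure_cols.values())
        assert not any("creatinine" in n for n in dt.col_names)

    def test_tertile_with_creatinine_rejected(self, small_cohort, registry):
        mothers, visits, _ = small_cohort
        with pytest.raises(ValueError, match="creatinine"):
            build_analysis_data(
                mothers, visits, registry,
                ModelSpec(exposure_coding="tertile",
                          creatinine_covariate=True))

    def test_exposure_priors_vs_covariate_priors(self, small_cohort,
                                                 registry):
        mothers, visits, _ = small_cohort
        d = build_analysis_data(mothers, visits, registry, ModelSpec())
        for cols in d.exposure_cols.values():
            assert all(d.prior_prec[c] == 1 / 16 for c in cols)
        assert d.prior_prec[d.col_names.index("sex")] == 1 / 64


class TestLogJoint:
    def test_matches_scipy_oracle(self, fitted_sampler):
        s = fitted_sampler
        st, d = s.state, s.data
        total = log_joint(st, d)
        # independent recomputation with scipy distributions
        resid = st.y - st.X @ st.beta - st.b[d.child_idx]
        parts = stats.norm.logpdf(resid, 0, np.sqrt(st.sig2_e)).sum()
        parts += stats.norm.logpdf(st.b, 0, np.sqrt(st.sig2_b)).sum()
        parts += stats.norm.logpdf(st.beta, 0,
                                   1 / np.sqrt(d.prior_prec)).sum()
        ci, cj = np.nonzero(d.censored)
        v = st.ln_conc[ci, cj]
        mu, sd, up = d.imp_mu[cj], d.imp_sd[cj], d.ln_lod[cj]
        parts += (stats.norm.logpdf(v, mu, sd)
                  - stats.norm.logcdf(up, mu, sd)).sum()
        w = (st.W - d.W_std[0]) / d.W_std[1]
        parts += stats.norm.logpdf(w - d.A_W @ st.theta_W, 0,
                                   np.sqrt(st.sig2_W)).sum()
        eta_B = st.A_B @ st.theta_B
        parts += (st.B * eta_B - np.log1p(np.exp(eta_B))).sum()
        eta_A = d.A_A @ st.theta_A + st.u[d.child_idx]
        parts += (st.active * eta_A - np.log1p(np.exp(eta_A))).sum()
        parts += stats.norm.logpdf(st.u, 0, np.sqrt(st.sig2_u)).sum()
        # submodel coefficient priors enter as N(0, 1/tau) kernels
        tau_i = d.spec.tau_imputation
        for th in (st.theta_W, st.theta_B, st.theta_A):
            parts += -0.5 * tau_i * float(th @ th)
        a0, b0 = d.spec.variance_prior[1:3]
        for var in (st.sig2_e, st.sig2_W, st.sig2_u, st.sig2_b):
            parts += -(a0 + 1) * np.log(var) - b0 / var
        assert total == pytest.approx(parts, abs=1e-6)

    def test_censored_cell_above_lod_is_minus_inf(self, fitted_sampler):
        s = fitted_sampler
        st = s.state.copy()
        ci, cj = np.nonzero(s.data.censored)
        if len(ci) == 0:
            pytest.skip("cohort draw contains no censored cells")
        st.ln_conc[ci[0], cj[0]] = s.data.ln_lod[cj[0]] + 0.5
        assert log_joint(st, s.data) == -np.inf

    def test_nonfinite_named(self, fitted_sampler):
        st = fitted_sampler.state.copy()
        st.beta = st.beta.copy()
        st.beta[0] = np.inf
        with pytest.raises(ValueError, match="outcome|beta"):
            log_joint(st, fitted_sampler.data)


class TestSamplerMechanics:
    def test_censored_cells_respect_support(self, fitted_sampler):
        s = fitted_sampler
        ci, cj = np.nonzero(s.data.censored)
        assert np.all(s.state.ln_conc[ci, cj] <= s.data.ln_lod[cj] + 1e-12)

    def test_fixed_seed_bit_identical(self, small_cohort, registry):
        mothers, visits, _ = small_cohort
        data = build_analysis_data(mothers, visits, registry, ModelSpec())
        a = GibbsSampler(data, seed=7).run(40)
        b = GibbsSampler(data, seed=7).run(40)
        np.testing.assert_array_equal(a, b)

    def test_checkpoint_resume_bit_exact(self, small_cohort, registry):
        mothers, visits, _ = small_cohort
        data = build_analysis_data(mothers, visits, registry, ModelSpec())
        s1 = GibbsSampler(data, seed=9)
        full = s1.run(60)
        s2 = GibbsSampler(data, seed=9)
        first = s2.run(30)
        snap = s2.get_state()
        s3 = GibbsSampler(data, seed=123)  # fresh object, divergent rng
        s3.run(5, collect=False)
        s3.set_state(snap)
        rest = s3.run(30)
        np.testing.assert_array_equal(np.vstack([first, rest]), full)


class TestPosteriorBehaviour:
    def test_conjugate_limit_matches_ols(self, registry, rng):
        # sigma_b = 0, complete data, vague priors: the posterior mean of
        # every fixed effect equals weighted least squares
        import statsmodels.api as sm
        truth = TruthConfig(n_children=60, sigma_b=0.0,
                            miss_last_weight=0.0, miss_breastfed=0.0,
                            miss_activity=0.0,
                            beta_exposure={"SumDEHP": -2.0})
        truth.dropout.mcar_rate = 0.0
        reg = lodless_registry(registry)
        mothers, visits, _ = simulate_cohort(truth, seed=21, registry=reg)
        est = ShrinkageLMM(tau_exposure=1e-8, tau_covariate=1e-8,
                           random_intercept=False, burn_in=500,
                           iterations=2500, chains=2, seed=5)
        est.fit(mothers, visits, reg)
        ols = sm.OLS(est.data_.y0, est.data_.X0).fit()
        for j, name in enumerate(est.data_.col_names):
            row = est.summary_.iloc[j]
            mcse = row["sd"] / np.sqrt(max(row["ess"], 1.0))
            assert abs(row["mean"] - ols.params[j]) < \
                2 * mcse + 2 * ols.bse[j] / np.sqrt(len(est.data_.y0))

    def test_shrinkage_monotone_in_tau(self, registry):
        truth = TruthConfig(n_children=120,
                            beta_exposure={"SumDEHP": -3.0})
        mothers, visits, _ = simulate_cohort(truth, seed=31,
                                             registry=registry)
        means = []
        for tau in (1 / 64, 1 / 16, 1.0):
            est = ShrinkageLMM(exposures=("SumDEHP",), tau_exposure=tau,
                               burn_in=800, iterations=3200, chains=1,
                               seed=3)
            est.fit(mothers, visits, registry)
            means.append(abs(est.summary_.loc["SumDEHP", "mean"]))
        assert means[0] >= means[1] - 0.06
        assert means[1] >= means[2] - 0.06
        assert means[0] > means[2]

    def test_child_order_exchangeability(self, registry):
        truth = TruthConfig(n_children=60,
                            beta_exposure={"SumDEHP": -0.89})
        mothers, visits, _ = simulate_cohort(truth, seed=41,
                                             registry=registry)
        perm_rng = np.random.default_rng(1)
        order = perm_rng.permutation(len(mothers))
        relabel = {sid: f"P{k:04d}" for k, sid in
                   enumerate(mothers["subject_id"].iloc[order])}
        m2 = mothers.copy()
        m2["subject_id"] = m2["subject_id"].map(relabel)
        v2 = visits.copy()
        v2["subject_id"] = v2["subject_id"].map(relabel)
        kw = dict(burn_in=800, iterations=3200, chains=1, seed=8)
        a = ShrinkageLMM(**kw).fit(mothers, visits, registry)
        b = ShrinkageLMM(**kw).fit(m2, v2, registry)
        ra, rb = (e.summary_.loc["SumDEHP"] for e in (a, b))
        mcse = np.hypot(ra["sd"] / np.sqrt(ra["ess"]),
                        rb["sd"] / np.sqrt(rb["ess"]))
        assert abs(ra["mean"] - rb["mean"]) < 4 * mcse

    def test_single_vs_multiple_metabolite_agreement(self, registry):
        # with independent non-DEHP exposures the 6-exposure and
        # single-exposure fits estimate the same quantity
        truth = TruthConfig(n_children=120, rho_cross=0.0,
                            beta_exposure={"SumDEHP": -0.89})
        mothers, visits, _ = simulate_cohort(truth, seed=51,
                                             registry=registry)
        kw = dict(burn_in=800, iterations=3200, chains=1, seed=13)
        multi = ShrinkageLMM(**kw).fit(mothers, visits, registry)
        single = ShrinkageLMM(exposures=("SumDEHP",), **kw).fit(
            mothers, visits, registry)
        rm = multi.summary_.loc["SumDEHP"]
        rs = single.summary_.loc["SumDEHP"]
        mcse = np.hypot(rm["sd"] / np.sqrt(rm["ess"]),
                        rs["sd"] / np.sqrt(rs["ess"]))
        assert abs(rm["mean"] - rs["mean"]) < 4 * mcse + 0.15
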