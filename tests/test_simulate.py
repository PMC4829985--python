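"""Synthetic-cohort generator: determinism, anchored distributions,
dropout mechanisms."""

import numpy as np
import pytest
from scipy.stats import norm

from phthalmix import DropoutConfig, TruthConfig, simulate_cohort
from phthalmix.simulate import (apply_dropout, generate_mothers,
                                generate_visits, write_cohort)


def test_same_seed_identical_files(tmp_path, registry):
    truth = TruthConfig(n_children=40)
    write_cohort(truth, 17, tmp_path / "a", registry)
    write_cohort(truth, 17, tmp_path / "b", registry)
    for f in ("mothers.csv", "visits.csv"):
        assert (tmp_path / "a" / f).read_bytes() == \
            (tmp_path / "b" / f).read_bytes()


def test_mehp_censoring_near_published_detection(registry):
    truth = TruthConfig(n_children=180)
    m = generate_mothers(truth, 3, registry)
    frac = m["cens_MEHP"].mean()
    p = 0.083  # 91.7% detected
    assert abs(frac - p) < 3 * np.sqrt(p * (1 - p) / 180)


def test_censored_fraction_converges_to_gaussian_tail(registry):
    truth = TruthConfig(n_children=50_000)
    m = generate_mothers(truth, 5, registry)
    for code in ("MEHP", "MECPP"):
        spec = next(s for s in registry if s.code == code)
        p = norm.cdf((np.log(spec.corrected_lod)
                      - truth.exposure_ln_mean[code])
                     / truth.exposure_ln_sd[code])
        frac = m[f"cens_{code}"].mean()
        tol = 3 * np.sqrt(max(p * (1 - p), 1e-9) / 50_000) + 1e-4
        assert abs(frac - p) < tol


def test_identity_correlation_gives_null_structure(registry):
    truth = TruthConfig(n_children=180, rho_dehp=0.0, rho_cross=0.0)
    m = generate_mothers(truth, 9, registry)
    a = np.log(m["conc_MECPP"][~m["cens_MECPP"] & ~m["cens_MEHHP"]])
    b = np.log(m["conc_MEHHP"][~m["cens_MECPP"] & ~m["cens_MEHHP"]])
    assert abs(np.corrcoef(a, b)[0, 1]) < 0.25


def test_dehp_block_highly_correlated(registry):
    truth = TruthConfig(n_children=2000)
    m = generate_mothers(truth, 13, registry)
    ok = ~m["cens_MECPP"] & ~m["cens_MEHHP"]
    r = np.corrcoef(np.log(m["conc_MECPP"][ok]),
                    np.log(m["conc_MEHHP"][ok]))[0, 1]
    assert r > 0.8


def test_null_betas_give_null_exposure_outcome_correlation(registry):
    truth = TruthConfig(n_children=1000, beta_exposure={})
    m = generate_mothers(truth, 21, registry)
    v, _ = generate_visits(truth, m, 21, registry)
    y = (v["fat_mass"] / v["weight"] * 100.0).groupby(
        v["subject_id"]).mean().to_numpy()
    x = np.log(m.sort_values("subject_id")["conc_MEP"]).to_numpy()
    assert abs(np.corrcoef(x, y)[0, 1]) < 0.1


def test_marginal_outcome_sd_in_plausible_band(registry):
    truth = TruthConfig(n_children=2000)
    m = generate_mothers(truth, 31, registry)
    v, _ = generate_visits(truth, m, 31, registry)
    y = v["fat_mass"] / v["weight"] * 100.0
    assert 7.2 <= y.std() <= 8.8


def test_no_random_intercept_no_within_child_correlation(registry):
    truth = TruthConfig(n_children=2000, sigma_b=0.0)
    m = generate_mothers(truth, 41, registry)
    v, _ = generate_visits(truth, m, 41, registry)
    y = v["fat_mass"] / v["weight"] * 100.0
    wide = y.groupby([v["subject_id"], v["visit"]]).first().unstack()
    r = np.corrcoef(wide[1], wide[2])[0, 1]
    assert abs(r) < 0.35  # shared covariates leave a little correlation


class TestDropout:
    def test_mcar_rate(self, registry):
        truth = TruthConfig(n_children=1000,
                            dropout=DropoutConfig(mechanism="MCAR",
                                                  mcar_rate=0.2))
        _, v, _ = simulate_cohort(truth, 51, registry)
        p = v["outcome_missing"].mean()
        assert abs(p - 0.2) < 3 * np.sqrt(0.2 * 0.8 / 3000)

    def test_extreme_negative_intercept_no_missingness(self, registry):
        truth = TruthConfig(
            n_children=200,
            dropout=DropoutConfig(mechanism="MNAR", gamma0=-40.0))
        _, v, _ = simulate_cohort(truth, 53, registry)
        assert v["outcome_missing"].sum() == 0

    def test_mnar_biases_observed_mean_upward(self, registry):
        # gamma_y < 0: higher fat mass -> retained, so the observed mean
        # exceeds the complete-data mean
        truth = TruthConfig(n_children=2000,
                            dropout=DropoutConfig(mechanism="MNAR"))
        m = generate_mothers(truth, 61, registry)
        v, _ = generate_visits(truth, m, 61, registry)
        full = (v["fat_mass"] / v["weight"] * 100.0)
        vd = apply_dropout(truth, v, m, 61)
        obs = (vd["fat_mass"] / vd["weight"] * 100.0).dropna()
        assert obs.mean() > full.mean() + 0.5

    def test_logistic_oracle_recovers_dropout_or(self, registry):
        import statsmodels.api as sm
        truth = TruthConfig(n_children=5000,
                            dropout=DropoutConfig(mechanism="MNAR"))
        m = generate_mothers(truth, 71, registry)
        v, _ = generate_visits(truth, m, 71, registry)
        y = (v["fat_mass"] / v["weight"] * 100.0).to_numpy()
        vd = apply_dropout(truth, v, m, 71)
        r = vd["outcome_missing"].to_numpy()
        fit = sm.Logit(r, sm.add_constant(y)).fit(disp=0)
        assert np.exp(fit.params[1]) == pytest.approx(0.81, abs=0.02)

    def test_dropout_stream_independent_of_exposures(self, registry):
        t1 = TruthConfig(n_children=50)
        t2 = TruthConfig(n_children=50,
                         dropout=DropoutConfig(mechanism="MNAR"))
        m1 = generate_mothers(t1, 81, registry)
        m2 = generate_mothers(t2, 81, registry)
        assert m1.equals(m2)


def test_invalid_rates_rejected():
    with pytest.raises(ValueError):
        TruthConfig(miss_breastfed=1.5).validate()
    with pytest.raises(ValueError):
        TruthConfig(sigma_e=0.0).validate()
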