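"""Model ladders, ML mixed-model fitting and likelihood-ratio tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate
from scipy.special import expit

from cpface.errors import ConfigurationError, ContractError
from cpface.mixed_models import (
    MixedModelSpec,
    binomial_agh_loglik,
    build_design,
    build_ladder,
    fit_mixed_model,
    lr_test,
)


def gaussian_lmm_data(n_participants=50, n_trials=32, beta_age=0.02,
                      beta_group=-0.3, sd_u=0.3, sd_e=0.4, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_participants):
        group = "cp" if i < n_participants // 2 else "control"
        age = rng.uniform(20, 65)
        u = sd_u * rng.standard_normal()
        for t in range(n_trials):
            block = t // 8 + 1
            y = (-2.0 + beta_age * age + beta_group * (group == "cp")
                 + u + sd_e * rng.standard_normal())
            rows.append({"participant_id": f"p{i}", "group": group,
                         "age": age, "block": block, "trial": t + 1,
                         "inv_rt": y})
    return pd.DataFrame(rows)


def binomial_glmm_data(n_participants=10, n_trials=20, sigma=0.7, seed=4):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_participants):
        age = rng.uniform(20, 60)
        u = sigma * rng.standard_normal()
        for t in range(n_trials):
            pt = rng.choice([20.0, 40.0, 80.0])
            eta = 0.3 + 0.01 * age + 0.8 * np.log(pt / 40.0) + u
            rows.append({"participant_id": f"p{i}", "group": "control",
                         "age": age, "trial": t + 1, "presentation_ms": pt,
                         "response_correct": int(rng.random() < expit(eta))})
    return pd.DataFrame(rows)


class TestLadders:
    def test_exp3_ladder_has_four_nested_models(self):
        specs = build_ladder(3)
        assert [s.label for s in specs] == [
            "nullmodel", "main effect", "PT interaction", "full interaction"]
        for a, b in zip(specs, specs[1:]):
            assert set(a.fixed_terms) < set(b.fixed_terms)

    def test_exp1_rt_and_pt80_ladders(self):
        rt = build_ladder(1, response="inv_rt")
        assert rt[0].random_terms == ("intercept", "block")
        assert len(rt) == 3
        pt = build_ladder(1, response="log_pt80")
        assert pt[0].random_terms == ()
        assert len(pt) == 2

    def test_unknown_experiment_rejected(self):
        with pytest.raises(ConfigurationError):
            build_ladder(9)

    def test_interaction_requires_main_effects(self):
        with pytest.raises(ConfigurationError):
            MixedModelSpec(response="correct", family="binomial-logit",
                           fixed_terms=("intercept", "group_x_block"))

    def test_rotation_codes_absolute_value(self):
        spec = build_ladder(3)[0]
        data = pd.DataFrame({
            "participant_id": ["p"] * 4, "group": ["control"] * 4,
            "age": [30.0] * 4, "rotation": [30, -30, 0, 60],
            "presentation_ms": [40.0] * 4, "response_correct": [1, 0, 1, 0],
        })
        X, names, *_ = build_design(spec, data)
        i30 = names.index("rotation[30]")
        assert X[0, i30] == 1.0 and X[1, i30] == 1.0  # +-30 share a level
        assert X[2, i30] == 0.0


class TestGaussianFits:
    def test_recovers_fixed_effects_within_3se(self):
        data = gaussian_lmm_data()
        spec = MixedModelSpec(response="inv_rt", family="gaussian",
                              fixed_terms=("intercept", "age", "group"),
                              random_terms=("intercept",))
        fit = fit_mixed_model(spec, data)
        assert fit.converged
        se = np.sqrt(np.diag(fit.fixed_cov))
        truth = {"intercept": -2.0, "age": 0.02, "group": -0.3}
        for i, name in enumerate(fit.fixed_estimates.index):
            assert abs(fit.fixed_estimates[name] - truth[name]) < 3 * se[i]

    def test_zero_variance_data_matches_ols_oracle(self):
        data = gaussian_lmm_data(sd_u=0.0, n_participants=20, n_trials=8,
                                 seed=2)
        spec = MixedModelSpec(response="inv_rt", family="gaussian",
                              fixed_terms=("intercept", "age", "group"),
                              random_terms=("intercept",))
        fit = fit_mixed_model(spec, data)
        import statsmodels.api as sm

        X, names, y, *_ = build_design(spec, data)
        ols = sm.OLS(y, X).fit()
        assert np.allclose(fit.fixed_estimates.to_numpy(), ols.params,
                           atol=1e-4)
        assert float(np.diag(fit.varcomp["cov_re"]).min()) < 1e-3

    def test_loglik_monotone_along_ladder(self):
        data = gaussian_lmm_data(n_participants=24, n_trials=16, seed=5)
        fits = [fit_mixed_model(s, data) for s in build_ladder(1)]
        lls = [f.log_likelihood for f in fits]
        assert lls == sorted(lls)
        assert [f.n_params for f in fits] == [7, 8, 9]

    def test_consistency_bias_shrinks_with_cohort_size(self):
        biases = []
        for n in (16, 64):
            errs = []
            for seed in range(6):
                data = gaussian_lmm_data(n_participants=n, n_trials=8,
                                         seed=seed)
                spec = MixedModelSpec(
                    response="inv_rt", family="gaussian",
                    fixed_terms=("intercept", "age", "group"),
                    random_terms=("intercept",))
                fit = fit_mixed_model(spec, data)
                errs.append(abs(fit.fixed_estimates["group"] - (-0.3)))
            biases.append(np.mean(errs))
        assert biases[1] < biases[0]


class TestBinomialFits:
    def test_loglik_matches_51_node_quadrature_oracle(self):
        """AGH marginal likelihood vs an independent quadrature refinement."""
        data = binomial_glmm_data()
        spec = MixedModelSpec(response="correct", family="binomial-logit",
                              fixed_terms=("intercept", "age",
                                           "log_pt_centered"),
                              random_terms=("intercept",))
        fit = fit_mixed_model(spec, data)
        assert fit.converged
        X, names, y, groups, _Z, _c = build_design(spec, data,
                                                   centering=fit.centering)
        beta = fit.fixed_estimates.to_numpy()
        sigma = fit.varcomp["sigma_intercept"]
        t51, w51 = np.polynomial.hermite.hermgauss(51)
        oracle = 0.0
        for gi in np.unique(groups):
            m = groups == gi
            eta0 = X[m] @ beta
            zz = y[m]
            vals = [np.sum(zz * (eta0 + np.sqrt(2) * sigma * t)
                           - np.logaddexp(0, eta0 + np.sqrt(2) * sigma * t))
                    for t in t51]
            oracle += np.log(np.sum(w51 * np.exp(vals)) / np.sqrt(np.pi))
        assert fit.log_likelihood == pytest.approx(oracle, abs=1e-4)

    def test_implementation_matches_direct_integration(self):
        """The AGH routine itself against scipy adaptive integration."""
        data = binomial_glmm_data(n_participants=6, n_trials=15, seed=9)
        spec = MixedModelSpec(response="correct", family="binomial-logit",
                              fixed_terms=("intercept", "log_pt_centered"),
                              random_terms=("intercept",))
        X, names, y, groups, _Z, _c = build_design(spec, data)
        beta = np.array([0.4, 0.9])
        sigma = 0.6
        ll = binomial_agh_loglik(beta, np.log(sigma), X, y, groups)
        oracle = 0.0
        for gi in np.unique(groups):
            m = groups == gi
            eta0 = X[m] @ beta
            zz = y[m]

            def dens(u):
                return (np.exp(np.sum(zz * (eta0 + u)
                                      - np.logaddexp(0, eta0 + u)))
                        * np.exp(-u**2 / (2 * sigma**2))
                        / np.sqrt(2 * np.pi * sigma**2))

            oracle += np.log(integrate.quad(dens, -8 * sigma, 8 * sigma,
                                            limit=200)[0])
        assert ll == pytest.approx(oracle, abs=1e-6)


class TestLRTest:
    def test_chi_square_tail_example(self):
        f0 = _stub_fit(loglik=-100.0, n_params=5)
        f1 = _stub_fit(loglik=-97.0, n_params=7,
                       fixed=("intercept", "age", "group"))
        res = lr_test(f0, f1)
        assert res.chi2 == pytest.approx(6.0)
        assert res.df == 2
        assert res.p_value == pytest.approx(0.0498, abs=1e-4)

    def test_identical_fits_give_p_one(self):
        f0 = _stub_fit(loglik=-50.0, n_params=3)
        f1 = _stub_fit(loglik=-50.0, n_params=4,
                       fixed=("intercept", "age", "group"))
        res = lr_test(f0, f1)
        assert res.chi2 == 0.0 and res.p_value == 1.0

    def test_rejects_non_nested_or_mismatched(self):
        f0 = _stub_fit(loglik=-50, n_params=3, fixed=("intercept", "block"))
        f1 = _stub_fit(loglik=-49, n_params=4,
                       fixed=("intercept", "age"))
        with pytest.raises(ContractError):
            lr_test(f0, f1)
        f2 = _stub_fit(loglik=-49, n_params=4,
                       fixed=("intercept", "age"), fingerprint="other")
        f3 = _stub_fit(loglik=-50, n_params=3, fixed=("intercept",))
        with pytest.raises(ContractError):
            lr_test(f3, f2)

    def test_rejects_non_converged(self):
        f0 = _stub_fit(loglik=-50, n_params=3, converged=False)
        f1 = _stub_fit(loglik=-49, n_params=4,
                       fixed=("intercept", "age", "group"))
        with pytest.raises(ContractError):
            lr_test(f0, f1)


def _stub_fit(loglik, n_params, fixed=("intercept", "age"), converged=True,
              fingerprint="abc"):
    from cpface.mixed_models import MixedModelFit

    spec = MixedModelSpec(response="inv_rt", family="gaussian",
                          fixed_terms=fixed, random_terms=())
    return MixedModelFit(
        spec=spec, fixed_estimates=pd.Series(0.0, index=list(fixed)),
        fixed_cov=np.eye(len(fixed)), varcomp={}, log_likelihood=loglik,
        n_params=n_params, converged=converged, boundary=False, n_obs=100,
        fingerprint=fingerprint,
    )
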