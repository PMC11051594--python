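"""Model layer: NB2 (mixed) regression, zero-inflated Gaussian (AR(1)),
backward selection and the two-sample t-tests."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats, special

from whistlecee.models import (
    ModelSpec,
    backward_select,
    build_design,
    fit_model,
    fit_nb_glmm,
    fit_zi_gaussian,
    fit_zi_gaussian_ar1,
    pooled_t_test,
    welch_t_test,
)


def zi_loglik_oracle(y, mu, sigma, pi):
    """Independent mixture log-likelihood: pi * 1{y=0} + (1-pi) * N(y)."""
    dens = (1 - pi) * stats.norm.pdf(y, mu, sigma)
    return float(np.sum(np.log(np.where(y == 0.0, pi + dens, dens))))


def sim_nb(rng, n, mu, theta):
    return rng.negative_binomial(theta, theta / (theta + mu), size=n)


def sim_zi(rng, n, pi, mu, sigma):
    y = rng.normal(mu, sigma, n)
    y[rng.random(n) < pi] = 0.0
    return y


class TestNegativeBinomial:
    def test_intercept_recovery(self, rng):
        y = sim_nb(rng, 2000, mu=5.0, theta=2.0)
        data = pd.DataFrame({"y": y})
        fit = fit_nb_glmm(data, ModelSpec("y", (), family="nbinom_log"))
        assert np.exp(fit.coef("(Intercept)")) == pytest.approx(5.0, rel=0.05)
        assert fit.converged

    def test_matches_statsmodels_nb2(self, rng):
        y = sim_nb(rng, 500, mu=4.0, theta=3.0)
        x = rng.normal(0, 1, 500)
        data = pd.DataFrame({"y": y, "x": x})
        fit = fit_nb_glmm(data, ModelSpec("y", ("x",), family="nbinom_log"))
        sm_fit = sm.NegativeBinomial(y, sm.add_constant(x)).fit(disp=0)
        assert fit.loglik == pytest.approx(sm_fit.llf, abs=0.01)
        assert fit.coef("(Intercept)") == pytest.approx(sm_fit.params[0], abs=1e-3)
        assert fit.coef("x") == pytest.approx(sm_fit.params[1], abs=1e-3)

    def test_poisson_limit(self, rng):
        y = rng.poisson(4.0, 1000)
        data = pd.DataFrame({"y": y})
        fit = fit_nb_glmm(data, ModelSpec("y", (), family="nbinom_log"))
        po = sm.Poisson(y, np.ones((1000, 1))).fit(disp=0)
        # theta runs large and the log-likelihood meets the Poisson one
        assert fit.dispersion > 20
        assert fit.loglik == pytest.approx(po.llf, abs=0.1)

    def test_type_i_error_near_nominal(self):
        """Wald test on an inert two-level covariate rejects at about the
        nominal 5% rate over 200 replicates."""
        rejections = 0
        reps = 200
        for seed in range(reps):
            r = np.random.default_rng(seed)
            y = sim_nb(r, 60, mu=5.0, theta=2.0)
            data = pd.DataFrame({"y": y, "g": np.repeat(["a", "b"], 30)})
            fit = fit_nb_glmm(data, ModelSpec("y", ("g",), family="nbinom_log"))
            if fit.pvalue("g_b") < 0.05:
                rejections += 1
        rate = rejections / reps
        se = np.sqrt(0.05 * 0.95 / reps)
        assert abs(rate - 0.05) <= 3 * se

    def test_random_intercept_recovery_and_quadrature(self, rng):
        b = rng.normal(0, 0.6, 30)
        rows = []
        for g in range(30):
            mu = np.exp(1.2 + b[g])
            for y in sim_nb(rng, 10, mu, theta=3.0):
                rows.append({"y": y, "grp": g})
        data = pd.DataFrame(rows)
        spec = ModelSpec("y", (), random_intercept="grp", family="nbinom_log")
        fit25 = fit_nb_glmm(data, spec, gh_nodes=25)
        fit50 = fit_nb_glmm(data, spec, gh_nodes=50)
        # node doubling leaves the maximized log-likelihood unchanged
        assert abs(fit25.loglik - fit50.loglik) < 1e-4
        assert fit25.sigma_b == pytest.approx(0.6, abs=0.25)
        assert fit25.coef("(Intercept)") == pytest.approx(1.2, abs=0.15)

    def test_half_to_even_rounding_message(self, rng):
        data = pd.DataFrame({"y": [0.5, 1.5, 2.0, 3.2, 4.0, 1.0] * 5})
        fit = fit_nb_glmm(data, ModelSpec("y", (), family="nbinom_log"))
        assert any("half-to-even" in m for m in fit.messages)

    def test_aic_identity_and_order_invariance(self, rng):
        y = sim_nb(rng, 300, mu=3.0, theta=2.0)
        x = rng.normal(0, 1, 300)
        data = pd.DataFrame({"y": y, "x": x})
        fit = fit_nb_glmm(data, ModelSpec("y", ("x",), family="nbinom_log"))
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * fit.df)
        perm = data.sample(frac=1.0, random_state=0).reset_index(drop=True)
        fit2 = fit_nb_glmm(perm, ModelSpec("y", ("x",), family="nbinom_log"))
        assert fit.coef("x") == pytest.approx(fit2.coef("x"), abs=1e-6)


class TestZeroInflatedGaussian:
    def _spec(self, terms=()):
        return ModelSpec("y", terms, zi_terms=(), family="gaussian")

    def test_parameter_recovery(self, rng):
        # mu sits several sigma from 0 so the mixture's density-at-zero
        # term is negligible and the point mass is cleanly identified
        y = sim_zi(rng, 5000, pi=0.3, mu=5.0, sigma=1.0)
        fit = fit_zi_gaussian(pd.DataFrame({"y": y}), self._spec())
        mu_hat = fit.coef("(Intercept)")
        sigma_hat = np.sqrt(fit.sigma2)
        pi_hat = special.expit(fit.coef("(Intercept)", part="zi"))
        assert mu_hat == pytest.approx(5.0, abs=3 * fit.params.iloc[0]["se"])
        assert sigma_hat == pytest.approx(1.0, abs=0.05)
        assert pi_hat == pytest.approx(0.3, abs=0.03)

    @pytest.mark.parametrize("pi", [0.1, 0.3, 0.5])
    def test_mixture_weight_bias_small(self, pi):
        rng = np.random.default_rng(int(pi * 1000))
        y = sim_zi(rng, 5000, pi=pi, mu=5.0, sigma=1.0)
        fit = fit_zi_gaussian(pd.DataFrame({"y": y}), self._spec())
        pi_hat = special.expit(fit.coef("(Intercept)", part="zi"))
        assert abs(pi_hat - pi) < 0.02

    def test_no_zeros_falls_back_to_ols(self, rng):
        x = rng.normal(0, 1, 200)
        y = 1.0 + 2.0 * x + rng.normal(0, 0.5, 200)
        data = pd.DataFrame({"y": y, "x": x})
        with pytest.warns(UserWarning, match="zero"):
            fit = fit_zi_gaussian(data, self._spec(("x",)))
        ols = sm.OLS(y, sm.add_constant(x)).fit()
        assert fit.coef("(Intercept)") == pytest.approx(ols.params[0], abs=1e-6)
        assert fit.coef("x") == pytest.approx(ols.params[1], abs=1e-6)

    def test_mle_is_a_maximum(self, rng):
        y = sim_zi(rng, 800, pi=0.25, mu=1.5, sigma=1.2)
        fit = fit_zi_gaussian(pd.DataFrame({"y": y}), self._spec())
        mu = fit.coef("(Intercept)")
        sigma = np.sqrt(fit.sigma2)
        pi = special.expit(fit.coef("(Intercept)", part="zi"))
        ll_hat = zi_loglik_oracle(y, mu, sigma, pi)
        assert ll_hat == pytest.approx(fit.loglik, abs=1e-6)
        for _ in range(100):
            d = rng.normal(0, 0.05, 3)
            ll = zi_loglik_oracle(y, mu + d[0], max(sigma + d[1], 1e-3),
                                  float(np.clip(pi + d[2], 1e-4, 1 - 1e-4)))
            assert ll <= ll_hat + 1e-9

    def test_zi_covariate_effect_recovered(self, rng):
        x = rng.uniform(0, 4, 4000)
        pi = special.expit(1.0 - 1.0 * x)
        y = rng.normal(5.0, 1.0, 4000)
        y[rng.random(4000) < pi] = 0.0
        data = pd.DataFrame({"y": y, "x": x})
        spec = ModelSpec("y", (), zi_terms=("x",), family="gaussian")
        fit = fit_zi_gaussian(data, spec)
        assert fit.coef("x", part="zi") == pytest.approx(-1.0, abs=0.2)

    def test_matches_glmmtmb_reference(self, rng, tmp_path):
        """The mixture MLE agrees with the R glmmTMB fit of the same
        zero-inflated Gaussian model (independent implementation)."""
        import subprocess

        y = sim_zi(rng, 600, pi=0.25, mu=2.0, sigma=1.2)
        x = rng.normal(0, 1, 600)
        data = pd.DataFrame({"y": y, "x": x})
        csv = tmp_path / "zi.csv"
        data.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(
            "suppressMessages(library(glmmTMB))\n"
            f"d <- read.csv('{csv}')\n"
            "f <- glmmTMB(y ~ x, ziformula = ~1, family = gaussian(), data = d)\n"
            "cat(fixef(f)$cond, fixef(f)$zi, sigma(f), as.numeric(logLik(f)), sep=',')\n"
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, timeout=300
        )
        assert out.returncode == 0, out.stderr
        b0, b1, zi0, sig, llf = map(float, out.stdout.strip().split(","))
        fit = fit_zi_gaussian(data, self._spec(("x",)))
        assert fit.loglik == pytest.approx(llf, abs=1e-3)
        assert fit.coef("(Intercept)") == pytest.approx(b0, abs=1e-3)
        assert fit.coef("x") == pytest.approx(b1, abs=1e-3)
        assert fit.coef("(Intercept)", part="zi") == pytest.approx(zi0, abs=1e-2)
        assert np.sqrt(fit.sigma2) == pytest.approx(sig, abs=1e-3)


class TestZeroInflatedGaussianAR1:
    def _sim_groups(self, rng, n_groups=40, n_per=24, phi=0.6, pi=0.2, mu=3.0, sigma=1.0):
        rows = []
        for g in range(n_groups):
            e = np.empty(n_per)
            e[0] = rng.normal(0, sigma)
            for t in range(1, n_per):
                e[t] = phi * e[t - 1] + rng.normal(0, sigma * np.sqrt(1 - phi**2))
            y = mu + e
            y[rng.random(n_per) < pi] = 0.0
            for t in range(n_per):
                rows.append({"y": y[t], "grp": f"g{g:02d}", "times": t + 1})
        return pd.DataFrame(rows)

    def _spec(self):
        return ModelSpec("y", (), zi_terms=(), family="gaussian",
                         correlation=("ar1", "times", "grp"))

    def test_phi_recovery(self):
        # mu near the zeros keeps the mixture likelihood unimodal (the
        # density-at-zero and point-mass components cooperate rather than
        # trade off), matching the ping-change regime the model targets
        rng = np.random.default_rng(7)
        data = self._sim_groups(rng, phi=0.6, mu=1.0)
        fit = fit_zi_gaussian_ar1(data, self._spec())
        se_phi = float(fit.params.loc[fit.params["name"] == "phi", "se"].iloc[0])
        assert fit.phi == pytest.approx(0.6, abs=3 * se_phi)
        assert fit.converged

    def test_nested_consistency_at_phi_zero(self):
        rng = np.random.default_rng(8)
        data = self._sim_groups(rng, phi=0.0)
        ar1 = fit_zi_gaussian_ar1(data, self._spec())
        indep = fit_zi_gaussian(data, ModelSpec("y", (), zi_terms=(), family="gaussian"))
        se_phi = float(ar1.params.loc[ar1.params["name"] == "phi", "se"].iloc[0])
        assert abs(ar1.phi) <= 3 * se_phi
        se_mu = float(indep.params.iloc[0]["se"])
        assert ar1.coef("(Intercept)") == pytest.approx(indep.coef("(Intercept)"), abs=2 * se_mu)

    def test_single_observation_per_group_reduces_to_independent(self):
        rng = np.random.default_rng(9)
        data = self._sim_groups(rng, n_groups=60, n_per=1, phi=0.6)
        fit = fit_zi_gaussian_ar1(data, self._spec())
        # with one observation per group the AR(1) likelihood must equal
        # the independent mixture likelihood at the same parameters
        y = data["y"].to_numpy()
        mu = fit.coef("(Intercept)")
        sigma = np.sqrt(fit.sigma2)
        pi = special.expit(fit.coef("(Intercept)", part="zi"))
        assert zi_loglik_oracle(y, mu, sigma, pi) == pytest.approx(fit.loglik, abs=1e-8)


class TestBackwardSelection:
    def _sim(self, seed, beta_g=0.8):
        r = np.random.default_rng(seed)
        n = 60
        g = np.repeat(["ctl", "trt"], n // 2)
        x1 = r.normal(0, 1, n)
        x2 = r.normal(0, 1, n)
        mu = np.exp(1.2 + beta_g * (g == "trt"))
        y = r.negative_binomial(3.0, 3.0 / (3.0 + mu))
        return pd.DataFrame({"y": y, "g": g, "x1": x1, "x2": x2})

    def _full(self):
        return ModelSpec("y", ("g", "x1", "x2"), family="nbinom_log")

    def test_active_term_retained_inert_dropped(self):
        # AIC elimination keeps an inert term with probability
        # ~P(chi2_1 > 2) ~= 0.16, so inert covariates are dropped in the
        # clear majority while the active term is (almost) always kept
        retained_active = 0
        inert_kept = 0
        reps = 40
        for seed in range(reps):
            sel = backward_select(self._sim(seed), self._full())
            terms = sel.best_spec.fixed_terms
            retained_active += "g" in terms
            inert_kept += ("x1" in terms) + ("x2" in terms)
        assert retained_active / reps >= 0.9
        assert inert_kept / (2 * reps) < 0.3

    def test_all_inert_prefers_intercept_only(self):
        outcomes = []
        for seed in range(40):
            sel = backward_select(self._sim(seed, beta_g=0.0), self._full())
            outcomes.append(sel.best_spec.fixed_terms == ())
        assert np.mean(outcomes) > 0.5

    def test_report_normalization_and_nesting(self):
        sel = backward_select(self._sim(3), self._full())
        assert sel.table["dAIC"].min() == 0.0
        assert sel.table["dAIC"].iloc[0] == 0.0
        # every elimination step may only lose log-likelihood
        by_formula = {f.spec.formula(): f for f in sel.fits}
        full = by_formula[self._full().formula()]
        for f in sel.fits:
            if f.df < full.df:
                assert f.loglik <= full.loglik + 1e-6


class TestTTests:
    def test_identical_groups_t_zero(self):
        x = [1.0, 2.0, 3.0]
        assert pooled_t_test(x, x).t == 0.0

    def test_matches_scipy_oracles(self, rng):
        x = rng.normal(0, 1, 9)
        y = rng.normal(0.5, 2, 10)
        res = pooled_t_test(x, y)
        ref = stats.ttest_ind(x, y, equal_var=True)
        assert res.t == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue)
        assert res.df == 17
        w = welch_t_test(x, y)
        ref_w = stats.ttest_ind(x, y, equal_var=False)
        assert w.t == pytest.approx(ref_w.statistic)
        assert w.p == pytest.approx(ref_w.pvalue)

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError):
            pooled_t_test([1.0, 1.0], [1.0, 1.0])
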