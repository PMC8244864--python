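"""Censored gamma survival model: likelihood, priors, sampling, summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nestdecay.core import ValidationError
from nestdecay.survival import (ModelSpec, gamma_log_sf, linear_predictor,
                                log_likelihood, log_prior, mu_draws,
                                overall_mean_decay, category_decay_summary,
                                contrast, pointwise_log_likelihood, rhat,
                                run_ensemble, sample_posterior, survival_curve)


def _toy_data(n=40, seed=0, mu=100.0, theta=0.02, censor_at=None):
    rng = np.random.default_rng(seed)
    design = pd.DataFrame({"nest_id": [f"n{i}" for i in range(n)],
                           "C": rng.integers(1, 3, size=n)})
    age = rng.gamma(mu * theta, 1 / theta, size=n)
    cens = np.zeros(n, bool)
    if censor_at is not None:
        cens = age > censor_at
        age = np.minimum(age, censor_at)
    ages = pd.DataFrame({"nest_id": design["nest_id"],
                         "age_days": np.maximum(1, np.ceil(age)).astype(int),
                         "censored": cens})
    return design, ages


class TestModelSpec:
    def test_factor_string_parsing(self):
        spec = ModelSpec.from_string("FEPCHWSDRSp")
        assert spec.factors == ("F", "E", "P", "C", "H", "W", "S", "D", "R",
                                "Sp")
        assert spec.n_coef == 2 + 2 + 2 + 2 + 3 + 3 + 3 + 3 + 2 + 11

    @pytest.mark.parametrize("bad", ["AH", "FTD", ""])
    def test_exclusive_pairs_rejected(self, bad):
        with pytest.raises(ValidationError):
            ModelSpec.from_string(bad)


class TestLinearPredictor:
    def test_zero_coefficients_give_unit_mean(self):
        spec = ModelSpec(factors=("C", "E"))
        assert linear_predictor(np.zeros(4), {"C": 1, "E": 2}, spec) == 1.0

    def test_inverse_link_identity(self):
        spec = ModelSpec(factors=("C",))
        params = np.array([np.log(95.5), 0.0])
        assert linear_predictor(params, {"C": 1}, spec) == \
            pytest.approx(95.5)

    def test_out_of_range_category(self):
        spec = ModelSpec(factors=("C",))
        with pytest.raises(ValidationError, match="out of range"):
            linear_predictor(np.zeros(2), {"C": 3}, spec)

    def test_shift_nonidentifiability(self):
        """Adding +c to one factor's categories and -c to another's leaves
        the likelihood unchanged to machine precision."""
        spec = ModelSpec(factors=("C", "E"))
        design, ages = _toy_data()
        design["E"] = (design["C"] % 2) + 1
        rng = np.random.default_rng(1)
        beta = rng.normal(size=4)
        shifted = beta + np.array([0.7, 0.7, -0.7, -0.7])
        ll0, _ = log_likelihood(beta, 0.02, design, ages, spec)
        ll1, _ = log_likelihood(shifted, 0.02, design, ages, spec)
        assert ll1 == pytest.approx(ll0, abs=1e-9)


class TestLogLikelihood:
    def test_matches_scipy_gamma_density(self):
        # mu = 100, theta = 0.02 -> shape k = 2, rate 0.02, observed 50 days
        spec = ModelSpec(factors=("C",))
        design = pd.DataFrame({"nest_id": ["n0"], "C": [1]})
        ages = pd.DataFrame({"nest_id": ["n0"], "age_days": [50],
                             "censored": [False]})
        total, per = log_likelihood(np.array([np.log(100.0), 0.0]), 0.02,
                                    design, ages, spec)
        expected = stats.gamma.logpdf(50, a=2.0, scale=1 / 0.02)
        assert total == pytest.approx(expected)
        assert per[0] == pytest.approx(expected)

    def test_censored_contribution_is_log_survival(self):
        spec = ModelSpec(factors=("C",))
        design = pd.DataFrame({"nest_id": ["n0"], "C": [1]})
        ages = pd.DataFrame({"nest_id": ["n0"], "age_days": [1],
                             "censored": [True]})
        total, _ = log_likelihood(np.array([np.log(100.0), 0.0]), 0.02,
                                  design, ages, spec)
        # S(1 day) for a ~100-day nest is nearly 1 -> contribution near 0.
        assert total == pytest.approx(stats.gamma.logsf(1, a=2.0,
                                                        scale=50.0))
        assert abs(total) < 1e-3

    def test_additivity_under_duplication(self):
        spec = ModelSpec(factors=("C",))
        design, ages = _toy_data(censor_at=120.0)
        params = np.array([4.5, 4.6])
        ll1, _ = log_likelihood(params, 0.02, design, ages, spec)
        d2 = pd.concat([design, design.assign(
            nest_id=design["nest_id"] + "b")], ignore_index=True)
        a2 = pd.concat([ages, ages.assign(
            nest_id=ages["nest_id"] + "b")], ignore_index=True)
        ll2, _ = log_likelihood(params, 0.02, d2, a2, spec)
        assert ll2 == pytest.approx(2 * ll1)

    def test_theta_must_be_positive(self):
        spec = ModelSpec(factors=("C",))
        design, ages = _toy_data()
        with pytest.raises(ValidationError, match="theta"):
            log_likelihood(np.zeros(2), -1.0, design, ages, spec)


class TestGammaLogSf:
    def test_matches_scipy_in_normal_range(self):
        ages = np.array([1.0, 50.0, 200.0, 600.0])
        got = gamma_log_sf(ages, shape=2.0, rate=0.02)
        want = stats.gamma.logsf(ages, a=2.0, scale=50.0)
        np.testing.assert_allclose(got, want, rtol=1e-10)

    def test_finite_at_extreme_ages(self):
        # Far beyond where gammaincc underflows: 1 - CDF would be 0.0.
        val = gamma_log_sf(50000.0, shape=2.0, rate=0.02)
        assert np.isfinite(val) and val < -900


class TestLogPrior:
    def test_closed_form_at_zero_coefficients(self):
        spec = ModelSpec(factors=("C", "E"))  # 4 coefficients
        got = log_prior(np.zeros(4), 1.0, spec)
        coef_part = 4 * np.log(1.0 / (5.0 * np.sqrt(2 * np.pi)))
        theta_part = stats.gamma.logpdf(1.0, a=0.1, scale=10.0)
        assert got == pytest.approx(coef_part + theta_part)

    def test_symmetry_in_coefficients(self):
        spec = ModelSpec(factors=("C",))
        x = np.array([1.3, -0.4])
        assert log_prior(x, 0.5, spec) == pytest.approx(
            log_prior(-x, 0.5, spec))

    def test_nonpositive_theta_rejected(self):
        spec = ModelSpec(factors=("C",))
        assert log_prior(np.zeros(2), 0.0, spec) == -np.inf


class TestSampler:
    def test_conjugate_exponential_rate(self):
        """The generic ensemble engine reproduces a known conjugate
        posterior: exponential data with a Gamma(a0, b0) prior on the rate
        has posterior Gamma(a0 + n, b0 + sum x)."""
        rng = np.random.default_rng(3)
        x = rng.exponential(1 / 0.02, size=80)
        a0 = b0 = 0.1

        def logpost(z):
            lam = np.exp(z[:, 0])
            return (len(x) * z[:, 0] - lam * x.sum()
                    + a0 * z[:, 0] - b0 * lam)  # likelihood+prior+Jacobian

        draws, _ = run_ensemble(logpost, 1, np.array([np.log(0.05)]),
                                iterations=2000, warmup=1000, seed=9,
                                n_out=4000)
        post_mean = np.exp(draws[:, 0]).mean()
        analytic = (a0 + len(x)) / (b0 + x.sum())
        assert post_mean == pytest.approx(analytic, rel=0.03)

    def test_seed_reproducibility(self):
        spec = ModelSpec(factors=("C",))
        design, ages = _toy_data()
        kw = dict(chains=2, iterations=400, warmup=200, check_rhat=False)
        d1 = sample_posterior(spec, design, ages, seed=5, **kw)
        d2 = sample_posterior(spec, design, ages, seed=5, **kw)
        assert np.array_equal(d1.beta, d2.beta)
        assert np.array_equal(d1.theta, d2.theta)
        assert (d1.theta > 0).all()

    def test_posterior_centers_on_sample_mean_without_censoring(self):
        design, ages = _toy_data(n=300, seed=4)
        spec = ModelSpec(factors=("C",))
        draws = sample_posterior(spec, design, ages, chains=2,
                                 iterations=1000, warmup=500, seed=1,
                                 check_rhat=False)
        md = overall_mean_decay(draws, design)
        assert md.mean() == pytest.approx(ages["age_days"].mean(), rel=0.05)


class TestRhat:
    def test_iid_chains_near_one(self):
        rng = np.random.default_rng(0)
        assert 0.99 <= rhat(rng.standard_normal((2, 2000))) <= 1.01

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((2, 1000))
        x[1] += 10.0
        assert rhat(x) > 1.1

    def test_identical_chains(self):
        base = np.random.default_rng(0).standard_normal(500)
        assert rhat(np.stack([base, base])) <= 1.01

    def test_single_chain_is_an_error(self):
        with pytest.raises(ValidationError):
            rhat(np.zeros((1, 100)))


class TestSummaries:
    def test_single_category_reduces_to_exp_coefficient(self, small_cohort):
        _, design, ages, _ = small_cohort
        sub = design.copy()
        sub["C"] = 1
        spec = ModelSpec(factors=("C",))
        draws = sample_posterior(spec, sub, ages, chains=2, iterations=500,
                                 warmup=250, seed=2, check_rhat=False)
        summ = category_decay_summary(draws, sub, "C")
        assert len(summ) == 1  # empty category absent, not zero
        expected = np.exp(draws.flat_beta()[:, 0]).mean()
        assert summ.iloc[0]["mean_days"] == pytest.approx(expected, rel=1e-6)

    def test_contrast_identity_and_antisymmetry(self, small_fit,
                                                small_cohort):
        _, design, _, _ = small_cohort
        spec, draws = small_fit
        same = contrast(draws, design, "C", 1, 1)
        assert np.all(same["samples"] == 0.0)
        ab = contrast(draws, design, "C", 1, 2)
        ba = contrast(draws, design, "C", 2, 1)
        np.testing.assert_allclose(ab["samples"], -ba["samples"])

    def test_mean_identity_monte_carlo(self):
        # With k = mu * theta, draws from the likelihood have mean -> mu.
        rng = np.random.default_rng(8)
        mu, theta, n = 95.0, 0.02, 40000
        x = rng.gamma(mu * theta, 1 / theta, size=n)
        se = np.sqrt(mu / theta / n)
        assert abs(x.mean() - mu) < 4 * se


class TestSurvivalCurve:
    def test_bounds_and_monotonicity(self, small_fit, small_cohort):
        _, design, _, _ = small_cohort
        _, draws = small_fit
        curve = survival_curve(draws, design, np.array([0, 30, 90, 180, 400,
                                                        2000]))
        assert curve["survival"].iloc[0] == 1.0
        assert curve["survival"].iloc[-1] < 0.01
        assert (np.diff(curve["survival"]) <= 0).all()
        assert curve["ci_high"].between(0, 1).all()

    def test_single_nest_matches_gamma_sf(self, small_fit, small_cohort):
        _, design, _, _ = small_cohort
        _, draws = small_fit
        one = np.zeros(len(design), dtype=bool)
        one[0] = True
        t = np.array([0.0, 60.0, 120.0])
        curve = survival_curve(draws, design, t, subset=one, max_draws=10 ** 9)
        mu = mu_draws(draws, design)[:, 0]
        theta = draws.flat_theta()
        direct = np.array([stats.gamma.sf(tv, a=mu * theta,
                                          scale=1 / theta).mean() for tv in t])
        np.testing.assert_allclose(curve["survival"], direct, atol=1e-10)

    def test_empty_subset_rejected(self, small_fit, small_cohort):
        _, design, _, _ = small_cohort
        _, draws = small_fit
        with pytest.raises(ValidationError, match="empty subset"):
            survival_curve(draws, design, np.array([0.0, 10.0]),
                           subset=np.zeros(len(design), dtype=bool))
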