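"""Weibull-Cox likelihood, MLE, and the measurement-error bias machinery."""

import math

import numpy as np
import pytest
from scipy import integrate, special, stats

from tmbsim import (
    SurvivalCohort,
    ValidationError,
    WeibullCoxParams,
    bias_factor,
    fit_mle,
    score_expectation_mc,
    simulate_survival,
    threshold_misclassification,
    weibull_cox_loglik,
)
from tmbsim.survival_bias import (
    CallerPipelineConfig,
    _loglik_score,
    attenuation_study,
)

TRUTH = WeibullCoxParams(lam=1.5, beta_z=(0.5, -0.5), beta_m=0.3)


class TestSimulation:
    def test_exponential_limit(self):
        # lam = 1 with all coefficients zero gives unit-exponential times
        params = WeibullCoxParams(lam=1.0, beta_z=(0.0, 0.0), beta_m=0.0)
        cohort = simulate_survival(params, 100_000,
                                   rng=np.random.default_rng(0))
        assert abs(cohort.time.mean() - 1.0) < 3 / np.sqrt(100_000)

    def test_weibull_moment(self):
        # lam = 2: E[T] = Gamma(1 + 1/2) ~ 0.8862
        params = WeibullCoxParams(lam=2.0, beta_z=(0.0, 0.0), beta_m=0.0)
        cohort = simulate_survival(params, 100_000,
                                   rng=np.random.default_rng(1))
        target = special.gamma(1.5)
        sd = np.sqrt(special.gamma(2.0) - target**2)
        assert abs(cohort.time.mean() - target) < 3 * sd / np.sqrt(100_000)

    def test_sigma_zero_observed_equals_true(self, rng):
        cohort = simulate_survival(TRUTH, 200, rng=rng)
        assert (cohort.tmb_obs == cohort.tmb_true).all()
        for rec in cohort[:5]:
            assert rec.tmb_obs == rec.tmb_true + rec.e

    def test_censoring_rate_calibrated(self):
        cohort = simulate_survival(TRUTH, 20_000, censoring_rate=0.3,
                                   rng=np.random.default_rng(2))
        censored = 1.0 - cohort.delta.mean()
        assert abs(censored - 0.3) < 3 * np.sqrt(0.3 * 0.7 / 20_000)

    def test_caller_pipeline_error_is_mechanistic(self):
        params = WeibullCoxParams(sigma_e=0.0)
        cohort = simulate_survival(
            params, 60, tmb_source="caller-pipeline",
            rng=np.random.default_rng(4),
            pipeline=CallerPipelineConfig())
        # observed TMB differs from truth exactly by the caller's FP-FN
        # balance, and both stay non-negative counts per Mb
        assert (cohort.tmb_obs == cohort.tmb_true + cohort.e).all()
        assert (cohort.tmb_obs >= 0).all()
        assert cohort.e.std() > 0  # the caller does make errors

    def test_invalid_inputs(self, rng):
        with pytest.raises(ValidationError):
            simulate_survival(TRUTH, 0, rng=rng)
        with pytest.raises(ValidationError):
            simulate_survival(TRUTH, 10, censoring_rate=1.0, rng=rng)
        with pytest.raises(ValidationError):
            simulate_survival(WeibullCoxParams(lam=-1.0), 10, rng=rng)


class TestLikelihood:
    def test_single_record_hand_value(self):
        # delta=1, T=1, lam=1, all beta zero: l = log 1 + 0 + 0 - 1 = -1
        cohort = SurvivalCohort(z=np.zeros((1, 2)), tmb_true=np.zeros(1),
                                e=np.zeros(1), time=np.ones(1),
                                delta=np.ones(1))
        ll, _ = weibull_cox_loglik(np.zeros(4), cohort)
        assert ll == pytest.approx(-1.0)

    def test_censored_only_closed_form(self, rng):
        cohort = simulate_survival(TRUTH, 100, rng=rng)
        censored = SurvivalCohort(cohort.z, cohort.tmb_true, cohort.e,
                                  cohort.time, np.zeros(len(cohort)))
        theta = np.array([np.log(TRUTH.lam), *TRUTH.beta_z, TRUTH.beta_m])
        ll, _ = weibull_cox_loglik(theta, censored)
        eta = censored.z @ np.array(TRUTH.beta_z) \
            + TRUTH.beta_m * censored.tmb_true
        expected = -np.sum(censored.time**TRUTH.lam * np.exp(eta))
        assert ll == pytest.approx(expected, rel=1e-12)

    def test_gradient_matches_finite_differences(self):
        # analytic score vs central differences at 20 random points
        rng = np.random.default_rng(8)
        cohort = simulate_survival(TRUTH, 300, censoring_rate=0.2, rng=rng)
        x_mat = np.column_stack([cohort.z, cohort.tmb_obs])

        def ll_only(theta):
            return _loglik_score(theta, x_mat, cohort.time, cohort.delta)[0]

        for _ in range(20):
            theta = np.concatenate([
                rng.uniform(-0.5, 0.5, size=1),        # log lam
                rng.uniform(-0.5, 0.5, size=2),        # beta_z
                rng.uniform(-0.05, 0.05, size=1),      # beta_m
            ])
            _, grad = _loglik_score(theta, x_mat, cohort.time, cohort.delta)
            h = 1e-6
            for j in range(len(theta)):
                tp, tm = theta.copy(), theta.copy()
                step = h * max(1.0, abs(theta[j]))
                tp[j] += step
                tm[j] -= step
                fd = (ll_only(tp) - ll_only(tm)) / (2 * step)
                assert grad[j] == pytest.approx(fd, rel=1e-5, abs=1e-6)

    def test_nonfinite_theta_rejected(self, rng):
        cohort = simulate_survival(TRUTH, 60, rng=rng)
        with pytest.raises(ValidationError):
            weibull_cox_loglik([np.nan, 0, 0, 0], cohort)


class TestFit:
    def test_recovers_truth_on_large_sample(self):
        cohort = simulate_survival(TRUTH, 4000, censoring_rate=0.3,
                                   rng=np.random.default_rng(10))
        fit = fit_mle(cohort, use_obs_tmb=False)
        assert fit.converged
        assert fit.lam == pytest.approx(TRUTH.lam, abs=0.1)
        assert fit.beta_m == pytest.approx(TRUTH.beta_m, abs=0.05)
        np.testing.assert_allclose(fit.beta_z, TRUTH.beta_z, atol=0.15)
        assert (fit.se_theta > 0).all()

    def test_observed_covariate_identical_when_error_free(self, rng):
        cohort = simulate_survival(TRUTH, 500, rng=rng)
        a = fit_mle(cohort, use_obs_tmb=True)
        b = fit_mle(cohort, use_obs_tmb=False)
        assert a.theta == pytest.approx(b.theta)

    def test_small_sample_floor(self, rng):
        cohort = simulate_survival(TRUTH, 30, rng=rng)
        with pytest.raises(ValidationError):
            fit_mle(cohort)

    def test_agrees_with_lifelines_weibull_aft(self):
        # Weibull PH and Weibull AFT are reparameterizations of the same
        # model: beta_PH = -shape * beta_AFT.  lifelines carries a free
        # baseline-scale intercept, so a constant covariate column is
        # appended on our side to fit the identical model through an
        # entirely independent optimizer route.
        lifelines = pytest.importorskip("lifelines")
        cohort = simulate_survival(TRUTH, 3000, censoring_rate=0.2,
                                   rng=np.random.default_rng(11))
        augmented = SurvivalCohort(
            z=np.column_stack([cohort.z, np.ones(len(cohort))]),
            tmb_true=cohort.tmb_true, e=cohort.e, time=cohort.time,
            delta=cohort.delta)
        fit = fit_mle(augmented, use_obs_tmb=False)
        df = cohort.to_frame()[["z0", "z1", "tmb_true", "time", "delta"]]
        aft = lifelines.WeibullAFTFitter()
        aft.fit(df, duration_col="time", event_col="delta")
        shape = math.exp(
            float(aft.summary.loc[("rho_", "Intercept"), "coef"]))
        assert shape == pytest.approx(fit.lam, rel=1e-3)
        beta_aft = float(aft.summary.loc[("lambda_", "tmb_true"), "coef"])
        assert -shape * beta_aft == pytest.approx(fit.beta_m, rel=1e-3)
        for j, name in enumerate(["z0", "z1"]):
            coef = float(aft.summary.loc[("lambda_", name), "coef"])
            assert -shape * coef == pytest.approx(fit.beta_z[j], rel=1e-2)
        assert fit.loglik == pytest.approx(aft.log_likelihood_, abs=1e-3)


class TestBiasFactor:
    @pytest.mark.parametrize("beta_m", [-2.0, 0.0, 2.0])
    def test_exactly_one_at_zero_variance(self, beta_m):
        assert bias_factor(beta_m, 0.0) == 1.0

    def test_one_for_null_coefficient(self):
        assert bias_factor(0.0, 3.0) == 1.0

    @pytest.mark.parametrize("beta_m,sigma", [(1.0, 1.0), (-1.0, 0.5),
                                              (0.5, 2.0)])
    def test_matches_mc_oracle(self, beta_m, sigma):
        rng = np.random.default_rng(13)
        draws = np.exp(beta_m * rng.normal(0.0, sigma, size=400_000))
        mc_se = draws.std(ddof=1) / np.sqrt(draws.size)
        assert abs(bias_factor(beta_m, sigma) - draws.mean()) < 3 * mc_se

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValidationError):
            bias_factor(1.0, -0.1)


class TestScoreExpectation:
    def test_zero_at_truth_without_error(self):
        se = score_expectation_mc(TRUTH, 0.0, 1000, 60,
                                  np.random.default_rng(14))
        assert (np.abs(se.mean) < 3 * se.se).all()

    def test_nonzero_under_error(self):
        params = WeibullCoxParams(lam=1.5, beta_z=(0.5, -0.5), beta_m=0.5)
        se = score_expectation_mc(params, 1.0, 1000, 60,
                                  np.random.default_rng(14))
        mean, mc_se = se.beta_m_component
        assert abs(mean) > 3 * mc_se


class TestThreshold:
    def test_no_error_no_misclassification(self, rng):
        cohort = simulate_survival(WeibullCoxParams(beta_m=0.3), 400, rng=rng)
        report = threshold_misclassification(cohort, 10.0)
        assert report.misclassification == 0.0
        assert report.log_hr_true == pytest.approx(report.log_hr_obs)

    def test_matches_numeric_integration_oracle(self):
        # TMB ~ N(10, 2^2), e ~ N(0, 2^2), cutoff at the mean: the flip
        # probability is 2 * int_0^inf phi(s) Phi(-s) ds = 1/4
        oracle = 2 * integrate.quad(
            lambda s: stats.norm.pdf(s) * stats.norm.cdf(-s), 0, np.inf)[0]
        params = WeibullCoxParams(beta_m=0.3, sigma_e=2.0, tmb_mean=10.0,
                                  tmb_sd=2.0)
        n = 20_000
        cohort = simulate_survival(params, n, rng=np.random.default_rng(15))
        report = threshold_misclassification(cohort, 10.0)
        se = np.sqrt(oracle * (1 - oracle) / n)
        assert abs(report.misclassification - oracle) < 3 * se

    def test_grouping_dilution(self):
        # error-contaminated grouping shrinks the apparent group effect
        params = WeibullCoxParams(beta_m=0.3, sigma_e=2.0)
        rng = np.random.default_rng(16)
        gaps = []
        for _ in range(20):
            cohort = simulate_survival(params, 800, rng=rng)
            report = threshold_misclassification(cohort, 10.0)
            gaps.append(abs(report.log_hr_true) - abs(report.log_hr_obs))
        assert np.mean(gaps) > 0


class TestAttenuation:
    def test_naive_estimate_shrinks_with_error(self):
        report = attenuation_study(TRUTH, [0.0, 2.0], 800, 15,
                                   np.random.default_rng(17),
                                   censoring_rate=0.2)
        means = np.abs(report.naive_beta_m_mean)
        assert means[1] < means[0]
        # at sigma = 0 the naive fit is the oracle fit
        assert report.naive_beta_m_mean[0] == pytest.approx(
            report.oracle_beta_m_mean)
        assert report.bias_factor[0] == 1.0
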