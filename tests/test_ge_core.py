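"""Distribution functions, likelihoods and the posterior kernel."""

import itertools
import math

import numpy as np
import pytest
from scipy import integrate
from scipy.special import logsumexp

from gemix.ge_core import (
    CensoredDataset,
    GEParams,
    Hyperparams,
    MixtureParams,
    ge_cdf,
    ge_pdf,
    ge_ppf,
    ge_rvs,
    log_posterior_kernel,
    log_prior,
    loglik_labeled,
    loglik_mixture,
    mixture_cdf,
    mixture_pdf,
)
from .conftest import random_omega


class TestGEDistribution:
    def test_reduces_to_exponential_at_unit_shape(self):
        assert ge_pdf(0.5, GEParams(1.0, 1.0)) == pytest.approx(math.exp(-0.5), rel=1e-12)

    def test_closed_form_point_evaluations(self):
        assert ge_pdf(math.log(2), GEParams(2.0, 1.0)) == pytest.approx(0.5, rel=1e-12)
        assert ge_cdf(math.log(2), GEParams(2.0, 1.0)) == pytest.approx(0.25, rel=1e-12)
        assert ge_cdf(0.0, GEParams(2.3, 0.7)) == 0.0

    def test_pdf_integrates_to_one(self):
        p = GEParams(0.75, 1.5)
        total, _ = integrate.quad(lambda x: ge_pdf(x, p), 0, np.inf)
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_cdf_matches_cumulative_quadrature(self):
        p = GEParams(0.75, 1.5)
        for x in np.linspace(0.05, 4.0, 20):
            num, _ = integrate.quad(lambda t: ge_pdf(t, p), 0, x)
            assert ge_cdf(x, p) == pytest.approx(num, abs=1e-8)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            GEParams(-1.0, 1.0)
        with pytest.raises(ValueError):
            ge_pdf(-0.1, GEParams(1.0, 1.0))

    @pytest.mark.parametrize("lam,theta", [(0.5, 1.2), (2.0, 0.3), (7.0, 4.0)])
    def test_quantile_roundtrip(self, lam, theta):
        p = GEParams(lam, theta)
        q = np.linspace(0.001, 0.999, 50)
        assert np.max(np.abs(ge_cdf(ge_ppf(q, p), p) - q)) < 1e-10

    def test_rvs_exponential_mean(self):
        x = ge_rvs(GEParams(1.0, 2.0), 100_000, np.random.default_rng(11))
        se = x.std() / math.sqrt(x.size)
        assert abs(x.mean() - 0.5) < 3 * se

    def test_rvs_distribution_and_determinism(self):
        from scipy import stats

        p = GEParams(0.75, 1.5)
        x = ge_rvs(p, 10_000, np.random.default_rng(7))
        assert stats.ks_1samp(x, lambda t: ge_cdf(t, p)).pvalue > 0.01
        y = ge_rvs(p, 10_000, np.random.default_rng(7))
        assert np.array_equal(x, y)


class TestMixture:
    def test_degenerate_weight_recovers_component(self):
        omega = MixtureParams.from_values(0.7, 1.1, 3.0, 0.4, 1 - 1e-14)
        x = np.linspace(0.1, 3, 30)
        assert np.allclose(mixture_pdf(x, omega), ge_pdf(x, omega.comp1), rtol=0, atol=1e-10)

    def test_identical_components_symmetry(self):
        omega = MixtureParams.from_values(0.7, 1.1, 0.7, 1.1, 0.5)
        x = np.linspace(0.1, 3, 30)
        assert np.allclose(mixture_pdf(x, omega), ge_pdf(x, omega.comp1))
        assert np.allclose(mixture_cdf(x, omega), ge_cdf(x, omega.comp1))

    def test_cdf_matches_quadrature_of_pdf(self, omega_s1):
        grid = np.linspace(0.02, 6.0, 100)
        cums = [
            integrate.quad(lambda t: mixture_pdf(t, omega_s1), 0, x, limit=200)[0]
            for x in grid
        ]
        assert np.max(np.abs(mixture_cdf(grid, omega_s1) - cums)) < 1e-8

    def test_cdf_monotone_bounded(self, omega_s1):
        grid = np.linspace(0, 50, 400)
        F = mixture_cdf(grid, omega_s1)
        assert np.all(np.diff(F) >= -1e-15) and F[0] == 0.0 and F[-1] <= 1.0


class TestLabeledLoglik:
    def test_single_exponential_point(self):
        ds = CensoredDataset([0.5], [False], [np.nan], [1])
        omega = MixtureParams.from_values(1.0, 1.0, 1.0, 1.0, 1 - 1e-15)
        assert loglik_labeled(ds, omega) == pytest.approx(-0.5, abs=1e-9)

    def test_factor_product_oracle(self, toy_mixed, omega_s1):
        """Term-by-term product of likelihood factors: weight * density for
        observed records, weight * CDF-at-limit for censored records."""
        expected = 0.0
        for i in range(toy_mixed.n):
            u = int(toy_mixed.labels[i])
            w = omega_s1.pi1 if u == 1 else 1 - omega_s1.pi1
            p = omega_s1.component(u)
            if toy_mixed.censored[i]:
                expected += math.log(w * ge_cdf(toy_mixed.limits[i], p))
            else:
                expected += math.log(w * ge_pdf(toy_mixed.values[i], p))
        assert loglik_labeled(toy_mixed, omega_s1) == pytest.approx(expected, abs=1e-10)

    def test_duplication_doubles_loglik(self, toy_mixed, omega_s1):
        doubled = CensoredDataset(
            np.tile(toy_mixed.values, 2),
            np.tile(toy_mixed.censored, 2),
            np.tile(toy_mixed.limits, 2),
            np.tile(toy_mixed.labels, 2),
        )
        assert loglik_labeled(doubled, omega_s1) == pytest.approx(
            2 * loglik_labeled(toy_mixed, omega_s1), rel=1e-12
        )

    def test_permutation_invariance(self, toy_mixed, omega_s1):
        perm = np.random.default_rng(3).permutation(toy_mixed.n)
        shuffled = CensoredDataset(
            toy_mixed.values[perm],
            toy_mixed.censored[perm],
            toy_mixed.limits[perm],
            toy_mixed.labels[perm],
        )
        assert loglik_labeled(shuffled, omega_s1) == pytest.approx(
            loglik_labeled(toy_mixed, omega_s1), rel=1e-12
        )

    def test_order_statistic_threshold_convention(self, toy_mixed, omega_s1):
        """The optional order-statistic convention replaces every censoring
        limit by the smallest observed value in the pooled sample."""
        x_min = toy_mixed.observed_values().min()
        forced = CensoredDataset(
            toy_mixed.values,
            toy_mixed.censored,
            np.where(toy_mixed.censored, x_min, np.nan),
            toy_mixed.labels,
        )
        assert loglik_labeled(
            toy_mixed, omega_s1, threshold="order-statistic"
        ) == pytest.approx(loglik_labeled(forced, omega_s1), rel=1e-12)
        with pytest.raises(ValueError):
            loglik_labeled(toy_mixed, omega_s1, threshold="bogus")

    def test_unlabeled_record_rejected(self, omega_s1):
        ds = CensoredDataset([0.5, 0.7], [False, False], [np.nan, np.nan], [1, 0])
        with pytest.raises(ValueError):
            loglik_labeled(ds, omega_s1)


class TestMixtureLoglik:
    def test_single_censored_record(self, omega_s1):
        ds = CensoredDataset([np.nan], [True], [0.4], None)
        assert loglik_mixture(ds, omega_s1) == pytest.approx(
            math.log(mixture_cdf(0.4, omega_s1))
        )

    def test_label_marginalization_identity(self, toy_mixed, omega_s1):
        """The unlabeled likelihood is exactly the sum of the labeled
        likelihood over all 2^n component assignments."""
        parts = []
        for labels in itertools.product((1, 2), repeat=toy_mixed.n):
            relabeled = toy_mixed.with_labels(np.array(labels))
            parts.append(loglik_labeled(relabeled, omega_s1))
        marginal = logsumexp(parts)
        mix = loglik_mixture(toy_mixed.without_labels(), omega_s1)
        assert mix == pytest.approx(marginal, abs=1e-9)
        # and hence dominates any single assignment, including the true one
        assert mix >= loglik_labeled(toy_mixed, omega_s1)


class TestPriorAndKernel:
    def test_flat_prior_is_zero(self, omega_s1):
        assert log_prior(omega_s1, Hyperparams()) == 0.0

    def test_beta_kernel_point(self):
        h = Hyperparams(mu1=2.0, tau1=2.0)
        omega = MixtureParams.from_values(1.0, 1.0, 1.0, 1.0, 0.5)
        assert log_prior(omega, h) == pytest.approx(math.log(0.5) + math.log(0.5))

    def test_componentwise_oracle(self, tiny_prior):
        from scipy import stats

        rng = np.random.default_rng(42)
        for _ in range(50):
            omega = random_omega(rng)
            expected = stats.beta.logpdf(omega.pi1, tiny_prior.mu1, tiny_prior.tau1)
            expected -= stats.beta.logpdf(0.5, tiny_prior.mu1, tiny_prior.tau1)  # const
            base = log_prior(
                MixtureParams.from_values(1, 1, 1, 1, 0.5), tiny_prior
            )
            got = log_prior(
                MixtureParams.from_values(1, 1, 1, 1, omega.pi1), tiny_prior
            )
            assert got - base == pytest.approx(expected, abs=1e-10)
            for u, (lam, theta) in ((1, (omega.comp1.lam, omega.comp1.theta)),
                                    (2, (omega.comp2.lam, omega.comp2.theta))):
                gl = stats.gamma.logpdf(lam, tiny_prior.mu2[u - 1], scale=1 / tiny_prior.tau2[u - 1])
                gl -= stats.gamma.logpdf(1.0, tiny_prior.mu2[u - 1], scale=1 / tiny_prior.tau2[u - 1])
                args = [1.0, 1.0, 1.0, 1.0, 0.5]
                args[2 * (u - 1)] = lam
                got_u = log_prior(MixtureParams.from_values(*args), tiny_prior) - base
                assert got_u == pytest.approx(gl, abs=1e-10)

    def test_kernel_equals_loglik_under_flat_prior(self, toy_mixed, omega_s1):
        assert log_posterior_kernel(toy_mixed, omega_s1, Hyperparams()) == pytest.approx(
            loglik_labeled(toy_mixed, omega_s1)
        )

    def test_kernel_minus_parts_constant(self, toy_mixed, tiny_prior):
        rng = np.random.default_rng(5)
        diffs = []
        for _ in range(100):
            omega = random_omega(rng)
            diffs.append(
                log_posterior_kernel(toy_mixed, omega, tiny_prior)
                - loglik_labeled(toy_mixed, omega)
                - log_prior(omega, tiny_prior)
            )
        assert np.ptp(diffs) < 1e-10

    def test_pi_exponent_bookkeeping(self, toy_mixed, tiny_prior):
        """The pi1 exponent of the kernel is k1+m1+mu1-1 (and the 1-pi1
        exponent k2+m2+tau1-1), extracted by differencing at two pi values."""
        a = np.log(0.3) - np.log(0.6)
        b = np.log(0.7) - np.log(0.4)
        om1 = MixtureParams.from_values(1, 1, 1, 1, 0.3)
        om2 = MixtureParams.from_values(1, 1, 1, 1, 0.6)
        diff = log_posterior_kernel(toy_mixed, om1, tiny_prior) - log_posterior_kernel(
            toy_mixed, om2, tiny_prior
        )
        e1 = toy_mixed.k1 + toy_mixed.m1 + tiny_prior.mu1 - 1
        e2 = toy_mixed.k2 + toy_mixed.m2 + tiny_prior.tau1 - 1
        assert diff == pytest.approx(e1 * a + e2 * b, abs=1e-10)
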