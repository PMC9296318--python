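"""Conditional-draw importance sampler and SELF/ELF estimators."""

import warnings

import numpy as np
import pytest
from scipy import stats

from gemix.bayes_mcmc import (
    PosteriorDraws,
    estimate,
    sample_posterior,
    sample_posterior_augmented,
)
from gemix.ge_core import (
    CensoredDataset,
    Hyperparams,
    MixtureParams,
    log1mexp,
    log_posterior_kernel,
)
from gemix.synthetic_data import SimConfig, make_prior, simulate


class TestSampler:
    def test_weight_is_kernel_minus_proposal(self, toy_mixed, tiny_prior):
        """log w must equal log posterior kernel minus the sum of the three
        proposal log-densities, up to one additive constant."""
        d = sample_posterior(toy_mixed, tiny_prior, m=200, m0=0, seed=8)
        g1 = toy_mixed.k1 + toy_mixed.m1 + tiny_prior.mu1
        g2 = toy_mixed.k2 + toy_mixed.m2 + tiny_prior.tau1
        diffs = []
        for z in range(d.m1):
            lam1, th1, lam2, th2, pi1 = d.draws[z]
            omega = MixtureParams.from_values(lam1, th1, lam2, th2, pi1)
            logq = stats.beta.logpdf(pi1, g1, g2)
            for u, (lam, th) in ((1, (lam1, th1)), (2, (lam2, th2))):
                x = toy_mixed.observed_values(u)
                g3 = x.size + tiny_prior.mu2[u - 1]
                g4 = x.size + tiny_prior.mu3[u - 1]
                k2 = tiny_prior.tau3[u - 1] + x.sum()
                k1 = tiny_prior.tau2[u - 1] - log1mexp(th * x).sum()
                logq += stats.gamma.logpdf(th, g4, scale=1 / k2)
                logq += stats.gamma.logpdf(lam, g3, scale=1 / k1)
            diffs.append(
                d.log_weights[z]
                - (log_posterior_kernel(toy_mixed, omega, tiny_prior) - logq)
            )
        assert np.ptp(diffs) < 1e-8

    def test_prior_only_limit(self, tiny_prior):
        """With no data the draws follow the priors exactly and the weights
        are constant."""
        empty = CensoredDataset(
            np.array([]), np.array([], bool), np.array([]), np.array([], int)
        )
        d = sample_posterior(empty, tiny_prior, m=20_000, m0=0, seed=9)
        assert np.ptp(d.log_weights) < 1e-12
        assert stats.kstest(
            d.draws[:, 4], stats.beta(tiny_prior.mu1, tiny_prior.tau1).cdf
        ).pvalue > 0.01
        assert stats.kstest(
            d.draws[:, 0], stats.gamma(tiny_prior.mu2[0], scale=1 / tiny_prior.tau2[0]).cdf
        ).pvalue > 0.01
        assert stats.kstest(
            d.draws[:, 1], stats.gamma(tiny_prior.mu3[0], scale=1 / tiny_prior.tau3[0]).cdf
        ).pvalue > 0.01

    def test_determinism(self, toy_mixed, tiny_prior):
        a = sample_posterior(toy_mixed, tiny_prior, m=500, m0=100, seed=10)
        b = sample_posterior(toy_mixed, tiny_prior, m=500, m0=100, seed=10)
        assert np.array_equal(a.draws, b.draws)
        assert np.array_equal(a.log_weights, b.log_weights)
        assert a.m1 == 400

    def test_burn_in_bounds(self, toy_mixed, tiny_prior):
        with pytest.raises(ValueError):
            sample_posterior(toy_mixed, tiny_prior, m=100, m0=100, seed=1)


class TestEstimators:
    def test_uniform_weights_give_arithmetic_mean(self):
        rng = np.random.default_rng(11)
        draws = np.column_stack(
            [rng.uniform(0.5, 2, 50)] * 4 + [rng.uniform(0.2, 0.8, 50)]
        )
        d = PosteriorDraws(draws=draws, log_weights=np.zeros(50))
        est = estimate(d, "self")
        assert np.allclose(est.as_array(), draws.mean(axis=0))

    def test_weight_rescaling_invariance(self, toy_mixed, tiny_prior):
        d = sample_posterior(toy_mixed, tiny_prior, m=500, m0=0, seed=12)
        shifted = PosteriorDraws(draws=d.draws, log_weights=d.log_weights + 123.4)
        for loss in ("self", "elf"):
            assert np.allclose(
                estimate(d, loss).as_array(), estimate(shifted, loss).as_array()
            )

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_elf_below_self_jensen(self, toy_mixed, tiny_prior, seed):
        d = sample_posterior(toy_mixed, tiny_prior, m=2000, m0=0, seed=seed)
        s = estimate(d, "self").as_array()
        e = estimate(d, "elf").as_array()
        assert np.all(e <= s + 1e-12)

    def test_low_ess_warns(self):
        draws = np.full((20, 5), 0.5)
        lw = np.zeros(20)
        lw[0] = 50.0  # one draw dominates
        d = PosteriorDraws(draws=draws, log_weights=lw)
        with pytest.warns(RuntimeWarning, match="effective sample size"):
            estimate(d, "self")


class TestAugmented:
    def test_prior_forces_all_labels_to_component_one(self, tiny_prior):
        ds = simulate(SimConfig(
            MixtureParams.from_values(0.75, 1.5, 0.75, 1.5, 0.5), 40, 0.1, seed=13
        )).without_labels()
        h = Hyperparams(
            mu1=1e6, tau1=1.0, mu2=tiny_prior.mu2, tau2=tiny_prior.tau2,
            mu3=tiny_prior.mu3, tau3=tiny_prior.tau3,
        )
        d = sample_posterior_augmented(ds, h, m=50, m0=10, seed=14)
        assert np.mean(d.labels_trace == 1) > 0.999

    def test_well_separated_labels_recovered(self):
        omega = MixtureParams.from_values(2.0, 8.0, 2.0, 0.25, 0.5)
        ds = simulate(SimConfig(omega, 150, 0.0, seed=15))
        h = Hyperparams(
            mu1=1.0, tau1=1.0, mu2=(4.0, 4.0), tau2=(2.0, 2.0),
            mu3=(16.0, 0.5), tau3=(2.0, 2.0),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            d = sample_posterior_augmented(ds.without_labels(), h, m=300, m0=100, seed=16)
        modal = np.where((d.labels_trace == 1).mean(axis=0) > 0.5, 1, 2)
        match = np.mean(modal == ds.labels)
        assert max(match, 1 - match) > 0.95  # up to global label swap

    def test_balanced_pi_centred(self, tiny_prior):
        omega = MixtureParams.from_values(0.75, 1.5, 0.75, 1.5, 0.5)
        ds = simulate(SimConfig(omega, 200, 0.0, seed=17)).without_labels()
        h = Hyperparams(
            mu1=1.0, tau1=1.0, mu2=tiny_prior.mu2, tau2=tiny_prior.tau2,
            mu3=tiny_prior.mu3, tau3=tiny_prior.tau3,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            d = sample_posterior_augmented(ds, h, m=600, m0=100, seed=18)
        pi = d.draws[:, 4]
        se = pi.std() / np.sqrt(len(pi))  # serial dependence makes this generous
        assert abs(pi.mean() - 0.5) < max(3 * se, 0.05)
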