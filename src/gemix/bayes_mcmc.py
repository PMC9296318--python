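"""Posterior sampling for the labeled censored GE mixture by conditional
draws with self-normalized importance weights, plus a data-augmentation
sampler for unlabeled data.

With known allocations the posterior kernel factorizes into

    pi1      ~ Beta(k1+m1+mu1, k2+m2+tau1)                      (exact)
    theta_u  ~ Gamma(m_u+mu3u, tau3u + sum_obs x_ui)            (proposal)
    lam_u | theta_u ~ Gamma(m_u+mu2u, tau2u - sum_obs log(1-e^{-theta_u x_ui}))

times a residual factor coupling (lam_u, theta_u) through the censored
records and the (lam-1)-power of the density.  Draws are independent across
iterations; posterior expectations are therefore self-normalized
importance-sampling averages.  The log-weight of a draw is the log posterior
kernel minus the log proposal density, which works out to

    log w = sum_u [ lam_u * C_u(theta_u) - A_u(theta_u)
                    - (m_u + mu2u) * log kappa1u(theta_u) ]  + const

with A_u = sum_obs log(1-e^{-theta_u x}), C_u = sum_cens log(1-e^{-theta_u L})
and kappa1u = tau2u - A_u.  The last term is the theta-dependent normalizer
of the lam proposal; without it the weighted average does not target the
posterior.

SELF estimates are weighted means of the draws; ELF estimates are
reciprocals of weighted means of reciprocals (so ELF <= SELF coordinate-wise
by Jensen's inequality).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import logsumexp

from .ge_core import (
    CensoredDataset,
    Hyperparams,
    MixtureParams,
    ge_cdf,
    ge_pdf,
    log1mexp,
)

__all__ = [
    "PosteriorDraws",
    "sample_posterior",
    "sample_posterior_augmented",
    "estimate",
    "effective_sample_size",
]


@dataclass
class PosteriorDraws:
    """Weighted posterior sample; draw columns ordered
    (lam1, theta1, lam2, theta2, pi1)."""

    draws: np.ndarray
    log_weights: np.ndarray
    m0: int = 0
    labels_trace: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.draws.ndim != 2 or self.draws.shape[1] != 5:
            raise ValueError("draws must be (m1, 5)")
        if self.log_weights.shape != (self.draws.shape[0],):
            raise ValueError("one log-weight per draw required")
        if not np.all(np.isfinite(self.log_weights)):
            raise ValueError("log-weights must be finite")
        if self.draws.shape[0] < 1:
            raise ValueError("need at least one retained draw")

    @property
    def m1(self) -> int:
        return self.draws.shape[0]

    @property
    def normalized_weights(self) -> np.ndarray:
        lw = self.log_weights - logsumexp(self.log_weights)
        return np.exp(lw)

    @property
    def ess(self) -> float:
        w = self.normalized_weights
        return float(1.0 / np.sum(w ** 2))

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(
            self.draws, columns=["lam1", "theta1", "lam2", "theta2", "pi1"]
        )
        df["log_weight"] = self.log_weights
        return df


def effective_sample_size(draws: PosteriorDraws) -> float:
    return draws.ess


def _component_sums(data: CensoredDataset, u: int, h: Hyperparams):
    x = data.observed_values(u)
    L = data.censored_limits(u)
    return {
        "x": x,
        "L": L,
        "m": x.size,
        "k": L.size,
        "gamma3": x.size + h.mu2[u - 1],
        "gamma4": x.size + h.mu3[u - 1],
        "kappa2": h.tau3[u - 1] + float(x.sum()),
        "tau2": h.tau2[u - 1],
    }


def _draw_component(cs, m, rng):
    """Vectorized conditional draws and log-weight pieces for one component.

    Returns (theta draws, lam draws, per-draw log-weight contribution)."""
    if cs["kappa2"] <= 0:
        raise ValueError("theta proposal rate must be positive (tau3 + sum x)")
    theta = rng.gamma(cs["gamma4"], 1.0 / cs["kappa2"], size=m)
    if cs["m"]:
        A = log1mexp(np.outer(theta, cs["x"])).sum(axis=1)
    else:
        A = np.zeros(m)
    kappa1 = cs["tau2"] - A
    bad = kappa1 <= 0
    if np.any(bad):
        # cannot form the lam proposal for these draws; reject and report
        warnings.warn(
            f"rejected {int(bad.sum())} draws with non-positive lam proposal rate",
            RuntimeWarning,
        )
        kappa1 = np.where(bad, np.nan, kappa1)
    lam = rng.gamma(cs["gamma3"], 1.0 / np.where(np.isnan(kappa1), 1.0, kappa1), size=m)
    lam = np.where(np.isnan(kappa1), np.nan, lam)
    if cs["k"]:
        C = log1mexp(np.outer(theta, cs["L"])).sum(axis=1)
    else:
        C = np.zeros(m)
    logw = lam * C - A - cs["gamma3"] * np.log(kappa1)
    return theta, lam, logw


def sample_posterior(
    data: CensoredDataset,
    h: Hyperparams,
    m: int = 11000,
    m0: int = 1000,
    seed=None,
) -> PosteriorDraws:
    """Importance-weighted posterior sample for a fully labeled dataset.

    ``m`` total draws are generated and the first ``m0`` discarded (a no-op
    thinning retained for procedural fidelity: the draws are i.i.d., so the
    discard only shortens the sample).  Draws whose lam-proposal rate is
    non-positive are rejected (possible only with a zero Gamma prior rate on
    lam and no observed records).
    """
    if not data.fully_labeled:
        raise ValueError("sample_posterior requires labeled records; see "
                         "sample_posterior_augmented for unlabeled data")
    if not 0 <= m0 < m:
        raise ValueError("need 0 <= m0 < m")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    gamma1 = data.k1 + data.m1 + h.mu1
    gamma2 = data.k2 + data.m2 + h.tau1
    pi1 = rng.beta(gamma1, gamma2, size=m)

    cols = {}
    logw = np.zeros(m)
    for u in (1, 2):
        cs = _component_sums(data, u, h)
        theta, lam, lw = _draw_component(cs, m, rng)
        cols[u] = (lam, theta)
        logw += lw

    draws = np.column_stack([cols[1][0], cols[1][1], cols[2][0], cols[2][1], pi1])
    keep = slice(m0, None)
    draws = draws[keep]
    logw = logw[keep]
    ok = np.all(np.isfinite(draws), axis=1) & np.isfinite(logw)
    if not np.all(ok):
        draws, logw = draws[ok], logw[ok]
    return PosteriorDraws(draws=draws, log_weights=logw, m0=m0)


def estimate(draws: PosteriorDraws, loss: str = "self") -> MixtureParams:
    """Self-normalized importance-sampling Bayes estimate.

    SELF: weighted mean of the draws.  ELF: reciprocal of the weighted mean
    of reciprocals.  Weights are normalized in log space; an effective sample
    size below 10 triggers a RuntimeWarning.
    """
    loss = loss.lower()
    if loss not in ("self", "elf"):
        raise ValueError("loss must be 'self' or 'elf'")
    w = draws.normalized_weights
    if draws.ess < 10:
        warnings.warn(
            f"effective sample size {draws.ess:.1f} < 10; estimates unstable",
            RuntimeWarning,
        )
    if loss == "self":
        est = w @ draws.draws
    else:
        est = 1.0 / (w @ (1.0 / draws.draws))
    return MixtureParams.from_array(est)


def _responsibilities_at(data: CensoredDataset, omega: MixtureParams) -> np.ndarray:
    obs = ~data.censored
    p1 = np.empty(data.n)
    p2 = np.empty(data.n)
    if obs.any():
        p1[obs] = omega.pi1 * ge_pdf(data.values[obs], omega.comp1)
        p2[obs] = (1 - omega.pi1) * ge_pdf(data.values[obs], omega.comp2)
    if (~obs).any():
        p1[~obs] = omega.pi1 * ge_cdf(data.limits[~obs], omega.comp1)
        p2[~obs] = (1 - omega.pi1) * ge_cdf(data.limits[~obs], omega.comp2)
    tot = p1 + p2
    bad = tot <= 0
    if bad.any():
        p1[bad] = 0.5
        tot[bad] = 1.0
    return p1 / tot


def sample_posterior_augmented(
    data: CensoredDataset,
    h: Hyperparams,
    m: int = 11000,
    m0: int = 1000,
    seed=None,
    init: Optional[MixtureParams] = None,
) -> PosteriorDraws:
    """Data-augmentation sampler for unlabeled data.

    Each sweep imputes component labels from the current parameter draw
    (density for observed records, CDF-at-limit for censored ones), then
    performs one labeled conditional draw given that allocation.  The first
    ``m0`` sweeps are discarded as burn-in (here genuinely needed: the label
    chain is Markov).  The retained label allocations are stored in
    ``labels_trace``.
    """
    if not 0 <= m0 < m:
        raise ValueError("need 0 <= m0 < m")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if init is None:
        # prior-mean start (falls back to neutral values under flat priors)
        init = MixtureParams.from_values(
            max(h.mu2[0] / max(h.tau2[0], 1e-12), 1.0) if h.tau2[0] > 0 else 1.0,
            max(h.mu3[0] / max(h.tau3[0], 1e-12), 1.0) if h.tau3[0] > 0 else 1.0,
            max(h.mu2[1] / max(h.tau2[1], 1e-12), 1.0) if h.tau2[1] > 0 else 1.0,
            max(h.mu3[1] / max(h.tau3[1], 1e-12), 1.0) if h.tau3[1] > 0 else 1.0,
            h.mu1 / (h.mu1 + h.tau1),
        )
    omega = init
    draws = np.empty((m, 5))
    logw = np.empty(m)
    labels_trace = np.empty((m, data.n), dtype=np.int8)
    for z in range(m):
        r1 = _responsibilities_at(data, omega)
        labels = np.where(rng.uniform(size=data.n) <= r1, 1, 2)
        labeled = data.with_labels(labels)
        one = sample_posterior(labeled, h, m=1, m0=0, seed=rng)
        draws[z] = one.draws[0]
        logw[z] = one.log_weights[0]
        labels_trace[z] = labels
        omega = MixtureParams.from_array(draws[z])
    return PosteriorDraws(
        draws=draws[m0:],
        log_weights=logw[m0:],
        m0=m0,
        labels_trace=labels_trace[m0:],
    )
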