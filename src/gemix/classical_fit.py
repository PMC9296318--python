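"""Maximum-likelihood and EM estimation of left-censored GE mixtures.

Two fitting regimes:

* **Labeled** (component allocations known, e.g. recorded at generation time
  or implied by distinct detection limits): the likelihood factorizes, the
  mixing weight has the closed form (k1+m1)/n, and each component reduces to
  a one-dimensional profile optimization in theta, since the score in lam
  solves to lam(theta) = -m / (A(theta) + C(theta)).

* **Unlabeled**: EM with responsibilities using the component density for
  observed records and the component CDF at the detection limit for censored
  records (left censoring: the record is known only to lie below its limit).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional

import numpy as np
from scipy.optimize import minimize_scalar

from ._derivs import component_derivs, loglik_gradient, loglik_hessian
from .ge_core import (
    CensoredDataset,
    GEParams,
    MixtureParams,
    ge_cdf,
    ge_pdf,
    loglik_labeled,
    loglik_mixture,
)

__all__ = [
    "FitResult",
    "Responsibilities",
    "FitError",
    "DegenerateComponentError",
    "mle_labeled",
    "em_fit",
    "fit_k_gem",
    "KComponentFit",
]


class FitError(RuntimeError):
    """Estimation failed (non-convergence or ill-posed data)."""


class DegenerateComponentError(FitError):
    """A mixture component collapsed (weight or observed mass near zero)."""


@dataclass
class FitResult:
    omega_hat: MixtureParams
    loglik: float
    method: str
    converged: bool
    n_iter: int
    info_matrix: Optional[np.ndarray] = None  # inverse observed information

    def __post_init__(self):
        if self.info_matrix is not None:
            if not np.allclose(self.info_matrix, self.info_matrix.T, atol=1e-8):
                raise ValueError("information matrix must be symmetric")


@dataclass
class Responsibilities:
    """Posterior component-membership probabilities, one row per record."""

    matrix: np.ndarray

    def __post_init__(self):
        if np.any(self.matrix < -1e-12) or not np.allclose(
            self.matrix.sum(axis=1), 1.0, atol=1e-8
        ):
            raise ValueError("responsibility rows must be probabilities summing to 1")


# ---------------------------------------------------------------------------
# single-component censored GE fit (weighted)
# ---------------------------------------------------------------------------


def _fit_component(x_obs, limits, w_obs=None, w_cens=None, polish=True):
    """Maximize the (optionally weighted) censored single-GE log-likelihood.

    Profiles out lam: for fixed theta the lam-score gives
    lam(theta) = -m / (A(theta) + C(theta)); the remaining 1-D problem in
    log(theta) is solved by bounded scalar minimization and polished with a
    couple of Newton steps on the full 2-D system.
    Returns (lam_hat, theta_hat).
    """
    x_obs = np.asarray(x_obs, dtype=float)
    limits = np.asarray(limits, dtype=float)
    w_obs = np.ones_like(x_obs) if w_obs is None else np.asarray(w_obs, dtype=float)
    w_cens = np.ones_like(limits) if w_cens is None else np.asarray(w_cens, dtype=float)

    m = float(w_obs.sum())
    if m <= 1e-8:
        raise DegenerateComponentError("component has (essentially) no observed mass")
    S = float((w_obs * x_obs).sum())
    if S <= 0:
        raise DegenerateComponentError("component observed values sum to zero")

    from .ge_core import log1mexp

    def profile_neg(log_theta):
        theta = math.exp(log_theta)
        A = float(w_obs @ log1mexp(theta * x_obs)) if x_obs.size else 0.0
        C = float(w_cens @ log1mexp(theta * limits)) if limits.size else 0.0
        denom = A + C
        if denom >= -1e-290:  # every log(1-e^{-theta x}) underflowed: theta too large
            return np.inf
        lam = -m / denom
        ll = m * (math.log(lam) + math.log(theta)) + (lam - 1.0) * A - theta * S + lam * C
        return -ll

    lt0 = math.log(m / S)
    res = minimize_scalar(
        profile_neg,
        bounds=(lt0 - 8.0, lt0 + 8.0),
        method="bounded",
        options={"xatol": 1e-10},
    )
    theta = math.exp(res.x)
    A = float(w_obs @ log1mexp(theta * x_obs)) if x_obs.size else 0.0
    C = float(w_cens @ log1mexp(theta * limits)) if limits.size else 0.0
    lam = -m / (A + C)

    if not (1e-6 < lam < 1e6 and 1e-6 < theta < 1e6):
        raise DegenerateComponentError(
            f"component estimate ran away (lam={lam:.3g}, theta={theta:.3g})"
        )
    if polish:
        # Newton refinement on (lam, theta); safeguarded by halving
        for _ in range(50):
            d = component_derivs(lam, theta, x_obs, limits, w_obs, w_cens)
            g = d["grad"]
            if np.max(np.abs(g)) < 1e-9:
                break
            try:
                step = np.linalg.solve(d["hess"], -g)
            except np.linalg.LinAlgError:
                break
            scale = 1.0
            while scale > 1e-4 and (lam + scale * step[0] <= 0 or theta + scale * step[1] <= 0):
                scale *= 0.5
            new_lam, new_theta = lam + scale * step[0], theta + scale * step[1]
            if new_lam <= 0 or new_theta <= 0:
                break
            lam, theta = new_lam, new_theta
    return lam, theta


# ---------------------------------------------------------------------------
# labeled MLE
# ---------------------------------------------------------------------------


def mle_labeled(data: CensoredDataset, compute_info: bool = True) -> FitResult:
    """MLE of the 2-component GE mixture from a fully labeled censored sample.

    pi1_hat = (k1+m1)/n exactly; (lam_u, theta_u) by profile optimization per
    component.  ``info_matrix`` holds the inverse observed information
    (negative-Hessian inverse) at the optimum, used downstream by the Lindley
    approximation.
    """
    if not data.fully_labeled:
        raise FitError("mle_labeled requires labeled records")
    n1 = data.k1 + data.m1
    n2 = data.k2 + data.m2
    if n1 == 0 or n2 == 0:
        raise DegenerateComponentError(
            f"component {1 if n1 == 0 else 2} has no records; pi1 MLE is on the boundary"
        )
    pi1 = n1 / data.n
    comps = []
    for u in (1, 2):
        if data.count_observed(u) == 0:
            raise DegenerateComponentError(f"component {u} has no observed records")
        lam, theta = _fit_component(data.observed_values(u), data.censored_limits(u))
        comps.append(GEParams(lam, theta))
    omega = MixtureParams(comps[0], comps[1], pi1)

    grad = loglik_gradient(data, omega)
    converged = bool(np.linalg.norm(grad) < 1e-6 * max(1.0, data.n))
    info = None
    if compute_info:
        H = loglik_hessian(data, omega)
        try:
            info = np.linalg.inv(-H)
        except np.linalg.LinAlgError:
            raise FitError("observed information is singular; need more data per component")
        info = 0.5 * (info + info.T)
    return FitResult(
        omega_hat=omega,
        loglik=loglik_labeled(data, omega),
        method="mle",
        converged=converged,
        n_iter=1,
        info_matrix=info,
    )


# ---------------------------------------------------------------------------
# EM for unlabeled data
# ---------------------------------------------------------------------------


def _responsibility_matrix(data: CensoredDataset, weights, comps) -> np.ndarray:
    """E-step: posterior membership probabilities.  Observed records use the
    component density, censored records the component CDF at their limit."""
    K = len(comps)
    lik = np.empty((data.n, K))
    obs = ~data.censored
    for r, (w, p) in enumerate(zip(weights, comps)):
        col = np.empty(data.n)
        if obs.any():
            col[obs] = w * ge_pdf(data.values[obs], p)
        if (~obs).any():
            col[~obs] = w * ge_cdf(data.limits[~obs], p)
        lik[:, r] = col
    tot = lik.sum(axis=1, keepdims=True)
    bad = tot[:, 0] <= 0
    if bad.any():
        # all components assign zero mass; split evenly to keep EM moving
        lik[bad] = 1.0
        tot[bad] = float(K)
    return lik / tot


def _default_init(data: CensoredDataset, k: int = 2):
    """Moment-style start: split records at value/limit quantiles into k
    groups; lam starts at 1 and theta at the reciprocal sub-sample mean."""
    proxy = np.where(data.censored, data.limits, data.values)
    order = np.argsort(proxy)
    groups = np.array_split(order, k)
    comps = []
    for g in groups:
        vals = data.values[g][~data.censored[g]]
        mean = float(vals.mean()) if vals.size else float(np.nanmean(proxy))
        comps.append(GEParams(1.0, 1.0 / max(mean, 1e-12)))
    weights = [1.0 / k] * k
    return weights, comps


def em_fit(
    data: CensoredDataset,
    init: Optional[MixtureParams] = None,
    tol: float = 1e-6,
    max_iter: int = 500,
):
    """EM fit of the 2-component GE mixture to unlabeled censored data.

    Returns ``(FitResult, Responsibilities)``.  The observed-data
    log-likelihood is guaranteed nondecreasing across iterations; the
    trajectory is exposed as ``FitResult.loglik_trace`` for auditing.
    """
    if init is None:
        weights, comps = _default_init(data, 2)
        pi1 = weights[0]
    else:
        comps = [init.comp1, init.comp2]
        pi1 = init.pi1

    obs = ~data.censored
    x_obs = data.values[obs]
    limits = data.limits[~obs]
    trace: List[float] = []
    prev = np.array([comps[0].lam, comps[0].theta, comps[1].lam, comps[1].theta, pi1])
    converged = False
    it = 0
    resp = None
    for it in range(1, max_iter + 1):
        resp = _responsibility_matrix(data, [pi1, 1.0 - pi1], comps)
        new_pi = float(resp[:, 0].mean())
        if not (1e-10 < new_pi < 1 - 1e-10):
            raise DegenerateComponentError(
                f"component {1 if new_pi <= 1e-10 else 2} weight collapsed during EM"
            )
        new_comps = []
        for r in range(2):
            w = resp[:, r]
            lam, theta = _fit_component(x_obs, limits, w[obs], w[~obs])
            new_comps.append(GEParams(lam, theta))
        pi1, comps = new_pi, new_comps
        omega = MixtureParams(comps[0], comps[1], pi1)
        trace.append(loglik_mixture(data, omega))
        cur = omega.as_array()
        if np.max(np.abs(cur - prev)) < tol:
            converged = True
            prev = cur
            break
        prev = cur

    omega = MixtureParams(comps[0], comps[1], pi1)
    result = FitResult(
        omega_hat=omega,
        loglik=trace[-1],
        method="em",
        converged=converged,
        n_iter=it,
    )
    result.loglik_trace = np.array(trace)
    return result, Responsibilities(matrix=resp)


# ---------------------------------------------------------------------------
# k-component generalization
# ---------------------------------------------------------------------------


@dataclass
class KComponentFit:
    """EM fit of a k-component GE mixture; 3k-1 free parameters."""

    weights: np.ndarray
    comps: List[GEParams]
    loglik: float
    converged: bool
    n_iter: int

    @property
    def k(self) -> int:
        return len(self.comps)

    @property
    def n_params(self) -> int:
        return 3 * self.k - 1

    def as_mixture(self) -> MixtureParams:
        if self.k != 2:
            raise ValueError("as_mixture is defined for k=2 only")
        return MixtureParams(self.comps[0], self.comps[1], float(self.weights[0]))


def _k_loglik(data: CensoredDataset, weights, comps) -> float:
    obs = ~data.censored
    ll = 0.0
    if obs.any():
        dens = sum(w * ge_pdf(data.values[obs], p) for w, p in zip(weights, comps))
        ll += float(np.sum(np.log(dens)))
    if (~obs).any():
        prob = sum(w * ge_cdf(data.limits[~obs], p) for w, p in zip(weights, comps))
        ll += float(np.sum(np.log(prob)))
    return ll


def fit_k_gem(
    data: CensoredDataset,
    k: int,
    tol: float = 1e-6,
    max_iter: int = 500,
    n_starts: int = 1,
    seed: Optional[int] = None,
) -> KComponentFit:
    """Fit a k-component GE mixture by EM (k=1 is a plain censored GE MLE).

    With ``n_starts > 1`` additional randomized initializations are tried and
    the best converged log-likelihood kept, guarding against local optima in
    the higher-k fits used for component selection.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    obs = ~data.censored
    x_obs = data.values[obs]
    limits = data.limits[~obs]
    if k == 1:
        lam, theta = _fit_component(x_obs, limits)
        comps = [GEParams(lam, theta)]
        return KComponentFit(
            weights=np.array([1.0]),
            comps=comps,
            loglik=_k_loglik(data, [1.0], comps),
            converged=True,
            n_iter=1,
        )

    rng = np.random.default_rng(seed)
    best = None
    for start in range(n_starts):
        weights, comps = _default_init(data, k)
        if start > 0:
            # jitter the moment start to explore other basins
            comps = [
                GEParams(p.lam * rng.lognormal(0, 0.5), p.theta * rng.lognormal(0, 0.5))
                for p in comps
            ]
        weights = np.asarray(weights, dtype=float)
        converged = False
        it = 0
        try:
            for it in range(1, max_iter + 1):
                resp = _responsibility_matrix(data, weights, comps)
                new_w = resp.mean(axis=0)
                if np.any(new_w < 1e-10):
                    raise DegenerateComponentError(
                        f"component {int(np.argmin(new_w)) + 1} weight collapsed"
                    )
                new_comps = []
                for r in range(k):
                    w = resp[:, r]
                    lam, theta = _fit_component(x_obs, limits, w[obs], w[~obs])
                    new_comps.append(GEParams(lam, theta))
                delta = max(
                    np.max(np.abs(new_w - weights)),
                    max(
                        max(abs(a.lam - b.lam), abs(a.theta - b.theta))
                        for a, b in zip(new_comps, comps)
                    ),
                )
                weights, comps = new_w, new_comps
                if delta < tol:
                    converged = True
                    break
        except DegenerateComponentError:
            if n_starts == 1:
                raise
            continue
        cand = KComponentFit(
            weights=weights,
            comps=comps,
            loglik=_k_loglik(data, weights, comps),
            converged=converged,
            n_iter=it,
        )
        if best is None or cand.loglik > best.loglik:
            best = cand
    if best is None:
        raise DegenerateComponentError(f"all {n_starts} EM starts collapsed for k={k}")
    return best
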