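"""Analytic derivatives of the labeled left-censored GE mixture
log-likelihood, up to third order.

The labeled log-likelihood separates into a term in pi1 alone plus one term
per component in (lam_u, theta_u), so the gradient/Hessian/third-derivative
tensor are block structured: a 1-parameter pi block and two independent
2-parameter component blocks.  All cross-block derivatives vanish.

Building block: g(theta; x) = log(1 - e^{-theta x}) and its theta-derivatives

    g'   =  x e^{-t} / (1 - e^{-t})
    g''  = -x^2 e^{-t} / (1 - e^{-t})^2
    g''' =  x^3 e^{-t} (1 + e^{-t}) / (1 - e^{-t})^3          (t = theta x)

evaluated in log space to stay finite for both tiny and large ``theta x``.
"""

from __future__ import annotations

import math

import numpy as np

from .ge_core import log1mexp

_ORDER = ("lam1", "theta1", "lam2", "theta2", "pi1")


def _g_derivs(theta: float, x: np.ndarray):
    """Return (g, g', g'', g''') of log(1-e^{-theta x}) wrt theta, per x."""
    t = theta * x
    lm = log1mexp(t)
    e = np.exp(-t)
    q1 = np.exp(-t - lm)          # e^{-t}/(1-e^{-t})
    q2 = np.exp(-t - 2.0 * lm)    # e^{-t}/(1-e^{-t})^2
    q3 = np.exp(-t - 3.0 * lm)    # e^{-t}/(1-e^{-t})^3
    return lm, x * q1, -(x ** 2) * q2, (x ** 3) * q3 * (1.0 + e)


def component_derivs(lam, theta, x_obs, limits, w_obs=None, w_cens=None):
    """Value, gradient, Hessian and third derivatives of the per-component
    censored GE log-likelihood

        l(lam, theta) = m log lam + m log theta + (lam-1) A(theta)
                        - theta S + lam C(theta)

    with A = sum_obs w g(theta; x), C = sum_cens w g(theta; L),
    m = sum_obs w, S = sum_obs w x.  Unit weights recover the ordinary
    labeled likelihood; fractional weights give the EM M-step objective.

    Returns dict with keys 'value', 'grad' (2,), 'hess' (2,2) and 'third'
    (dict lll/llt/ltt/ttt); parameter order (lam, theta).
    """
    x_obs = np.asarray(x_obs, dtype=float)
    limits = np.asarray(limits, dtype=float)
    w_obs = np.ones_like(x_obs) if w_obs is None else np.asarray(w_obs, dtype=float)
    w_cens = np.ones_like(limits) if w_cens is None else np.asarray(w_cens, dtype=float)

    m = float(w_obs.sum())
    S = float((w_obs * x_obs).sum())
    A = A1 = A2 = A3 = 0.0
    if x_obs.size:
        g0, g1, g2, g3 = _g_derivs(theta, x_obs)
        A = float(w_obs @ g0)
        A1 = float(w_obs @ g1)
        A2 = float(w_obs @ g2)
        A3 = float(w_obs @ g3)
    C = C1 = C2 = C3 = 0.0
    if limits.size:
        h0, h1, h2, h3 = _g_derivs(theta, limits)
        C = float(w_cens @ h0)
        C1 = float(w_cens @ h1)
        C2 = float(w_cens @ h2)
        C3 = float(w_cens @ h3)

    value = m * (math.log(lam) + math.log(theta)) + (lam - 1.0) * A - theta * S + lam * C
    grad = np.array(
        [m / lam + A + C, m / theta + (lam - 1.0) * A1 - S + lam * C1]
    )
    hess = np.array(
        [
            [-m / lam ** 2, A1 + C1],
            [A1 + C1, -m / theta ** 2 + (lam - 1.0) * A2 + lam * C2],
        ]
    )
    third = {
        "lll": 2.0 * m / lam ** 3,
        "llt": 0.0,
        "ltt": A2 + C2,
        "ttt": 2.0 * m / theta ** 3 + (lam - 1.0) * A3 + lam * C3,
    }
    return {
        "value": value,
        "grad": grad,
        "hess": hess,
        "third": third,
        "sums": {"m": m, "S": S, "A": A, "C": C},
    }


def pi_derivs(pi1, a, b):
    """Derivatives of a log(pi1) + b log(1-pi1): the mixing-weight block
    (a = k1+m1, b = k2+m2)."""
    value = a * math.log(pi1) + b * math.log1p(-pi1)
    g = a / pi1 - b / (1.0 - pi1)
    h = -a / pi1 ** 2 - b / (1.0 - pi1) ** 2
    t = 2.0 * a / pi1 ** 3 - 2.0 * b / (1.0 - pi1) ** 3
    return {"value": value, "grad": g, "hess": h, "third": t}


def loglik_hessian(data, omega):
    """5x5 Hessian of the labeled log-likelihood, order
    (lam1, theta1, lam2, theta2, pi1)."""
    H = np.zeros((5, 5))
    for u, sl in ((1, slice(0, 2)), (2, slice(2, 4))):
        p = omega.component(u)
        d = component_derivs(p.lam, p.theta, data.observed_values(u), data.censored_limits(u))
        H[sl, sl] = d["hess"]
    a = data.k1 + data.m1
    b = data.k2 + data.m2
    H[4, 4] = pi_derivs(omega.pi1, a, b)["hess"]
    return H


def loglik_gradient(data, omega):
    """5-vector gradient of the labeled log-likelihood (same ordering)."""
    g = np.zeros(5)
    for u, sl in ((1, slice(0, 2)), (2, slice(2, 4))):
        p = omega.component(u)
        d = component_derivs(p.lam, p.theta, data.observed_values(u), data.censored_limits(u))
        g[sl] = d["grad"]
    g[4] = pi_derivs(omega.pi1, data.k1 + data.m1, data.k2 + data.m2)["grad"]
    return g


def loglik_third_tensor(data, omega):
    """5x5x5 symmetric tensor of third derivatives of the labeled
    log-likelihood.  Only within-block entries are nonzero."""
    T = np.zeros((5, 5, 5))
    for u, off in ((1, 0), (2, 2)):
        p = omega.component(u)
        d = component_derivs(p.lam, p.theta, data.observed_values(u), data.censored_limits(u))
        t = d["third"]
        il, it = off, off + 1
        T[il, il, il] = t["lll"]
        for perm in ((il, il, it), (il, it, il), (it, il, il)):
            T[perm] = t["llt"]
        for perm in ((il, it, it), (it, il, it), (it, it, il)):
            T[perm] = t["ltt"]
        T[it, it, it] = t["ttt"]
    T[4, 4, 4] = pi_derivs(omega.pi1, data.k1 + data.m1, data.k2 + data.m2)["third"]
    return T
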