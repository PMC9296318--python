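"""Lindley's approximation to posterior expectations for the censored GE
mixture.

For a posterior proportional to exp(l(O) + H(O)) with log-likelihood l and
log-prior H, Lindley's second-order expansion around the MLE gives

    E[W | x] ~= W(O^) + grad(W)' S D  +  1/2 tr(hess(W) S)
                + 1/2 grad(W)' S q,        q_k = sum_ij T_ijk S_ij

where S is the inverse observed information (-hessian of l)^{-1}, D the
log-prior gradient and T the third-derivative tensor of l, all evaluated at
the MLE.  The squared-error-loss (SELF) estimate of a coordinate applies the
expansion to W = O_i; the entropy-loss (ELF) estimate applies it to
W = 1/O_i and inverts.  The correction terms are O(1/n), so both estimates
collapse onto the MLE as the sample grows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from ._derivs import loglik_hessian, loglik_third_tensor
from .classical_fit import FitError, FitResult, mle_labeled
from .ge_core import CensoredDataset, Hyperparams, MixtureParams

__all__ = [
    "LindleyWorkspace",
    "build_workspace",
    "lindley_correction",
    "lindley_estimate",
    "prior_gradient",
    "third_tensor_fd",
]


@dataclass
class LindleyWorkspace:
    mle: MixtureParams
    omega_inv: np.ndarray      # S: inverse observed information, 5x5
    third_derivs: np.ndarray   # T: symmetric third-derivative tensor, 5x5x5
    prior_grad: np.ndarray     # D: gradient of the log prior, 5-vector

    def __post_init__(self):
        if not np.allclose(self.omega_inv, self.omega_inv.T, atol=1e-8):
            raise ValueError("omega_inv must be symmetric")
        T = self.third_derivs
        if not (
            np.allclose(T, np.transpose(T, (1, 0, 2)), atol=1e-8)
            and np.allclose(T, np.transpose(T, (0, 2, 1)), atol=1e-8)
        ):
            raise ValueError("third-derivative tensor must be index-symmetric")


def prior_gradient(omega: MixtureParams, h: Hyperparams) -> np.ndarray:
    """Gradient of the log prior; order (lam1, theta1, lam2, theta2, pi1).

    Gamma coordinates contribute (mu-1)/value - tau; the Beta coordinate
    contributes (mu1-1)/pi1 - (tau1-1)/(1-pi1).  Flat priors give zero."""
    D = np.zeros(5)
    for u, (il, it) in ((1, (0, 1)), (2, (2, 3))):
        p = omega.component(u)
        D[il] = (h.mu2[u - 1] - 1.0) / p.lam - h.tau2[u - 1]
        D[it] = (h.mu3[u - 1] - 1.0) / p.theta - h.tau3[u - 1]
    D[4] = (h.mu1 - 1.0) / omega.pi1 - (h.tau1 - 1.0) / (1.0 - omega.pi1)
    return D


def third_tensor_fd(data: CensoredDataset, omega: MixtureParams, rel_step: float = 1e-4) -> np.ndarray:
    """Third-derivative tensor by Richardson-extrapolated central differences
    of the analytic gradient.  Independent cross-check of the closed-form
    tensor; symmetrized over the first two indices."""
    x0 = omega.as_array()

    def third_fd(step_scale):
        T = np.zeros((5, 5, 5))
        for k in range(5):
            hk = rel_step * step_scale * max(abs(x0[k]), 1e-2)
            e = np.zeros(5)
            e[k] = hk
            Hp = _hess_at(data, x0 + e)
            Hm = _hess_at(data, x0 - e)
            T[:, :, k] = (Hp - Hm) / (2.0 * hk)
        return T

    T1 = third_fd(1.0)
    T2 = third_fd(2.0)
    T = (4.0 * T1 - T2) / 3.0  # Richardson: cancel the O(h^2) error term
    return (T + np.transpose(T, (1, 0, 2)) + np.transpose(T, (0, 2, 1))
            + np.transpose(T, (2, 1, 0)) + np.transpose(T, (1, 2, 0))
            + np.transpose(T, (2, 0, 1))) / 6.0


def _hess_at(data, x):
    return loglik_hessian(data, MixtureParams.from_array(x))


def build_workspace(
    data: CensoredDataset,
    h: Hyperparams,
    mle: Optional[FitResult] = None,
    ridge: float = 0.0,
) -> LindleyWorkspace:
    """Assemble everything Lindley's expansion needs at the MLE.

    The Hessian and the third-derivative tensor are closed-form (the labeled
    likelihood is block separable); ``third_tensor_fd`` provides an
    independent numerical check.  A singular information matrix raises with
    advice; passing ``ridge > 0`` adds that multiple of the identity to the
    negative Hessian before inversion as an explicitly-reported fallback.
    """
    if mle is None:
        mle = mle_labeled(data)
    omega = mle.omega_hat
    H = loglik_hessian(data, omega)
    neg = -H + ridge * np.eye(5)
    cond = np.linalg.cond(neg)
    if not np.isfinite(cond) or cond > 1e12:
        raise FitError(
            "observed information matrix is (near-)singular; collect more "
            "observed records per component or pass ridge > 0 explicitly"
        )
    S = np.linalg.inv(neg)
    S = 0.5 * (S + S.T)
    return LindleyWorkspace(
        mle=omega,
        omega_inv=S,
        third_derivs=loglik_third_tensor(data, omega),
        prior_grad=prior_gradient(omega, h),
    )


def lindley_correction(
    psi_grad: np.ndarray,
    psi_hess: Optional[np.ndarray],
    ws: LindleyWorkspace,
) -> float:
    """Generic Lindley correction for a smooth scalar W(Omega):

        grad(W)' S D + 1/2 tr(hess(W) S) + 1/2 grad(W)' S q

    with q the contraction of the third-derivative tensor with S.  A constant
    W (zero derivatives) gets zero correction.
    """
    S = ws.omega_inv
    corr = float(psi_grad @ S @ ws.prior_grad)
    if psi_hess is not None:
        corr += 0.5 * float(np.einsum("ij,ij->", psi_hess, S))
    q = np.einsum("ij,ijk->k", S, ws.third_derivs)
    corr += 0.5 * float(psi_grad @ S @ q)
    return corr


def lindley_estimate(ws: LindleyWorkspace, loss: str = "self") -> MixtureParams:
    """SELF or ELF Bayes estimate of all five parameters.

    SELF applies the expansion to each coordinate W = O_i.  ELF applies it to
    W = 1/O_i (psi_i = -O_i^{-2}, psi_ii = 2 O_i^{-3}) and returns the
    reciprocal of the approximated posterior mean of 1/O_i.
    """
    loss = loss.lower()
    if loss not in ("self", "elf"):
        raise ValueError("loss must be 'self' or 'elf'")
    x = ws.mle.as_array()
    out = np.empty(5)
    for i in range(5):
        e = np.zeros(5)
        if loss == "self":
            e[i] = 1.0
            out[i] = x[i] + lindley_correction(e, None, ws)
        else:
            e[i] = -x[i] ** -2
            Hw = np.zeros((5, 5))
            Hw[i, i] = 2.0 * x[i] ** -3
            w_post = x[i] ** -1 + lindley_correction(e, Hw, ws)
            if w_post <= 0:
                raise FitError(
                    f"ELF Lindley estimate for coordinate {i} passed through zero"
                )
            out[i] = 1.0 / w_post
    if not (0.0 < out[4] < 1.0) or np.any(out[:4] <= 0):
        raise FitError("Lindley correction left the parameter domain (sample too small)")
    return MixtureParams.from_array(out)
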