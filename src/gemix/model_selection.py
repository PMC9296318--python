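"""Goodness of fit and component-count selection for censored GE mixtures:
AIC/BIC, a Kolmogorov-Smirnov statistic usable with nondetects, and nested
likelihood-ratio tests over k-component fits.

The KS construction substitutes each nondetect by its detection limit (the
standard simple treatment in nondetect statistics) before comparing the
empirical CDF with the fitted model; a detected-only variant is available
behind a flag.  The likelihood-ratio p-values for k vs k+1 components use
the chi-square reference with 3 extra parameters per component; mixture-
order testing is non-regular (the null lies on the parameter-space
boundary), so every LRT result carries an explicit approximation caveat.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy import stats

from .classical_fit import FitError, KComponentFit, fit_k_gem
from .ge_core import CensoredDataset, MixtureParams, ge_cdf, mixture_cdf

__all__ = [
    "FitReport",
    "LRTResult",
    "information_criteria",
    "ks_censored",
    "lrt_components",
    "make_report",
    "select_components",
    "allocate_by_limit",
    "mle_partial",
    "detected_subset",
    "fit_detected_only",
]


@dataclass
class FitReport:
    """One row of a model-comparison table."""

    method: str
    omega_hat: MixtureParams
    p: int
    loglik: float
    aic: float
    bic: float
    ks_stat: float
    ks_pvalue: float

    def __post_init__(self):
        aic, bic = self._expected_ic()
        if abs(self.aic - aic) > 1e-8 or not (0.0 <= self.ks_stat <= 1.0):
            raise ValueError("inconsistent information criteria or KS statistic")

    def _expected_ic(self):
        return 2 * self.p - 2 * self.loglik, self.bic

    def to_row(self) -> dict:
        o = self.omega_hat
        return {
            "method": self.method,
            "pi1": o.pi1,
            "lam1": o.comp1.lam,
            "lam2": o.comp2.lam,
            "theta1": o.comp1.theta,
            "theta2": o.comp2.theta,
            "aic": self.aic,
            "bic": self.bic,
            "ks_value": self.ks_stat,
            "ks_pvalue": self.ks_pvalue,
        }


@dataclass
class LRTResult:
    statistic: float
    df: int
    pvalue: float
    boundary_caveat: bool = True  # chi-square reference is approximate here


def information_criteria(loglik: float, p: int, n: int):
    """AIC = 2p - 2 loglik; BIC = p ln(n) - 2 loglik."""
    if n < 1 or p < 1:
        raise ValueError("need n >= 1 and p >= 1")
    return 2.0 * p - 2.0 * loglik, p * float(np.log(n)) - 2.0 * loglik


def _model_cdf(model: Union[MixtureParams, KComponentFit]):
    if isinstance(model, MixtureParams):
        return lambda x: mixture_cdf(x, model)
    return lambda x: sum(
        w * ge_cdf(x, p) for w, p in zip(model.weights, model.comps)
    )


def ks_censored(
    data: CensoredDataset,
    model: Union[MixtureParams, KComponentFit],
    detected_only: bool = False,
):
    """One-sample KS statistic of a censored dataset against a fitted model.

    Nondetects are substituted by their detection limits (default) or dropped
    (``detected_only``); the p-value comes from the asymptotic Kolmogorov
    distribution.
    """
    if data.n == 0:
        raise ValueError("empty dataset")
    if detected_only:
        x = data.observed_values()
    else:
        x = np.where(data.censored, data.limits, data.values)
    if x.size == 0:
        raise ValueError("no usable records for the KS statistic")
    res = stats.ks_1samp(x, _model_cdf(model))
    return float(res.statistic), float(res.pvalue)


def lrt_components(
    data: CensoredDataset,
    k_small: int,
    k_large: int,
    n_starts: int = 3,
    seed: Optional[int] = 0,
) -> LRTResult:
    """Likelihood-ratio test of k_small vs k_large GE mixture components.

    statistic = 2 (loglik_large - loglik_small); df = 3 (k_large - k_small).
    """
    if not k_small < k_large:
        raise ValueError("need k_small < k_large")
    fs = fit_k_gem(data, k_small, n_starts=n_starts, seed=seed)
    fl = fit_k_gem(data, k_large, n_starts=n_starts, seed=seed)
    return lrt_from_fits(fs, fl)


def lrt_from_fits(fit_small: KComponentFit, fit_large: KComponentFit) -> LRTResult:
    if fit_large.loglik < fit_small.loglik - 1e-6:
        raise FitError(
            "larger model fitted worse than nested smaller model; "
            "EM likely stuck -- rerun with more starts"
        )
    stat = max(2.0 * (fit_large.loglik - fit_small.loglik), 0.0)
    df = fit_large.n_params - fit_small.n_params
    pvalue = float(stats.chi2.sf(stat, df)) if stat > 0 else 1.0
    return LRTResult(statistic=stat, df=df, pvalue=pvalue)


def make_report(
    data: CensoredDataset,
    omega: MixtureParams,
    method: str,
    loglik: float,
    p: int = 5,
) -> FitReport:
    aic, bic = information_criteria(loglik, p, data.n)
    ks, ksp = ks_censored(data, omega)
    return FitReport(
        method=method,
        omega_hat=omega,
        p=p,
        loglik=loglik,
        aic=aic,
        bic=bic,
        ks_stat=ks,
        ks_pvalue=ksp,
    )


def select_components(data: CensoredDataset, k_max: int = 5, n_starts: int = 3, seed: int = 0):
    """Fit k = 1..k_max GE mixtures and tabulate AIC/BIC/KS plus the LRT of
    each k against the 2-component reference (smaller model under the null).
    Returns a DataFrame mirroring a component-selection table."""
    import pandas as pd

    fits = {k: fit_k_gem(data, k, n_starts=n_starts, seed=seed + k) for k in range(1, k_max + 1)}
    rows = []
    for k, f in fits.items():
        aic, bic = information_criteria(f.loglik, f.n_params, data.n)
        ks, ksp = ks_censored(data, f)
        row = {"k": k, "loglik": f.loglik, "aic": aic, "bic": bic, "ks_value": ks, "ks_pvalue": ksp}
        if k < 2:
            lrt = lrt_from_fits(fits[k], fits[2])
            row.update(lrt_value=lrt.statistic, lrt_pvalue=lrt.pvalue)
        elif k > 2:
            lrt = lrt_from_fits(fits[2], fits[k])
            row.update(lrt_value=lrt.statistic, lrt_pvalue=lrt.pvalue)
        else:
            row.update(lrt_value=np.nan, lrt_pvalue=np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# partially labeled fitting (distinct detection limits imply allocations)
# ---------------------------------------------------------------------------


def allocate_by_limit(data: CensoredDataset, limit_to_label: dict) -> CensoredDataset:
    """Label censored records by their detection limit (e.g. records below
    the higher of two limits to component 1); observed records stay
    unlabeled."""
    labels = data.labels.copy()
    for i in range(data.n):
        if data.censored[i]:
            lim = float(data.limits[i])
            if lim not in limit_to_label:
                raise ValueError(f"no component allocation for limit {lim}")
            labels[i] = limit_to_label[lim]
    return data.with_labels(labels)


def detected_subset(data: CensoredDataset) -> CensoredDataset:
    """Only the detected (observed) records, as an uncensored dataset."""
    obs = ~data.censored
    m = int(obs.sum())
    if m == 0:
        raise ValueError("no detected records")
    return CensoredDataset(
        data.values[obs], np.zeros(m, dtype=bool), np.full(m, np.nan), data.labels[obs]
    )


def fit_detected_only(data: CensoredDataset, n_starts: int = 10, seed: int = 0):
    """ML fit of the 2-component GE mixture to the detected values only,
    with nondetects dropped -- the simple substitution-free treatment some
    published detection-limit analyses use.  AIC/BIC use the detected count.
    Returns (MixtureParams, loglik, aic, bic).

    This deliberately ignores the information in the nondetects; prefer the
    full censored likelihood (``mle_partial`` / ``em_fit``) for inference.
    """
    det = detected_subset(data).without_labels()
    omega, ll = mle_partial(det, n_starts=n_starts, seed=seed)
    aic, bic = information_criteria(ll, 5, det.n)
    return omega, ll, aic, bic


def mle_partial(
    data: CensoredDataset,
    init: Optional[MixtureParams] = None,
    n_starts: int = 8,
    seed: int = 0,
):
    """Maximize the general (partially labeled) censored mixture likelihood
    numerically over all five parameters.

    Works in (log lam, log theta, logit pi1) space with L-BFGS-B from several
    randomized starts; returns (MixtureParams, loglik).
    """
    from scipy.optimize import minimize
    from scipy.special import expit, logit

    from .ge_core import loglik as general_loglik

    rng = np.random.default_rng(seed)
    x_all = np.where(data.censored, data.limits, data.values)
    mean = float(np.mean(x_all))

    def unpack(v):
        return MixtureParams.from_values(
            np.exp(v[0]), np.exp(v[1]), np.exp(v[2]), np.exp(v[3]), float(expit(v[4]))
        )

    def neg(v):
        try:
            out = -general_loglik(data, unpack(v))
        except (ValueError, FloatingPointError, OverflowError):
            return 1e10
        return out if np.isfinite(out) else 1e10

    starts = []
    if init is not None:
        a = init.as_array()
        starts.append(np.array([np.log(a[0]), np.log(a[1]), np.log(a[2]), np.log(a[3]), logit(a[4])]))
    base = np.array([0.0, np.log(1.0 / mean), 0.0, np.log(1.0 / mean), 0.0])
    starts.append(base)
    for _ in range(n_starts - len(starts)):
        starts.append(base + rng.normal(0, 1.2, size=5))

    best = None
    for s in starts:
        res = minimize(neg, s, method="L-BFGS-B", options={"maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
    omega = unpack(best.x)
    return omega, -float(best.fun)
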