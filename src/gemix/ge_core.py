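"""Generalized-exponential (GE) distribution, two-component mixtures, and
left-censored likelihoods.

The GE distribution has CDF ``F(x) = (1 - exp(-theta*x))**lam`` for ``x > 0``,
with shape ``lam > 0`` and rate ``theta > 0``; at ``lam = 1`` it reduces to the
exponential distribution.  A two-component GE mixture (weight ``pi1`` on the
first component) is the working model for positive-valued concentration data
in which a subset of records is reported only as "below the detection limit
L" -- i.e. left censored.  A censored record contributes the component CDF at
its limit to the likelihood; an observed record contributes the density.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GEParams",
    "MixtureParams",
    "CensoredRecord",
    "CensoredDataset",
    "Hyperparams",
    "log1mexp",
    "ge_pdf",
    "ge_logpdf",
    "ge_cdf",
    "ge_logcdf",
    "ge_ppf",
    "ge_rvs",
    "mixture_pdf",
    "mixture_cdf",
    "loglik_labeled",
    "loglik_mixture",
    "loglik",
    "log_prior",
    "log_posterior_kernel",
]

def log1mexp(t):
    """Stable ``log(1 - exp(-t))`` for ``t > 0`` (vectorized).

    Uses ``log(-expm1(-t))`` for small ``t`` and ``log1p(-exp(-t))`` for
    large ``t`` (switch at ``log 2``), the standard accuracy-preserving split.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("log1mexp requires t > 0")
    small = t <= math.log(2.0)
    out = np.where(
        small,
        np.log(-np.expm1(-np.where(small, t, 1.0))),
        np.log1p(-np.exp(-np.where(small, 1.0, t))),
    )
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GEParams:
    """Shape/rate parameter pair of a single GE component."""

    lam: float
    theta: float

    def __post_init__(self):
        if not (self.lam > 0 and self.theta > 0):
            raise ValueError(f"GE parameters must be positive, got {self}")

    @property
    def mean(self) -> float:
        """E[X] = (psi(lam+1) - psi(1)) / theta."""
        from scipy.special import digamma

        return float((digamma(self.lam + 1.0) - digamma(1.0)) / self.theta)


@dataclass(frozen=True)
class MixtureParams:
    """Full parameter vector (lam1, theta1, lam2, theta2, pi1) of the
    two-component GE mixture."""

    comp1: GEParams
    comp2: GEParams
    pi1: float

    def __post_init__(self):
        if not (0.0 < self.pi1 < 1.0):
            raise ValueError(f"pi1 must lie in (0, 1), got {self.pi1}")

    @classmethod
    def from_values(cls, lam1, theta1, lam2, theta2, pi1) -> "MixtureParams":
        return cls(GEParams(lam1, theta1), GEParams(lam2, theta2), pi1)

    def as_array(self) -> np.ndarray:
        """Order (lam1, theta1, lam2, theta2, pi1)."""
        return np.array(
            [self.comp1.lam, self.comp1.theta, self.comp2.lam, self.comp2.theta, self.pi1]
        )

    @classmethod
    def from_array(cls, a: Sequence[float]) -> "MixtureParams":
        a = np.asarray(a, dtype=float)
        if a.shape != (5,):
            raise ValueError("expected 5 parameters")
        return cls.from_values(*a)

    def component(self, u: int) -> GEParams:
        if u == 1:
            return self.comp1
        if u == 2:
            return self.comp2
        raise ValueError("component index must be 1 or 2")

    def weight(self, u: int) -> float:
        return self.pi1 if u == 1 else 1.0 - self.pi1


@dataclass(frozen=True)
class Hyperparams:
    """Prior constants: Beta(mu1, tau1) on pi1 and independent Gamma priors
    (shape mu2[u], rate tau2[u]) on lam_u and (mu3[u], tau3[u]) on theta_u.

    Zero rates with unit shapes give the flat (improper) prior."""

    mu1: float = 1.0
    tau1: float = 1.0
    mu2: tuple = (1.0, 1.0)
    tau2: tuple = (0.0, 0.0)
    mu3: tuple = (1.0, 1.0)
    tau3: tuple = (0.0, 0.0)

    def __post_init__(self):
        for name in ("mu1", "tau1"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("mu2", "mu3"):
            if any(v <= 0 for v in getattr(self, name)):
                raise ValueError(f"all {name} must be > 0")
        for name in ("tau2", "tau3"):
            if any(v < 0 for v in getattr(self, name)):
                raise ValueError(f"all {name} must be >= 0")

    @property
    def is_flat(self) -> bool:
        return (
            self.mu1 == self.tau1 == 1.0
            and self.mu2 == (1.0, 1.0)
            and self.mu3 == (1.0, 1.0)
            and self.tau2 == (0.0, 0.0)
            and self.tau3 == (0.0, 0.0)
        )


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CensoredRecord:
    """One measurement: either an observed value or a nondetect below `limit`.

    ``label`` is the mixture-component index (1 or 2) when the allocation is
    known, else None.
    """

    value: Optional[float] = None
    is_censored: bool = False
    limit: Optional[float] = None
    label: Optional[int] = None

    def __post_init__(self):
        if self.is_censored:
            if self.limit is None or self.limit <= 0:
                raise ValueError("censored records need a positive detection limit")
        else:
            if self.value is None or self.value < 0:
                raise ValueError("observed records need a nonnegative value")
        if self.label is not None and self.label not in (1, 2):
            raise ValueError("label must be 1, 2 or None")


class CensoredDataset:
    """Array-backed collection of :class:`CensoredRecord`.

    Censoring limits are stored per record, so datasets with several distinct
    detection limits (as in multi-laboratory monitoring data) are represented
    exactly.  Counts follow the convention n = k1 + k2 + m1 + m2 when fully
    labeled: k_u censored and m_u observed records in component u.
    """

    def __init__(self, values, censored, limits, labels=None):
        self.values = np.asarray(values, dtype=float)
        self.censored = np.asarray(censored, dtype=bool)
        self.limits = np.asarray(limits, dtype=float)
        n = self.values.shape[0]
        if labels is None:
            labels = np.zeros(n, dtype=int)
        self.labels = np.asarray(labels, dtype=int)  # 0 = unknown
        if not (self.censored.shape == self.limits.shape == self.labels.shape == (n,)):
            raise ValueError("all record arrays must share one length")
        if np.any(self.censored & ~(self.limits > 0)):
            raise ValueError("censored records need positive limits")
        obs = ~self.censored
        if np.any(obs & ~(self.values >= 0)):
            raise ValueError("observed values must be nonnegative")
        if not np.all(np.isin(self.labels, (0, 1, 2))):
            raise ValueError("labels must be 0 (unknown), 1 or 2")

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_records(cls, records: Iterable[CensoredRecord]) -> "CensoredDataset":
        records = list(records)
        values = [np.nan if r.is_censored else r.value for r in records]
        censored = [r.is_censored for r in records]
        limits = [r.limit if r.limit is not None else np.nan for r in records]
        labels = [r.label if r.label is not None else 0 for r in records]
        return cls(values, censored, limits, labels)

    def to_records(self) -> list:
        out = []
        for i in range(self.n):
            out.append(
                CensoredRecord(
                    value=None if self.censored[i] else float(self.values[i]),
                    is_censored=bool(self.censored[i]),
                    limit=None if np.isnan(self.limits[i]) else float(self.limits[i]),
                    label=int(self.labels[i]) or None,
                )
            )
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "value": self.values,
                "censored": self.censored.astype(int),
                "limit": self.limits,
                "label": self.labels,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CensoredDataset":
        required = {"value", "censored", "limit"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"missing required columns: {sorted(missing)}")
        labels = df["label"].fillna(0).astype(int).to_numpy() if "label" in df else None
        return cls(
            df["value"].to_numpy(dtype=float),
            df["censored"].to_numpy(dtype=bool),
            df["limit"].to_numpy(dtype=float),
            labels,
        )

    # -- bookkeeping --------------------------------------------------------

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return int(self.censored.sum())

    @property
    def fully_labeled(self) -> bool:
        return bool(np.all(self.labels > 0))

    def count_censored(self, u: int) -> int:
        """k_u: censored records allocated to component u."""
        return int(np.sum(self.censored & (self.labels == u)))

    def count_observed(self, u: int) -> int:
        """m_u: observed records allocated to component u."""
        return int(np.sum(~self.censored & (self.labels == u)))

    @property
    def k1(self) -> int:
        return self.count_censored(1)

    @property
    def k2(self) -> int:
        return self.count_censored(2)

    @property
    def m1(self) -> int:
        return self.count_observed(1)

    @property
    def m2(self) -> int:
        return self.count_observed(2)

    def observed_values(self, u: Optional[int] = None) -> np.ndarray:
        mask = ~self.censored
        if u is not None:
            mask = mask & (self.labels == u)
        return self.values[mask]

    def censored_limits(self, u: Optional[int] = None) -> np.ndarray:
        mask = self.censored
        if u is not None:
            mask = mask & (self.labels == u)
        return self.limits[mask]

    def without_labels(self) -> "CensoredDataset":
        return CensoredDataset(self.values, self.censored, self.limits)

    def with_labels(self, labels) -> "CensoredDataset":
        return CensoredDataset(self.values, self.censored, self.limits, labels)

    def __len__(self) -> int:
        return self.n

    def __repr__(self) -> str:
        return f"CensoredDataset(n={self.n}, censored={self.k})"


# ---------------------------------------------------------------------------
# GE distribution
# ---------------------------------------------------------------------------


def _check_params(p: GEParams):
    if not (p.lam > 0 and p.theta > 0):
        raise ValueError("GE parameters must be positive")


def ge_logpdf(x, p: GEParams):
    """log f(x) = log(lam) + log(theta) + (lam-1) log(1-e^{-theta x}) - theta x."""
    _check_params(p)
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("ge_logpdf requires x > 0")
    out = (
        math.log(p.lam)
        + math.log(p.theta)
        + (p.lam - 1.0) * log1mexp(p.theta * x)
        - p.theta * x
    )
    return out if np.ndim(out) else float(out)


def ge_pdf(x, p: GEParams):
    with np.errstate(under="ignore"):
        return np.exp(ge_logpdf(x, p))


def ge_logcdf(x, p: GEParams):
    _check_params(p)
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("ge_logcdf requires x >= 0")
    with np.errstate(divide="ignore"):
        out = np.where(x > 0, p.lam * log1mexp(np.where(x > 0, p.theta * x, 1.0)), -np.inf)
    return out if out.ndim else float(out)


def ge_cdf(x, p: GEParams):
    with np.errstate(under="ignore"):
        return np.exp(ge_logcdf(x, p))


def ge_ppf(q, p: GEParams):
    """Quantile function: x = -log(1 - q**(1/lam)) / theta."""
    _check_params(p)
    q = np.asarray(q, dtype=float)
    if np.any((q < 0) | (q > 1)):
        raise ValueError("quantile levels must lie in [0, 1]")
    out = -np.log1p(-np.power(q, 1.0 / p.lam)) / p.theta
    return out if out.ndim else float(out)


def ge_rvs(p: GEParams, n: int, rng) -> np.ndarray:
    """Inverse-CDF sample of size n; `rng` is a seed or numpy Generator."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    return ge_ppf(rng.uniform(size=n), p)


def mixture_pdf(x, omega: MixtureParams):
    return omega.pi1 * ge_pdf(x, omega.comp1) + (1.0 - omega.pi1) * ge_pdf(x, omega.comp2)


def mixture_cdf(x, omega: MixtureParams):
    return omega.pi1 * ge_cdf(x, omega.comp1) + (1.0 - omega.pi1) * ge_cdf(x, omega.comp2)


def mixture_rvs(omega: MixtureParams, n: int, rng):
    """Labeled mixture draws: returns (values, labels in {1,2})."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    labels = np.where(rng.uniform(size=n) <= omega.pi1, 1, 2)
    x = np.empty(n)
    for u in (1, 2):
        idx = labels == u
        if idx.any():
            x[idx] = ge_rvs(omega.component(u), int(idx.sum()), rng)
    return x, labels


# ---------------------------------------------------------------------------
# likelihoods
# ---------------------------------------------------------------------------


def _component_loglik(lam, theta, x_obs, limits):
    """Censored single-component GE log-likelihood (no mixing-weight terms):

        m log(lam) + m log(theta) + (lam-1) sum log(1-e^{-theta x})
        - theta sum x + lam sum log(1-e^{-theta L_i})

    with per-record censoring limits L_i.
    """
    m = x_obs.size
    out = m * (math.log(lam) + math.log(theta)) - theta * float(np.sum(x_obs))
    if m:
        out += (lam - 1.0) * float(np.sum(log1mexp(theta * x_obs)))
    if limits.size:
        out += lam * float(np.sum(log1mexp(theta * limits)))
    return out


def loglik_labeled(
    data: CensoredDataset, omega: MixtureParams, threshold: str = "limit"
) -> float:
    """Log-likelihood of a fully labeled left-censored sample.

    Component allocation known for every record: the mixing weight enters
    through the counts (k_u + m_u) and each record contributes its component
    density (observed) or component CDF at a censoring threshold.

    ``threshold`` selects the censoring-threshold convention:
    ``"limit"`` (default) uses each record's own detection limit;
    ``"order-statistic"`` uses the smallest observed value in the pooled
    sample for every censored record -- the convention of common-limit
    formulations in which the threshold and the smallest complete
    observation coincide asymptotically.
    """
    if not data.fully_labeled:
        raise ValueError("loglik_labeled requires every record to carry a label")
    if threshold not in ("limit", "order-statistic"):
        raise ValueError("threshold must be 'limit' or 'order-statistic'")
    x_min = None
    if threshold == "order-statistic":
        all_obs = data.observed_values()
        if all_obs.size == 0:
            raise ValueError("order-statistic threshold needs at least one observed record")
        x_min = float(all_obs.min())
    out = 0.0
    for u in (1, 2):
        x_obs = data.observed_values(u)
        if np.any(x_obs == 0):
            raise ValueError("observed value of 0 has zero density under the GE model")
        lim = data.censored_limits(u)
        if x_min is not None and lim.size:
            lim = np.full_like(lim, x_min)
        n_u = x_obs.size + lim.size
        out += n_u * math.log(omega.weight(u))
        p = omega.component(u)
        out += _component_loglik(p.lam, p.theta, x_obs, lim)
    return out


def loglik_mixture(data: CensoredDataset, omega: MixtureParams) -> float:
    """Observed-data log-likelihood with unknown allocations:
    sum over observed records of log mixture_pdf plus sum over censored
    records of log mixture_cdf(limit)."""
    x_obs = data.observed_values()
    if np.any(x_obs == 0):
        raise ValueError("observed value of 0 has zero density under the GE model")
    out = 0.0
    with np.errstate(divide="ignore"):
        if x_obs.size:
            out += float(np.sum(np.log(mixture_pdf(x_obs, omega))))
        lim = data.censored_limits()
        if lim.size:
            out += float(np.sum(np.log(mixture_cdf(lim, omega))))
    return out


def loglik(data: CensoredDataset, omega: MixtureParams) -> float:
    """General log-likelihood honouring whatever labels are present.

    Labeled records contribute ``pi_u * (density or CDF-at-limit)`` for their
    component; unlabeled records contribute the mixture density / CDF.
    Reduces to :func:`loglik_labeled` when fully labeled and to
    :func:`loglik_mixture` when no labels are present.
    """
    out = 0.0
    for u in (1, 2):
        x_obs = data.observed_values(u)
        if np.any(x_obs == 0):
            raise ValueError("observed value of 0 has zero density under the GE model")
        lim = data.censored_limits(u)
        p = omega.component(u)
        logw = math.log(omega.weight(u))
        if x_obs.size:
            out += x_obs.size * logw + float(np.sum(ge_logpdf(x_obs, p)))
        if lim.size:
            out += lim.size * logw + float(np.sum(ge_logcdf(lim, p)))
    unl = data.labels == 0
    with np.errstate(divide="ignore"):
        x_u = data.values[unl & ~data.censored]
        if x_u.size:
            out += float(np.sum(np.log(mixture_pdf(x_u, omega))))
        l_u = data.limits[unl & data.censored]
        if l_u.size:
            out += float(np.sum(np.log(mixture_cdf(l_u, omega))))
    return out


# ---------------------------------------------------------------------------
# priors and posterior kernel
# ---------------------------------------------------------------------------


def log_prior(omega: MixtureParams, h: Hyperparams) -> float:
    """Unnormalized log prior: Beta(mu1, tau1) kernel in pi1 plus Gamma
    kernels (shape mu, rate tau) in each of lam1, lam2, theta1, theta2."""
    out = (h.mu1 - 1.0) * math.log(omega.pi1) + (h.tau1 - 1.0) * math.log1p(-omega.pi1)
    for u in (1, 2):
        p = omega.component(u)
        out += (h.mu2[u - 1] - 1.0) * math.log(p.lam) - h.tau2[u - 1] * p.lam
        out += (h.mu3[u - 1] - 1.0) * math.log(p.theta) - h.tau3[u - 1] * p.theta
    return out


def log_posterior_kernel(data: CensoredDataset, omega: MixtureParams, h: Hyperparams) -> float:
    """Unnormalized log posterior for a fully labeled sample:
    ``loglik_labeled + log_prior``."""
    return loglik_labeled(data, omega) + log_prior(omega, h)
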