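import numpy as np
import pytest

from gemix.ge_core import CensoredDataset, GEParams, Hyperparams, MixtureParams, ge_rvs


@pytest.fixture(scope="session")
def tiny_labeled():
    """Small fully labeled dataset for the exact posterior-quadrature
    oracles: 6 observed + 2 censored component-1 records and 12 observed
    component-2 records, all drawn once from GE(0.75, 1.5).

    The two smallest component-1 draws are reported as nondetects below
    L = 0.2 (midway between the 2nd and 3rd order statistics).  The censored
    records temper the small-theta tail of the importance weights, and the
    component-1 MLE lies near the prior centre -- the regime in which the
    second-order Lindley expansion is accurate."""
    rng = np.random.default_rng(1)
    p = GEParams(0.75, 1.5)
    x1 = np.sort(ge_rvs(p, 8, rng))
    x2 = ge_rvs(p, 12, rng)
    L = round(float((x1[1] + x1[2]) / 2), 3)
    vals = np.concatenate([x1[2:], [np.nan] * 2, x2])
    cens = np.array([False] * 6 + [True] * 2 + [False] * 12)
    lims = np.concatenate([[np.nan] * 6, [L] * 2, [np.nan] * 12])
    labels = np.array([1] * 8 + [2] * 12)
    return CensoredDataset(vals, cens, lims, labels)


@pytest.fixture(scope="session")
def tiny_prior():
    """Weakly informative prior centred at (lam, theta) = (0.75, 1.5) for
    both components and pi1 = 0.45 (concentration 2)."""
    return Hyperparams(
        mu1=0.9, tau1=1.1, mu2=(1.5, 1.5), tau2=(2.0, 2.0), mu3=(3.0, 3.0), tau3=(2.0, 2.0)
    )


@pytest.fixture(scope="session")
def toy_mixed():
    """Ten labeled records mixing observed and censored, both components."""
    vals = np.array([0.5, 0.9, np.nan, 1.4, 0.3, np.nan, 0.7, 2.2, np.nan, 0.25])
    cens = np.array([False, False, True, False, False, True, False, False, True, False])
    lims = np.array([np.nan, np.nan, 0.3, np.nan, np.nan, 0.2, np.nan, np.nan, 0.35, np.nan])
    labels = np.array([1, 2, 1, 2, 1, 2, 1, 2, 1, 2])
    return CensoredDataset(vals, cens, lims, labels)


@pytest.fixture(scope="session")
def omega_s1():
    from gemix.synthetic_data import S1

    return S1


def random_omega(rng):
    return MixtureParams.from_values(
        rng.uniform(0.3, 3.0),
        rng.uniform(0.3, 3.0),
        rng.uniform(0.3, 3.0),
        rng.uniform(0.3, 3.0),
        rng.uniform(0.05, 0.95),
    )
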