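import numpy as np
import pytest

from survmod.data import SurvivalDataset, standardize


@pytest.fixture
def toy_data() -> SurvivalDataset:
    """Ten patients, two biomarkers, mixed censoring, one tied event pair."""
    time = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 4.5, 5.0, 6.0, 7.0, 8.0])
    event = np.array([1, 1, 1, 0, 1, 0, 1, 1, 0, 1])
    trt = np.array([0.5, -0.5, 0.5, -0.5, 0.5, -0.5, 0.5, -0.5, 0.5, -0.5])
    x1 = np.array([0.3, -1.2, 0.8, 1.5, -0.4, 0.1, -0.9, 2.0, -1.1, 0.6])
    x2 = np.array([-0.5, 0.7, 1.1, -1.3, 0.2, -0.8, 1.4, 0.0, -0.2, 0.9])
    return SurvivalDataset(
        time=time, event=event, treatment=trt, biomarkers=np.column_stack([x1, x2])
    )


@pytest.fixture
def toy_std(toy_data) -> SurvivalDataset:
    return standardize(toy_data)


def make_sim(seed=0, n=200, p=8, effect=None):
    """Small synthetic interaction-model dataset with known truth.

    ``effect``: optional (alpha, beta, gamma) arrays; defaults to a single
    strong prognostic marker and a single strong modifier.
    """
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    T = np.where(rng.random(n) < 0.5, 0.5, -0.5)
    if effect is None:
        beta = np.zeros(p)
        gamma = np.zeros(p)
        beta[0] = -0.6
        gamma[1] = -1.0
        alpha = -0.4
    else:
        alpha, beta, gamma = effect
    lp = alpha * T + X @ beta + (X @ gamma) * T
    t_event = rng.exponential(np.exp(-lp))
    t_cens = rng.exponential(2.0, size=n)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return SurvivalDataset(time=time, event=event, treatment=T, biomarkers=X)


@pytest.fixture
def sim_small() -> SurvivalDataset:
    return make_sim(seed=3)


# -- independent brute-force oracles ---------------------------------------


def brute_partial_loglik(time, event, eta):
    """Breslow partial log-likelihood by explicit risk-set enumeration."""
    time = np.asarray(time, float)
    event = np.asarray(event)
    eta = np.asarray(eta, float)
    ll = 0.0
    for t in np.unique(time[event == 1]):
        dead = (time == t) & (event == 1)
        risk = time >= t
        ll += eta[dead].sum() - dead.sum() * np.log(np.exp(eta[risk]).sum())
    return ll


def brute_breslow(time, event, eta):
    """(times, cumulative hazard) by explicit enumeration."""
    time = np.asarray(time, float)
    event = np.asarray(event)
    eta = np.asarray(eta, float)
    times = np.unique(time[event == 1])
    cum = []
    total = 0.0
    for t in times:
        dead = (time == t) & (event == 1)
        risk = time >= t
        total += dead.sum() / np.exp(eta[risk]).sum()
        cum.append(total)
    return times, np.array(cum)
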