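"""IPCW metrics against explicit brute-force enumeration."""

import numpy as np
import pytest

from survmod.data import SurvivalDataset
from survmod.metrics import (
    NoUsablePairsError,
    brier,
    censoring_km,
    delta_c,
    event_km,
    integrated_brier,
    uno_c,
)


@pytest.fixture
def censored10():
    """Ten patients with a mix of events and censorings (no tied times)."""
    return SurvivalDataset(
        time=[0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 4.5, 5.5],
        event=[1, 0, 1, 1, 0, 1, 0, 1, 0, 1],
        treatment=[0.5, -0.5, 0.5, -0.5, 0.5, -0.5, 0.5, -0.5, 0.5, -0.5],
        biomarkers=np.linspace(-1, 1, 10)[:, None],
    )


def brute_censoring_km(time, event):
    """Hand KM of the censoring distribution (reverse the indicator)."""
    time = np.asarray(time, float)
    cens = 1 - np.asarray(event)

    def at(t):
        s = 1.0
        for u in np.unique(time[cens == 1]):
            if u <= t:
                n_at_risk = (time >= u).sum()
                d = ((time == u) & (cens == 1)).sum()
                s *= 1 - d / n_at_risk
        return s

    return at


def test_censoring_km_matches_hand_computation(censored10):
    cs = censoring_km(censored10)
    oracle = brute_censoring_km(censored10.time, censored10.event)
    for t in [0.4, 1.0, 2.4, 2.5, 3.7, 5.0]:
        assert cs.at(t) == pytest.approx(oracle(t), rel=1e-12)


def test_censoring_km_no_censoring_is_one():
    data = SurvivalDataset(
        time=[1, 2, 3, 4], event=[1, 1, 1, 1],
        treatment=[0.5, -0.5, 0.5, -0.5], biomarkers=np.zeros((4, 1)),
    )
    cs = censoring_km(data)
    assert cs.at(10.0) == 1.0


def test_censoring_km_single_step():
    # one censoring at t=2 among 4 still at risk -> step to 3/4
    data = SurvivalDataset(
        time=[2.0, 3.0, 4.0, 5.0], event=[0, 1, 1, 1],
        treatment=[0.5, -0.5, 0.5, -0.5], biomarkers=np.zeros((4, 1)),
    )
    cs = censoring_km(data)
    assert cs.at(1.9) == 1.0
    assert cs.at(2.0) == pytest.approx(0.75)


def test_brier_uncensored_closed_forms():
    data = SurvivalDataset(
        time=[1, 2, 6, 7], event=[1, 1, 1, 1],
        treatment=[0.5, -0.5, 0.5, -0.5], biomarkers=np.zeros((4, 1)),
    )
    perfect = np.array([0.0, 0.0, 1.0, 1.0])
    assert brier(data, perfect, 5.0) == 0.0
    assert brier(data, np.full(4, 0.5), 5.0) == pytest.approx(0.25)
    # without censoring the score is the plain MSE of survival indicators
    preds = np.array([0.2, 0.4, 0.9, 0.7])
    ind = (data.time > 5.0).astype(float)
    assert brier(data, preds, 5.0) == pytest.approx(np.mean((ind - preds) ** 2))


def test_brier_censored_matches_hand_weighted_sum(censored10):
    preds = np.linspace(0.9, 0.1, 10)
    tau = 3.2
    oracle_g = brute_censoring_km(censored10.time, censored10.event)
    total = 0.0
    for i in range(10):
        t_i, d_i, s_i = censored10.time[i], censored10.event[i], preds[i]
        if t_i <= tau and d_i == 1:
            total += s_i**2 / oracle_g(t_i)
        elif t_i > tau:
            total += (1 - s_i) ** 2 / oracle_g(tau)
    assert brier(censored10, preds, tau) == pytest.approx(total / 10, rel=1e-12)


def test_integrated_brier_perfect_predictions_zero(censored10):
    def perfect(times):
        return (censored10.time[:, None] > times[None, :]).astype(float)

    # "perfect" foresight of the observed outcome gives zero error for the
    # uncensored contributions at every jump time
    data = SurvivalDataset(
        time=[1, 2, 3, 4, 6], event=[1, 1, 1, 1, 1],
        treatment=[0.5, -0.5, 0.5, -0.5, 0.5], biomarkers=np.zeros((5, 1)),
    )

    def perfect2(times):
        return (data.time[:, None] > times[None, :]).astype(float)

    assert integrated_brier(data, perfect2, 5.0) == 0.0


def test_integrated_brier_weight_normalization(censored10):
    """iBrier of constant predictions equals the hand Stieltjes sum."""
    tau = 4.0
    const = 0.6

    def fn(times):
        return np.full((censored10.n, len(times)), const)

    km = event_km(censored10)
    jumps = km.times[km.times <= tau]
    w = (1 - km.at(jumps)) / (1 - km.at(tau))
    assert w[-1] == pytest.approx(1.0)  # W(tau) = 1 by construction
    dw = np.diff(np.concatenate([[0.0], w]))
    expected = sum(
        brier(censored10, np.full(censored10.n, const), t) * d
        for t, d in zip(jumps, dw)
    )
    assert integrated_brier(censored10, fn, tau) == pytest.approx(expected, rel=1e-12)


def brute_uno(time, event, g_at, scores, tau):
    num = den = 0.0
    n = len(time)
    for i in range(n):
        if event[i] != 1 or time[i] >= tau:
            continue
        w = g_at(time[i]) ** -2
        for j in range(n):
            if time[i] < time[j]:
                den += w
                if scores[i] > scores[j]:
                    num += w
                elif scores[i] == scores[j]:
                    num += 0.5 * w
    return num / den


def test_uno_c_matches_bruteforce(censored10):
    rng = np.random.default_rng(0)
    s = rng.normal(size=10)
    s[3] = s[4]  # a score tie
    g = brute_censoring_km(censored10.time, censored10.event)
    assert uno_c(censored10, s, 4.0) == pytest.approx(
        brute_uno(censored10.time, censored10.event, g, s, 4.0), rel=1e-12
    )


def test_uno_c_extremes():
    data = SurvivalDataset(
        time=[1, 2, 3, 4, 5], event=[1, 1, 1, 1, 1],
        treatment=[0.5, -0.5, 0.5, -0.5, 0.5], biomarkers=np.zeros((5, 1)),
    )
    anti = np.array([5.0, 4.0, 3.0, 2.0, 1.0])  # higher score = earlier event
    assert uno_c(data, anti, 6.0) == 1.0
    assert uno_c(data, np.zeros(5), 6.0) == 0.5
    assert uno_c(data, -anti, 6.0) == 0.0


def test_uno_c_antisymmetry(censored10):
    s = np.random.default_rng(3).normal(size=10)
    c1 = uno_c(censored10, s, 4.0)
    c2 = uno_c(censored10, -s, 4.0)
    assert c1 + c2 == pytest.approx(1.0)


def test_metrics_invariant_to_reordering(censored10):
    s = np.random.default_rng(5).normal(size=10)
    perm = np.random.default_rng(6).permutation(10)
    shuffled = censored10.subset(perm)
    assert uno_c(shuffled, s[perm], 4.0) == pytest.approx(uno_c(censored10, s, 4.0))
    assert brier(shuffled, np.full(10, 0.7)[perm], 3.0) == pytest.approx(
        brier(censored10, np.full(10, 0.7), 3.0)
    )


def test_uno_c_failure_distinct_from_zero(censored10):
    with pytest.raises(NoUsablePairsError):
        uno_c(censored10, np.zeros(10), 0.1)


def test_delta_c_trivial_cases(censored10):
    # constant scores: both arms at 0.5
    assert delta_c(censored10, np.zeros(10), 4.0) == 0.0
    # arms with identical data and scores
    data = SurvivalDataset(
        time=[1, 2, 3, 1, 2, 3], event=[1, 1, 0, 1, 1, 0],
        treatment=[0.5, 0.5, 0.5, -0.5, -0.5, -0.5],
        biomarkers=np.zeros((6, 1)),
    )
    s = np.array([3.0, 1.0, 2.0, 3.0, 1.0, 2.0])
    assert delta_c(data, s, 4.0) == 0.0


def test_delta_c_equals_within_arm_difference(censored10):
    s = np.random.default_rng(9).normal(size=10)
    g_plus = censored10.subset(np.flatnonzero(censored10.treatment == 0.5))
    g_minus = censored10.subset(np.flatnonzero(censored10.treatment == -0.5))
    expected = abs(
        uno_c(g_plus, s[censored10.treatment == 0.5], 4.0)
        - uno_c(g_minus, s[censored10.treatment == -0.5], 4.0)
    )
    assert delta_c(censored10, s, 4.0) == pytest.approx(expected)
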