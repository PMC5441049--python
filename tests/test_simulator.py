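"""Synthetic-trial generator: correlation structure, calibration, oracle."""

import numpy as np
import pytest

from survmod._cox import RiskSetEngine
from survmod.simulator import (
    ScenarioSpec,
    calibrate_censoring,
    draw_effects,
    generate_biomarkers,
    generate_dataset,
    generate_pair,
    oracle_model,
    scenario,
    theoretical_survival,
)


def test_block_ar1_correlations():
    X = generate_biomarkers(2000, 75, block_size=25, rho=0.8, seed=0)
    corr = np.corrcoef(X, rowvar=False)
    # adjacent within a block ~ rho
    adj = [corr[j, j + 1] for j in range(24)]
    assert np.mean(adj) == pytest.approx(0.8, abs=0.05)
    # lag 5 within a block ~ rho^5
    lag5 = [corr[j, j + 5] for j in range(20)]
    assert np.mean(lag5) == pytest.approx(0.8**5, abs=0.05)
    # across blocks independent
    cross = [corr[j, 30 + j] for j in range(20)]
    assert np.abs(np.mean(cross)) < 0.05
    # unit variance
    assert np.allclose(X.std(axis=0), 1.0, atol=0.1)


def test_rho_zero_independent():
    X = generate_biomarkers(2000, 50, block_size=25, rho=0.0, seed=1)
    corr = np.corrcoef(X, rowvar=False)
    off = corr[np.triu_indices(50, k=1)]
    assert np.abs(off).max() < 0.1


@pytest.mark.parametrize(
    "sc,alpha,n_prog,n_mod",
    [(1, 0.0, 0, 0), (2, -0.8, 0, 0), (3, 0.0, 20, 0),
     (4, 0.0, 0, 15), (5, -0.8, 0, 15), (6, -0.8, 20, 15)],
)
def test_scenario_table(sc, alpha, n_prog, n_mod):
    spec = scenario(sc)
    assert spec.alpha == alpha
    assert spec.n_prog == n_prog and spec.n_mod == n_mod
    eff = draw_effects(spec, seed=0)
    assert eff.alpha == alpha
    assert (eff.beta != 0).sum() == n_prog
    assert (eff.gamma != 0).sum() == n_mod
    nz_b = eff.beta[eff.beta != 0]
    nz_g = eff.gamma[eff.gamma != 0]
    assert ((nz_b >= -0.20) & (nz_b <= -0.05)).all()
    assert ((nz_g >= -0.40) & (nz_g <= -0.10)).all()
    # prognostic and modifier truth sets are disjoint
    assert np.intersect1d(eff.prognostic_set, eff.modifier_set).size == 0


def test_censoring_calibration_closed_form():
    spec = scenario(1)
    lam_c = calibrate_censoring(spec)
    lam0 = spec.baseline_hazard
    # exponential competing risks: P(censored) = c / (lam0 + c)
    assert lam_c / (lam0 + lam_c) == pytest.approx(0.72, abs=1e-4)
    assert calibrate_censoring(scenario(1, censor_rate_target=0.0)) == 0.0


def test_empirical_censoring_rates_null_and_treatment():
    spec1 = scenario(1, n=1500, p=5)
    rates = []
    for r in range(5):
        data, _ = generate_dataset(spec1, seed=100 + r)
        rates.append(1 - data.event.mean())
    assert np.mean(rates) == pytest.approx(0.72, abs=0.02)
    # the same censoring hazard under a treatment effect gives asymmetric arms
    spec2 = scenario(2, n=1500, p=5)
    minus, plus = [], []
    for r in range(5):
        data, _ = generate_dataset(spec2, seed=200 + r)
        for arm, store in ((-0.5, minus), (0.5, plus)):
            m = data.treatment == arm
            store.append(1 - data.event[m].mean())
    assert np.mean(minus) == pytest.approx(0.62, abs=0.02)
    assert np.mean(plus) == pytest.approx(0.80, abs=0.02)


def test_baseline_survival_calibration():
    # no censoring: P(T > 5) for a baseline patient ~ 0.77
    spec = scenario(1, n=20000, p=2, censor_rate_target=0.0)
    data, eff = generate_dataset(spec, seed=3)
    assert (data.time > 5).mean() == pytest.approx(0.77, abs=0.02)


def test_theoretical_survival_closed_forms():
    spec = scenario(2, p=4)
    eff = draw_effects(spec, seed=0)
    x0 = np.zeros((1, 4))
    assert theoretical_survival(eff, spec, x0, np.array([0.5]), 5.0)[0] == pytest.approx(
        0.77 ** np.exp(-0.4), abs=1e-10
    )
    assert 0.77 ** np.exp(-0.4) == pytest.approx(0.839, abs=5e-4)
    # empirical KM of a large uncensored cohort matches the formula
    spec_nc = scenario(2, n=50000, p=4, censor_rate_target=0.0)
    data, eff2 = generate_dataset(spec_nc, seed=9)
    s_true = theoretical_survival(eff2, spec_nc, data.biomarkers, data.treatment, 5.0)
    assert (data.time > 5).mean() == pytest.approx(s_true.mean(), abs=0.01)


def test_doubling_hazard_halves_times():
    """S0 -> S0^2 doubles every hazard; identical draws then halve exactly."""
    spec_a = scenario(1, n=500, p=3, censor_rate_target=0.0)
    spec_b = ScenarioSpec(scenario_id=1, n=500, p=3, S0_tau=0.77**2,
                          censor_rate_target=0.0)
    da, _ = generate_dataset(spec_a, seed=77)
    db, _ = generate_dataset(spec_b, seed=77)
    np.testing.assert_allclose(db.time, da.time / 2.0, rtol=1e-12)


def test_seed_determinism_byte_identical():
    spec = scenario(6, n=100, p=50)
    a_train, a_valid, a_eff = generate_pair(spec, seed=5)
    b_train, b_valid, b_eff = generate_pair(spec, seed=5)
    np.testing.assert_array_equal(a_train.time, b_train.time)
    np.testing.assert_array_equal(a_train.biomarkers, b_train.biomarkers)
    np.testing.assert_array_equal(a_valid.time, b_valid.time)
    np.testing.assert_array_equal(a_eff.beta, b_eff.beta)
    # twin shares the truth but not the patients
    np.testing.assert_array_equal(a_eff.gamma, b_eff.gamma)
    assert not np.array_equal(a_train.time, a_valid.time)


def test_oracle_structural_counts():
    spec1 = scenario(1, n=200, p=30)
    train, eff = generate_dataset(spec1, seed=1)
    m1 = oracle_model(train, eff)
    assert (m1.beta_hat == 0).all() and (m1.gamma_hat == 0).all()

    spec3 = scenario(3, n=300, p=500)
    train3, eff3 = generate_dataset(spec3, seed=2)
    m3 = oracle_model(train3, eff3)
    # treatment + 20 main effects, no interactions
    assert (m3.beta_hat != 0).sum() == 20
    assert (m3.gamma_hat == 0).all()


def test_oracle_coefficient_recovery_coverage():
    """Oracle Wald 95% CIs cover the drawn truth at roughly nominal rate."""
    spec = scenario(3, n=800, p=50)
    hits = total = 0
    for r in range(15):
        train, eff = generate_dataset(spec, seed=300 + r)
        model = oracle_model(train, eff)
        from survmod.data import standardize
        from survmod.penalized import build_design

        data = standardize(train)
        design = build_design(data)
        sel = np.flatnonzero(np.concatenate([[True], eff.beta != 0, eff.gamma != 0]))
        eng = RiskSetEngine(data.time, data.event, design.matrix[:, sel])
        _, hess = eng.grad_hess(model.coef_vector()[sel])
        se = np.sqrt(np.diag(np.linalg.inv(-hess)))
        est = model.coef_vector()[sel][1:]   # biomarker terms only
        truth = eff.beta[eff.beta != 0]
        half = 1.96 * se[1:]
        hits += ((truth >= est - half) & (truth <= est + half)).sum()
        total += truth.size
    assert 0.88 <= hits / total <= 1.0
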