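"""Penalized interaction-model fitting: KKT boundary, weights, refits, paths."""

import numpy as np
import pytest

from survmod._cox import newton_cox
from survmod.data import WEIGHT_CAP, PenaltySpec, standardize
from survmod.penalized import (
    adaptive_weights,
    build_design,
    cox_partial_loglik,
    default_lambda_grid,
    default_ridge_grid,
    fit_path,
    fit_penalized,
    lambda_max,
    refit_unpenalized,
)

from conftest import make_sim


@pytest.fixture(scope="module")
def data():
    return standardize(make_sim(seed=11, n=250, p=6))


def test_design_matrix_layout(data):
    design = build_design(data)
    assert design.d == 1 + 2 * data.p
    assert not design.penalized_mask[0]
    assert design.penalized_mask[1:].all()
    np.testing.assert_allclose(design.matrix[:, 0], data.treatment)
    np.testing.assert_allclose(
        design.matrix[:, 1 + data.p :], data.biomarkers * data.treatment[:, None]
    )


def test_partial_loglik_op_matches_engine(data):
    from conftest import brute_partial_loglik

    coefs = np.linspace(-0.3, 0.3, 1 + 2 * data.p)
    design = build_design(data)
    expected = brute_partial_loglik(data.time, data.event, design.matrix @ coefs)
    assert cox_partial_loglik(data, coefs) == pytest.approx(expected, rel=1e-10)


def test_kkt_boundary_all_zero_and_treatment_only(data):
    pen = PenaltySpec.lasso(data.p)
    lmax = lambda_max(data, pen)
    model = fit_penalized(data, pen, lmax * (1 + 1e-6))
    assert (model.beta_hat == 0).all() and (model.gamma_hat == 0).all()
    trt_only = newton_cox(data.time, data.event, data.treatment[:, None])
    assert model.alpha_hat == pytest.approx(trt_only[0], abs=1e-5)
    # just below lambda_max at least one penalized coefficient activates
    below = fit_penalized(data, pen, lmax * 0.95, with_baseline=False)
    assert (below.beta_hat != 0).any() or (below.gamma_hat != 0).any()


def test_adaptive_with_unit_weights_reproduces_lasso(data):
    pen_l = PenaltySpec.lasso(data.p)
    pen_a = PenaltySpec.adaptive(np.ones(data.p), np.ones(data.p))
    grid = default_lambda_grid(lambda_max(data, pen_l), n_lambda=10)
    path_l = fit_path(data, pen_l, grid)
    path_a = fit_path(data, pen_a, grid)
    np.testing.assert_allclose(path_a, path_l, atol=1e-6)


def test_path_sparsity_monotone_endpoints(data):
    pen = PenaltySpec.lasso(data.p)
    grid = default_lambda_grid(lambda_max(data, pen) * (1 + 1e-6), n_lambda=30)
    path = fit_path(data, pen, grid)
    nz = (np.abs(path[1:]) > 0).sum(axis=0)
    assert nz[0] == 0
    assert nz[-1] >= nz[0]
    # shrinkage endpoint check: |coef| at lambda_max <= |coef| at ~0
    small = fit_path(data, pen, [grid[-1] * 1e-4])[:, 0]
    np.testing.assert_array_less(np.abs(path[1:, 0]), np.abs(small[1:]) + 1e-6)


def test_objective_not_worse_than_zero_start(data):
    """Penalized objective at the optimum >= objective at the null point."""
    from survmod.penalized import effective_l1_weights

    pen = PenaltySpec.lasso(data.p)
    lam = 0.3 * lambda_max(data, pen)
    model = fit_penalized(data, pen, lam, with_baseline=False)
    design = build_design(data)
    coefs = model.coef_vector()
    w_eff = effective_l1_weights(design, pen)

    def objective(c):
        pen_term = lam * np.sum(w_eff * np.abs(c[design.penalized_mask]))
        return cox_partial_loglik(data, c) - pen_term

    zero = np.zeros(design.d)
    zero[0] = newton_cox(data.time, data.event, data.treatment[:, None])[0]
    assert objective(coefs) >= objective(zero) - 1e-6


def test_adaptive_weights_are_capped_reciprocals(data):
    """Weights equal 1/|ridge coefficient| of the cvl-selected ridge fit."""
    from survmod.tuning import FoldAssignment, cvl_path

    grid = default_ridge_grid(data)
    pen = adaptive_weights(data, ridge_lambda_grid=grid, seed=5)
    folds = FoldAssignment.create(data, k=5, seed=5)
    values = cvl_path(data, PenaltySpec.ridge(data.p), grid, folds)
    lam_r = grid[int(np.argmax(values))]
    coefs = fit_path(data, PenaltySpec.ridge(data.p), [lam_r])[:, 0]
    beta_r = coefs[1 : 1 + data.p]
    gamma_r = coefs[1 + data.p :]
    np.testing.assert_allclose(
        pen.theta, np.minimum(1 / np.abs(beta_r), WEIGHT_CAP), rtol=1e-5
    )
    np.testing.assert_allclose(
        pen.vartheta, np.minimum(1 / np.abs(gamma_r), WEIGHT_CAP), rtol=1e-5
    )
    assert (pen.theta > 0).all() and (pen.theta <= WEIGHT_CAP).all()


def test_capped_weight_excludes_coefficient(data):
    theta = np.ones(data.p)
    vartheta = np.ones(data.p)
    theta[2] = WEIGHT_CAP       # excluded main effect
    vartheta[4] = WEIGHT_CAP    # excluded interaction
    pen = PenaltySpec.adaptive(theta, vartheta)
    model = fit_penalized(data, pen, 1e-6, with_baseline=False)
    assert model.beta_hat[2] == 0.0
    assert model.gamma_hat[4] == 0.0
    assert (model.beta_hat != 0).sum() >= 1


def test_refit_matches_direct_unpenalized_fit(data):
    pen = PenaltySpec.lasso(data.p)
    lam = 0.4 * lambda_max(data, pen)
    model = fit_penalized(data, pen, lam)
    refit = refit_unpenalized(model, data)
    design = build_design(data)
    sel = np.concatenate(
        [[True], model.beta_hat != 0, model.gamma_hat != 0]
    )
    direct = newton_cox(data.time, data.event, design.matrix[:, sel])
    np.testing.assert_allclose(refit.coef_vector()[sel], direct, atol=1e-6)
    assert (refit.coef_vector()[~sel] == 0).all()
    # independent oracle: lifelines (no ties in this sample, so Efron == Breslow)
    import pandas as pd
    from lifelines import CoxPHFitter

    cols = design.matrix[:, sel]
    df = pd.DataFrame(cols, columns=[f"c{i}" for i in range(cols.shape[1])])
    df["T"] = data.time
    df["E"] = data.event
    cph = CoxPHFitter().fit(df, "T", "E")
    np.testing.assert_allclose(refit.coef_vector()[sel], cph.params_.values, atol=1e-4)


def test_empty_selection_refit_is_treatment_only(data):
    pen = PenaltySpec.lasso(data.p)
    model = fit_penalized(data, pen, lambda_max(data, pen) * (1 + 1e-6))
    refit = refit_unpenalized(model, data)
    assert (refit.beta_hat == 0).all() and (refit.gamma_hat == 0).all()
    trt_only = newton_cox(data.time, data.event, data.treatment[:, None])
    assert refit.alpha_hat == pytest.approx(trt_only[0], abs=1e-8)


def test_strong_interaction_recovered():
    """A dominant true interaction has the largest fitted |gamma|."""
    data = standardize(make_sim(seed=21, n=300, p=10))
    pen = PenaltySpec.lasso(data.p)
    lam = 0.05 * lambda_max(data, pen)
    model = fit_penalized(data, pen, lam, with_baseline=False)
    # conftest.make_sim puts gamma = -1 on biomarker index 1
    assert np.argmax(np.abs(model.gamma_hat)) == 1
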