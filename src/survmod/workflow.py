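"""End-to-end model development pipeline.

``develop_model`` chains the steps used throughout the package (and
re-run inside every bootstrap resample and every outer 2CV fold):

1. standardize the biomarkers;
2. for the adaptive lasso, compute weights from a cvl-tuned ridge pre-fit;
3. build the lambda grid from the weighted KKT ``lambda_max``;
4. select ``lambda`` by k1-fold cross-validated partial log-likelihood;
5. fit at the selected ``lambda`` (optionally refit unpenalized on the
   selected terms) and attach the Breslow baseline hazard.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .data import FittedCoxModel, Penalty, PenaltySpec, SurvivalDataset, standardize
from .penalized import (
    adaptive_weights,
    build_design,
    default_lambda_grid,
    default_ridge_grid,
    fit_penalized,
    lambda_max,
    refit_unpenalized,
)
from .tuning import CVReport, FoldAssignment, cvl_path, select_lambda

__all__ = ["ModelSpec", "develop_model"]


@dataclass(frozen=True)
class ModelSpec:
    """Configuration of the model-development pipeline."""

    penalty: Penalty = Penalty.ADAPTIVE_LASSO
    refit: bool = False
    n_lambda: int = 100
    lambda_min_ratio: float = 0.01
    ridge_grid_size: int = 6

    def label(self) -> str:
        name = Penalty(self.penalty).value
        return f"refit_{name}" if self.refit else name


def _treatment_only(data: SurvivalDataset, spec_pen: PenaltySpec) -> FittedCoxModel:
    """Fallback when no biomarker term has a finite penalty weight."""
    from ._cox import RiskSetEngine, newton_cox
    from .prediction import breslow_baseline

    design = build_design(data)
    free = np.flatnonzero(~design.penalized_mask)
    sub = RiskSetEngine(data.time, data.event, design.matrix[:, free])
    coefs = np.zeros(design.d)
    coefs[free] = newton_cox(engine=sub)
    alpha, clin, beta, gamma = design.split_coefs(coefs)
    model = FittedCoxModel(
        alpha_hat=alpha, beta_hat=beta, gamma_hat=gamma, clinical_hat=clin,
        penalty=spec_pen, train_standardization=data.standardization,
        biomarker_names=data.biomarker_names, clinical_names=data.clinical_names,
    )
    model.baseline = breslow_baseline(model, data)
    return model


def develop_model(
    data: SurvivalDataset,
    spec: ModelSpec | None = None,
    seed: int | None = 0,
    k1: int = 5,
    return_report: bool = False,
):
    """Run the full development pipeline on (raw or standardized) data."""
    if spec is None:
        spec = ModelSpec()
    data = standardize(data)
    data.require_fittable()
    penalty = Penalty(spec.penalty)
    folds = FoldAssignment.create(data, k=k1, seed=seed)

    if penalty is Penalty.NONE:
        model = fit_penalized(data, PenaltySpec.none(data.p), 0.0)
        return (model, None) if return_report else model

    if penalty is Penalty.RIDGE:
        grid = default_ridge_grid(data, spec.ridge_grid_size)
        pen = PenaltySpec.ridge(data.p)
        values = cvl_path(data, pen, grid, folds)
        lam = float(grid[int(np.argmax(values))])
        model = fit_penalized(data, pen, lam)
        report = CVReport(grid, values, lam, folds)
        return (model, report) if return_report else model

    if penalty is Penalty.ADAPTIVE_LASSO:
        pen = adaptive_weights(
            data, ridge_lambda_grid=default_ridge_grid(data, spec.ridge_grid_size),
            k1=k1, seed=seed,
        )
        # reuse the same folds for ridge tuning and lambda selection
        pen = replace(pen, lambda_grid=None)
    else:
        pen = PenaltySpec.lasso(data.p)

    try:
        lmax = lambda_max(data, pen)
    except ValueError:
        # every biomarker term excluded by the weight cap
        model = _treatment_only(data, pen)
        return (model, None) if return_report else model
    grid = default_lambda_grid(lmax * (1 + 1e-6), spec.n_lambda, spec.lambda_min_ratio)
    lam, report = select_lambda(data, pen, grid=grid, folds=folds)
    model = fit_penalized(data, pen, lam)
    if spec.refit:
        model = refit_unpenalized(model, data)
    return (model, report) if return_report else model
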