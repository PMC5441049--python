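"""Fitting the interaction Cox model under none/ridge/lasso/adaptive-lasso penalties.

The model for patient hazard is

    h(t | T, X) = h0(t) * exp(alpha*T + sum_j beta_j X_j + sum_j gamma_j X_j T)

with treatment ``T`` coded +/-0.5 and ``X`` standardized.  The penalized
partial log-likelihood is

    l_p = l(alpha, beta, gamma) - lambda * (sum_j theta_j |beta_j|
                                            + sum_j vartheta_j |gamma_j|)

(for the ridge penalty the absolute values are replaced by squares with the
same weights).  Treatment and clinical covariates are never penalized.

L1 solutions are computed with the coordinate-descent path solver of
scikit-survival (``CoxnetSurvivalAnalysis``); per-coefficient weights are
folded into the design by column rescaling, so arbitrary adaptive weights
are supported exactly.  Ridge and unpenalized fits use the damped Newton
solver in :mod:`survmod._cox`.  ``lambda`` is always expressed on the
partial-log-likelihood scale of the display above.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from ._cox import ConvergenceError, RiskSetEngine, lbfgs_ridge_cox, newton_cox
from .data import (
    WEIGHT_CAP,
    FittedCoxModel,
    Penalty,
    PenaltySpec,
    SurvivalDataset,
)

logger = logging.getLogger(__name__)

__all__ = [
    "DesignMatrix",
    "build_design",
    "cox_partial_loglik",
    "lambda_max",
    "default_lambda_grid",
    "fit_path",
    "fit_penalized",
    "adaptive_weights",
    "refit_unpenalized",
]


@dataclass
class DesignMatrix:
    """Columns ``[T, clinical..., X_1..X_p, X_1*T..X_p*T]`` plus penalty mask."""

    matrix: np.ndarray
    penalized_mask: np.ndarray  # bool, False exactly on T and clinical columns
    p: int
    q: int

    @property
    def d(self) -> int:
        return self.matrix.shape[1]

    def split_coefs(self, coefs: np.ndarray):
        """Split a design-order coefficient vector into (alpha, clinical, beta, gamma)."""
        q = self.q
        alpha = float(coefs[0])
        clin = coefs[1 : 1 + q] if q else None
        beta = coefs[1 + q : 1 + q + self.p]
        gamma = coefs[1 + q + self.p :]
        return alpha, clin, beta, gamma


def build_design(data: SurvivalDataset) -> DesignMatrix:
    """Assemble the interaction design from a standardized dataset.

    Interaction columns are the product of the *standardized* biomarkers
    with the +/-0.5 treatment code.
    """
    if data.standardization is None:
        raise ValueError("dataset must be standardized before building the design")
    X = data.biomarkers
    T = data.treatment[:, None]
    blocks = [data.treatment[:, None]]
    q = data.n_clinical
    if q:
        blocks.append(data.clinical)
    blocks.extend([X, X * T])
    mat = np.hstack(blocks)
    mask = np.ones(mat.shape[1], dtype=bool)
    mask[: 1 + q] = False
    return DesignMatrix(matrix=mat, penalized_mask=mask, p=data.p, q=q)


def cox_partial_loglik(data: SurvivalDataset, coefs) -> float:
    """Breslow partial log-likelihood of the interaction model at ``coefs``.

    ``coefs`` is in design order ``[alpha, clinical, beta, gamma]``.
    """
    data.require_fittable()
    design = build_design(data)
    coefs = np.asarray(coefs, dtype=float)
    if coefs.shape[0] != design.d:
        raise ValueError("coefficient vector does not match the design")
    return RiskSetEngine(data.time, data.event).loglik(design.matrix @ coefs)


# ---------------------------------------------------------------------------
# lambda grid
# ---------------------------------------------------------------------------


def _effective_weights(spec: PenaltySpec) -> np.ndarray:
    """(2p,) weights; entries >= WEIGHT_CAP are treated as +inf (excluded)."""
    w = spec.weights().copy()
    w[w >= WEIGHT_CAP] = np.inf
    return w


def effective_l1_weights(design: DesignMatrix, spec: PenaltySpec) -> np.ndarray:
    """Per-coefficient L1 weights on the design columns as given.

    The penalty acts on the raw (unrescaled) design columns: main effects
    are pre-standardized and interaction columns keep their natural
    +/-0.5-coding scale, so ``theta_j = vartheta_j = 1`` is the plain
    lasso exactly as written.
    """
    return _effective_weights(spec)


def _unpenalized_fit(design: DesignMatrix, engine: RiskSetEngine) -> np.ndarray:
    """Cox fit on the unpenalized columns only, zero elsewhere."""
    d = design.d
    free = np.flatnonzero(~design.penalized_mask)
    sub = RiskSetEngine(engine.time, engine.event, design.matrix[:, free])
    coefs = np.zeros(d)
    coefs[free] = newton_cox(engine=sub)
    return coefs


def lambda_max(data: SurvivalDataset, penalty: PenaltySpec) -> float:
    """Smallest lambda at which every penalized coefficient is zero.

    From the KKT conditions of the weighted L1 problem: with the
    unpenalized columns at their treatment(-and-clinical)-only Cox optimum,
    the penalized coefficients stay at zero iff
    ``lambda >= max_j |d l / d coef_j| / w_j``.
    """
    data.require_fittable()
    design = build_design(data)
    engine = RiskSetEngine(data.time, data.event, design.matrix)
    coefs0 = _unpenalized_fit(design, engine)
    grad = engine.gradient(coefs0)
    w = effective_l1_weights(design, penalty)
    with np.errstate(divide="ignore"):
        crit = np.abs(grad[design.penalized_mask]) / w
    crit = crit[np.isfinite(crit)]
    if crit.size == 0:
        raise ValueError("no penalized coefficient with finite weight")
    return float(crit.max())


def default_lambda_grid(lmax: float, n_lambda: int = 100, min_ratio: float = 0.01) -> np.ndarray:
    """Log-spaced decreasing grid from ``lmax`` down to ``min_ratio * lmax``."""
    return np.geomspace(lmax, min_ratio * lmax, n_lambda)


# ---------------------------------------------------------------------------
# path fitting
# ---------------------------------------------------------------------------


def fit_path(
    data: SurvivalDataset,
    penalty: PenaltySpec,
    lambdas,
    engine: RiskSetEngine | None = None,
) -> np.ndarray:
    """Coefficient path over a decreasing ``lambdas`` grid.

    Returns an array of shape ``(d, len(lambdas))`` in design order.  For
    L1 penalties the path is computed in one warm-started coordinate-descent
    sweep; for the ridge penalty a warm-started Newton fit is run per
    lambda; the ``none`` penalty ignores ``lambdas``.
    """
    data.require_fittable()
    lambdas = np.atleast_1d(np.asarray(lambdas, dtype=float))
    design = build_design(data)
    if engine is None:
        engine = RiskSetEngine(data.time, data.event, design.matrix)

    if penalty.penalty is Penalty.NONE:
        sub = RiskSetEngine(data.time, data.event, design.matrix)
        coef = newton_cox(engine=sub)
        return np.tile(coef[:, None], (1, lambdas.shape[0]))

    w = _effective_weights(penalty)
    if penalty.penalty is Penalty.RIDGE:
        return _ridge_path(data, design, w, lambdas)
    return _l1_path(data, design, w, lambdas)


def _ridge_path(data, design, w, lambdas) -> np.ndarray:
    full_w = np.zeros(design.d)
    full_w[design.penalized_mask] = w
    keep = np.isfinite(full_w)
    sub = RiskSetEngine(data.time, data.event, design.matrix[:, keep])
    out = np.zeros((design.d, lambdas.shape[0]))
    init = None
    order = np.argsort(lambdas)[::-1]  # largest penalty first for warm starts
    for k in order:
        coef = lbfgs_ridge_cox(sub, lambdas[k] * full_w[keep], init=init)
        init = coef
        out[keep, k] = coef
    return out


def _l1_path(data, design, w, lambdas) -> np.ndarray:
    from sksurv.linear_model import CoxnetSurvivalAnalysis
    from sksurv.util import Surv

    n = data.n
    full_w = np.full(design.d, np.inf)
    full_w[~design.penalized_mask] = 0.0
    full_w[design.penalized_mask] = w
    keep = np.isfinite(full_w)          # capped weights drop out of the fit
    cols = design.matrix[:, keep]
    wk = full_w[keep]
    # coxnet rescales penalty factors to sum to the column count; its
    # effective per-coefficient penalty is alpha * w_j * d / sum(w), so the
    # lambda of our objective (log-likelihood scale, per-coefficient weight
    # w_j) maps to alpha = lambda * sum(w) / (n * d)
    alphas = lambdas * wk.sum() / (n * cols.shape[1])
    y = Surv.from_arrays(event=data.event.astype(bool), time=data.time)
    m = lambdas.shape[0]
    coef = np.empty((cols.shape[1], m))

    # Above this sample's own KKT lambda_max every penalized coefficient is
    # exactly zero and the unpenalized columns sit at their restricted Cox
    # optimum; fill those grid columns analytically and run coordinate
    # descent only below (also avoids solver early-stops on the flat part).
    eng = RiskSetEngine(data.time, data.event, cols)
    free_cols = np.flatnonzero(wk == 0)
    base = np.zeros(cols.shape[1])
    base[free_cols] = newton_cox(
        engine=RiskSetEngine(data.time, data.event, cols[:, free_cols])
    )
    grad = eng.gradient(base)
    with np.errstate(divide="ignore"):
        crit = np.abs(grad) / np.where(wk > 0, wk, np.inf)
    lam_top = crit.max()
    head = lambdas >= lam_top
    coef[:, head] = base[:, None]

    done = int(head.sum())
    for _ in range(m + 1):
        if done >= m:
            break
        model = CoxnetSurvivalAnalysis(
            alphas=alphas[done:],
            l1_ratio=1.0,
            penalty_factor=wk,
            normalize=False,
            tol=1e-7,
            max_iter=200000,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(cols, y)
        got = model.coef_.shape[1]
        coef[:, done : done + got] = model.coef_
        done += got
    if done < m:
        raise ConvergenceError("coordinate descent did not cover the full lambda grid")
    out = np.zeros((design.d, m))
    out[keep] = coef
    return out


def fit_penalized(
    data: SurvivalDataset,
    penalty: PenaltySpec,
    lam: float,
    with_baseline: bool = True,
) -> FittedCoxModel:
    """Maximize the penalized partial log-likelihood at a single ``lam``."""
    coefs = fit_path(data, penalty, [lam])[:, 0]
    design = build_design(data)
    alpha, clin, beta, gamma = design.split_coefs(coefs)
    model = FittedCoxModel(
        alpha_hat=alpha,
        beta_hat=beta,
        gamma_hat=gamma,
        clinical_hat=clin,
        lambda_star=float(lam),
        penalty=penalty,
        train_standardization=data.standardization,
        biomarker_names=data.biomarker_names,
        clinical_names=data.clinical_names,
    )
    if with_baseline:
        from .prediction import breslow_baseline

        model.baseline = breslow_baseline(model, data)
    return model


def coefficient_path_frame(data: SurvivalDataset, penalty: PenaltySpec, lambdas) -> "pd.DataFrame":
    """Coefficient path as a table: lambda, nonzero count, coefficients.

    One row per grid value; suitable for delimited-text export.
    """
    import pandas as pd

    lambdas = np.atleast_1d(np.asarray(lambdas, dtype=float))
    coefs = fit_path(data, penalty, lambdas)
    design = build_design(data)
    names = (
        ["treatment"]
        + list(data.clinical_names or [])
        + list(data.biomarker_names)
        + [f"{b}:treatment" for b in data.biomarker_names]
    )
    out = pd.DataFrame(coefs.T, columns=names)
    out.insert(0, "lambda", lambdas)
    out.insert(1, "n_nonzero", (coefs[design.penalized_mask] != 0).sum(axis=0))
    return out


# ---------------------------------------------------------------------------
# adaptive weights
# ---------------------------------------------------------------------------


def default_ridge_grid(data: SurvivalDataset, n_lambda: int = 6) -> np.ndarray:
    """Ridge tuning grid, log-spaced and scaled with the number of events."""
    scale = max(data.n_events, 1)
    return np.geomspace(30.0, 0.03, n_lambda) * scale


def adaptive_weights(
    data: SurvivalDataset,
    ridge_lambda_grid=None,
    k1: int = 5,
    seed: int | None = 0,
) -> PenaltySpec:
    """Adaptive-lasso weights from a cross-validation-tuned ridge pre-fit.

    The interaction model is first fit under the ridge penalty with its own
    lambda chosen by the cross-validated partial log-likelihood (same fold
    count as the main tuning); the weights are the reciprocal magnitudes of
    the ridge coefficients, ``theta_j = 1/|beta_j^R|`` and
    ``vartheta_j = 1/|gamma_j^R|``, capped at :data:`~survmod.data.WEIGHT_CAP`
    (a capped coefficient is excluded from the L1 fit).
    """
    from .tuning import FoldAssignment, cvl_path

    data.require_fittable()
    if ridge_lambda_grid is None:
        ridge_lambda_grid = default_ridge_grid(data)
    ridge_lambda_grid = np.asarray(ridge_lambda_grid, dtype=float)
    ridge_spec = PenaltySpec.ridge(data.p)
    folds = FoldAssignment.create(data, k=k1, seed=seed)
    cvls = cvl_path(data, ridge_spec, ridge_lambda_grid, folds)
    best = int(np.argmax(cvls))
    coefs = fit_path(data, ridge_spec, [ridge_lambda_grid[best]])[:, 0]
    design = build_design(data)
    _, _, beta_r, gamma_r = design.split_coefs(coefs)
    with np.errstate(divide="ignore"):
        theta = np.minimum(1.0 / np.abs(beta_r), WEIGHT_CAP)
        vartheta = np.minimum(1.0 / np.abs(gamma_r), WEIGHT_CAP)
    return PenaltySpec.adaptive(theta, vartheta)


# ---------------------------------------------------------------------------
# refit
# ---------------------------------------------------------------------------


def refit_unpenalized(model: FittedCoxModel, data: SurvivalDataset) -> FittedCoxModel:
    """Re-estimate the selected coefficients in an unpenalized Cox model.

    The fit is restricted to treatment, clinical covariates and the
    biomarker terms with nonzero penalized estimates; every other
    coefficient is exactly zero.
    """
    data.require_fittable()
    design = build_design(data)
    sel = np.zeros(design.d, dtype=bool)
    sel[: 1 + design.q] = True
    q, p = design.q, design.p
    sel[1 + q : 1 + q + p] = model.beta_hat != 0
    sel[1 + q + p :] = model.gamma_hat != 0
    if sel.sum() > data.n / 2:
        logger.warning(
            "refit with %d selected columns for %d patients", sel.sum(), data.n
        )
    sub = RiskSetEngine(data.time, data.event, design.matrix[:, sel])
    coefs = np.zeros(design.d)
    coefs[sel] = newton_cox(engine=sub)
    alpha, clin, beta, gamma = design.split_coefs(coefs)
    refit = FittedCoxModel(
        alpha_hat=alpha,
        beta_hat=beta,
        gamma_hat=gamma,
        clinical_hat=clin,
        lambda_star=model.lambda_star,
        penalty=model.penalty,
        train_standardization=data.standardization,
        biomarker_names=data.biomarker_names,
        clinical_names=data.clinical_names,
    )
    from .prediction import breslow_baseline

    refit.baseline = breslow_baseline(refit, data)
    return refit
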