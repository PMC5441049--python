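"""Confidence intervals for expected survival probabilities.

Two approaches are implemented:

* **Analytic**: a normal approximation of the cumulative risk
  ``H_i(t) = H0(t) exp(pi_i)``.  Its variance combines the baseline-hazard
  variance with the coefficient covariance via the delta method; the
  coefficient covariance is the inverse Hessian of the (penalized) partial
  log-likelihood at the estimates, restricted to the active set
  (unpenalized columns plus nonzero penalized coefficients).  The interval
  is ``exp(-(H_i -/+ z * sd))``, clipped to [0, 1].

* **Non-parametric bootstrap**: patients are resampled with replacement
  and the *entire* development pipeline (standardization, adaptive
  weights, 1CV lambda selection, fit, Breslow baseline) is re-run on each
  resample, so selection variability propagates into the interval; the
  bounds are empirical percentiles (linear interpolation) of the
  per-patient replicate distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._cox import RiskSetEngine
from .data import FittedCoxModel, Penalty, SurvivalDataset
from .penalized import build_design

logger = logging.getLogger(__name__)

__all__ = ["analytic_ci", "bootstrap_ci", "BootstrapCIResult"]


def _active_columns(model: FittedCoxModel, design) -> np.ndarray:
    active = ~design.penalized_mask.copy()
    q, p = design.q, design.p
    active[1 + q : 1 + q + p] |= model.beta_hat != 0
    active[1 + q + p :] |= model.gamma_hat != 0
    return np.flatnonzero(active)


def analytic_ci(
    model: FittedCoxModel,
    train_data: SurvivalDataset,
    new_data: SurvivalDataset,
    t: float,
    level: float = 0.95,
):
    """Delta-method confidence bounds for S_i(t) of each new patient.

    ``train_data`` must be the dataset the model was fit on (it supplies
    the risk sets of the Breslow estimator).  Returns ``(lower, upper)``.
    """
    from .prediction import _model_scale_biomarkers, scores

    train_std = _ensure_std(model, train_data)
    design = build_design(train_std)
    engine = RiskSetEngine(train_std.time, train_std.event, design.matrix)
    coefs = model.coef_vector()
    eta_train = design.matrix @ coefs

    active = _active_columns(model, design)
    _, hess = RiskSetEngine(
        train_std.time, train_std.event, design.matrix[:, active]
    ).grad_hess(coefs[active])
    # L1 terms contribute nothing to the Hessian at nonzero coefficients;
    # a ridge penalty adds a diagonal 2*lambda*w term
    if model.penalty is not None and model.penalty.penalty is Penalty.RIDGE:
        w_full = np.zeros(design.d)
        w_full[design.penalized_mask] = model.penalty.weights()
        hess = hess - np.diag(2.0 * (model.lambda_star or 0.0) * w_full[active])
    info = -hess
    cond = np.linalg.cond(info)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            f"singular Hessian over the active set (condition number {cond:.3g})"
        )
    cov = np.linalg.inv(info)

    # Breslow sums on the training data
    g = engine.groups
    e = eta_train[g.order]
    shift = e.max()
    w = np.exp(e - shift)
    s0 = np.cumsum(w[::-1])[::-1] * np.exp(shift)
    Xa = design.matrix[:, active][g.order]
    s1 = np.cumsum((np.exp(e - shift)[:, None] * Xa)[::-1], axis=0)[::-1] * np.exp(shift)
    upto = g.start[g.time_sorted[g.start] <= t]
    d_k = g.n_events[g.time_sorted[g.start] <= t].astype(float)
    h0 = float(np.sum(d_k / s0[upto]))
    v_base = float(np.sum(d_k / s0[upto] ** 2))
    # sum_k d_k * S1(t_k)/S0(t_k)^2  (vector over active columns)
    s_term = (d_k / s0[upto] ** 2) @ s1[upto]

    new_std = _model_scale_biomarkers(model, new_data)
    _, _, pi = scores(model, new_std, new_data.treatment, new_data.clinical)
    rows = _design_rows(new_std, new_data, design)[:, active]
    h_i = h0 * np.exp(pi)
    b = np.exp(pi)[:, None] * (rows * h0 - s_term[None, :])
    var_h = np.exp(2.0 * pi) * v_base + np.einsum("ij,jk,ik->i", b, cov, b)
    sd = np.sqrt(np.maximum(var_h, 0.0))
    z = stats.norm.ppf(0.5 + level / 2.0)
    lower = np.exp(-(h_i + z * sd))
    upper = np.exp(-(h_i - z * sd))
    return np.clip(lower, 0.0, 1.0), np.clip(upper, 0.0, 1.0)


def _ensure_std(model: FittedCoxModel, data: SurvivalDataset) -> SurvivalDataset:
    """Training data on the model's biomarker scale."""
    from dataclasses import replace

    if data.standardization is not None:
        return data
    if model.train_standardization is None:
        raise ValueError("model carries no standardization metadata")
    return replace(
        data,
        biomarkers=model.train_standardization.apply(data.biomarkers),
        standardization=model.train_standardization,
    )


def _design_rows(X_std, data: SurvivalDataset, design) -> np.ndarray:
    blocks = [data.treatment[:, None]]
    if design.q:
        blocks.append(data.clinical)
    blocks.extend([X_std, X_std * data.treatment[:, None]])
    return np.hstack(blocks)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------


@dataclass
class BootstrapCIResult:
    lower: np.ndarray
    upper: np.ndarray
    replicates: np.ndarray  # (B, n_new) survival probabilities
    n_redrawn: int
    n_failed: int


def bootstrap_ci(
    data: SurvivalDataset,
    pipeline,
    new_data: SurvivalDataset,
    t: float,
    B: int = 200,
    level: float = 0.95,
    seed: int | None = 0,
    max_failure_fraction: float = 0.1,
) -> BootstrapCIResult:
    """Percentile-bootstrap CIs that re-run the whole fitting pipeline.

    ``pipeline`` is either a :class:`~survmod.workflow.ModelSpec` or any
    callable ``(dataset, seed) -> FittedCoxModel``; it is re-executed on
    each with-replacement resample of ``data`` so that standardization,
    adaptive-weight estimation and tuning-parameter selection all
    contribute their variability.  Resamples without events are redrawn.
    """
    from .prediction import predict_survival
    from .workflow import ModelSpec, develop_model

    if isinstance(pipeline, ModelSpec):
        spec = pipeline

        def pipeline(ds, s):  # noqa: F811 - deliberate shadowing
            return develop_model(ds, spec, seed=s)

    raw = data.unstandardized()
    rng = np.random.default_rng(seed)
    reps = np.full((B, new_data.n), np.nan)
    n_redrawn = n_failed = 0
    for b in range(B):
        for _ in range(100):
            idx = rng.integers(0, raw.n, size=raw.n)
            if raw.event[idx].sum() > 0:
                break
            n_redrawn += 1
            logger.info("bootstrap resample %d had no events; redrawn", b)
        sample = raw.subset(idx)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        try:
            model = pipeline(sample, sub_seed)
            reps[b] = predict_survival(model, new_data, t).survival
        except Exception as err:  # noqa: BLE001 - count and continue
            n_failed += 1
            logger.warning("bootstrap resample %d failed to fit: %s", b, err)
    if n_failed > max_failure_fraction * B:
        raise RuntimeError(
            f"{n_failed}/{B} bootstrap resamples failed to fit"
        )
    ok = ~np.isnan(reps).all(axis=1)
    theta = 1.0 - level
    lower = np.nanquantile(reps[ok], theta / 2.0, axis=0)
    upper = np.nanquantile(reps[ok], 1.0 - theta / 2.0, axis=0)
    return BootstrapCIResult(
        lower=lower, upper=upper, replicates=reps, n_redrawn=n_redrawn, n_failed=n_failed
    )
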