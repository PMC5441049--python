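"""Breslow baseline hazard and per-patient expected survival probabilities.

The expected survival probability at horizon ``t`` is

    S_i(t) = exp(-H0(t) * exp(pi_i)),

with ``H0`` the Breslow estimate of the cumulative baseline hazard on the
training data and ``pi_i`` the full linear predictor of the interaction
model.  The two summary scores are the prognostic score
``phi_i = sum_j beta_j X_ij`` and the treatment-effect modifying score
``eta_i = sum_j gamma_j X_ij``; note ``eta`` does not depend on the arm.
"""

from __future__ import annotations

import logging

import numpy as np

from ._cox import RiskSetEngine
from .data import (
    BaselineHazard,
    CIMethod,
    FittedCoxModel,
    PredictionResult,
    SurvivalDataset,
)

logger = logging.getLogger(__name__)

__all__ = [
    "breslow_baseline",
    "scores",
    "linear_predictor",
    "predict_survival",
    "survival_matrix",
]


def _model_scale_biomarkers(model: FittedCoxModel, data: SurvivalDataset) -> np.ndarray:
    """Biomarkers on the model's training scale.

    A dataset that has not been standardized is mapped with the training
    (center, scale); a standardized dataset is taken to be on the training
    scale already (this is the caller's contract for held-out folds).
    """
    if data.standardization is None:
        if model.train_standardization is None:
            return data.biomarkers
        return model.train_standardization.apply(data.biomarkers)
    return data.biomarkers


def scores(model: FittedCoxModel, X: np.ndarray, T, clinical=None):
    """Per-patient (phi, eta, pi) from standardized biomarkers ``X``.

    ``pi = alpha*T + clinical'z + phi + eta*T``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    T = np.asarray(T, dtype=float)
    if X.shape[1] != model.p:
        raise ValueError(f"expected {model.p} biomarker columns, got {X.shape[1]}")
    phi = X @ model.beta_hat
    eta = X @ model.gamma_hat
    pi = model.alpha_hat * T + phi + eta * T
    if model.clinical_hat is not None and model.clinical_hat.size:
        if clinical is None:
            raise ValueError("model has clinical coefficients but no clinical data given")
        pi = pi + np.atleast_2d(np.asarray(clinical, dtype=float)) @ model.clinical_hat
    return phi, eta, pi


def linear_predictor(model: FittedCoxModel, data: SurvivalDataset) -> np.ndarray:
    """Full linear predictor ``pi`` for every patient of a dataset."""
    X = _model_scale_biomarkers(model, data)
    return scores(model, X, data.treatment, data.clinical)[2]


def breslow_baseline(model: FittedCoxModel, data: SurvivalDataset) -> BaselineHazard:
    """Breslow estimator of the cumulative baseline hazard.

    ``H0(t) = sum_{event times t_k <= t} d_k / sum_{j at risk} exp(pi_j)``
    evaluated on the training data at the fitted coefficients; the baseline
    refers to a patient with standardized biomarkers 0 and treatment code 0
    (halfway between the arms).
    """
    data.require_fittable()
    eta = linear_predictor(model, data)
    times, d_h0 = RiskSetEngine(data.time, data.event).breslow(eta)
    return BaselineHazard(event_times=times, cum_hazard=np.cumsum(d_h0))


def _check_horizon(baseline: BaselineHazard, t: float) -> None:
    if t > baseline.final_time:
        logger.warning(
            "horizon %.3g beyond last event time %.3g; using last step value",
            t, baseline.final_time,
        )


def predict_survival(
    model: FittedCoxModel,
    data: SurvivalDataset,
    t: float,
    ci=None,
    ci_method: CIMethod = CIMethod.NONE,
) -> PredictionResult:
    """Expected survival probability at horizon ``t`` for each patient.

    Biomarkers are standardized with the *training* (center, scale) when
    the incoming dataset is unstandardized.  Optionally attaches
    pre-computed confidence bounds ``ci=(lower, upper)``.
    """
    if model.baseline is None:
        raise ValueError("model has no baseline hazard; fit it on training data first")
    _check_horizon(model.baseline, t)
    X = _model_scale_biomarkers(model, data)
    phi, eta, pi = scores(model, X, data.treatment, data.clinical)
    h = model.baseline.cum_at(t) * np.exp(pi)
    surv = np.exp(-h)
    lo = hi = None
    if ci is not None:
        lo, hi = (np.asarray(b, dtype=float) for b in ci)
    return PredictionResult(
        patient_id=data.patient_id,
        tau=float(t),
        survival=surv,
        prog_score=phi,
        mod_score=eta,
        linear_predictor=pi,
        ci_lower=lo,
        ci_upper=hi,
        ci_method=ci_method if ci is not None else CIMethod.NONE,
    )


def survival_matrix(model: FittedCoxModel, data: SurvivalDataset, times) -> np.ndarray:
    """``(n, len(times))`` matrix of S_i(t) for a grid of horizons."""
    if model.baseline is None:
        raise ValueError("model has no baseline hazard")
    times = np.asarray(times, dtype=float)
    pi = linear_predictor(model, data)
    h0 = model.baseline.cum_at(times)
    return np.exp(-np.exp(pi)[:, None] * h0[None, :])
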