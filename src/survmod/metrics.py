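"""IPCW predictive-accuracy metrics: Brier score, Uno's C and arm-specific ΔC.

Censoring is handled by inverse-probability-of-censoring weighting: the
weights come from the Kaplan-Meier estimate of the censoring distribution
(event indicator reversed).  All metrics are evaluated at a horizon
``tau`` (default 5 years elsewhere in the package).

The time-dependent Brier score follows the Graf estimator:

    Brier(t) = 1/n * sum_i [ S_i(t)^2 * I(t_i <= t, d_i = 1) / S_C(t_i)
                             + (1 - S_i(t))^2 * I(t_i > t) / S_C(t) ]

and is integrated over [0, tau] against the weight function
``W(t) = (1 - S(t)) / (1 - S(tau))`` with ``S`` the marginal Kaplan-Meier
of the event distribution (an exact Stieltjes sum over its jumps).

Uno's C compares pairs (i, i') with ``t_i < t_i'`` and ``t_i < tau``,
weighting by ``S_C(t_i)^-2``; tied risk scores contribute one half, so a
score-free (constant) model sits at C = 0.5.  ΔC is the absolute
difference of the within-arm C statistics of the treatment-effect
modifying score and measures interaction strength.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from lifelines import KaplanMeierFitter

from .data import SurvivalDataset

__all__ = [
    "CensoringSurvival",
    "MetricReport",
    "EvaluationMode",
    "censoring_km",
    "event_km",
    "brier",
    "integrated_brier",
    "uno_c",
    "delta_c",
    "evaluate_model",
]


class NoUsablePairsError(ValueError):
    """No (i, i') pair contributes to the concordance denominator."""


@dataclass
class CensoringSurvival:
    """Right-continuous step estimate of P(C > t)."""

    times: np.ndarray
    survival: np.ndarray

    def at(self, t) -> np.ndarray:
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="right")
        padded = np.concatenate([[1.0], self.survival])
        return padded[idx]


def _km(time, event_flag) -> CensoringSurvival:
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event_flag)
    sf = kmf.survival_function_
    times = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    keep = times > 0
    return CensoringSurvival(times=times[keep], survival=surv[keep])


def censoring_km(data: SurvivalDataset) -> CensoringSurvival:
    """Kaplan-Meier estimate of the censoring distribution.

    Censorings are treated as events and events as censorings; with no
    censored patient the estimate is identically one.
    """
    return _km(data.time, 1 - data.event)


def event_km(data: SurvivalDataset) -> CensoringSurvival:
    """Ordinary Kaplan-Meier of the event-time distribution."""
    return _km(data.time, data.event)


# ---------------------------------------------------------------------------
# Brier score
# ---------------------------------------------------------------------------


def brier(
    data: SurvivalDataset,
    survival_predictions,
    tau: float,
    cens: CensoringSurvival | None = None,
) -> float:
    """IPCW (Graf) Brier score of predicted survival probabilities at ``tau``."""
    s_hat = np.asarray(survival_predictions, dtype=float)
    if s_hat.shape != data.time.shape:
        raise ValueError("one prediction per patient is required")
    if ((s_hat < 0) | (s_hat > 1)).any():
        raise ValueError("survival predictions must lie in [0, 1]")
    if cens is None:
        cens = censoring_km(data)
    early_event = (data.time <= tau) & (data.event == 1)
    later = data.time > tau
    total = 0.0
    if early_event.any():
        g = cens.at(data.time[early_event])
        if (g <= 0).any():
            raise ValueError("censoring survival is zero for a contributing patient")
        total += float(np.sum(s_hat[early_event] ** 2 / g))
    if later.any():
        g_tau = float(cens.at(tau))
        if g_tau <= 0:
            raise ValueError("censoring survival is zero at the horizon")
        total += float(np.sum((1.0 - s_hat[later]) ** 2) / g_tau)
    return total / data.n


def integrated_brier(data: SurvivalDataset, survival_fn, tau: float) -> float:
    """Brier score integrated over [0, tau] against W(t) = (1-S(t))/(1-S(tau)).

    ``survival_fn(times)`` must return an ``(n, len(times))`` matrix of
    predicted survival probabilities.  The integral is the exact Stieltjes
    sum of ``Brier(t) dW(t)`` over the jump times of the marginal
    Kaplan-Meier estimate ``S``.
    """
    km = event_km(data)
    jump = km.times[km.times <= tau]
    if jump.size == 0:
        raise ValueError("no event occurs before the horizon")
    s_marg = km.at(jump)
    s_tau = float(km.at(tau))
    if s_tau >= 1.0:
        raise ValueError("marginal survival is one at the horizon")
    w = (1.0 - s_marg) / (1.0 - s_tau)
    dw = np.diff(np.concatenate([[0.0], w]))
    preds = np.asarray(survival_fn(jump), dtype=float)
    cens = censoring_km(data)
    values = np.array(
        [brier(data, preds[:, k], t, cens=cens) for k, t in enumerate(jump)]
    )
    return float(values @ dw)


# ---------------------------------------------------------------------------
# concordance
# ---------------------------------------------------------------------------


def uno_c(
    data: SurvivalDataset,
    risk_scores,
    tau: float,
    cens: CensoringSurvival | None = None,
) -> float:
    """Uno's IPCW C-statistic of a risk score at horizon ``tau``.

    Higher scores are taken to mean higher risk (earlier events).  Pairs
    with identical times are excluded; tied scores contribute one half.
    """
    s = np.asarray(risk_scores, dtype=float)
    if s.shape != data.time.shape:
        raise ValueError("one risk score per patient is required")
    if cens is None:
        cens = censoring_km(data)
    t, d = data.time, data.event
    usable = (d == 1) & (t < tau)
    if not usable.any():
        raise NoUsablePairsError("no event before the horizon")
    g = cens.at(t[usable])
    if (g <= 0).any():
        raise ValueError("censoring survival is zero for a contributing patient")
    w = g ** -2.0
    later = t[usable][:, None] < t[None, :]          # t_i < t_i'
    if not later.any():
        raise NoUsablePairsError("no comparable pair before the horizon")
    si = s[usable][:, None]
    conc = (si > s[None, :]).astype(float) + 0.5 * (si == s[None, :])
    num = float(np.sum(w[:, None] * later * conc))
    den = float(np.sum(w[:, None] * later))
    return num / den


def delta_c(
    data: SurvivalDataset,
    eta_scores,
    tau: float,
) -> float:
    """|C(eta; experimental arm) - C(eta; control arm)|, each within-arm."""
    eta = np.asarray(eta_scores, dtype=float)
    values = {}
    for arm in (0.5, -0.5):
        mask = data.treatment == arm
        if not mask.any():
            raise NoUsablePairsError(f"arm {arm:+.1f} is empty")
        sub = data.subset(np.flatnonzero(mask))
        values[arm] = uno_c(sub, eta[mask], tau)
    return abs(values[0.5] - values[-0.5])


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------


class EvaluationMode(str, Enum):
    TRAIN_1CV = "train_1cv"
    TRAIN_2CV = "train_2cv"
    EXTERNAL = "external"


@dataclass
class MetricReport:
    tau: float
    ibrier: float
    uno_c: float
    delta_c: float | None
    mode: EvaluationMode

    def to_dict(self) -> dict:
        return {
            "tau": self.tau,
            "ibrier": self.ibrier,
            "uno_c": self.uno_c,
            "delta_c": self.delta_c,
            "mode": EvaluationMode(self.mode).value,
        }


def evaluate_model(
    model,
    data: SurvivalDataset,
    tau: float,
    mode: EvaluationMode = EvaluationMode.EXTERNAL,
) -> MetricReport:
    """iBrier, C and ΔC of a fitted model on an evaluation dataset."""
    from .prediction import _model_scale_biomarkers, scores, survival_matrix

    X = _model_scale_biomarkers(model, data)
    _, eta, pi = scores(model, X, data.treatment, data.clinical)
    ib = integrated_brier(data, lambda ts: survival_matrix(model, data, ts), tau)
    c = uno_c(data, pi, tau)
    try:
        dc = delta_c(data, eta, tau)
    except NoUsablePairsError:
        dc = None
    return MetricReport(tau=tau, ibrier=ib, uno_c=c, delta_c=dc, mode=mode)
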