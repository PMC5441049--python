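"""Synthetic randomized-trial generator with biomarker-by-treatment effects.

Data are generated from the proportional-hazards model

    h(t | T, x) = lambda0 * exp(alpha*T + beta'x + gamma'x*T),

with constant baseline hazard ``lambda0 = -ln(S0(tau))/tau`` calibrated so
that a baseline patient (x = 0) has survival ``S0`` at the horizon ``tau``
(defaults: S0 = 0.77 at tau = 5 years).  Treatment is assigned +/-0.5 with
probability one half.  Biomarkers are unit-variance Gaussians with an
AR(1) correlation of 0.8^|j-j'| inside consecutive 25-marker blocks and
independence across blocks.

Censoring is exponential with a single hazard calibrated once so that the
*complete-null* configuration reaches the target censoring proportion
(default 72%); the same censoring hazard is reused unchanged in every
scenario, so arm-specific censoring rates under nonzero treatment effects
(e.g. 62%/80% with alpha = -0.8) emerge endogenously.

Six standard scenarios are provided:

1. complete null; 2. treatment effect only (alpha = -0.8);
3. 20 prognostic markers, beta_j ~ U(-0.20, -0.05);
4. 15 treatment-effect modifiers, gamma_j ~ U(-0.40, -0.10);
5. scenario 4 plus alpha = -0.8; 6. scenario 5 plus 20 prognostic markers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from ._cox import RiskSetEngine, newton_cox
from .data import FittedCoxModel, PenaltySpec, SurvivalDataset, standardize
from .penalized import build_design

__all__ = [
    "ScenarioSpec",
    "EffectRealization",
    "scenario",
    "generate_biomarkers",
    "draw_effects",
    "calibrate_censoring",
    "generate_survival",
    "generate_dataset",
    "generate_pair",
    "theoretical_survival",
    "oracle_model",
]


@dataclass(frozen=True)
class ScenarioSpec:
    """Full parameterization of one simulation scenario."""

    scenario_id: int = 1
    n: int = 1500
    p: int = 500
    block_size: int = 25
    rho: float = 0.8
    alpha: float = 0.0
    n_prog: int = 0
    prog_range: tuple[float, float] = (-0.20, -0.05)
    n_mod: int = 0
    mod_range: tuple[float, float] = (-0.40, -0.10)
    S0_tau: float = 0.77
    tau: float = 5.0
    censor_rate_target: float = 0.72

    def __post_init__(self):
        if self.n_prog + self.n_mod > self.p:
            raise ValueError("more active markers than biomarkers")
        for lo, hi in (self.prog_range, self.mod_range):
            if lo >= hi:
                raise ValueError("effect ranges must be (lo, hi) with lo < hi")

    @property
    def baseline_hazard(self) -> float:
        """Constant event hazard of a baseline patient: -ln(S0)/tau."""
        return -math.log(self.S0_tau) / self.tau


_SCENARIOS = {
    1: dict(alpha=0.0, n_prog=0, n_mod=0),
    2: dict(alpha=-0.8, n_prog=0, n_mod=0),
    3: dict(alpha=0.0, n_prog=20, n_mod=0),
    4: dict(alpha=0.0, n_prog=0, n_mod=15),
    5: dict(alpha=-0.8, n_prog=0, n_mod=15),
    6: dict(alpha=-0.8, n_prog=20, n_mod=15),
}


def scenario(scenario_id: int, **overrides) -> ScenarioSpec:
    """The six standard scenarios, with optional overrides (n, p, ...)."""
    if scenario_id not in _SCENARIOS:
        raise ValueError("scenario_id must be in 1..6")
    kw = dict(_SCENARIOS[scenario_id])
    kw.update(overrides)
    return ScenarioSpec(scenario_id=scenario_id, **kw)


@dataclass
class EffectRealization:
    """One drawn truth (alpha, beta, gamma) for a replication."""

    alpha: float
    beta: np.ndarray
    gamma: np.ndarray

    @property
    def prognostic_set(self) -> np.ndarray:
        return np.flatnonzero(self.beta != 0)

    @property
    def modifier_set(self) -> np.ndarray:
        return np.flatnonzero(self.gamma != 0)


# ---------------------------------------------------------------------------
# biomarkers
# ---------------------------------------------------------------------------


def _ar1_cholesky(size: int, rho: float) -> np.ndarray:
    idx = np.arange(size)
    corr = rho ** np.abs(idx[:, None] - idx[None, :])
    return np.linalg.cholesky(corr)


def generate_biomarkers(n, p, block_size=25, rho=0.8, seed=None, rng=None) -> np.ndarray:
    """Unit-variance Gaussian markers, block-AR(1) correlated.

    Within a block of ``block_size`` consecutive columns,
    ``corr(X_j, X_j') = rho^|j-j'|``; distinct blocks are independent.  A
    shorter trailing block is allowed.
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    Z = rng.standard_normal((n, p))
    if rho == 0:
        return Z
    out = np.empty_like(Z)
    chol_full = _ar1_cholesky(min(block_size, p), rho)
    for start in range(0, p, block_size):
        stop = min(start + block_size, p)
        L = chol_full if stop - start == chol_full.shape[0] else _ar1_cholesky(stop - start, rho)
        out[:, start:stop] = Z[:, start:stop] @ L.T
    return out


# ---------------------------------------------------------------------------
# effects
# ---------------------------------------------------------------------------


def draw_effects(spec: ScenarioSpec, seed=None, rng=None) -> EffectRealization:
    """Draw one (alpha, beta, gamma) truth for the scenario.

    The active positions are drawn uniformly at random (without
    replacement) among the ``p`` markers, so chance same-block pairs carry
    the block correlation into the true scores — the variance a random
    biomarker panel would actually have; the prognostic and modifier sets
    are always disjoint.  Effect magnitudes are then uniform draws from
    the stated (lo, hi) ranges.  Everything derives from the supplied
    seed/generator, so a truth draw is exactly reproducible.
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    beta = np.zeros(spec.p)
    gamma = np.zeros(spec.p)
    n_active = spec.n_prog + spec.n_mod
    pos = rng.choice(spec.p, size=n_active, replace=False)
    prog, mod = pos[: spec.n_prog], pos[spec.n_prog :]
    if spec.n_prog:
        beta[prog] = rng.uniform(*spec.prog_range, size=spec.n_prog)
    if spec.n_mod:
        gamma[mod] = rng.uniform(*spec.mod_range, size=spec.n_mod)
    return EffectRealization(alpha=spec.alpha, beta=beta, gamma=gamma)


# ---------------------------------------------------------------------------
# censoring and survival times
# ---------------------------------------------------------------------------


def calibrate_censoring(spec: ScenarioSpec, tol: float = 1e-4) -> float:
    """Exponential censoring hazard hitting the complete-null target rate.

    Under the complete null every patient's event hazard is the constant
    ``lambda0``, so with censoring hazard ``c`` the expected censoring
    proportion is ``c / (lambda0 + c)``; the hazard solving this for the
    target is found by one-dimensional root finding.  The value depends
    only on (S0, tau, target) and is reused unchanged across scenarios.
    """
    target = spec.censor_rate_target
    if target < 0 or target >= 1:
        raise ValueError("censoring target must be in [0, 1)")
    if target == 0:
        return 0.0
    lam0 = spec.baseline_hazard

    def rate(c):
        return c / (lam0 + c) - target

    hi = lam0
    while rate(hi) < 0:
        hi *= 2
    return float(brentq(rate, 0.0, hi, xtol=tol * lam0))


def generate_survival(
    X: np.ndarray,
    T: np.ndarray,
    effects: EffectRealization,
    spec: ScenarioSpec,
    seed=None,
    rng=None,
    censor_hazard: float | None = None,
):
    """Draw observed times and event flags given covariates and a truth.

    Event times are exponential with hazard
    ``lambda0 * exp(alpha*T + beta'x + gamma'x*T)`` (inverse transform);
    censoring times are independent exponentials with the calibrated
    hazard; the observation is the earlier of the two.
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    if censor_hazard is None:
        censor_hazard = calibrate_censoring(spec)
    lp = effects.alpha * T + X @ effects.beta + (X @ effects.gamma) * T
    rate = spec.baseline_hazard * np.exp(lp)
    t_event = rng.exponential(1.0 / rate)
    if censor_hazard > 0:
        t_cens = rng.exponential(1.0 / censor_hazard, size=t_event.shape)
    else:
        t_cens = np.full_like(t_event, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return time, event


def generate_dataset(
    spec: ScenarioSpec,
    seed=None,
    rng=None,
    effects: EffectRealization | None = None,
    censor_hazard: float | None = None,
) -> tuple[SurvivalDataset, EffectRealization]:
    """One full dataset plus its truth; same seed, byte-identical output."""
    rng = np.random.default_rng(seed) if rng is None else rng
    if effects is None:
        effects = draw_effects(spec, rng=rng)
    X = generate_biomarkers(spec.n, spec.p, spec.block_size, spec.rho, rng=rng)
    T = np.where(rng.random(spec.n) < 0.5, 0.5, -0.5)
    time, event = generate_survival(
        X, T, effects, spec, rng=rng, censor_hazard=censor_hazard
    )
    data = SurvivalDataset(time=time, event=event, treatment=T, biomarkers=X)
    return data, effects


def generate_pair(
    spec: ScenarioSpec, seed=None
) -> tuple[SurvivalDataset, SurvivalDataset, EffectRealization]:
    """A training set and its validation twin (same truth, fresh patients)."""
    rng = np.random.default_rng(seed)
    censor_hazard = calibrate_censoring(spec)
    train, effects = generate_dataset(spec, rng=rng, censor_hazard=censor_hazard)
    valid, _ = generate_dataset(spec, rng=rng, effects=effects, censor_hazard=censor_hazard)
    return train, valid, effects


def theoretical_survival(
    effects: EffectRealization,
    spec: ScenarioSpec,
    X: np.ndarray,
    T: np.ndarray,
    t: float,
) -> np.ndarray:
    """True survival probability S_i(t) under the generating model."""
    lp = effects.alpha * np.asarray(T) + X @ effects.beta + (X @ effects.gamma) * np.asarray(T)
    return np.exp(-spec.baseline_hazard * t * np.exp(lp))


# ---------------------------------------------------------------------------
# oracle model
# ---------------------------------------------------------------------------


def oracle_model(train: SurvivalDataset, effects: EffectRealization) -> FittedCoxModel:
    """Unpenalized Cox fit on the truly active terms of the simulation.

    Columns: treatment, the main effects of every truly related biomarker
    (nonzero beta or gamma) and the interactions of the true modifiers.
    """
    from .prediction import breslow_baseline

    data = standardize(train)
    data.require_fittable()
    design = build_design(data)
    p, q = design.p, design.q
    main_set = np.flatnonzero((effects.beta != 0) | (effects.gamma != 0))
    sel = np.zeros(design.d, dtype=bool)
    sel[: 1 + q] = True
    sel[1 + q + main_set] = True
    sel[1 + q + p + effects.modifier_set] = True
    sub = RiskSetEngine(data.time, data.event, design.matrix[:, sel])
    coefs = np.zeros(design.d)
    coefs[sel] = newton_cox(engine=sub)
    alpha, clin, beta, gamma = design.split_coefs(coefs)
    model = FittedCoxModel(
        alpha_hat=alpha,
        beta_hat=beta,
        gamma_hat=gamma,
        clinical_hat=clin,
        penalty=PenaltySpec.none(p),
        train_standardization=data.standardization,
        biomarker_names=data.biomarker_names,
        clinical_names=data.clinical_names,
    )
    model.baseline = breslow_baseline(model, data)
    return model
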