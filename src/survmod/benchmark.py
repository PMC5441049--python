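"""Simulation experiments: operating characteristics of the full pipeline.

``run_experiment`` replicates the complete workflow — generate a training
set and its validation twin, develop a model (per penalty method),
validate internally (2CV) and externally, predict expected survival
probabilities and construct confidence intervals — and summarizes:

* predictive accuracy (iBrier, Uno's C, ΔC) per evaluation mode
  (training 1CV, training 2CV, validation of the selected model,
  validation of the oracle model);
* accuracy of the survival-probability point estimates via mean bias (MB)
  and standard error (SE), for the pointwise and the spline-smoothed
  strategies;
* empirical coverage probability (CP) of analytic and bootstrap 95%
  confidence intervals.

All per-replication rows are retained so the aggregates can be recomputed
exactly from the persisted table.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data import standardize
from .metrics import EvaluationMode, delta_c, evaluate_model, integrated_brier, uno_c
from .prediction import predict_survival
from .simulator import (
    EffectRealization,
    ScenarioSpec,
    calibrate_censoring,
    generate_dataset,
    generate_pair,
    oracle_model,
    theoretical_survival,
)
from .tuning import double_cv_scores
from .uncertainty import analytic_ci, bootstrap_ci
from .visualization import fit_constrained_spline, prognostic_groups, scale_eta
from .workflow import ModelSpec, develop_model

logger = logging.getLogger(__name__)

__all__ = [
    "mean_bias",
    "standard_error",
    "coverage",
    "ExperimentConfig",
    "SimulationResult",
    "run_experiment",
    "aggregate_rows",
]


def mean_bias(estimates, truths) -> float:
    """Mean of (estimated - true) survival probability over patients."""
    est = np.asarray(estimates, dtype=float)
    tru = np.asarray(truths, dtype=float)
    if est.shape != tru.shape:
        raise ValueError("estimates and truths must be aligned")
    return float(np.mean(est - tru))


def standard_error(estimates, expected) -> float:
    """sqrt( sum (estimate_i - E[estimate_i])^2 / (n-1) ).

    ``expected`` supplies the per-patient expectation E[S_i(tau)]; in the
    default (per-replication cohort) mode of ``run_experiment`` this is
    the true survival probability shifted by the replication's mean bias,
    so SE measures the spread of the estimation error around its mean.
    """
    est = np.asarray(estimates, dtype=float)
    exp_ = np.asarray(expected, dtype=float)
    if est.shape != exp_.shape:
        raise ValueError("estimates and expectations must be aligned")
    if est.size < 2:
        raise ValueError("at least two patients are required")
    return float(np.sqrt(np.sum((est - exp_) ** 2) / (est.size - 1)))


def coverage(lower, upper, truths) -> float:
    """Fraction of patients whose true S_i(tau) lies inside the interval."""
    lo = np.asarray(lower, dtype=float)
    hi = np.asarray(upper, dtype=float)
    tru = np.asarray(truths, dtype=float)
    if not (lo.shape == hi.shape == tru.shape):
        raise ValueError("interval bounds and truths must be aligned")
    if (lo > hi + 1e-12).any():
        raise ValueError("malformed intervals (lower > upper)")
    return float(np.mean((lo <= tru) & (tru <= hi)))


# ---------------------------------------------------------------------------
# experiment orchestration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExperimentConfig:
    """Resolved settings of one simulation experiment."""

    scenario: ScenarioSpec
    methods: tuple[ModelSpec, ...] = (ModelSpec(),)
    reps: int = 25
    tau: float = 5.0
    do_2cv: bool = False
    ci: str = "none"              # none | analytic | bootstrap | both
    B: int = 200
    n_ci_patients: int = 100
    spline: bool = True
    se_mode: str = "cohort"       # cohort | patient_mean
    share_truth: bool = False     # fixed truth + validation cohort across reps

    def __post_init__(self):
        if self.ci not in ("none", "analytic", "bootstrap", "both"):
            raise ValueError("ci must be none/analytic/bootstrap/both")
        if self.se_mode == "patient_mean" and not self.share_truth:
            raise ValueError("patient_mean SE requires share_truth=True")


@dataclass
class SimulationResult:
    config: ExperimentConfig
    seed: int
    rows: pd.DataFrame           # one row per (replication, method)
    aggregates: pd.DataFrame     # means across replications per method
    n_failed: int = 0

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.rows.to_csv(out / "replicates.csv", index=False)
        self.aggregates.to_csv(out / "aggregates.csv")
        manifest = {
            "seed": self.seed,
            "n_failed": self.n_failed,
            "config": _config_dict(self.config),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))


def _config_dict(config: ExperimentConfig) -> dict:
    doc = asdict(config)
    doc["methods"] = [m.label() for m in config.methods]
    doc["scenario"] = asdict(config.scenario)
    return doc


def _smooth_per_patient(x, values, groups, min_points: int = 5) -> np.ndarray:
    """Spline-smoothed value at each patient's own abscissa, per group.

    Falls back to the group mean when the abscissa is degenerate (e.g. a
    model with no modifying component) or the group is too small.
    """
    out = np.empty_like(np.asarray(values, dtype=float))
    x = np.asarray(x, dtype=float)
    values = np.asarray(values, dtype=float)
    for grp in np.unique(groups):
        m = groups == grp
        if m.sum() >= min_points and np.ptp(x[m]) > 0:
            try:
                out[m] = fit_constrained_spline(x[m], np.clip(values[m], 0, 1))(x[m])
                continue
            except ValueError:
                pass
        out[m] = np.clip(values[m].mean(), 0.0, 1.0)
    return out


def _spline_groups(eta_scaled, phi, treatment) -> np.ndarray:
    """Group key combining prognostic risk group and arm."""
    if np.ptp(phi) == 0:
        risk = np.ones(phi.shape, dtype=int)
    else:
        risk = prognostic_groups(phi)
    return risk * 10 + (np.asarray(treatment) > 0).astype(int)


def _try_scale_eta(eta_train, eta_new):
    try:
        return scale_eta(eta_train, eta_new)
    except ValueError:
        return np.zeros(np.asarray(eta_new, dtype=float).shape)


def run_experiment(config: ExperimentConfig, seed: int = 0) -> SimulationResult:
    """Replicate the full pipeline and aggregate its operating characteristics."""
    sc = config.scenario
    root = np.random.SeedSequence(seed)
    rep_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(config.reps + 1)]
    censor_hazard = calibrate_censoring(sc)

    shared_effects = shared_valid = None
    if config.share_truth:
        rng0 = np.random.default_rng(rep_seeds[-1])
        from .simulator import draw_effects

        shared_effects = draw_effects(sc, rng=rng0)
        shared_valid, _ = generate_dataset(
            sc, rng=rng0, effects=shared_effects, censor_hazard=censor_hazard
        )

    rows: list[dict] = []
    s_hat_store: dict[str, list[np.ndarray]] = {m.label(): [] for m in config.methods}
    n_failed = 0
    for r in range(config.reps):
        rng = np.random.default_rng(rep_seeds[r])
        if config.share_truth:
            effects, valid = shared_effects, shared_valid
            train, _ = generate_dataset(
                sc, rng=rng, effects=effects, censor_hazard=censor_hazard
            )
        else:
            train, effects = generate_dataset(sc, rng=rng, censor_hazard=censor_hazard)
            valid, _ = generate_dataset(
                sc, rng=rng, effects=effects, censor_hazard=censor_hazard
            )
        truth = theoretical_survival(
            effects, sc, valid.biomarkers, valid.treatment, config.tau
        )
        oracle = oracle_model(train, effects)
        oracle_metrics = evaluate_model(oracle, valid, config.tau)
        ci_idx = np.random.default_rng(rep_seeds[r] ^ 0x5EED).choice(
            valid.n, size=min(config.n_ci_patients, valid.n), replace=False
        )
        for method in config.methods:
            try:
                row = _run_one(
                    config, method, train, valid, truth, oracle_metrics,
                    ci_idx, rep_seeds[r],
                )
            except Exception as err:  # noqa: BLE001
                n_failed += 1
                logger.warning("replicate %d method %s failed: %s", r, method.label(), err)
                continue
            row["rep"] = r
            row["seed"] = rep_seeds[r]
            rows.append(row)
            if "s_hat" in row:
                s_hat_store[method.label()].append(row.pop("s_hat"))
    if n_failed > 0.1 * config.reps * len(config.methods):
        raise RuntimeError(f"{n_failed} replicate fits failed")
    frame = pd.DataFrame(rows)
    if config.se_mode == "patient_mean":
        frame = _patient_mean_se(frame, s_hat_store)
    agg = aggregate_rows(frame)
    return SimulationResult(config=config, seed=seed, rows=frame,
                            aggregates=agg, n_failed=n_failed)


def _run_one(config, method, train, valid, truth, oracle_metrics, ci_idx, rep_seed):
    tau = config.tau
    model = develop_model(train, method, seed=rep_seed)
    train_std = standardize(train)
    m_train = evaluate_model(model, train_std, tau, EvaluationMode.TRAIN_1CV)
    m_valid = evaluate_model(model, valid, tau, EvaluationMode.EXTERNAL)
    row = {
        "method": method.label(),
        "ibrier_train_1cv": m_train.ibrier,
        "c_train_1cv": m_train.uno_c,
        "dc_train_1cv": m_train.delta_c,
        "ibrier_validation": m_valid.ibrier,
        "c_validation": m_valid.uno_c,
        "dc_validation": m_valid.delta_c,
        "ibrier_oracle": oracle_metrics.ibrier,
        "c_oracle": oracle_metrics.uno_c,
        "dc_oracle": oracle_metrics.delta_c,
    }

    if config.do_2cv:
        dcv = double_cv_scores(train, method, seed=rep_seed)
        row["c_train_2cv"] = uno_c(train, dcv.linear_predictor, tau)
        try:
            row["dc_train_2cv"] = delta_c(train, dcv.mod_score, tau)
        except ValueError:
            row["dc_train_2cv"] = np.nan
        row["ibrier_train_2cv"] = integrated_brier(
            train, lambda ts: dcv.survival_matrix(train, ts), tau
        )

    # -- survival-probability accuracy on the validation cohort --------
    pred = predict_survival(model, valid, tau)
    s_hat = pred.survival
    row["mb_pointwise"] = mean_bias(s_hat, truth)
    row["se_pointwise"] = standard_error(s_hat, truth + row["mb_pointwise"])
    row["s_hat"] = s_hat

    X_train = standardize(train).biomarkers
    eta_train = X_train @ model.gamma_hat
    eta_scaled = _try_scale_eta(eta_train, pred.mod_score)
    grp = _spline_groups(eta_scaled, pred.prog_score, valid.treatment)
    s_spline = _smooth_per_patient(eta_scaled, s_hat, grp)
    row["mb_spline"] = mean_bias(s_spline, truth)
    row["se_spline"] = standard_error(s_spline, truth + row["mb_spline"])

    # -- confidence intervals -------------------------------------------
    if config.ci != "none":
        sub = valid.subset(ci_idx)
        tr_sub, gr_sub = truth[ci_idx], grp[ci_idx]
        x_sub = eta_scaled[ci_idx]
        if config.ci in ("analytic", "both"):
            lo, hi = analytic_ci(model, standardize(train), sub, tau)
            row["cp_pointwise_analytic"] = coverage(lo, hi, tr_sub)
            row["cp_spline_analytic"] = _spline_cp(x_sub, lo, hi, gr_sub, tr_sub)
        if config.ci in ("bootstrap", "both"):
            boot = bootstrap_ci(
                train, method, sub, tau, B=config.B, seed=rep_seed ^ 0xB00
            )
            row["cp_pointwise_bootstrap"] = coverage(boot.lower, boot.upper, tr_sub)
            row["cp_spline_bootstrap"] = _spline_cp(
                x_sub, boot.lower, boot.upper, gr_sub, tr_sub
            )
    return row


def _spline_cp(x, lower, upper, groups, truths) -> float:
    lo_s = _smooth_per_patient(x, lower, groups)
    hi_s = _smooth_per_patient(x, upper, groups)
    hi_s = np.maximum(lo_s, hi_s)
    return coverage(lo_s, hi_s, truths)


def _patient_mean_se(frame: pd.DataFrame, store: dict) -> pd.DataFrame:
    """SE against the patient-level mean estimate across replications."""
    frame = frame.copy()
    for label, mats in store.items():
        if len(mats) < 2:
            continue
        mat = np.vstack(mats)               # reps x n patients (fixed cohort)
        expected = mat.mean(axis=0)
        ses = [standard_error(m, expected) for m in mat]
        frame.loc[frame["method"] == label, "se_pointwise"] = ses
    return frame


def aggregate_rows(rows: pd.DataFrame) -> pd.DataFrame:
    """Mean of every numeric column per method (recomputable from rows)."""
    keep = rows.drop(columns=["rep", "seed"], errors="ignore")
    return keep.groupby("method").mean(numeric_only=True)
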