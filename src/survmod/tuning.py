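"""Tuning-parameter selection (1CV) and double cross-validation (2CV).

The penalty parameter ``lambda`` is chosen by maximizing the
Verweij-van Houwelingen cross-validated partial log-likelihood

    cvl(lambda) = sum_k [ l(theta_hat_{-k}; all data)
                          - l(theta_hat_{-k}; data without fold k) ],

where ``theta_hat_{-k}`` is the penalized fit without fold ``k`` at the
given ``lambda``.  Because the same coefficients appear in both terms, the
penalty contribution cancels and plain partial log-likelihoods are
evaluated.

Double cross-validation mimics an external validation: each patient's
prediction scores come from a model whose standardization, adaptive
weights and tuning parameter were all computed without that patient's
fold.  The 2CV scores are used only for predictive-accuracy metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._cox import RiskSetEngine
from .data import PenaltySpec, SurvivalDataset
from .penalized import build_design, default_lambda_grid, fit_path, lambda_max

__all__ = [
    "FoldAssignment",
    "CVReport",
    "cvl",
    "cvl_path",
    "select_lambda",
    "DoubleCVResult",
    "double_cv_scores",
]


@dataclass(frozen=True)
class FoldAssignment:
    """Partition of patients into ``k`` folds, optionally event-stratified."""

    k: int
    fold_of: np.ndarray
    stratified_on_events: bool = True

    @classmethod
    def create(
        cls,
        data: SurvivalDataset | int,
        k: int = 5,
        seed: int | None = 0,
        stratify_on_events: bool = True,
    ) -> "FoldAssignment":
        """Random seeded fold assignment.

        With stratification, events and censored patients are dealt to the
        folds separately (round-robin after shuffling) so that every fold
        receives a proportional number of events.
        """
        if k < 2:
            raise ValueError("at least two folds are required")
        rng = np.random.default_rng(seed)
        if isinstance(data, SurvivalDataset):
            n = data.n
            event = data.event.astype(bool)
        else:
            n = int(data)
            event = None
            stratify_on_events = False
        fold_of = np.empty(n, dtype=int)
        if stratify_on_events:
            for grp in (np.flatnonzero(event), np.flatnonzero(~event)):
                perm = rng.permutation(grp)
                fold_of[perm] = np.arange(perm.size) % k
        else:
            fold_of[rng.permutation(n)] = np.arange(n) % k
        return cls(k=k, fold_of=fold_of, stratified_on_events=stratify_on_events)

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of != fold)


@dataclass
class CVReport:
    """Grid, criterion values and the selected tuning parameter."""

    lambda_grid: np.ndarray
    cvl_values: np.ndarray
    lambda_star: float
    folds: FoldAssignment

    def to_dict(self) -> dict:
        """JSON-serializable summary of the selection."""
        return {
            "lambda_grid": np.asarray(self.lambda_grid).tolist(),
            "cvl_values": np.asarray(self.cvl_values).tolist(),
            "lambda_star": self.lambda_star,
            "k": self.folds.k,
            "fold_of": self.folds.fold_of.tolist(),
        }


def cvl_path(
    data: SurvivalDataset,
    penalty: PenaltySpec,
    lambdas,
    folds: FoldAssignment,
) -> np.ndarray:
    """Cross-validated partial log-likelihood for each ``lambda`` of a grid.

    One warm-started path fit per fold complement; the criterion is then
    evaluated for all grid values at once.
    """
    data.require_fittable()
    lambdas = np.atleast_1d(np.asarray(lambdas, dtype=float))
    design_full = build_design(data)
    eng_full = RiskSetEngine(data.time, data.event)
    out = np.zeros(lambdas.shape[0])
    for k in range(folds.k):
        test_idx = folds.test_indices(k)
        if test_idx.size == 0:
            continue  # empty fold contributes zero by definition
        sub = data.subset(folds.train_indices(k))
        try:
            coefs = fit_path(sub, penalty, lambdas)
        except Exception as err:  # noqa: BLE001 - annotate the failing fold
            raise RuntimeError(f"cross-validation fit failed for fold {k}") from err
        eng_sub = RiskSetEngine(sub.time, sub.event)
        design_sub = build_design(sub)
        out += eng_full.loglik_many(design_full.matrix @ coefs)
        out -= eng_sub.loglik_many(design_sub.matrix @ coefs)
    return out


def cvl(
    data: SurvivalDataset,
    penalty: PenaltySpec,
    lam: float,
    folds: FoldAssignment,
) -> float:
    """cvl criterion at a single ``lambda``."""
    return float(cvl_path(data, penalty, [lam], folds)[0])


def argmax_sparser(values) -> int:
    """Index of the maximal cvl; exact ties break to the smallest index.

    Grids are stored in decreasing lambda order, so the smallest index is
    the largest lambda, i.e. the sparser model.
    """
    values = np.asarray(values, dtype=float)
    if np.isnan(values).all():
        raise RuntimeError("cvl criterion is NaN over the whole grid")
    best = int(np.nanargmax(values))
    return best


def select_lambda(
    data: SurvivalDataset,
    penalty: PenaltySpec,
    grid=None,
    folds: FoldAssignment | None = None,
    k1: int = 5,
    seed: int | None = 0,
) -> tuple[float, CVReport]:
    """Choose ``lambda`` on a grid by maximizing cvl.

    Ties are broken toward the larger ``lambda`` (the sparser model).  The
    default grid runs log-spaced from the weighted-KKT ``lambda_max`` down
    to one hundredth of it.
    """
    if grid is None:
        grid = default_lambda_grid(lambda_max(data, penalty))
    grid = np.asarray(grid, dtype=float)
    if folds is None:
        folds = FoldAssignment.create(data, k=k1, seed=seed)
    values = cvl_path(data, penalty, grid, folds)
    best = argmax_sparser(values)
    report = CVReport(
        lambda_grid=grid,
        cvl_values=values,
        lambda_star=float(grid[best]),
        folds=folds,
    )
    return report.lambda_star, report


# ---------------------------------------------------------------------------
# double cross-validation
# ---------------------------------------------------------------------------


@dataclass
class DoubleCVResult:
    """Cross-validated per-patient prediction scores.

    Each patient appears in exactly one outer fold; the scores (and any
    survival prediction derived from ``fold_models``) come from a model
    developed entirely without that fold.
    """

    folds: FoldAssignment
    prog_score: np.ndarray
    mod_score: np.ndarray
    linear_predictor: np.ndarray
    fold_models: list = field(default_factory=list)

    def scores_frame(self, data: SurvivalDataset):
        """Per-patient cross-validated scores as a delimited-text-ready table."""
        import pandas as pd

        return pd.DataFrame(
            {
                "patient_id": data.patient_id,
                "fold": self.folds.fold_of,
                "prog_score": self.prog_score,
                "mod_score": self.mod_score,
                "linear_predictor": self.linear_predictor,
            }
        )

    def survival_matrix(self, data: SurvivalDataset, times) -> np.ndarray:
        """S_i(t) for each patient from its own held-out fold model."""
        from .prediction import survival_matrix

        times = np.asarray(times, dtype=float)
        out = np.empty((data.n, times.shape[0]))
        raw = data.unstandardized()
        for k, model in enumerate(self.fold_models):
            idx = self.folds.test_indices(k)
            out[idx] = survival_matrix(model, raw.subset(idx), times)
        return out


def double_cv_scores(
    data: SurvivalDataset,
    model_spec=None,
    k2: int = 5,
    k1: int = 5,
    seed: int | None = 0,
) -> DoubleCVResult:
    """Nested cross-validation of the full model-development pipeline.

    For each of the ``k2`` outer folds the complete pipeline
    (standardization, adaptive weights, inner ``k1``-fold lambda tuning,
    final fit, Breslow baseline) is re-run on the outer-training part, and
    the held-out patients are scored on the outer-training biomarker scale.
    """
    from .workflow import ModelSpec, develop_model

    if model_spec is None:
        model_spec = ModelSpec()
    raw = data.unstandardized()
    raw.require_fittable()
    rng_root = np.random.SeedSequence(seed)
    inner_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in rng_root.spawn(k2 + 1)]
    folds = FoldAssignment.create(raw, k=k2, seed=inner_seeds[0])
    phi = np.full(raw.n, np.nan)
    eta = np.full(raw.n, np.nan)
    pi = np.full(raw.n, np.nan)
    models = []
    for k in range(folds.k):
        train = raw.subset(folds.train_indices(k))
        if train.n_events == 0:
            raise RuntimeError(f"outer fold {k} leaves a training set without events")
        model = develop_model(train, model_spec, seed=inner_seeds[k + 1], k1=k1)
        models.append(model)
        idx = folds.test_indices(k)
        held = raw.subset(idx)
        from .prediction import _model_scale_biomarkers, scores

        X = _model_scale_biomarkers(model, held)
        phi[idx], eta[idx], pi[idx] = scores(model, X, held.treatment, held.clinical)
    return DoubleCVResult(
        folds=folds,
        prog_score=phi,
        mod_score=eta,
        linear_predictor=pi,
        fold_models=models,
    )
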