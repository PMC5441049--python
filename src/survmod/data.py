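"""Domain types and dataset handling.

The central container is :class:`SurvivalDataset`: right-censored follow-up
for a two-arm randomized trial together with a biomarker matrix and optional
unpenalized clinical covariates.  Treatment is coded ``+0.5`` (experimental)
and ``-0.5`` (control) so that main effects are averaged over arms and
interaction terms are orthogonal to them in expectation.

Biomarkers are standardized (mean 0, unit sample variance) before model
fitting; the per-column ``(center, scale)`` pair is retained so that future
patients can be mapped onto the training scale.  Treatment and clinical
covariates are never standardized.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Standardization",
    "SurvivalDataset",
    "Penalty",
    "PenaltySpec",
    "BaselineHazard",
    "FittedCoxModel",
    "PredictionResult",
    "load_dataset",
    "save_dataset",
    "standardize",
    "save_model",
    "load_model",
]

#: default evaluation horizon (years)
DEFAULT_TAU = 5.0

#: adaptive-lasso weights at or above this value mark a coefficient as excluded
WEIGHT_CAP = 1e6


@dataclass(frozen=True)
class Standardization:
    """Per-biomarker centering/scaling constants (training scale)."""

    center: np.ndarray
    scale: np.ndarray

    def apply(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.center) / self.scale

    def invert(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) * self.scale + self.center


@dataclass
class SurvivalDataset:
    """Right-censored two-arm trial data with a biomarker matrix.

    Attributes
    ----------
    time : (n,) nonnegative follow-up times, in years.
    event : (n,) 0/1 event indicator (1 = event observed).
    treatment : (n,) arm code, +0.5 experimental / -0.5 control.
    biomarkers : (n, p) biomarker matrix.
    clinical : optional (n, q) unpenalized covariates.
    standardization : set once ``standardize`` has been applied; records the
        (center, scale) constants of the *training* sample.
    """

    time: np.ndarray
    event: np.ndarray
    treatment: np.ndarray
    biomarkers: np.ndarray
    patient_id: np.ndarray | None = None
    clinical: np.ndarray | None = None
    biomarker_names: list[str] | None = None
    clinical_names: list[str] | None = None
    standardization: Standardization | None = None

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        self.treatment = np.asarray(self.treatment, dtype=float)
        self.biomarkers = np.atleast_2d(np.asarray(self.biomarkers, dtype=float))
        if self.patient_id is None:
            self.patient_id = np.arange(self.n)
        else:
            self.patient_id = np.asarray(self.patient_id)
        if self.clinical is not None:
            self.clinical = np.atleast_2d(np.asarray(self.clinical, dtype=float))
        if self.biomarker_names is None:
            self.biomarker_names = [f"x{j + 1}" for j in range(self.p)]
        if self.clinical is not None and self.clinical_names is None:
            self.clinical_names = [f"z{j + 1}" for j in range(self.clinical.shape[1])]
        self.validate()

    # -- basic shape ---------------------------------------------------
    @property
    def n(self) -> int:
        return self.time.shape[0]

    @property
    def p(self) -> int:
        return self.biomarkers.shape[1]

    @property
    def n_clinical(self) -> int:
        return 0 if self.clinical is None else self.clinical.shape[1]

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def validate(self) -> None:
        n = self.n
        for name, arr in (("event", self.event), ("treatment", self.treatment)):
            if arr.shape[0] != n:
                raise ValueError(f"column '{name}' has wrong length")
        if self.biomarkers.shape[0] != n:
            raise ValueError("biomarker matrix row count does not match time")
        if np.isnan(self.time).any() or (self.time < 0).any():
            raise ValueError("column 'time' must be nonnegative and non-missing")
        if not np.isin(self.event, (0, 1)).all():
            raise ValueError("column 'event' must be a 0/1 indicator")
        if not np.isin(self.treatment, (-0.5, 0.5)).all():
            raise ValueError("column 'treatment' must be coded +0.5/-0.5")
        if np.isnan(self.biomarkers).any():
            bad = self.biomarker_names[
                int(np.flatnonzero(np.isnan(self.biomarkers).any(axis=0))[0])]
            raise ValueError(f"biomarker column '{bad}' contains missing values")
        if self.clinical is not None and np.isnan(self.clinical).any():
            bad = self.clinical_names[
                int(np.flatnonzero(np.isnan(self.clinical).any(axis=0))[0])]
            raise ValueError(f"clinical column '{bad}' contains missing values")

    def require_fittable(self) -> None:
        if self.n < 2:
            raise ValueError("at least two patients are required for fitting")
        if self.n_events == 0:
            raise ValueError("at least one event is required for fitting")

    def subset(self, idx) -> "SurvivalDataset":
        """Row subset (fold complement, bootstrap resample, ...)."""
        idx = np.asarray(idx)
        return SurvivalDataset(
            time=self.time[idx],
            event=self.event[idx],
            treatment=self.treatment[idx],
            biomarkers=self.biomarkers[idx],
            patient_id=self.patient_id[idx],
            clinical=None if self.clinical is None else self.clinical[idx],
            biomarker_names=self.biomarker_names,
            clinical_names=self.clinical_names,
            standardization=self.standardization,
        )

    def unstandardized(self) -> "SurvivalDataset":
        """Return the dataset on the original biomarker scale."""
        if self.standardization is None:
            return self
        return replace(
            self,
            biomarkers=self.standardization.invert(self.biomarkers),
            standardization=None,
        )


def standardize(data: SurvivalDataset) -> SurvivalDataset:
    """Standardize biomarker columns to mean 0 and unit sample variance.

    The (center, scale) constants are stored on the returned dataset so the
    identical affine map can later be applied to new patients.  Treatment
    and clinical covariates are left untouched.  Idempotent: an already
    standardized dataset is returned as is.
    """
    if data.standardization is not None:
        return data
    if data.n < 2:
        raise ValueError("standardization requires at least two patients")
    center = data.biomarkers.mean(axis=0)
    scale = data.biomarkers.std(axis=0, ddof=1)
    if (scale == 0).any():
        bad = data.biomarker_names[int(np.flatnonzero(scale == 0)[0])]
        raise ValueError(f"biomarker column '{bad}' is constant; cannot standardize")
    std = Standardization(center=center, scale=scale)
    return replace(data, biomarkers=std.apply(data.biomarkers), standardization=std)


# ---------------------------------------------------------------------------
# penalties
# ---------------------------------------------------------------------------


class Penalty(str, Enum):
    NONE = "none"
    RIDGE = "ridge"
    LASSO = "lasso"
    ADAPTIVE_LASSO = "adaptive_lasso"


@dataclass
class PenaltySpec:
    """Penalty type plus per-coefficient weights for the biomarker terms.

    ``theta`` weights the main effects, ``vartheta`` the interactions; the
    treatment (and clinical covariates) are never penalized.  Weights at or
    above :data:`WEIGHT_CAP` mark a coefficient as excluded from the model.
    """

    penalty: Penalty
    theta: np.ndarray
    vartheta: np.ndarray
    lambda_grid: np.ndarray | None = None

    def __post_init__(self):
        self.penalty = Penalty(self.penalty)
        self.theta = np.asarray(self.theta, dtype=float)
        self.vartheta = np.asarray(self.vartheta, dtype=float)
        if (self.theta < 0).any() or (self.vartheta < 0).any():
            raise ValueError("penalty weights must be nonnegative")
        if self.lambda_grid is not None:
            grid = np.asarray(self.lambda_grid, dtype=float)
            if (np.diff(grid) >= 0).any():
                raise ValueError("lambda grid must be strictly decreasing")
            self.lambda_grid = grid

    @classmethod
    def none(cls, p: int) -> "PenaltySpec":
        return cls(Penalty.NONE, np.ones(p), np.ones(p))

    @classmethod
    def lasso(cls, p: int) -> "PenaltySpec":
        return cls(Penalty.LASSO, np.ones(p), np.ones(p))

    @classmethod
    def ridge(cls, p: int) -> "PenaltySpec":
        return cls(Penalty.RIDGE, np.ones(p), np.ones(p))

    @classmethod
    def adaptive(cls, theta, vartheta) -> "PenaltySpec":
        return cls(Penalty.ADAPTIVE_LASSO, theta, vartheta)

    @property
    def p(self) -> int:
        return self.theta.shape[0]

    def weights(self) -> np.ndarray:
        """Concatenated (theta, vartheta) in design-matrix order."""
        return np.concatenate([self.theta, self.vartheta])


# ---------------------------------------------------------------------------
# fitted model and predictions
# ---------------------------------------------------------------------------


@dataclass
class BaselineHazard:
    """Right-continuous step estimate of the cumulative baseline hazard."""

    event_times: np.ndarray
    cum_hazard: np.ndarray

    def __post_init__(self):
        self.event_times = np.asarray(self.event_times, dtype=float)
        self.cum_hazard = np.asarray(self.cum_hazard, dtype=float)
        if (np.diff(self.event_times) <= 0).any():
            raise ValueError("event times must be strictly increasing")
        if (self.cum_hazard < 0).any() or (np.diff(self.cum_hazard) < 0).any():
            raise ValueError("cumulative hazard must be nonnegative, nondecreasing")

    def cum_at(self, t) -> np.ndarray:
        """H0(t): value at t includes events exactly at t (right-continuous)."""
        idx = np.searchsorted(self.event_times, np.asarray(t, dtype=float), side="right")
        padded = np.concatenate([[0.0], self.cum_hazard])
        return padded[idx]

    @property
    def final_time(self) -> float:
        return float(self.event_times[-1])


@dataclass
class FittedCoxModel:
    """Interaction Cox model on the standardized-biomarker scale.

    The linear predictor is
    ``pi = alpha*T + clinical'z + sum_j beta_j X_j + sum_j gamma_j X_j T``
    with ``X`` standardized using ``train_standardization``.
    """

    alpha_hat: float
    beta_hat: np.ndarray
    gamma_hat: np.ndarray
    clinical_hat: np.ndarray | None = None
    lambda_star: float | None = None
    penalty: PenaltySpec | None = None
    baseline: BaselineHazard | None = None
    train_standardization: Standardization | None = None
    biomarker_names: list[str] | None = None
    clinical_names: list[str] | None = None

    def __post_init__(self):
        self.beta_hat = np.asarray(self.beta_hat, dtype=float)
        self.gamma_hat = np.asarray(self.gamma_hat, dtype=float)
        if self.beta_hat.shape != self.gamma_hat.shape:
            raise ValueError("beta and gamma must have equal length p")
        if self.clinical_hat is not None:
            self.clinical_hat = np.asarray(self.clinical_hat, dtype=float)

    @property
    def p(self) -> int:
        return self.beta_hat.shape[0]

    def coef_vector(self) -> np.ndarray:
        """Coefficients in design order [T, clinical, X, X*T]."""
        clin = self.clinical_hat if self.clinical_hat is not None else np.empty(0)
        return np.concatenate([[self.alpha_hat], clin, self.beta_hat, self.gamma_hat])

    def active_biomarkers(self) -> np.ndarray:
        return np.flatnonzero((self.beta_hat != 0) | (self.gamma_hat != 0))


class CIMethod(str, Enum):
    ANALYTIC = "analytic"
    BOOTSTRAP = "bootstrap"
    NONE = "none"


@dataclass
class PredictionResult:
    """Per-patient predictions at a common horizon ``tau``."""

    patient_id: np.ndarray
    tau: float
    survival: np.ndarray
    prog_score: np.ndarray
    mod_score: np.ndarray
    linear_predictor: np.ndarray
    ci_lower: np.ndarray | None = None
    ci_upper: np.ndarray | None = None
    ci_method: CIMethod = CIMethod.NONE

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "patient_id": self.patient_id,
                "tau": self.tau,
                "survival": self.survival,
                "prog_score": self.prog_score,
                "mod_score": self.mod_score,
                "linear_predictor": self.linear_predictor,
            }
        )
        if self.ci_lower is not None:
            out["ci_lower"] = self.ci_lower
            out["ci_upper"] = self.ci_upper
        out["ci_method"] = CIMethod(self.ci_method).value
        return out


# ---------------------------------------------------------------------------
# delimited-text I/O
# ---------------------------------------------------------------------------


def load_dataset(
    path,
    schema: Mapping[str, object] | None = None,
    sep: str = ",",
) -> SurvivalDataset:
    """Read a delimited text file into a validated :class:`SurvivalDataset`.

    ``schema`` maps the roles to column names::

        {"time": "time", "event": "event", "treatment": "trt",
         "biomarkers": ["x1", "x2", ...],        # or omitted: all remaining
         "clinical": ["age"], "patient_id": "id"}

    A two-level treatment column coded other than +/-0.5 is recoded with the
    *larger* value (e.g. 1 in a 0/1 coding) mapped to +0.5 (experimental).
    """
    schema = dict(schema or {})
    df = pd.read_csv(path, sep=sep)
    tcol = schema.get("time", "time")
    ecol = schema.get("event", "event")
    rcol = schema.get("treatment", "treatment")
    for col in (tcol, ecol, rcol):
        if col not in df.columns:
            raise ValueError(f"required column '{col}' is missing")
    idcol = schema.get("patient_id")
    clin_cols = list(schema.get("clinical", []))
    bio_cols = schema.get("biomarkers")
    if bio_cols is None:
        reserved = {tcol, ecol, rcol, idcol, *clin_cols}
        bio_cols = [c for c in df.columns if c not in reserved]
    bio_cols = list(bio_cols)

    event = df[ecol].to_numpy()
    if not np.isin(event[~pd.isna(event)], (0, 1)).all() or pd.isna(event).any():
        raise ValueError("column 'event' must be a 0/1 indicator without missing values")

    trt_raw = df[rcol].to_numpy()
    levels = np.unique(trt_raw[~pd.isna(trt_raw)])
    if pd.isna(trt_raw).any():
        raise ValueError("column 'treatment' contains missing values")
    if set(levels) == {-0.5, 0.5}:
        treatment = trt_raw.astype(float)
    elif len(levels) == 2:
        treatment = np.where(trt_raw == levels.max(), 0.5, -0.5)
    elif len(levels) == 1:
        raise ValueError("column 'treatment' has a single level; two arms required")
    else:
        raise ValueError("column 'treatment' has more than two levels")

    return SurvivalDataset(
        time=df[tcol].to_numpy(dtype=float),
        event=event.astype(int),
        treatment=treatment,
        biomarkers=df[bio_cols].to_numpy(dtype=float),
        patient_id=None if idcol is None else df[idcol].to_numpy(),
        clinical=None if not clin_cols else df[clin_cols].to_numpy(dtype=float),
        biomarker_names=bio_cols,
        clinical_names=clin_cols or None,
    )


def save_dataset(data: SurvivalDataset, path, sep: str = ",") -> None:
    """Write a dataset (original scale) as delimited text with header."""
    out = pd.DataFrame(
        {"patient_id": data.patient_id, "time": data.time,
         "event": data.event, "treatment": data.treatment}
    )
    if data.clinical is not None:
        for j, name in enumerate(data.clinical_names):
            out[name] = data.clinical[:, j]
    raw = data.unstandardized().biomarkers
    for j, name in enumerate(data.biomarker_names):
        out[name] = raw[:, j]
    out.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# model JSON
# ---------------------------------------------------------------------------

_MODEL_FORMAT_VERSION = 1


def save_model(model: FittedCoxModel, path) -> None:
    """Persist a fitted model (coefficients, penalty, baseline, scaling)."""
    doc = {
        "format_version": _MODEL_FORMAT_VERSION,
        "alpha_hat": model.alpha_hat,
        "beta_hat": model.beta_hat.tolist(),
        "gamma_hat": model.gamma_hat.tolist(),
        "clinical_hat": None if model.clinical_hat is None else model.clinical_hat.tolist(),
        "lambda_star": model.lambda_star,
        "penalty": None
        if model.penalty is None
        else {
            "penalty": model.penalty.penalty.value,
            "theta": model.penalty.theta.tolist(),
            "vartheta": model.penalty.vartheta.tolist(),
        },
        "baseline": None
        if model.baseline is None
        else {
            "event_times": model.baseline.event_times.tolist(),
            "cum_hazard": model.baseline.cum_hazard.tolist(),
        },
        "standardization": None
        if model.train_standardization is None
        else {
            "center": model.train_standardization.center.tolist(),
            "scale": model.train_standardization.scale.tolist(),
        },
        "biomarker_names": model.biomarker_names,
        "clinical_names": model.clinical_names,
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_model(path) -> FittedCoxModel:
    doc = json.loads(Path(path).read_text())
    if doc.get("format_version") != _MODEL_FORMAT_VERSION:
        raise ValueError("unsupported model file version")
    pen = doc["penalty"]
    base = doc["baseline"]
    std = doc["standardization"]
    return FittedCoxModel(
        alpha_hat=doc["alpha_hat"],
        beta_hat=np.array(doc["beta_hat"]),
        gamma_hat=np.array(doc["gamma_hat"]),
        clinical_hat=None if doc["clinical_hat"] is None else np.array(doc["clinical_hat"]),
        lambda_star=doc["lambda_star"],
        penalty=None if pen is None else PenaltySpec(pen["penalty"], pen["theta"], pen["vartheta"]),
        baseline=None if base is None else BaselineHazard(base["event_times"], base["cum_hazard"]),
        train_standardization=None
        if std is None
        else Standardization(np.array(std["center"]), np.array(std["scale"])),
        biomarker_names=doc["biomarker_names"],
        clinical_names=doc["clinical_names"],
    )
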