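"""Treatment-benefit visualization.

The central display plots each patient's expected survival probability at
the horizon against the scaled treatment-effect modifying score, under
both arms (every patient is predicted counterfactually with T = +0.5 and
T = -0.5).  The modifying score is scaled so that the 2.5% and 97.5%
training quantiles map to 0 and 1; new patients use the *training*
quantiles and values outside the range are deliberately not clipped.

Two strategies are offered: *pointwise* (one dot plus a vertical CI
segment per patient and arm) and *spline* (constrained cubic B-splines
smoothing the point estimates and the CI bounds, usually stratified into
four prognostic risk groups with the 16.4/33.6/33.6/16.4 percentile split
suggested by Cox).  Spline values are kept inside [0, 1] by constraining
the basis coefficients to [0, 1] (the spline then lies in the convex hull
of its coefficients).  The node count is chosen by a Gaussian
least-squares AIC over a small candidate set.

The figure is a pure function of the returned plot-data table, so the
table alone suffices to reproduce the display.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.optimize import lsq_linear

from .data import FittedCoxModel, SurvivalDataset

__all__ = [
    "SplineCurve",
    "scale_eta",
    "prognostic_groups",
    "fit_constrained_spline",
    "benefit_plot_data",
    "render_benefit_plot",
    "treatment_benefit_plot",
]

#: Cox's percentile split for four prognostic risk groups
GROUP_PERCENTILES = (0.164, 0.5, 0.836)

_DEGREE = 3


def scale_eta(eta_train, eta_new=None) -> np.ndarray:
    """Scale modifying scores by the training 2.5%/97.5% quantile range.

    ``eta' = (eta - q_.025(train)) / (q_.975(train) - q_.025(train))``;
    values outside the training range map outside [0, 1] and are not
    clipped.
    """
    eta_train = np.asarray(eta_train, dtype=float)
    q_lo, q_hi = np.quantile(eta_train, [0.025, 0.975])
    if q_hi <= q_lo:
        raise ValueError(
            "modifying score is degenerate (2.5% and 97.5% quantiles coincide); "
            "the model has no treatment-effect modifying component"
        )
    target = eta_train if eta_new is None else np.asarray(eta_new, dtype=float)
    return (target - q_lo) / (q_hi - q_lo)


def prognostic_groups(phi_scores) -> np.ndarray:
    """Four risk groups from the prognostic score (labels 1..4).

    Cut points are the 16.4th, 50th and 83.6th percentiles (linear
    interpolation); boundary ties fall in the lower group.  A constant
    score yields a single group with a warning.
    """
    phi = np.asarray(phi_scores, dtype=float)
    if phi.size < 4:
        raise ValueError("at least four patients are required for grouping")
    if np.ptp(phi) == 0:
        warnings.warn("constant prognostic score; returning a single group")
        return np.ones(phi.shape, dtype=int)
    cuts = np.quantile(phi, GROUP_PERCENTILES)
    return 1 + (phi[:, None] > cuts[None, :]).sum(axis=1)


@dataclass
class SplineCurve:
    """Constrained cubic B-spline with values in [0, 1] over its domain."""

    knots: np.ndarray          # full knot vector
    coefficients: np.ndarray   # each in [0, 1]
    domain: tuple[float, float]
    n_nodes: int
    aic: float

    def __call__(self, x) -> np.ndarray:
        x = np.clip(np.asarray(x, dtype=float), *self.domain)
        return BSpline(self.knots, self.coefficients, _DEGREE, extrapolate=False)(x)


def fit_constrained_spline(x, y, node_candidates=range(1, 6)) -> SplineCurve:
    """Least-squares B-spline of y on x with values constrained to [0, 1].

    Interior nodes sit at quantiles of ``x``; the node count is chosen by
    the Gaussian AIC ``n log(RSS/n) + 2 * n_coefficients``.  Coefficients
    are bounded to [0, 1], which by the convex-hull property keeps every
    evaluated value inside [0, 1].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 5:
        raise ValueError("at least five points are required for spline smoothing")
    if ((y < -1e-12) | (y > 1 + 1e-12)).any():
        raise ValueError("spline responses must lie in [0, 1]")
    y = np.clip(y, 0.0, 1.0)
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    lo, hi = float(xs[0]), float(xs[-1])
    if hi <= lo:
        # degenerate abscissa: constant curve at the mean
        c = float(np.clip(ys.mean(), 0, 1))
        knots = np.concatenate([np.full(_DEGREE + 1, lo), np.full(_DEGREE + 1, lo + 1)])
        return SplineCurve(knots, np.full(_DEGREE + 1, c), (lo, lo), 0, np.nan)

    best = None
    for n_nodes in node_candidates:
        interior = np.quantile(xs, np.linspace(0, 1, n_nodes + 2)[1:-1])
        interior = interior[(interior > lo) & (interior < hi)]
        knots = np.concatenate(
            [np.full(_DEGREE + 1, lo), np.sort(interior), np.full(_DEGREE + 1, hi)]
        )
        n_coef = knots.size - _DEGREE - 1
        if xs.size <= n_coef:
            continue
        design = BSpline.design_matrix(xs, knots, _DEGREE).toarray()
        sol = lsq_linear(design, ys, bounds=(0.0, 1.0), tol=1e-12)
        rss = float(np.sum((design @ sol.x - ys) ** 2))
        aic = xs.size * np.log(max(rss, 1e-12) / xs.size) + 2 * n_coef
        if best is None or aic < best.aic:
            best = SplineCurve(knots, sol.x, (lo, hi), int(interior.size), aic)
    if best is None:
        raise ValueError("fewer points than the smallest candidate basis")
    return best


# ---------------------------------------------------------------------------
# treatment-benefit plot
# ---------------------------------------------------------------------------


def benefit_plot_data(
    model: FittedCoxModel,
    data: SurvivalDataset,
    tau: float = 5.0,
    ci_bounds=None,
    stratify: bool | None = None,
) -> pd.DataFrame:
    """Long-format table behind the treatment-benefit plot.

    One row per patient per (counterfactual) arm: scaled modifying score,
    expected survival at ``tau``, optional CI bounds and the prognostic
    risk group.  ``ci_bounds`` maps the arm code to ``(lower, upper)``
    arrays aligned with the patients.
    """
    from dataclasses import replace

    from .prediction import _model_scale_biomarkers, predict_survival, scores

    X = _model_scale_biomarkers(model, data)
    phi, eta, _ = scores(model, X, data.treatment, data.clinical)
    eta_scaled = scale_eta(eta)
    if stratify is None:
        stratify = bool((model.beta_hat != 0).any())
    groups = prognostic_groups(phi) if stratify else np.ones(data.n, dtype=int)

    rows = []
    for arm in (-0.5, 0.5):
        arm_data = replace(data, treatment=np.full(data.n, arm))
        pred = predict_survival(model, arm_data, tau)
        lo = hi = np.full(data.n, np.nan)
        if ci_bounds is not None and arm in ci_bounds:
            lo, hi = (np.asarray(b, dtype=float) for b in ci_bounds[arm])
        rows.append(
            pd.DataFrame(
                {
                    "patient_id": data.patient_id,
                    "arm": arm,
                    "eta_scaled": eta_scaled,
                    "prog_score": phi,
                    "group": groups,
                    "survival": pred.survival,
                    "ci_lower": lo,
                    "ci_upper": hi,
                    "tau": tau,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def render_benefit_plot(table: pd.DataFrame, strategy: str = "pointwise"):
    """Render the treatment-benefit figure from its plot-data table.

    A pure function of the table: panels by prognostic group, one color
    per arm; either per-patient points with CI segments or three smoothed
    curves (estimate, lower, upper) per group and arm.
    """
    if strategy not in ("pointwise", "spline"):
        raise ValueError("strategy must be 'pointwise' or 'spline'")
    groups = np.sort(table["group"].unique())
    fig, axes = plt.subplots(
        1, len(groups), figsize=(4 * len(groups), 4), sharey=True, squeeze=False
    )
    colors = {-0.5: "tab:blue", 0.5: "tab:red"}
    labels = {-0.5: "control", 0.5: "experimental"}
    has_ci = np.isfinite(table["ci_lower"].to_numpy()).any()
    for ax, grp in zip(axes[0], groups):
        sub = table[table["group"] == grp]
        for arm in (-0.5, 0.5):
            arm_rows = sub[sub["arm"] == arm]
            x = arm_rows["eta_scaled"].to_numpy()
            y = arm_rows["survival"].to_numpy()
            if strategy == "pointwise":
                ax.plot(x, y, "o", ms=3, color=colors[arm], label=labels[arm])
                if has_ci:
                    ax.vlines(
                        x,
                        arm_rows["ci_lower"],
                        arm_rows["ci_upper"],
                        color=colors[arm],
                        alpha=0.3,
                        lw=0.8,
                    )
            else:
                grid = np.linspace(x.min(), x.max(), 200)
                curves = {"survival": "-"}
                if has_ci:
                    curves.update({"ci_lower": "--", "ci_upper": "--"})
                for col, style in curves.items():
                    vals = arm_rows[col].to_numpy()
                    if np.ptp(x) == 0 or x.size < 5:
                        ax.hlines(np.nanmean(vals), x.min(), x.max() + 1e-9,
                                  color=colors[arm], linestyles=style)
                        continue
                    spl = fit_constrained_spline(x, vals)
                    ax.plot(grid, spl(grid), style, color=colors[arm],
                            label=labels[arm] if col == "survival" else None)
        ax.set_xlabel("scaled treatment-effect modifying score")
        ax.set_title(f"prognostic group {int(grp)}" if len(groups) > 1 else "")
        ax.set_ylim(0, 1)
    axes[0][0].set_ylabel(f"expected survival at {table['tau'].iloc[0]:g} years")
    axes[0][0].legend(loc="lower left", fontsize=8)
    fig.tight_layout()
    return fig


def treatment_benefit_plot(
    model: FittedCoxModel,
    data: SurvivalDataset,
    tau: float = 5.0,
    strategy: str = "pointwise",
    ci_bounds=None,
    stratify: bool | None = None,
):
    """Plot-data table plus the rendered figure (see the module docstring)."""
    table = benefit_plot_data(model, data, tau, ci_bounds=ci_bounds, stratify=stratify)
    fig = render_benefit_plot(table, strategy)
    return table, fig
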