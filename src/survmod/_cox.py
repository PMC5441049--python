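"""Core Cox partial-likelihood machinery (Breslow tie handling).

All routines operate on plain ``numpy`` arrays: an ``(n,)`` vector of
follow-up times, an ``(n,)`` 0/1 event indicator and either a linear
predictor ``eta`` or a design matrix ``X``.  Ties between event times are
handled with the Breslow approximation throughout, so the likelihood, its
derivatives and the Breslow baseline-hazard estimator are mutually
consistent.

The module also provides a damped Newton solver for Cox regression with an
optional per-coefficient quadratic (ridge) penalty; unpenalized columns
simply carry a zero penalty entry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RiskSetEngine",
    "ConvergenceError",
    "partial_loglik",
    "gradient",
    "hessian",
    "newton_cox",
]


@dataclass
class _Groups:
    """Grouping of a sample, sorted ascending in time, by distinct event time."""

    order: np.ndarray          # sort permutation (ascending time, stable)
    time_sorted: np.ndarray
    event_sorted: np.ndarray   # bool
    start: np.ndarray          # first sorted index of each event-carrying time
    n_events: np.ndarray       # events at that time (d_t)


def _group_events(time: np.ndarray, event: np.ndarray) -> _Groups:
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    order = np.argsort(time, kind="stable")
    ts, es = time[order], event[order].astype(bool)
    n = ts.shape[0]
    is_start = np.ones(n, dtype=bool)
    is_start[1:] = ts[1:] != ts[:-1]
    run_start = np.flatnonzero(is_start)
    d = np.add.reduceat(es.astype(np.int64), run_start)
    keep = d > 0
    return _Groups(order, ts, es, run_start[keep], d[keep])


class RiskSetEngine:
    """Pre-sorted view of a right-censored sample for repeated evaluation.

    Sorting and tie-grouping are done once; ``loglik`` then costs O(n),
    ``gradient`` O(nd) and ``grad_hess`` O(nd^2).  The risk set at an event
    time ``t`` is every subject with follow-up time ``>= t``.
    """

    def __init__(self, time, event, X=None):
        time = np.asarray(time, dtype=float)
        event = np.asarray(event, dtype=int)
        if time.ndim != 1 or event.shape != time.shape:
            raise ValueError("time and event must be 1-d arrays of equal length")
        if not (event == (event != 0)).all():
            raise ValueError("event indicator must be 0/1")
        if not event.any():
            raise ValueError("at least one event is required")
        self.n = time.shape[0]
        self.groups = _group_events(time, event)
        self.X = None
        if X is not None:
            X = np.asarray(X, dtype=float)
            if X.shape[0] != self.n:
                raise ValueError("X row count does not match time")
            self.X = X[self.groups.order]
        self.time = time
        self.event = event

    @property
    def n_events(self) -> int:
        return int(self.groups.n_events.sum())

    # -- likelihood ----------------------------------------------------
    def loglik(self, eta) -> float:
        """Breslow partial log-likelihood at linear predictor ``eta``."""
        return self.loglik_sorted(np.asarray(eta, dtype=float)[self.groups.order])

    def loglik_sorted(self, e) -> float:
        """Log-likelihood at a linear predictor already in engine sort order."""
        g = self.groups
        shift = e.max()
        s0 = np.cumsum(np.exp(e - shift)[::-1])[::-1]
        ll = e[g.event_sorted].sum() - float(
            g.n_events @ (np.log(s0[g.start]) + shift))
        return float(ll)

    def loglik_many(self, etas) -> np.ndarray:
        """Partial log-likelihood for each column of an ``(n, m)`` matrix."""
        g = self.groups
        e = np.asarray(etas, dtype=float)[g.order]
        shift = e.max(axis=0)
        s0 = np.cumsum(np.exp(e - shift)[::-1], axis=0)[::-1]
        return e[g.event_sorted].sum(axis=0) - g.n_events.astype(float) @ (
            np.log(s0[g.start]) + shift)

    # -- derivatives ---------------------------------------------------
    def _weights_a(self, e):
        """exp-weights w_i and A_i = sum_{t_k <= t_i} d_k/S0(t_k) (sorted order).

        These give ``sum_k d_k S1(t_k)/S0(t_k) = X'(w * A)`` by swapping the
        order of the risk-set summation, so the score costs one O(nd)
        matrix-vector product instead of an (n, d) cumulative sum.
        """
        g = self.groups
        shift = e.max()
        w = np.exp(e - shift)
        s0 = np.cumsum(w[::-1])[::-1]
        incr = np.zeros(self.n)
        incr[g.start] = g.n_events / s0[g.start]
        ll = e[g.event_sorted].sum() - float(g.n_events @ (np.log(s0[g.start]) + shift))
        return w, np.cumsum(incr), ll

    def loglik_grad(self, beta):
        """Partial log-likelihood and score vector in one cheap pass."""
        X = self._require_X()
        e = X @ np.asarray(beta, dtype=float)
        w, a, ll = self._weights_a(e)
        grad = X[self.groups.event_sorted].sum(axis=0) - (w * a) @ X
        return ll, grad

    def gradient(self, beta) -> np.ndarray:
        """Score vector of the Breslow partial log-likelihood at ``beta``."""
        return self.loglik_grad(beta)[1]

    def grad_hess(self, beta):
        """Score vector and (negative-definite) Hessian at ``beta``.

        Uses the identity
        ``sum_k d_k S2(t_k)/S0(t_k) = X' diag(w_i * A_i) X`` with
        ``A_i = sum_{t_k <= t_i} d_k / S0(t_k)`` (swapping the order of the
        risk-set summation), so the Hessian costs two BLAS products.
        """
        X = self._require_X()
        g = self.groups
        e = X @ np.asarray(beta, dtype=float)
        shift = e.max()
        w = np.exp(e - shift)
        s0 = np.cumsum(w[::-1])[::-1]
        s1 = np.cumsum((w[:, None] * X)[::-1], axis=0)[::-1]
        mu = s1[g.start] / s0[g.start, None]
        grad = X[g.event_sorted].sum(axis=0) - g.n_events @ mu
        # A_i: per-subject sum of d_k/S0_k over event times <= t_i
        incr = np.zeros(self.n)
        incr[g.start] = g.n_events / s0[g.start]
        a = np.cumsum(incr)
        hess = -((w * a)[:, None] * X).T @ X + (g.n_events[:, None] * mu).T @ mu
        return grad, hess

    def _require_X(self):
        if self.X is None:
            raise ValueError("engine was built without a design matrix")
        return self.X

    # -- Breslow baseline ----------------------------------------------
    def breslow(self, eta):
        """Distinct event times and Breslow baseline-hazard increments.

        Returns ``(times, dH0)`` with ``dH0[k] = d_k / sum_{risk set} exp(eta)``.
        """
        g = self.groups
        e = np.asarray(eta, dtype=float)[g.order]
        shift = e.max()
        s0 = np.cumsum(np.exp(e - shift)[::-1])[::-1]
        times = g.time_sorted[g.start]
        d_h0 = g.n_events / (s0[g.start] * np.exp(shift))
        return times, d_h0


def partial_loglik(time, event, eta) -> float:
    """Breslow partial log-likelihood of a fixed linear predictor."""
    return RiskSetEngine(time, event).loglik(eta)


def gradient(time, event, X, beta) -> np.ndarray:
    return RiskSetEngine(time, event, X).gradient(beta)


def hessian(time, event, X, beta) -> np.ndarray:
    return RiskSetEngine(time, event, X).grad_hess(beta)[1]


class ConvergenceError(RuntimeError):
    """Raised when an iterative fit does not reach its tolerance."""


def lbfgs_ridge_cox(engine: RiskSetEngine, ridge, init=None, gtol: float = 1e-3):
    """Ridge-penalized Cox fit by L-BFGS (gradient-only; for large designs).

    Maximizes ``l(beta) - sum_j ridge_j beta_j**2`` using the O(nd) score
    of :meth:`RiskSetEngine.loglik_grad`; preferred over full Newton when
    the design is wide (the Hessian would cost O(nd^2)).
    """
    from scipy.optimize import minimize

    X = engine._require_X()
    r = np.asarray(ridge, dtype=float)
    scale = max(engine.n_events, 1)

    def fg(b):
        ll, g = engine.loglik_grad(b)
        return -(ll - r @ (b * b)) / scale, -(g - 2.0 * r * b) / scale

    x0 = np.zeros(X.shape[1]) if init is None else np.asarray(init, dtype=float)
    res = minimize(
        fg, x0, jac=True, method="L-BFGS-B",
        options=dict(maxiter=2000, maxcor=20, ftol=1e-13, gtol=gtol / scale),
    )
    if np.max(np.abs(res.jac)) * scale > max(100 * gtol, 1e-2):
        raise ConvergenceError(f"L-BFGS ridge fit did not converge: {res.message}")
    return res.x


def newton_cox(
    time=None,
    event=None,
    X=None,
    ridge=None,
    init=None,
    tol: float = 1e-9,
    max_iter: int = 100,
    engine: RiskSetEngine | None = None,
):
    """Maximize ``l(beta) - sum_j ridge_j * beta_j**2`` by damped Newton.

    ``ridge`` is a per-coefficient vector of quadratic penalty strengths
    (``None`` or zeros gives the unpenalized Cox fit).  Pass a pre-built
    ``engine`` (with design matrix) to amortize sorting across fits.
    Raises :class:`ConvergenceError` when the coefficient change does not
    fall below ``tol`` within ``max_iter`` iterations.
    """
    if engine is None:
        engine = RiskSetEngine(time, event, X)
    Xs = engine._require_X()
    d = Xs.shape[1]
    r = np.zeros(d) if ridge is None else np.asarray(ridge, dtype=float)
    beta = np.zeros(d) if init is None else np.asarray(init, dtype=float).copy()

    def objective(b):
        return engine.loglik_sorted(Xs @ b) - float(r @ (b * b))

    obj = objective(beta)
    for _ in range(max_iter):
        grad, hess = engine.grad_hess(beta)
        grad = grad - 2.0 * r * beta
        hess = hess - np.diag(2.0 * r)
        try:
            step = np.linalg.solve(hess, -grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hess, -grad, rcond=None)[0]
        t = 1.0
        for _ in range(40):
            cand = beta + t * step
            cand_obj = objective(cand)
            if np.isfinite(cand_obj) and cand_obj >= obj - 1e-12:
                break
            t *= 0.5
        else:
            raise ConvergenceError("step halving failed to improve objective")
        delta = float(np.max(np.abs(t * step)))
        beta, obj = cand, cand_obj
        if delta < tol:
            return beta
    raise ConvergenceError(f"Newton did not converge within {max_iter} iterations")
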