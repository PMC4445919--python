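"""Cox proportional-hazards fitting by Newton-Raphson on the partial likelihood.

The Monte Carlo experiments in this package refit a Cox model thousands of
times on cohorts of a few thousand subjects, so the fitter is written as a
small vectorized Newton solver rather than delegating to a general-purpose
survival package: risk-set sums are suffix cumulative sums over the
time-sorted data, making each Newton iteration O(n p^2).

Ties are handled with the Breslow approximation.  Simulated event times are
continuous (ties occur with probability zero); the Breslow path matters only
when real, rounded data are supplied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .exceptions import ConvergenceError, EstimationError

__all__ = ["CoxPHResult", "fit_cox_breslow", "cox_partial_loglik"]


@dataclass
class CoxPHResult:
    """Maximum partial-likelihood estimates for a Cox model.

    Attributes
    ----------
    params : ndarray
        Coefficient estimates (log hazard ratios), one per design column.
    bse : ndarray
        Wald standard errors from the inverse observed information.
    loglik : float
        Log partial likelihood at the optimum (Breslow ties).
    n_iter : int
        Newton iterations used.
    n : int
        Number of rows.
    n_events : int
        Number of events.
    names : list of str
        Design column names, parallel to ``params``.
    """

    params: np.ndarray
    bse: np.ndarray
    loglik: float
    n_iter: int
    n: int
    n_events: int
    names: list = field(default_factory=list)

    @property
    def zvalues(self) -> np.ndarray:
        return self.params / self.bse

    @property
    def pvalues(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.zvalues))

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        """Wald confidence limits, shape (p, 2)."""
        z = stats.norm.ppf(1.0 - alpha / 2.0)
        return np.column_stack(
            [self.params - z * self.bse, self.params + z * self.bse]
        )


def _breslow_sums(X, w, first):
    """Suffix risk-set sums S0, S1, S2 evaluated at every row.

    ``first[i]`` is the index of the first row sharing row i's event time in
    the ascending sort, so tied times share one risk set.
    """
    # suffix cumulative sums (risk set = everyone with time >= t_i)
    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum((w[:, None] * X)[::-1], axis=0)[::-1]
    s2 = np.cumsum((w[:, None, None] * (X[:, :, None] * X[:, None, :]))[::-1],
                   axis=0)[::-1]
    return s0[first], s1[first], s2[first]


def cox_partial_loglik(beta, X, time, event):
    """Breslow log partial likelihood at ``beta`` (no fitting).

    Exposed separately so that small-sample results can be checked against
    direct maximization of the same objective.
    """
    beta = np.asarray(beta, dtype=float)
    X = np.asarray(X, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    order = np.argsort(time, kind="stable")
    Xs, ts, es = X[order], time[order], event[order].astype(bool)
    first = np.searchsorted(ts, ts, side="left")
    lp = Xs @ beta
    lp = lp - lp.max()
    w = np.exp(lp)
    s0 = np.cumsum(w[::-1])[::-1]
    return float(np.sum(lp[es] - np.log(s0[first][es])))


def fit_cox_breslow(X, time, event, names=None, tol=1e-9, max_iter=100):
    """Fit a Cox proportional-hazards model by Newton-Raphson.

    Parameters
    ----------
    X : (n, p) array_like
        Covariate design (no intercept; the baseline hazard absorbs it).
    time : (n,) array_like
        Event or censoring times, strictly positive.
    event : (n,) array_like
        1 for an observed event, 0 for censoring.
    names : list of str, optional
        Column names carried into the result.
    tol : float
        Convergence threshold on the relative change of the log partial
        likelihood between iterations.
    max_iter : int
        Iteration budget; exceeding it raises :class:`ConvergenceError`.

    Returns
    -------
    CoxPHResult

    Raises
    ------
    EstimationError
        If no events are present or the design is degenerate (a constant or
        linearly dependent column leaves the information matrix singular).
    ConvergenceError
        If Newton iterations do not converge within ``max_iter``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1 and np.asarray(time).size > 1:
        X = X.T
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    n, p = X.shape
    if time.shape[0] != n or event.shape[0] != n:
        raise EstimationError("time/event length does not match design rows")
    if not np.all(np.isfinite(X)):
        raise EstimationError("non-finite values in the covariate design")
    n_events = int(np.sum(event != 0))
    if n_events == 0:
        raise EstimationError("cannot fit a Cox model with zero events")
    # rank check up front: a degenerate design would only fail obscurely
    # inside the Newton solve
    if n >= p:
        sv = np.linalg.svd(X - X.mean(axis=0), compute_uv=False)
        if sv.size and (sv.min() <= 1e-10 * max(sv.max(), 1.0)):
            raise EstimationError(
                "degenerate covariate design (constant or collinear column); "
                "remove it before fitting"
            )

    order = np.argsort(time, kind="stable")
    Xs, ts = X[order], time[order]
    es = event[order].astype(bool)
    first = np.searchsorted(ts, ts, side="left")
    Xe = Xs[es]
    first_e = first[es]

    beta = np.zeros(p)
    ll_old = -np.inf
    for it in range(1, max_iter + 1):
        lp = Xs @ beta
        shift = lp.max()
        w = np.exp(lp - shift)
        s0, s1, s2 = _breslow_sums(Xs, w, first)
        s0e, s1e, s2e = s0[es], s1[es], s2[es]
        ll = float(np.sum((lp[es] - shift) - np.log(s0e)))
        mean_e = s1e / s0e[:, None]
        grad = Xe.sum(axis=0) - mean_e.sum(axis=0)
        info = (s2e / s0e[:, None, None]).sum(axis=0) - mean_e.T @ mean_e
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as err:
            raise EstimationError(
                f"singular information matrix at iteration {it}"
            ) from err
        # step-halving: never accept a move that lowers the likelihood
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            lp_c = Xs @ cand
            shift_c = lp_c.max()
            w_c = np.exp(lp_c - shift_c)
            s0_c = np.cumsum(w_c[::-1])[::-1][first_e]
            ll_c = float(np.sum((lp_c[es] - shift_c) - np.log(s0_c)))
            if ll_c >= ll - 1e-12:
                break
            scale *= 0.5
        beta = beta + scale * step
        if np.isfinite(ll_old) and np.abs(ll - ll_old) <= tol * (np.abs(ll_old) + tol):
            ll_old = ll
            break
        ll_old = ll
    else:
        raise ConvergenceError(
            f"Cox Newton-Raphson did not converge in {max_iter} iterations "
            f"(last log-PL {ll_old:.6g}, |grad| {np.abs(grad).max():.3g})"
        )

    # observed information at the optimum for Wald standard errors
    lp = Xs @ beta
    w = np.exp(lp - lp.max())
    s0, s1, s2 = _breslow_sums(Xs, w, first)
    s0e, s1e, s2e = s0[es], s1[es], s2[es]
    mean_e = s1e / s0e[:, None]
    info = (s2e / s0e[:, None, None]).sum(axis=0) - mean_e.T @ mean_e
    cov = np.linalg.inv(info)
    return CoxPHResult(
        params=beta,
        bse=np.sqrt(np.diag(cov)),
        loglik=ll_old,
        n_iter=it,
        n=n,
        n_events=n_events,
        names=list(names) if names is not None else [f"x{j}" for j in range(p)],
    )
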