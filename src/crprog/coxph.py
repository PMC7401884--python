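"""Minimal Cox proportional-hazards fitter (Breslow ties, Newton-Raphson).

A deliberately small partial-likelihood solver: the MI-bootstrap confidence
intervals and the selection-recovery simulations refit Cox models inside
tight loops, so the fitter is written directly on numpy suffix sums rather
than through a general survival library.  Event times in this package are
continuous, so ties are rare and the Breslow approximation is essentially
exact; agreement with an Efron-ties reference on tie-free data is part of
the test suite.

Only right censoring is supported; covariates enter linearly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CoxPHResult", "fit_coxph", "null_partial_loglik", "breslow_baseline"]

#: |beta| cap signalling a monotone partial likelihood (e.g. a stratum with
#: no events); fits hitting the cap are flagged, not failed.
BETA_CAP = 15.0


@dataclass
class CoxPHResult:
    beta: np.ndarray
    cov: np.ndarray
    loglik: float
    loglik_null: float
    df: int
    n: int
    n_events: int
    converged: bool
    capped: bool

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov), 0.0, None))


def _prepare(X, time, event):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    order = np.argsort(time, kind="stable")
    t = time[order]
    e = event[order]
    Xs = X[order]
    u = np.unique(t[e])
    first = np.searchsorted(t, u, side="left")  # index of first subject at risk
    pos = np.searchsorted(u, t[e])
    d = np.bincount(pos, minlength=u.size).astype(float)
    return Xs, t, e, u, first, pos, d


def null_partial_loglik(time, event) -> float:
    """Breslow partial log-likelihood of the null (no-covariate) model."""
    _, _, _, _, first, _, d = _prepare(np.zeros((len(time), 1)), time, event)
    n = len(time)
    y = (n - first).astype(float)
    return float(-np.sum(d * np.log(y)))


def _suffix_cumsum(a: np.ndarray) -> np.ndarray:
    return np.cumsum(a[::-1], axis=0)[::-1]


def fit_coxph(X, time, event, max_iter: int = 40, tol: float = 1e-9) -> CoxPHResult:
    """Fit a Cox model by Newton-Raphson on the Breslow partial likelihood.

    Parameters
    ----------
    X : (n, p) design matrix (no intercept).
    time : follow-up times.
    event : boolean (or 0/1) indicator of the event of interest; competing
        events must already be coded as censored by the caller.
    """
    Xs, t, e, u, first, pos, d = _prepare(X, time, event)
    n, p = Xs.shape
    n_events = int(e.sum())
    if n_events == 0:
        raise ValueError("no events: Cox model not identifiable")
    if u.size == 0:
        raise ValueError("no event times")

    sum_x_events = np.zeros((u.size, p))
    np.add.at(sum_x_events, pos, Xs[e])

    def loglik_grad_hess(beta):
        eta = Xs @ beta
        shift = eta.max()  # overflow guard; cancels between the two terms
        w = np.exp(eta - shift)
        s0 = _suffix_cumsum(w)[first]
        ll = float((Xs[e] @ beta).sum() - np.sum(d * (np.log(s0) + shift)))
        s1 = _suffix_cumsum(w[:, None] * Xs)[first]
        xbar = s1 / s0[:, None]
        grad = sum_x_events.sum(axis=0) - (d[:, None] * xbar).sum(axis=0)
        iu = np.triu_indices(p)
        prod = _suffix_cumsum(w[:, None] * Xs[:, iu[0]] * Xs[:, iu[1]])[first]
        s2 = np.zeros((u.size, p, p))
        s2[:, iu[0], iu[1]] = prod
        s2[:, iu[1], iu[0]] = prod
        info = (d[:, None, None] * (s2 / s0[:, None, None]
                                    - xbar[:, :, None] * xbar[:, None, :])).sum(axis=0)
        hess = -info
        return ll, grad, hess

    beta = np.zeros(p)
    ll, grad, hess = loglik_grad_hess(beta)
    converged = False
    capped = False
    ll_scale = abs(ll) + 1.0  # rounding floor for likelihood comparisons
    for _ in range(max_iter):
        try:
            delta = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            delta = np.linalg.solve(-hess + 1e-8 * np.eye(p), grad)
        if np.max(np.abs(delta)) < tol:
            converged = True
            break
        step = 1.0
        for _halve in range(30):
            cand = beta + step * delta
            if np.max(np.abs(cand)) > BETA_CAP:
                cand = np.clip(cand, -BETA_CAP, BETA_CAP)
                capped = True
            ll_new, g_new, h_new = loglik_grad_hess(cand)
            if ll_new >= ll - 1e-12 * ll_scale:
                break
            step /= 2.0
        improvement = ll_new - ll
        beta, ll, grad, hess = cand, ll_new, g_new, h_new
        if abs(improvement) < 1e-10 * ll_scale:
            converged = True
            break
        if capped and np.max(np.abs(beta)) >= BETA_CAP:
            break
    try:
        cov = np.linalg.inv(-hess)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(-hess)
    return CoxPHResult(
        beta=beta,
        cov=cov,
        loglik=ll,
        loglik_null=null_partial_loglik(time, np.asarray(event, dtype=bool)),
        df=p,
        n=n,
        n_events=n_events,
        converged=converged,
        capped=capped,
    )


def breslow_baseline(result_beta, X, time, event):
    """Breslow baseline cumulative-hazard increments at covariates = 0.

    Returns ``(times, increments)`` with ``dL0(u) = d(u) / sum_{i at risk}
    exp(x_i' beta)`` at the distinct event times ``u``.
    """
    beta = np.atleast_1d(np.asarray(result_beta, dtype=float))
    Xs, t, e, u, first, pos, d = _prepare(X, time, event)
    w = np.exp(Xs @ beta)
    s0 = _suffix_cumsum(w)[first]
    return u, d / s0
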