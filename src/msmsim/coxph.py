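"""Weighted Cox partial likelihood for counting-process (start, stop] data.

Newton–Raphson maximization of the Breslow partial likelihood with
case weights, plus two variance estimators:

* model-based — inverse observed information of the weighted likelihood;
* robust — the Lin–Wei sandwich built from score residuals summed within
  clusters (individuals), with the weights treated as fixed.  This is the
  "simple sandwich" appropriate for inverse-probability-weighted fits.

Risk sets use the usual counting-process convention: a row (start, stop]
is at risk at time t iff start < t <= stop.  All per-event quantities are
computed with sorted suffix sums and searchsorted, so a fit on a few
hundred thousand rows takes well under a second.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CoxTVResult", "fit_coxtv"]


@dataclass
class CoxTVResult:
    beta: np.ndarray
    vcov_model: np.ndarray
    vcov_robust: np.ndarray | None
    loglik: float
    n_iter: int
    converged: bool
    n_events: int

    def se(self, robust: bool = False) -> np.ndarray:
        v = self.vcov_robust if robust else self.vcov_model
        return np.sqrt(np.diag(v))


def _suffix_sums_at(values, keys, query):
    """sum_i values_i * [keys_i >= q] for each q, via sorted suffix sums."""
    order = np.argsort(keys, kind="stable")
    sorted_keys = keys[order]
    v = values[order]
    suffix = np.cumsum(v[::-1], axis=0)[::-1]
    pos = np.searchsorted(sorted_keys, query, side="left")
    out = np.zeros((len(query),) + v.shape[1:], dtype=float)
    inside = pos < len(sorted_keys)
    out[inside] = suffix[pos[inside]]
    return out


class _PartialLikelihood:
    """Breslow partial likelihood, gradient, information on fixed data."""

    def __init__(self, X, start, stop, event, w):
        self.X, self.start, self.stop, self.w = X, start, stop, w
        ev_idx = np.flatnonzero(event)
        t_ev = stop[ev_idx]
        order = np.argsort(t_ev, kind="stable")
        self.ev_idx = ev_idx[order]
        self.t_ev = t_ev[order]
        self.w_ev = w[self.ev_idx]
        self.X_ev = X[self.ev_idx]
        p = X.shape[1]
        self.iu = np.triu_indices(p)
        self.xx = X[:, self.iu[0]] * X[:, self.iu[1]]

    def event_sums(self, r):
        """S0, S1, S2 over the risk set at each event time.

        Uses [start < t <= stop] = [stop >= t] - [start >= t], valid
        because start < stop on every row.
        """
        p = self.X.shape[1]
        vals = np.concatenate(
            [r[:, None], r[:, None] * self.X, r[:, None] * self.xx], axis=1
        )
        tot = (
            _suffix_sums_at(vals, self.stop, self.t_ev)
            - _suffix_sums_at(vals, self.start, self.t_ev)
        )
        S0 = tot[:, 0]
        S1 = tot[:, 1 : 1 + p]
        S2 = np.zeros((len(self.t_ev), p, p))
        S2[:, self.iu[0], self.iu[1]] = tot[:, 1 + p :]
        S2[:, self.iu[1], self.iu[0]] = tot[:, 1 + p :]
        return S0, S1, S2

    def at(self, beta):
        eta = self.X @ beta
        shift = eta.max()
        r = self.w * np.exp(eta - shift)
        S0, S1, S2 = self.event_sums(r)
        ll = float(np.sum(self.w_ev * (eta[self.ev_idx] - shift - np.log(S0))))
        xbar = S1 / S0[:, None]
        grad = (self.w_ev[:, None] * (self.X_ev - xbar)).sum(axis=0)
        M2 = S2 / S0[:, None, None] - np.einsum("ep,eq->epq", xbar, xbar)
        info = np.einsum("e,epq->pq", self.w_ev, M2)
        return ll, grad, info, r, S0, xbar


def fit_coxtv(
    X: np.ndarray,
    start: np.ndarray,
    stop: np.ndarray,
    event: np.ndarray,
    weights: np.ndarray | None = None,
    ids: np.ndarray | None = None,
    robust: bool = False,
    max_iter: int = 50,
    tol: float = 1e-9,
) -> CoxTVResult:
    """Fit the weighted Cox model; see module docstring.

    Parameters are row-aligned arrays; ``ids`` is required when
    ``robust=True`` (score residuals are summed within id before the
    sandwich is formed).
    """
    X = np.asarray(X, dtype=float)
    start = np.asarray(start, dtype=float)
    stop = np.asarray(stop, dtype=float)
    event = np.asarray(event).astype(bool)
    n, p = X.shape
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    if np.any(stop <= start):
        raise ValueError("rows must satisfy stop > start")
    if not event.any():
        raise ValueError("no events in the data")

    pl = _PartialLikelihood(X, start, stop, event, w)
    beta = np.zeros(p)
    ll, grad, info, r, S0, xbar = pl.at(beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "singular information matrix (separation or collinearity)"
            ) from exc
        new = pl.at(beta + step)
        halvings = 0
        while not np.isfinite(new[0]) or (new[0] < ll - 1e-10 and halvings < 10):
            step = step / 2.0
            new = pl.at(beta + step)
            halvings += 1
        beta = beta + step
        ll, grad, info, r, S0, xbar = new
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    vcov_model = np.linalg.inv(info)

    vcov_robust = None
    if robust:
        if ids is None:
            raise ValueError("robust variance requires ids for clustering")
        # score residuals: event part minus cumulative-hazard part
        U = np.zeros((n, p))
        U[pl.ev_idx] = pl.w_ev[:, None] * (pl.X_ev - xbar)
        q = pl.w_ev / S0
        A_cum = np.concatenate([[0.0], np.cumsum(q)])
        B_cum = np.vstack([np.zeros(p), np.cumsum(q[:, None] * xbar, axis=0)])
        hi = np.searchsorted(pl.t_ev, stop, side="right")
        lo = np.searchsorted(pl.t_ev, start, side="right")
        A = A_cum[hi] - A_cum[lo]
        B = B_cum[hi] - B_cum[lo]
        U -= r[:, None] * (X * A[:, None] - B)
        ids = np.asarray(ids)
        uniq, inv = np.unique(ids, return_inverse=True)
        Uc = np.zeros((uniq.size, p))
        np.add.at(Uc, inv, U)
        meat = Uc.T @ Uc
        vcov_robust = vcov_model @ meat @ vcov_model

    return CoxTVResult(
        beta=beta, vcov_model=vcov_model, vcov_robust=vcov_robust,
        loglik=ll, n_iter=it, converged=converged, n_events=int(pl.ev_idx.size),
    )
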