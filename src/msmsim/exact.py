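"""Exact-CDF simulation of individual trajectories, and interval hazard math.

This module implements the simulation algorithm in the case where the
conditional CDF of the risk score among survivors is known analytically
(``DgpConfig.exact_cdf``).  At each visit the covariates and treatment are
drawn from their conditional laws, the risk quantile is obtained by plugging
the risk score into its known CDF, and the Gaussian copula converts it into
a failure indicator whose marginal hazard (given ``X``) is exactly the MSM
hazard.

For continuous-time families the discrete failure probability over
``(k, k+1]`` is ``g = 1 - exp(-∫ λ dt)`` and the failure time is localized
within the interval by inverting the interval CDF at the latent uniform
``u_Y`` (see :func:`invert_interval_failure_time`): this nests the discrete
thresholding rule and preserves the continuous-time hazard given ``X``.

Also defined here: :class:`TrajectoryBatch`, the columnar container shared
with the match-pool simulator, and :func:`apply_censoring`.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import brentq
from scipy.special import ndtr, ndtri

from .config import DgpConfig, MsmSpec, Trajectory
from .copula import QUANTILE_EPS

__all__ = [
    "TrajectoryBatch",
    "simulate_individual_exact",
    "simulate_batch_exact",
    "interval_failure_prob",
    "invert_interval_failure_time",
    "apply_censoring",
]

_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(32)


@dataclass
class TrajectoryBatch:
    """Columnar batch of simulated trajectories.

    ``l`` has shape ``(n, K+1, d_l)`` and ``a`` shape ``(n, K+1)``; entries
    beyond ``n_visits[i]`` are NaN (the individual had failed).  ``y`` holds
    the survival indicators ``Y_1..Y_{K+1}``.  ``t_fail`` is ``inf`` for
    individuals surviving past ``K+1``; for the discrete family it is the
    visit index at which failure was recorded.  Censoring fields are filled
    by :func:`apply_censoring`.
    """

    x: np.ndarray
    b: np.ndarray
    l: np.ndarray
    a: np.ndarray
    y: np.ndarray
    t_fail: np.ndarray
    n_visits: np.ndarray
    K: int
    x_names: tuple
    b_names: tuple
    l_names: tuple
    t_cens: Optional[np.ndarray] = None
    t_obs: Optional[np.ndarray] = None
    event: Optional[np.ndarray] = None

    @property
    def n(self) -> int:
        return self.x.shape[0]

    def trajectory(self, i: int) -> Trajectory:
        nv = int(self.n_visits[i])
        return Trajectory(
            x=self.x[i].copy(),
            b=self.b[i].copy(),
            l=self.l[i, :nv].copy(),
            a=self.a[i, :nv].copy(),
            y=self.y[i].copy(),
            t_fail=float(self.t_fail[i]),
            t_cens=float(self.t_cens[i]) if self.t_cens is not None else np.inf,
            t_obs=float(self.t_obs[i]) if self.t_obs is not None else None,
            event=int(self.event[i]) if self.event is not None else None,
        )

    def to_trajectories(self) -> list[Trajectory]:
        return [self.trajectory(i) for i in range(self.n)]


def interval_failure_prob(msm: MsmSpec, a_bar, x, k: int):
    """Failure probability over ``(k, k+1]`` for a continuous-time MSM.

    ``1 - exp(-Λ_k)`` with ``Λ_k = ∫_k^{k+1} λ^{ā_k}(t | x) dt``; the
    integral is closed form for a piecewise-constant rate and 32-point
    Gauss–Legendre quadrature otherwise.  ``x`` is ``(N, d_x)``; returns
    ``(N,)``.  Raises if the rate is negative anywhere probed (the additive
    family can stray below zero).
    """
    if msm.family == "discrete_logistic":
        raise ValueError("interval_failure_prob applies to continuous-time families")
    lam = _interval_cumhaz(msm, a_bar, x, k)
    return -np.expm1(-lam)


def _interval_rate(msm, a_bar, x, k):
    """Constant within-interval rate (piecewise-constant families)."""
    lam = np.asarray(msm.hazard_fn(k + 0.5, a_bar, x, msm.beta), dtype=float)
    if np.any(lam < 0):
        raise ValueError(f"negative hazard rate on interval ({k}, {k + 1}]")
    return lam


def _interval_cumhaz(msm, a_bar, x, k):
    if msm.piecewise_constant:
        return _interval_rate(msm, a_bar, x, k)
    t = k + 0.5 + 0.5 * _GL_NODES  # nodes mapped onto (k, k+1)
    rates = np.stack(
        [np.asarray(msm.hazard_fn(ti, a_bar, x, msm.beta), dtype=float) for ti in t]
    )
    if np.any(rates < 0):
        raise ValueError(f"negative hazard rate on interval ({k}, {k + 1}]")
    return 0.5 * np.tensordot(_GL_WEIGHTS, rates, axes=1)


def invert_interval_failure_time(u_Y, msm: MsmSpec, a_bar, x, k: int):
    """Failure time in ``(k, k+1]`` solving ``1 - exp(-∫_k^t λ ds) = u_Y``.

    Closed form ``t = k - log(1 - u_Y)/λ`` for a constant rate; bisection
    (``brentq``, tol 1e-10) otherwise.  Requires ``u_Y`` below the interval
    failure probability.  Marginally over ``u_Y ~ Uniform`` restricted below
    that bound, ``T`` follows the MSM hazard on the interval given ``x``.
    """
    u = np.atleast_1d(np.asarray(u_Y, dtype=float))
    g = interval_failure_prob(msm, a_bar, x, k)
    if np.any(u >= g):
        raise ValueError("u_Y must be below the interval failure probability")
    if msm.piecewise_constant:
        lam = _interval_rate(msm, a_bar, x, k)
        t = k - np.log1p(-u) / lam
    else:
        t = np.empty_like(u)
        for i, ui in enumerate(u):
            xi = x[i : i + 1]
            ai = [np.asarray(av)[i : i + 1] for av in a_bar]

            def cdf_minus_u(s):
                frac = s - k
                nodes = k + frac * 0.5 * (1 + _GL_NODES)
                rates = np.array(
                    [float(msm.hazard_fn(ti, ai, xi, msm.beta)[0]) for ti in nodes]
                )
                cum = 0.5 * frac * np.dot(_GL_WEIGHTS, rates)
                return -np.expm1(-cum) - ui

            t[i] = brentq(cdf_minus_u, k + 1e-14, k + 1.0, xtol=1e-10)
    t = np.minimum(t, float(k + 1))
    return t if np.asarray(u_Y).ndim else float(t[0])


def _hazard_threshold(msm, a_hist, x, k):
    """Per-row failure probability g_{k+1} and its normal-score threshold."""
    if msm.family == "discrete_logistic":
        g = np.asarray(msm.hazard_fn(k + 1, a_hist, x, msm.beta), dtype=float)
        if np.any((g < 0) | (g > 1)):
            raise ValueError(f"discrete hazard outside [0, 1] at visit {k + 1}")
    else:
        g = interval_failure_prob(msm, a_hist, x, k)
    with np.errstate(divide="ignore"):
        thr = np.where(g <= 0, -np.inf, np.where(g >= 1, np.inf, ndtri(np.clip(g, 1e-300, 1 - 1e-16))))
    return g, thr


def simulate_batch_exact(
    msm: MsmSpec,
    dgp: DgpConfig,
    n: int,
    rng: np.random.Generator,
    policy=None,
) -> TrajectoryBatch:
    """Simulate ``n`` trajectories using the known risk-score CDFs.

    ``policy`` optionally overrides the observational treatment sampler with
    ``policy(k, x, b, l, a_prev, rng) -> (N,)`` (e.g. a static regime, to
    check MSM compatibility under intervention).
    """
    if dgp.exact_cdf is None:
        raise ValueError("exact simulation requires DgpConfig.exact_cdf")
    if len(dgp.exact_cdf) < msm.K + 1:
        raise ValueError("exact_cdf must provide one CDF per visit 0..K")
    K = msm.K
    x = np.atleast_2d(dgp.sample_x(rng, n))
    b = np.atleast_2d(dgp.sample_b(rng, x))
    dl = None
    l_store = None
    a_store = np.full((n, K + 1), np.nan)
    y = np.ones((n, K + 1), dtype=np.int8)
    t_fail = np.full(n, np.inf)
    n_visits = np.zeros(n, dtype=np.int64)
    discrete = msm.family == "discrete_logistic"

    act = np.arange(n)
    l_prev = None
    a_prev = None
    a_hist: list[np.ndarray] = []
    l_hist: list[np.ndarray] = []
    for k in range(K + 1):
        if act.size == 0:
            break
        xa, ba = x[act], b[act]
        l = np.atleast_2d(dgp.sample_l(rng, k, xa, ba, l_prev, a_prev))
        if l_store is None:
            dl = l.shape[1]
            l_store = np.full((n, K + 1, dl), np.nan)
        l_store[act, k] = l
        if policy is None:
            a = np.asarray(dgp.sample_a(rng, k, xa, ba, l, a_prev), dtype=float)
        else:
            a = np.asarray(policy(k, xa, ba, l, a_prev, rng), dtype=float)
        a_store[act, k] = a
        l_hist.append(l)
        if dgp.history_depth is not None:
            l_hist = l_hist[-dgp.history_depth :]
        a_hist.append(a)
        h = np.asarray(dgp.risk_score(k, xa, ba, l_hist), dtype=float)
        u_H = np.clip(
            np.asarray(dgp.exact_cdf[k](h, xa, a_hist), dtype=float),
            QUANTILE_EPS,
            1 - QUANTILE_EPS,
        )
        z_H = ndtri(u_H)
        rho = dgp.rho_at(k)
        z_Y = rho * z_H + np.sqrt(1 - rho**2) * rng.standard_normal(act.size)
        g, thr = _hazard_threshold(msm, a_hist, xa, k)
        fail = z_Y < thr
        if fail.any():
            idx = act[fail]
            if discrete:
                t_fail[idx] = k + 1
            else:
                u_Y = ndtr(z_Y[fail])
                t_fail[idx] = invert_interval_failure_time(
                    u_Y, msm, [av[fail] for av in a_hist], xa[fail], k
                )
            y[idx, k:] = 0
        n_visits[act] = k + 1
        keep = ~fail
        act = act[keep]
        l_prev = l[keep]
        a_prev = a[keep]
        a_hist = [av[keep] for av in a_hist]
        l_hist = [lv[keep] for lv in l_hist]

    return TrajectoryBatch(
        x=x, b=b, l=l_store, a=a_store, y=y, t_fail=t_fail, n_visits=n_visits,
        K=K, x_names=tuple(dgp.x_names), b_names=tuple(dgp.b_names),
        l_names=tuple(dgp.l_names),
    )


def simulate_individual_exact(
    msm: MsmSpec, dgp: DgpConfig, rng: np.random.Generator, policy=None
) -> Trajectory:
    """Simulate one trajectory with known risk-score CDFs (steps 1–8)."""
    return simulate_batch_exact(msm, dgp, 1, rng, policy=policy).trajectory(0)


def apply_censoring(traj, dgp: DgpConfig, rng: np.random.Generator):
    """Draw independent censoring and fill observed time / event status.

    ``t_obs = min(t_fail, t_cens, K+1)`` and ``event = 1`` iff the failure
    time is observed (``t_fail <= min(t_cens, K+1)``).  Works on a
    :class:`TrajectoryBatch` or a single :class:`Trajectory`; returns a
    shallow copy with the censoring fields filled.
    """
    if isinstance(traj, TrajectoryBatch):
        n = traj.n
        t_cens = (
            np.asarray(dgp.sample_censoring(rng, n), dtype=float)
            if dgp.sample_censoring is not None
            else np.full(n, np.inf)
        )
        admin = float(traj.K + 1)
        out = _copy.copy(traj)
        out.t_cens = t_cens
        out.t_obs = np.minimum(np.minimum(traj.t_fail, t_cens), admin)
        out.event = (traj.t_fail <= np.minimum(t_cens, admin)).astype(np.int8)
        return out
    t_cens = (
        float(dgp.sample_censoring(rng, 1)[0])
        if dgp.sample_censoring is not None
        else np.inf
    )
    admin = float(len(traj.y))  # y holds Y_1..Y_{K+1}
    out = _copy.copy(traj)
    out.t_cens = t_cens
    out.t_obs = min(traj.t_fail, t_cens, admin)
    out.event = int(traj.t_fail <= min(t_cens, admin))
    return out
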