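"""Bivariate Gaussian-copula machinery linking risk quantiles to survival outcomes.

The simulation algorithm reduces the dependence of the potential survival
indicator ``Y_{k+1}`` on the covariate history to a scalar *risk score*
``H_k``, whose conditional quantile ``U_H`` (given baseline covariates ``X``
and survival to visit ``k``) is Uniform(0,1).  A bivariate Gaussian copula
with correlation ``rho`` (``-1 < rho <= 0``) then ties ``U_H`` to a latent
uniform ``U_Y`` that is thresholded against the marginal hazard ``g`` to
produce the failure indicator.  Because ``U_Y`` is marginally uniform given
``X``, the marginal (over ``B`` and the confounder history) failure
probability is exactly ``g`` — this is what makes the simulated data
compatible with the chosen marginal structural model.

All functions are pure, accept scalars or numpy arrays, and draw randomness
only from an explicitly passed :class:`numpy.random.Generator`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr, ndtri

__all__ = [
    "RiskState",
    "LatentOutcome",
    "conditional_failure_prob",
    "sample_latent",
    "threshold_failure",
    "exact_risk_quantile",
    "empirical_risk_quantiles",
    "QUANTILE_EPS",
]

#: Quantiles are clipped into (QUANTILE_EPS, 1 - QUANTILE_EPS) before the
#: normal PPF so latent normal scores stay finite.
QUANTILE_EPS = 1e-12


@dataclass(frozen=True)
class RiskState:
    """A risk score together with its quantile and normal score.

    Attributes
    ----------
    h : float or ndarray
        Risk score ``H_k = h_k(X, B, L̄_k)``.
    u_H : float or ndarray
        Risk quantile ``F_{H_k}(h | X, survival)``, strictly inside (0, 1).
    z_H : float or ndarray
        Normal score ``Φ⁻¹(u_H)``.
    """

    h: np.ndarray
    u_H: np.ndarray
    z_H: np.ndarray


@dataclass(frozen=True)
class LatentOutcome:
    """Latent normal/uniform pair and the thresholded failure indicator."""

    z_Y: np.ndarray
    u_Y: np.ndarray
    y: np.ndarray | None = None


def _check_rho(rho) -> np.ndarray:
    rho = np.asarray(rho, dtype=float)
    if np.any(rho <= -1.0) or np.any(rho > 0.0):
        raise ValueError(f"copula correlation must satisfy -1 < rho <= 0, got {rho}")
    return rho


def conditional_failure_prob(g, u_H, rho):
    """Conditional failure probability given the risk quantile.

    Computes ``Φ((Φ⁻¹(g) − ρ·Φ⁻¹(u_H)) / sqrt(1 − ρ²))``, the probability of
    failure in the next interval for an individual whose risk quantile among
    same-``X`` survivors is ``u_H``, when the marginal (MSM) hazard is ``g``.
    Averaging over ``u_H ~ Uniform(0,1)`` returns ``g`` exactly.

    ``g`` equal to 0 or 1 passes through unchanged (degenerate threshold).
    """
    rho = _check_rho(rho)
    g = np.asarray(g, dtype=float)
    u_H = np.asarray(u_H, dtype=float)
    interior = (g > 0.0) & (g < 1.0)
    z_g = ndtri(np.where(interior, g, 0.5))
    z_h = ndtri(u_H)
    p = ndtr((z_g - rho * z_h) / np.sqrt(1.0 - rho**2))
    out = np.where(interior, p, g)
    return out if out.ndim else float(out)


def sample_latent(z_H, rho, rng: np.random.Generator) -> LatentOutcome:
    """Draw the latent outcome score ``Z_Y ~ Normal(ρ z_H, 1 − ρ²)``.

    Marginally over ``z_H ~ Normal(0,1)``, ``Z_Y`` is standard normal and
    ``U_Y = Φ(Z_Y)`` is Uniform(0,1) — the property that preserves the
    marginal hazard.
    """
    rho = _check_rho(rho)
    z_H = np.asarray(z_H, dtype=float)
    z_Y = rho * z_H + np.sqrt(1.0 - rho**2) * rng.standard_normal(z_H.shape)
    return LatentOutcome(z_Y=z_Y, u_Y=ndtr(z_Y))


def threshold_failure(u_Y, g):
    """Failure indicator: ``y = 0`` iff ``u_Y < g`` (strict), else ``y = 1``.

    Returns an integer (array) in {0, 1}; note the survival-indicator coding,
    ``y = 1`` means the individual survives the interval.
    """
    y = (np.asarray(u_Y, dtype=float) >= np.asarray(g, dtype=float)).astype(np.int8)
    return y if y.ndim else int(y)


def exact_risk_quantile(h, cdf, eps: float = QUANTILE_EPS) -> RiskState:
    """Risk quantile from a known conditional CDF of the risk score.

    Parameters
    ----------
    h : float or ndarray
        Risk score value(s).
    cdf : callable
        The conditional CDF ``F_{H_k}(· | X, survival)``; must map ``h`` into
        [0, 1].
    eps : float
        Clipping bound applied before ``Φ⁻¹`` so that ``z_H`` is finite.
    """
    h = np.asarray(h, dtype=float)
    u = np.asarray(cdf(h), dtype=float)
    if np.any(u < 0.0) or np.any(u > 1.0):
        raise ValueError("cdf returned values outside [0, 1]")
    u = np.clip(u, eps, 1.0 - eps)
    return RiskState(h=h, u_H=u, z_H=ndtri(u))


def _ordinal_ranks(h: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Ascending ordinal ranks (1 = smallest) along the last axis.

    Ties are broken by an independent uniform key, i.e. by a uniformly random
    permutation among tied values.  The tie-break draws are consumed only for
    rows that actually contain ties, so continuous scores cost one argsort.
    """
    h = np.atleast_2d(h)
    order = np.argsort(h, axis=-1)  # ties re-ranked below, stability not needed
    sorted_h = np.take_along_axis(h, order, axis=-1)
    tied_rows = np.flatnonzero((np.diff(sorted_h, axis=-1) == 0.0).any(axis=-1))
    if tied_rows.size:
        key = rng.random((tied_rows.size, h.shape[-1]))
        order[tied_rows] = np.lexsort((key, h[tied_rows]))
    ranks = np.empty_like(order)
    np.put_along_axis(ranks, order, np.arange(1, h.shape[-1] + 1)[None, :], axis=-1)
    return ranks


def empirical_risk_quantiles(h, rng: np.random.Generator, axis: int = -1) -> np.ndarray:
    """Rank-based risk quantiles ``U_j = (R_j − W_j) / m`` over a pool.

    ``R_j`` is the ascending rank of ``h_j`` within the pool of ``m`` scores
    and ``W_j ~ Uniform(0,1)`` jitters the rank so that, when the scores are
    exchangeable draws from a common law, each ``U_j`` is marginally
    Uniform(0,1).  Every returned value lies strictly in (0, 1).  Invariant
    under strictly increasing transforms of the scores (ranks only matter).

    ``h`` may be a vector (one pool) or a 2-D array of pools along ``axis``.
    """
    h = np.asarray(h, dtype=float)
    if not np.all(np.isfinite(h)):
        raise ValueError("risk scores must be finite")
    vector_in = h.ndim == 1
    if h.ndim > 2:
        raise ValueError("h must be 1- or 2-dimensional")
    h2 = np.atleast_2d(np.moveaxis(h, axis, -1) if h.ndim == 2 else h)
    m = h2.shape[-1]
    ranks = _ordinal_ranks(h2, rng)
    u = (ranks - rng.random(h2.shape)) / m
    if vector_in:
        return u[0]
    return np.moveaxis(u, -1, axis) if axis not in (-1, 1) else u
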