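"""Match-pool simulation: estimate risk-score CDFs by ranks while simulating.

When the conditional CDF of the risk score among survivors is not available
in closed form, each sampled individual is simulated together with ``m - 1``
*matches* that share its baseline covariates ``X`` and (imposed) treatment
path, but draw their own ``B`` and confounder histories.  At every visit the
pool's empirical ranks provide the risk quantiles
``U_j = (R_j - W_j) / m``; matches that fail are replaced by copies of
randomly chosen surviving matches (provenance indices ``I_j`` track the
copies), and when fewer than a set fraction of the *original* matches
remain, the pool is discarded and rebuilt at a much larger size ``m_big``
by replaying the match generation from visit 0 under the realized treatment
path.  Only the sampled individual's trajectory is kept.

Two entry points: :func:`simulate_individual_extended` is the per-individual
reference implementation (one RNG stream per individual);
:func:`simulate_batch_extended` vectorizes many individuals' pools as 2-D
arrays and is what the study harness uses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr, ndtri

from .config import DgpConfig, MsmSpec, Trajectory
from .copula import empirical_risk_quantiles
from .exact import TrajectoryBatch, _hazard_threshold, invert_interval_failure_time

__all__ = [
    "MatchPool",
    "PoolDepletedError",
    "simulate_individual_extended",
    "simulate_batch_extended",
    "replace_failed_matches",
    "restart_pool",
]

logger = logging.getLogger(__name__)


class PoolDepletedError(RuntimeError):
    """Every match in a pool failed, leaving no survivor to copy.

    Cannot occur in practice when restarts are enabled and ``m_big`` is
    large relative to the per-visit hazard, but must be surfaced rather
    than silently producing a degenerate pool.
    """


@dataclass
class MatchPool:
    """State of one sampled individual's pool of matched pseudo-individuals.

    Row 0 of the member arrays is the sampled individual; rows ``1..m-1``
    are the matches.  ``I`` holds the matches' provenance indices (initially
    ``I_j = j``); the number of distinct values of ``I`` is the number of
    original matches still represented.  ``l_hist`` retains the most recent
    confounder arrays (all visits when the config's ``history_depth`` is
    None), aligned so that ``l_hist[-1]`` is visit ``k_next - 1``.
    """

    m: int
    k_next: int
    x: np.ndarray               # (1, d_x) shared baseline covariates
    a_hist: list                # realized treatments a_0 .. a_{k_next-1}
    b: np.ndarray               # (m, d_b) member baselines
    I: np.ndarray               # (m-1,) provenance indices of the matches
    l_hist: list = field(default_factory=list)  # recent (m, d_l) arrays

    def n_distinct(self) -> int:
        return int(np.unique(self.I).size) if self.I.size else 0

    def original_fraction(self) -> float:
        return self.n_distinct() / max(self.m - 1, 1)


def replace_failed_matches(pool: MatchPool, failures, rng: np.random.Generator) -> MatchPool:
    """Replace failed matches by copies of uniformly chosen surviving matches.

    ``failures`` holds member indices ``j`` in ``1..m-1``.  Each failed
    match independently receives the provenance index, baselines and
    confounder history of a randomly chosen surviving match and its survival
    state is reset; the sampled individual (member 0) is never replaced and
    never copied.  Mutates and returns ``pool``.
    """
    failures = np.asarray(failures, dtype=np.int64)
    if failures.size == 0:
        return pool
    if failures.min() < 1 or failures.max() >= pool.m:
        raise ValueError("failures must be match member indices in 1..m-1")
    alive = np.ones(pool.m, dtype=bool)
    alive[failures] = False
    survivors = np.flatnonzero(alive[1:]) + 1
    if survivors.size == 0:
        raise PoolDepletedError(
            f"all {pool.m - 1} matches failed at visit {pool.k_next}; "
            "increase m/m_big or the restart fraction"
        )
    src = rng.choice(survivors, size=failures.size, replace=True)
    pool.I[failures - 1] = pool.I[src - 1]
    pool.b[failures] = pool.b[src]
    for arr in pool.l_hist:
        arr[failures] = arr[src]
    return pool


def _push_history(l_hist: list, l: np.ndarray, depth) -> list:
    l_hist.append(l)
    if depth is not None and len(l_hist) > depth:
        del l_hist[: len(l_hist) - depth]
    return l_hist


def restart_pool(pool: MatchPool, msm: MsmSpec, dgp: DgpConfig,
                 rng: np.random.Generator) -> MatchPool:
    """Discard the matches and rebuild a pool of ``m_big - 1`` fresh ones.

    The sampled individual's realized data through visit ``k_next - 1`` and
    its survival indicator are retained verbatim.  New matches are replayed
    from visit 0 under the realized treatment path: fresh ``B`` and
    confounder draws, within-pool rank quantiles and copula failure draws at
    every replayed visit, with failed-match replacement applied, so that the
    surviving replayed matches are draws from the survivor-conditional law.
    """
    mb = dgp.m_big
    n_match = mb - 1
    x_mem = np.repeat(pool.x, n_match, axis=0)
    b_m = np.atleast_2d(dgp.sample_b(rng, x_mem))
    I = np.arange(1, mb, dtype=np.int64)
    l_hist_m: list[np.ndarray] = []
    l_prev = None
    for k in range(pool.k_next):
        a_prev = None if k == 0 else np.full(n_match, pool.a_hist[k - 1])
        l = np.atleast_2d(dgp.sample_l(rng, k, x_mem, b_m, l_prev, a_prev))
        _push_history(l_hist_m, l, dgp.history_depth)
        h = np.asarray(dgp.risk_score(k, x_mem, b_m, l_hist_m), dtype=float)
        u = empirical_risk_quantiles(h, rng)
        rho = dgp.rho_at(k)
        z_y = rho * ndtri(u) + np.sqrt(1 - rho**2) * rng.standard_normal(n_match)
        a_arrays = [np.full(1, av) for av in pool.a_hist[: k + 1]]
        _, thr = _hazard_threshold(msm, a_arrays, pool.x, k)
        failed = np.flatnonzero(z_y < thr[0])
        if failed.size == n_match:
            raise PoolDepletedError(
                f"all {n_match} replayed matches failed at visit {k} during restart"
            )
        if failed.size:
            alive = np.ones(n_match, dtype=bool)
            alive[failed] = False
            survivors = np.flatnonzero(alive)
            src = rng.choice(survivors, size=failed.size, replace=True)
            I[failed] = I[src]
            b_m[failed] = b_m[src]
            for arr in l_hist_m:
                arr[failed] = arr[src]
        l_prev = l_hist_m[-1]
    # stitch the sampled individual's retained rows back on top
    b_new = np.vstack([pool.b[:1], b_m])
    n_keep = len(l_hist_m)
    sampled_recent = pool.l_hist[-n_keep:] if n_keep else []
    l_hist_new = [
        np.vstack([s[:1], lm]) for s, lm in zip(sampled_recent, l_hist_m)
    ]
    logger.debug(
        "pool restart at visit %d: %d distinct originals of %d; new size %d",
        pool.k_next, pool.n_distinct(), pool.m - 1, mb,
    )
    return MatchPool(
        m=mb, k_next=pool.k_next, x=pool.x, a_hist=list(pool.a_hist),
        b=b_new, I=I, l_hist=l_hist_new,
    )


@dataclass
class _SampledState:
    """The sampled individual's accumulating record."""

    x: np.ndarray
    l: list = field(default_factory=list)
    a: list = field(default_factory=list)
    y: list = field(default_factory=list)
    t_fail: float = np.inf


def _run_pool(state: _SampledState, pool: MatchPool, msm: MsmSpec, dgp: DgpConfig,
              rng: np.random.Generator, policy=None) -> None:
    """Advance a single sampled individual and its pool to failure or visit K."""
    K = msm.K
    discrete = msm.family == "discrete_logistic"
    while pool.k_next <= K and state.t_fail == np.inf:
        k = pool.k_next
        m = pool.m
        x_mem = np.repeat(pool.x, m, axis=0)
        l_prev = pool.l_hist[-1] if k > 0 else None
        a_prev_mem = None if k == 0 else np.full(m, pool.a_hist[k - 1])
        l = np.atleast_2d(dgp.sample_l(rng, k, x_mem, pool.b, l_prev, a_prev_mem))
        _push_history(pool.l_hist, l, dgp.history_depth)
        a_prev = None if k == 0 else np.full(1, pool.a_hist[k - 1])
        if policy is None:
            a = float(np.asarray(
                dgp.sample_a(rng, k, pool.x, pool.b[:1], l[:1], a_prev)
            ).ravel()[0])
        else:
            a = float(np.asarray(policy(k, pool.x, pool.b[:1], l[:1], a_prev, rng)).ravel()[0])
        pool.a_hist.append(a)
        state.l.append(l[0].copy())
        state.a.append(a)
        h = np.asarray(dgp.risk_score(k, x_mem, pool.b, pool.l_hist), dtype=float)
        u = empirical_risk_quantiles(h, rng)
        rho = dgp.rho_at(k)
        z_y = rho * ndtri(u) + np.sqrt(1 - rho**2) * rng.standard_normal(m)
        a_arrays = [np.full(1, av) for av in pool.a_hist]
        g, thr = _hazard_threshold(msm, a_arrays, pool.x, k)
        fail = z_y < thr[0]
        state.y.append(0 if fail[0] else 1)
        pool.k_next = k + 1
        if fail[0]:
            if discrete:
                state.t_fail = float(k + 1)
            else:
                u_y = min(ndtr(z_y[0]), g[0] * (1 - 1e-15))
                state.t_fail = float(
                    invert_interval_failure_time(
                        np.array([u_y]), msm, a_arrays, pool.x, k
                    )[0]
                )
            return
        if k == K:
            return
        failures = np.flatnonzero(fail[1:]) + 1
        depleted = failures.size == m - 1
        if not depleted:
            replace_failed_matches(pool, failures, rng)
        if pool.m < dgp.m_big and (
            depleted or pool.original_fraction() < dgp.restart_fraction
        ):
            # full depletion is the extreme case of the restart rule: the
            # matches are discarded either way
            pool = restart_pool(pool, msm, dgp, rng)
        elif depleted:
            raise PoolDepletedError(
                f"all {m - 1} matches failed at visit {k}; "
                "increase m/m_big or the restart fraction"
            )


def simulate_individual_extended(
    msm: MsmSpec, dgp: DgpConfig, rng: np.random.Generator,
    m: int | None = None, policy=None,
) -> Trajectory:
    """Simulate one trajectory with rank-estimated risk-score CDFs.

    The reference, per-individual implementation of the extended algorithm
    (shared ``X`` and treatment path across the pool, per-member ``B`` and
    confounders, within-pool rank quantiles, failed-match replacement, and
    large-pool restart).  Pass an independent ``rng`` per individual for
    reproducibility independent of vectorization; the match data are
    discarded.
    """
    m = int(m if m is not None else dgp.m)
    if m < 2:
        raise ValueError("match pool size m must be >= 2")
    x = np.atleast_2d(dgp.sample_x(rng, 1))
    x_mem = np.repeat(x, m, axis=0)
    b = np.atleast_2d(dgp.sample_b(rng, x_mem))
    pool = MatchPool(
        m=m, k_next=0, x=x, a_hist=[], b=b,
        I=np.arange(1, m, dtype=np.int64),
    )
    state = _SampledState(x=x[0])
    _run_pool(state, pool, msm, dgp, rng, policy=policy)
    K = msm.K
    y = np.ones(K + 1, dtype=np.int8)
    y[: len(state.y)] = state.y
    if state.t_fail < np.inf:
        y[len(state.y) - 1 :] = 0
    return Trajectory(
        x=state.x, b=b[0].copy(),
        l=np.array(state.l), a=np.array(state.a, dtype=float),
        y=y, t_fail=state.t_fail,
    )


# --------------------------------------------------------------------------
# Vectorized batch engine
# --------------------------------------------------------------------------

def _batch_replace(rng, fail_m, row_idx, arrays_3d, I):
    """Vectorized failed-match replacement across many pools.

    ``fail_m`` is ``(r, m-1)`` for the rows in ``row_idx``; each failed slot
    draws source match columns uniformly until it hits a survivor (rejection
    sampling, with an argsort fallback when pools are nearly depleted).
    """
    r, mm = fail_m.shape
    n_alive = mm - fail_m.sum(axis=1)
    if np.any(n_alive == 0):
        bad = row_idx[np.flatnonzero(n_alive == 0)[0]]
        raise PoolDepletedError(
            f"all matches failed in pool of sampled individual {bad}; "
            "increase m/m_big or the restart fraction"
        )
    rows, cols = np.nonzero(fail_m)
    if rows.size == 0:
        return
    src = rng.integers(0, mm, size=rows.size)
    bad = fail_m[rows, src]
    for _ in range(30):
        if not bad.any():
            break
        nb = int(bad.sum())
        src[bad] = rng.integers(0, mm, size=nb)
        bad = fail_m[rows, src]
    if bad.any():  # nearly-depleted pools: pick survivors directly
        sub_rows = np.unique(rows[bad])
        order = np.argsort(fail_m[sub_rows], axis=1, kind="stable")  # alive first
        pos = np.searchsorted(sub_rows, rows[bad])
        pick = rng.integers(0, n_alive[rows[bad]])
        src[bad] = order[pos, pick]
        assert not fail_m[rows, src].any()
    gr, gf, gs = row_idx[rows], cols + 1, src + 1  # member columns incl. sampled offset
    for arr in arrays_3d:
        arr[gr, gf] = arr[gr, gs]
    I[row_idx[rows], cols] = I[row_idx[rows], src]


def _distinct_counts(I: np.ndarray) -> np.ndarray:
    s = np.sort(I, axis=1)
    return 1 + (np.diff(s, axis=1) > 0).sum(axis=1)


def simulate_batch_extended(
    msm: MsmSpec,
    dgp: DgpConfig,
    n: int,
    rng: np.random.Generator,
    m: int | None = None,
    policy=None,
    max_chunk_members: int = 1_000_000,
) -> TrajectoryBatch:
    """Simulate ``n`` trajectories with the match-pool algorithm, vectorized.

    Individuals are processed in chunks whose pools form ``(rows, m)``
    arrays; all per-visit operations (confounder sampling, ranking, copula
    draws, replacement) act on whole chunks.  Rows whose pools hit the
    restart threshold fall back to the per-individual engine with an
    ``m_big`` pool.  Deterministic given ``(rng state, n, m, chunk size)``.
    """
    m = int(m if m is not None else dgp.m)
    if m < 2:
        raise ValueError("match pool size m must be >= 2")
    rows_per_chunk = max(1, max_chunk_members // m)
    chunks = []
    done = 0
    while done < n:
        r = min(rows_per_chunk, n - done)
        chunks.append(_simulate_chunk(msm, dgp, r, m, rng, policy))
        done += r
    if len(chunks) == 1:
        return chunks[0]
    first = chunks[0]
    return TrajectoryBatch(
        x=np.concatenate([c.x for c in chunks]),
        b=np.concatenate([c.b for c in chunks]),
        l=np.concatenate([c.l for c in chunks]),
        a=np.concatenate([c.a for c in chunks]),
        y=np.concatenate([c.y for c in chunks]),
        t_fail=np.concatenate([c.t_fail for c in chunks]),
        n_visits=np.concatenate([c.n_visits for c in chunks]),
        K=first.K, x_names=first.x_names, b_names=first.b_names,
        l_names=first.l_names,
    )


def _simulate_chunk(msm, dgp, n, m, rng, policy):
    K = msm.K
    discrete = msm.family == "discrete_logistic"
    depth = dgp.history_depth
    x = np.atleast_2d(dgp.sample_x(rng, n))
    x_mem0 = np.repeat(x, m, axis=0)
    b_flat = np.atleast_2d(dgp.sample_b(rng, x_mem0))
    db = b_flat.shape[1]
    b = b_flat.reshape(n, m, db)
    b_s = b[:, 0].copy()
    I = np.tile(np.arange(1, m, dtype=np.int64), (n, 1))
    y = np.ones((n, K + 1), dtype=np.int8)
    t_fail = np.full(n, np.inf)
    n_visits = np.zeros(n, dtype=np.int64)
    l_store = None
    a_store = np.full((n, K + 1), np.nan)
    dl = None

    act = np.arange(n)
    l_deque: list[np.ndarray] = []      # (ra, m, dl) recent visits
    a_hist: list[np.ndarray] = []       # (ra,) realized treatments
    restart_rows: list[tuple] = []      # (orig index, k_next, a_hist row, l recent)
    # conservative per-row upper bound on the distinct original-match count:
    # each replacement removes at most one lineage, so the exact (sort-based)
    # count is only needed for rows whose bound approaches the threshold
    dub = np.full(n, m - 1, dtype=np.int64)
    for k in range(K + 1):
        ra = act.size
        if ra == 0:
            break
        xa = x[act]
        x_mem = np.repeat(xa, m, axis=0)
        l_prev = l_deque[-1].reshape(-1, dl) if k > 0 else None
        a_prev_mem = np.repeat(a_hist[-1], m) if k > 0 else None
        l = np.atleast_2d(
            dgp.sample_l(rng, k, x_mem, b.reshape(-1, db), l_prev, a_prev_mem)
        )
        if l_store is None:
            dl = l.shape[1]
            l_store = np.full((n, K + 1, dl), np.nan)
        l = l.reshape(ra, m, dl)
        _push_history(l_deque, l, depth)
        l_store[act, k] = l[:, 0]
        a_prev = None if k == 0 else a_hist[-1]
        if policy is None:
            a = np.asarray(
                dgp.sample_a(rng, k, xa, b[:, 0], l[:, 0], a_prev), dtype=float
            )
        else:
            a = np.asarray(policy(k, xa, b[:, 0], l[:, 0], a_prev, rng), dtype=float)
        a_hist.append(a)
        a_store[act, k] = a
        h = np.asarray(
            dgp.risk_score(k, x_mem, b.reshape(-1, db),
                           [arr.reshape(-1, dl) for arr in l_deque]),
            dtype=float,
        ).reshape(ra, m)
        u = empirical_risk_quantiles(h, rng)
        rho = dgp.rho_at(k)
        z_y = rho * ndtri(u) + np.sqrt(1 - rho**2) * rng.standard_normal((ra, m))
        g, thr = _hazard_threshold(msm, a_hist, xa, k)
        fail = z_y < thr[:, None]
        fail0 = fail[:, 0]
        n_visits[act] = k + 1
        if fail0.any():
            idx = act[fail0]
            y[idx, k:] = 0
            if discrete:
                t_fail[idx] = k + 1
            else:
                u_y0 = np.minimum(ndtr(z_y[fail0, 0]), g[fail0] * (1 - 1e-15))
                t_fail[idx] = invert_interval_failure_time(
                    u_y0, msm, [av[fail0] for av in a_hist], xa[fail0], k
                )
        if k == K:
            break
        cont = ~fail0
        rows_c = np.flatnonzero(cont)
        if rows_c.size == 0:
            break
        # fully depleted pools go straight to the restart fallback
        depleted = np.zeros(ra, dtype=bool)
        depleted[rows_c] = fail[rows_c, 1:].all(axis=1)
        if depleted.any():
            if m >= dgp.m_big:
                raise PoolDepletedError(
                    f"all matches failed in a pool of size {m} at visit {k}; "
                    "increase m/m_big or the restart fraction"
                )
            rows_c = np.flatnonzero(cont & ~depleted)
        if rows_c.size:
            _batch_replace(rng, fail[rows_c, 1:], rows_c, [b] + l_deque, I)
        # restart check (once per visit, after replacement)
        need = depleted.copy()
        if m < dgp.m_big:
            dub = dub - fail[:, 1:].sum(axis=1)
            thr = dgp.restart_fraction * (m - 1)
            maybe = cont & (dub < thr)
            if maybe.any():
                idx = np.flatnonzero(maybe)
                exact = _distinct_counts(I[idx])
                dub[idx] = exact
                need[idx] |= exact < thr
        need &= cont
        if need.any():
            for i in np.flatnonzero(need):
                recent = [arr[i, 0].copy() for arr in l_deque]
                restart_rows.append(
                    (int(act[i]), k + 1, np.array([av[i] for av in a_hist]), recent)
                )
            cont &= ~need
        keep = np.flatnonzero(cont)
        if keep.size < ra:
            act = act[keep]
            b = b[keep]
            I = I[keep]
            dub = dub[keep]
            l_deque = [arr[keep] for arr in l_deque]
            a_hist = [av[keep] for av in a_hist]

    for orig, k_next, a_row, recent in restart_rows:
        _finish_with_restart(
            msm, dgp, rng, orig, k_next, a_row, recent,
            x, b_s, l_store, a_store, y, t_fail, n_visits,
        )

    return TrajectoryBatch(
        x=x, b=b_s, l=l_store, a=a_store, y=y, t_fail=t_fail,
        n_visits=n_visits, K=K, x_names=tuple(dgp.x_names),
        b_names=tuple(dgp.b_names), l_names=tuple(dgp.l_names),
    )


def _finish_with_restart(msm, dgp, rng, orig, k_next, a_row, recent,
                         x, b_s, l_store, a_store, y, t_fail, n_visits):
    """Continue a frozen batch row with a large restarted pool."""
    logger.debug("batch row %d restarting at visit %d with m_big=%d",
                 orig, k_next, dgp.m_big)
    seed_pool = MatchPool(
        m=1, k_next=k_next, x=x[orig: orig + 1],
        a_hist=[float(av) for av in a_row],
        b=b_s[orig: orig + 1].copy(),
        I=np.empty(0, dtype=np.int64),
        l_hist=[r[None, :].copy() for r in recent],
    )
    pool = restart_pool(seed_pool, msm, dgp, rng)
    state = _SampledState(x=x[orig])
    state.l = [l_store[orig, kk].copy() for kk in range(k_next)]
    state.a = [float(av) for av in a_row]
    state.y = [1] * k_next
    _run_pool(state, pool, msm, dgp, rng)
    nv = len(state.a)
    n_visits[orig] = nv
    for kk in range(k_next, nv):
        l_store[orig, kk] = state.l[kk]
        a_store[orig, kk] = state.a[kk]
    t_fail[orig] = state.t_fail
    y[orig, :] = 1
    if state.t_fail < np.inf:
        y[orig, nv - 1:] = 0
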