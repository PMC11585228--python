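"""Fit the MSM to simulated observed data: naive, IPTW, and bootstrap CIs.

The analysis dataset is a person-period (counting-process) DataFrame with
one row per individual-visit at risk: ``id, k, tstart, tstop, event``,
the observed covariates, current and lagged treatment, and (once
estimated) the stabilized weight ``sw``.

The unweighted ("naive") fit uses the model-based variance; the IPTW fit
multiplies each person-interval by its stabilized
inverse-probability-of-treatment weight and uses the simple clustered
sandwich variance (weights treated as fixed).  The percentile bootstrap
resamples individuals and re-estimates the weights inside every resample,
so weight-estimation uncertainty is propagated into the CI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.linear_model import LogisticRegression

from .coxph import fit_coxtv
from .exact import TrajectoryBatch

__all__ = [
    "FitResult",
    "build_person_period",
    "stabilized_weights",
    "fit_cox_msm",
    "fit_discrete_msm",
    "bootstrap_ci",
]

logger = logging.getLogger(__name__)

Z975 = 1.959963984540054

#: default stabilized-weight model covariates (study configuration):
#: denominator conditions on the full measured history, numerator only on
#: the MSM baseline covariates and lagged treatment.
DENOMINATOR_COLS = ("x1", "x2", "b1", "l1", "l2", "a_lag")
NUMERATOR_COLS = ("x1", "x2", "a_lag")


@dataclass
class FitResult:
    """Point estimates with CIs from one analysis method.

    ``method`` is one of ``naive`` (unweighted, model-based variance),
    ``iptw_sandwich`` (weighted, clustered simple sandwich) or
    ``iptw_bootstrap`` (weighted point estimate, percentile CI).
    """

    method: str
    params: pd.Series
    se: pd.Series
    ci_lower: pd.Series
    ci_upper: pd.Series
    vcov: Optional[pd.DataFrame] = None
    n_events: Optional[int] = None
    converged: bool = True
    extra: Optional[dict] = None

    def __post_init__(self):
        if not np.all(self.ci_lower.values < self.ci_upper.values):
            raise ValueError("ci_lower must be < ci_upper for every parameter")


def build_person_period(trajectories, observed_b: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Expand censored trajectories into counting-process rows.

    Each individual contributes one row per visit ``k < t_obs`` with
    ``tstart = k``, ``tstop = min(k+1, t_obs)`` and the event flag on the
    last row iff the failure time was observed.  Covariate columns are the
    baseline ``x``/observed ``b`` names plus the visit-``k`` confounders,
    the current treatment ``a`` and its lag ``a_lag`` (0 at the first
    visit).
    """
    batch = _as_batch(trajectories)
    if batch.t_obs is None:
        raise ValueError("apply_censoring must be called before building person-period data")
    n_rows_per = np.ceil(batch.t_obs).astype(np.int64)
    n_rows_per = np.maximum(n_rows_per, 1)
    ids = np.repeat(np.arange(batch.n), n_rows_per)
    k = _ragged_arange(n_rows_per)
    tstart = k.astype(float)
    tstop = np.minimum(tstart + 1.0, batch.t_obs[ids])
    last = np.r_[np.diff(ids) != 0, True]
    event = np.zeros(len(ids), dtype=np.int8)
    event[last] = batch.event
    df = pd.DataFrame({"id": ids, "k": k, "tstart": tstart, "tstop": tstop, "event": event})
    for j, name in enumerate(batch.x_names):
        df[name] = batch.x[ids, j]
    b_names = batch.b_names if observed_b is None else tuple(observed_b)
    for name in b_names:
        j = batch.b_names.index(name)
        df[name] = batch.b[ids, j]
    l_cols = [
        batch.l_names[j] if j < len(batch.l_names) else f"l{j+1}"
        for j in range(batch.l.shape[2])
    ]
    for j, name in enumerate(l_cols):
        df[name] = batch.l[ids, k, j]
    df["a"] = batch.a[ids, k]
    a_lag = np.zeros(len(ids))
    nz = k > 0
    a_lag[nz] = batch.a[ids[nz], k[nz] - 1]
    df["a_lag"] = a_lag
    if df[["a", *l_cols]].isna().any().any():
        raise AssertionError("person-period rows reference visits without data")
    return df


def _ragged_arange(counts):
    total = counts.sum()
    out = np.arange(total) - np.repeat(np.cumsum(counts) - counts, counts)
    return out


def _as_batch(trajectories) -> TrajectoryBatch:
    if isinstance(trajectories, TrajectoryBatch):
        return trajectories
    trajs = list(trajectories)
    K = len(trajs[0].y) - 1
    dl = trajs[0].l.shape[1] if trajs[0].l.ndim == 2 else 1
    n = len(trajs)
    l = np.full((n, K + 1, dl), np.nan)
    a = np.full((n, K + 1), np.nan)
    for i, t in enumerate(trajs):
        nv = t.n_visits
        l[i, :nv] = np.atleast_2d(t.l)
        a[i, :nv] = t.a
    return TrajectoryBatch(
        x=np.vstack([t.x for t in trajs]),
        b=np.vstack([t.b for t in trajs]),
        l=l, a=a,
        y=np.vstack([t.y for t in trajs]),
        t_fail=np.array([t.t_fail for t in trajs]),
        n_visits=np.array([t.n_visits for t in trajs]),
        K=K,
        x_names=tuple(f"x{j+1}" for j in range(np.atleast_1d(trajs[0].x).size)),
        b_names=tuple(f"b{j+1}" for j in range(np.atleast_1d(trajs[0].b).size)),
        l_names=tuple(f"l{j+1}" for j in range(dl)),
        t_cens=np.array([t.t_cens for t in trajs]),
        t_obs=np.array([t.t_obs for t in trajs]) if trajs[0].t_obs is not None else None,
        event=np.array([t.event for t in trajs]) if trajs[0].event is not None else None,
    )


def _fit_logistic(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Unpenalized logistic fit returning P(y=1 | X) for each row."""
    clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=1000, tol=1e-8)
    clf.fit(X, y)
    if not np.all(clf.n_iter_ < 1000):
        raise RuntimeError("treatment-model logistic regression did not converge")
    return clf.predict_proba(X)[:, 1]


def stabilized_weights(
    data: pd.DataFrame,
    denominator_cols: Sequence[str] = DENOMINATOR_COLS,
    numerator_cols: Sequence[str] = NUMERATOR_COLS,
    truncate: Optional[float] = None,
) -> np.ndarray:
    """Stabilized inverse-probability-of-treatment weights per person-period row.

    Both treatment models are pooled logistic regressions over all visits
    (binary treatment): the denominator of ``A_k`` on the measured history,
    the numerator on the MSM baseline covariates and lagged treatment.  The
    weight attached to the row for interval ``(k, k+1]`` is the cumulative
    product over visits ``j <= k`` of ``p_num(A_j) / p_den(A_j)``.

    ``truncate``, if given, caps the per-visit probability ratio at the
    given quantile symmetric in both tails (not used by the study analyses).
    """
    a = data["a"].to_numpy()
    if not np.isin(a, (0.0, 1.0)).all():
        raise ValueError("stabilized_weights requires a binary treatment")
    p_den = _fit_logistic(data[list(denominator_cols)].to_numpy(), a)
    p_num = _fit_logistic(data[list(numerator_cols)].to_numpy(), a)
    if np.any(p_den < 1e-10) or np.any(1 - p_den < 1e-10):
        raise RuntimeError("treatment model produced probabilities at the boundary")
    lik_den = np.where(a == 1.0, p_den, 1.0 - p_den)
    lik_num = np.where(a == 1.0, p_num, 1.0 - p_num)
    ratio = lik_num / lik_den
    if truncate is not None:
        lo, hi = np.quantile(ratio, [1.0 - truncate, truncate])
        ratio = np.clip(ratio, lo, hi)
    # cumulative product within individual, in visit order (rows must be
    # sorted by id then visit, as build_person_period emits them)
    ids = data["id"].to_numpy()
    logr = np.log(ratio)
    cs = np.cumsum(logr)
    starts = np.r_[0, np.flatnonzero(np.diff(ids) != 0) + 1]
    counts = np.diff(np.r_[starts, len(ids)])
    offset = np.repeat(np.r_[0.0, cs[starts[1:] - 1]], counts)
    return np.exp(cs - offset)


def _design_matrix(data: pd.DataFrame, design) -> pd.DataFrame:
    if callable(design):
        return design(data)
    return data[list(design)]


def fit_cox_msm(
    data: pd.DataFrame,
    design,
    weights=None,
    variance: str = "model",
) -> FitResult:
    """Fit the Cox MSM on counting-process rows.

    ``design`` is either a callable mapping the person-period frame to the
    DataFrame of MSM covariates or a list of column names.  ``weights`` may
    be None (naive), a column name, or a row-aligned array.  ``variance``
    selects the model-based or the clustered simple-sandwich estimator.
    """
    if variance not in ("model", "sandwich"):
        raise ValueError("variance must be 'model' or 'sandwich'")
    Xdf = _design_matrix(data, design)
    w = data[weights].to_numpy() if isinstance(weights, str) else weights
    res = fit_coxtv(
        Xdf.to_numpy(),
        data["tstart"].to_numpy(),
        data["tstop"].to_numpy(),
        data["event"].to_numpy(),
        weights=w,
        ids=data["id"].to_numpy(),
        robust=variance == "sandwich",
    )
    names = list(Xdf.columns)
    se = pd.Series(res.se(robust=variance == "sandwich"), index=names)
    params = pd.Series(res.beta, index=names)
    method = "naive" if w is None else "iptw_sandwich"
    vc = res.vcov_robust if variance == "sandwich" else res.vcov_model
    return FitResult(
        method=method,
        params=params,
        se=se,
        ci_lower=params - Z975 * se,
        ci_upper=params + Z975 * se,
        vcov=pd.DataFrame(vc, index=names, columns=names),
        n_events=res.n_events,
        converged=res.converged,
    )


def fit_discrete_msm(data: pd.DataFrame, design, weights=None) -> FitResult:
    """Weighted pooled logistic fit of the per-visit event indicator.

    For discrete-time MSM families: logistic regression of the event flag
    on the MSM design over person-period rows, with variance clustered by
    individual (statsmodels GLM).
    """
    if data["event"].sum() == 0:
        raise ValueError("no events in the person-period data")
    Xdf = sm.add_constant(_design_matrix(data, design), has_constant="add")
    w = data[weights].to_numpy() if isinstance(weights, str) else weights
    model = sm.GLM(
        data["event"].to_numpy(),
        Xdf,
        family=sm.families.Binomial(),
        var_weights=np.ones(len(data)) if w is None else np.asarray(w),
    )
    res = model.fit(cov_type="cluster", cov_kwds={"groups": data["id"].to_numpy()})
    params = pd.Series(res.params, index=Xdf.columns)
    se = pd.Series(res.bse, index=Xdf.columns)
    return FitResult(
        method="naive" if w is None else "iptw_sandwich",
        params=params,
        se=se,
        ci_lower=params - Z975 * se,
        ci_upper=params + Z975 * se,
        n_events=int(data["event"].sum()),
        converged=res.converged if hasattr(res, "converged") else True,
    )


def bootstrap_ci(
    data: pd.DataFrame,
    design,
    n_boot: int,
    rng: np.random.Generator,
    denominator_cols: Sequence[str] = DENOMINATOR_COLS,
    numerator_cols: Sequence[str] = NUMERATOR_COLS,
    max_redraws: int = 100,
) -> FitResult:
    """Percentile-bootstrap CI for the IPTW Cox fit, resampling individuals.

    Inside every bootstrap resample the stabilized weights are re-estimated
    before refitting, so the CI reflects weight-estimation uncertainty.
    Resamples with no events are redrawn (counted in ``extra``).
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    sw = stabilized_weights(data, denominator_cols, numerator_cols)
    full = fit_cox_msm(data, design, weights=sw, variance="sandwich")
    ids = data["id"].to_numpy()
    uniq = np.unique(ids)
    # row blocks per individual for fast resampling
    order = np.argsort(ids, kind="stable")
    sorted_ids = ids[order]
    starts = np.searchsorted(sorted_ids, uniq, side="left")
    stops = np.searchsorted(sorted_ids, uniq, side="right")
    boot = np.empty((n_boot, len(full.params)))
    redraws = 0
    for bi in range(n_boot):
        for _ in range(max_redraws + 1):
            pick = rng.integers(0, uniq.size, size=uniq.size)
            rows = np.concatenate([order[starts[p]: stops[p]] for p in pick])
            new_ids = np.repeat(np.arange(uniq.size), stops[pick] - starts[pick])
            bdf = data.iloc[rows].copy()
            bdf["id"] = new_ids
            if bdf["event"].sum() > 0:
                break
            redraws += 1
        else:
            raise RuntimeError("bootstrap resampling kept producing event-free samples")
        bsw = stabilized_weights(bdf, denominator_cols, numerator_cols)
        fit = fit_cox_msm(bdf, design, weights=bsw, variance="model")
        boot[bi] = fit.params.to_numpy()
    if redraws:
        logger.debug("bootstrap redrew %d event-free resamples", redraws)
    lo = np.quantile(boot, 0.025, axis=0)
    hi = np.quantile(boot, 0.975, axis=0)
    eps = 1e-12  # degenerate resamples can collapse the percentile interval
    hi = np.maximum(hi, lo + eps)
    names = full.params.index
    return FitResult(
        method="iptw_bootstrap",
        params=full.params,
        se=pd.Series(boot.std(axis=0, ddof=1), index=names),
        ci_lower=pd.Series(lo, index=names),
        ci_upper=pd.Series(hi, index=names),
        n_events=full.n_events,
        converged=full.converged,
        extra={"n_boot": n_boot, "event_free_redraws": redraws},
    )
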