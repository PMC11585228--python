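"""Declarative specification of the MSM estimand and the data-generating process.

Two objects drive every simulation:

* :class:`MsmSpec` — the causal estimand: the hazard of the potential
  survival time under an intervened treatment history, conditional on the
  baseline covariates ``X`` that appear in the MSM.  Supported families are a
  discrete-time logistic hazard, and continuous-time Cox or additive hazards.
* :class:`DgpConfig` — everything else: samplers for baseline covariates
  ``X`` and ``B``, time-varying confounders ``L_k`` and treatment ``A_k``,
  the per-visit risk-score functions and copula correlations, the censoring
  law, and the match-pool sizes used by the rank-based simulator.

All samplers are vectorized: they receive ``(N, d)`` arrays and an explicit
:class:`numpy.random.Generator` and return ``(N, d')`` arrays, so the same
callables serve both the per-individual and the batched simulators.
Custom data-generating processes can be registered by name via
:func:`register_config` and addressed from config files.
"""

from __future__ import annotations

import dataclasses
import io
from collections.abc import Callable, Sequence
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

__all__ = [
    "MsmSpec",
    "DgpConfig",
    "Trajectory",
    "study_config",
    "named_config",
    "register_config",
    "available_configs",
    "validate_config",
    "config_to_yaml",
    "config_from_yaml",
]

FAMILIES = ("discrete_logistic", "cox", "additive_hazard")


@dataclass
class MsmSpec:
    """A marginal structural model for a survival outcome.

    Parameters
    ----------
    family : str
        ``"discrete_logistic"`` for a discrete-time hazard ``g_k`` in [0,1],
        ``"cox"`` or ``"additive_hazard"`` for a continuous-time rate.
    K : int
        Last post-baseline visit; visits are 0..K and administrative
        censoring happens at time K+1.
    beta : ndarray
        MSM parameter vector.
    hazard_fn : callable ``(t, a_hist, x, beta) -> (N,) array``
        For the discrete family, ``t`` is the visit index ``k+1`` whose
        hazard is requested and the return value is the failure probability
        ``g_{k+1}(ā_k, x; β)``.  For continuous families, ``t`` is a time in
        ``(k, k+1]`` with ``k = len(a_hist) - 1`` and the return value is the
        instantaneous hazard rate.  ``a_hist`` is the list of treatment
        arrays ``[a_0, ..., a_k]`` and ``x`` an ``(N, d_x)`` array.
    piecewise_constant : bool
        Continuous families only: declare the rate constant on each interval
        ``(k, k+1]`` so interval integrals and inverse-CDF failure times are
        closed form; otherwise Gauss–Legendre quadrature and root-finding
        are used.
    design_fn : callable, optional
        Maps a person-period DataFrame to the DataFrame of MSM covariates
        used when *fitting* the model (needed by the fitting/harness layers
        only).
    param_names : tuple of str, optional
        Names for the elements of ``beta`` (fit output labels).
    """

    family: str
    K: int
    beta: np.ndarray
    hazard_fn: Callable
    piecewise_constant: bool = True
    design_fn: Optional[Callable[[pd.DataFrame], pd.DataFrame]] = None
    param_names: Optional[tuple] = None
    manifest: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown MSM family {self.family!r}")
        self.beta = np.asarray(self.beta, dtype=float)
        if self.K < 0:
            raise ValueError("K must be >= 0")


@dataclass
class DgpConfig:
    """The observational data-generating process around an :class:`MsmSpec`.

    Sampler contracts (``N`` rows, explicit ``rng`` first):

    * ``sample_x(rng, n) -> (n, d_x)``
    * ``sample_b(rng, x) -> (N, d_b)``
    * ``sample_l(rng, k, x, b, l_prev, a_prev) -> (N, d_l)`` with
      ``l_prev``/``a_prev`` equal to ``None`` at ``k = 0`` (the convention
      ``A_{-1} = 0`` is the sampler's business).
    * ``sample_a(rng, k, x, b, l, a_prev) -> (N,)`` — treatment at visit k;
      ``a_prev`` is ``None`` at ``k = 0``.
    * ``risk_score(k, x, b, l_hist) -> (N,)`` with ``l_hist`` the list of
      confounder arrays for the most recent visits (all visits when
      ``history_depth`` is None), ``l_hist[-1]`` being visit ``k``.
    * ``sample_censoring(rng, n) -> (n,)`` continuous censoring times, or
      ``None`` for no random censoring.
    * ``exact_cdf`` — optional list (length K+1) of callables
      ``cdf_k(h, x, a_hist) -> u`` giving the conditional risk-score CDF
      among survivors; required by the exact simulator only.
    """

    sample_x: Callable
    sample_b: Callable
    sample_l: Callable
    sample_a: Callable
    risk_score: Callable
    rho: np.ndarray
    sample_censoring: Optional[Callable] = None
    m: int = 5000
    m_big: int = 100_000
    restart_fraction: float = 0.10
    exact_cdf: Optional[Sequence[Callable]] = None
    history_depth: Optional[int] = None
    x_names: tuple = ("x1",)
    b_names: tuple = ("b1",)
    l_names: tuple = ("l1",)
    observed_b: Optional[tuple] = None
    manifest: dict = field(default_factory=dict)

    def __post_init__(self):
        self.rho = np.atleast_1d(np.asarray(self.rho, dtype=float))
        if self.observed_b is None:
            self.observed_b = tuple(self.b_names)

    def rho_at(self, k: int) -> float:
        """Copula correlation for visit ``k`` (scalar rho broadcasts)."""
        return float(self.rho[k]) if self.rho.size > 1 else float(self.rho[0])


@dataclass
class Trajectory:
    """One individual's realized history.

    ``l`` and ``a`` hold entries only for the ``n_visits`` visits the
    individual actually entered (``Y_k = 1``); ``y`` holds the survival
    indicators ``Y_1 .. Y_{K+1}`` (monotone non-increasing).  ``t_fail`` is
    ``inf`` when the individual survives beyond ``K+1``.
    """

    x: np.ndarray
    b: np.ndarray
    l: np.ndarray
    a: np.ndarray
    y: np.ndarray
    t_fail: float
    t_cens: float = np.inf
    t_obs: Optional[float] = None
    event: Optional[int] = None

    @property
    def n_visits(self) -> int:
        return len(self.a)


# --------------------------------------------------------------------------
# The illustrative study configuration (Cox MSM, K = 9)
# --------------------------------------------------------------------------

_DELTAS = {
    "low": np.array([0.1, 0.15, 0.1, 0.3, 0.3]),
    "high": np.array([0.2, 0.3, 0.2, 0.6, 0.6]),
}
_RHOS = {"low": -0.5, "high": -0.9}

#: true MSM parameters of the study Cox model
STUDY_BETA = np.array([0.5, 0.5, -1.0, -0.4, 0.0])
STUDY_LOG_BASELINE = -3.3
STUDY_LOG_CENS_RATE = -3.6
STUDY_K = 9


def _study_hazard(t, a_hist, x, beta):
    # rate constant on (k, k+1], depends on current treatment a_k and x
    a = np.asarray(a_hist[-1], dtype=float)
    lin = (
        STUDY_LOG_BASELINE
        + beta[0] * x[:, 0]
        + beta[1] * x[:, 1]
        + a * (beta[2] + beta[3] * x[:, 0] + beta[4] * x[:, 1])
    )
    return np.exp(lin)


def _study_design(df: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "x1": df["x1"],
            "x2": df["x2"],
            "a": df["a"],
            "x1_a": df["x1"] * df["a"],
            "x2_a": df["x2"] * df["a"],
        },
        index=df.index,
    )


def _study_sample_x(rng, n):
    return np.column_stack(
        [rng.standard_normal(n), (rng.random(n) < 0.5).astype(float)]
    )


def _study_sample_b(rng, x):
    n = x.shape[0]
    out = rng.standard_normal((2, n))  # filled in place: rng.normal(loc_array) is slow
    out[0] += -0.2 + 0.4 * x[:, 1]
    out[1] += 0.2 * x[:, 0]
    return np.ascontiguousarray(out.T)


def _study_sample_l(rng, k, x, b, l_prev, a_prev):
    n = x.shape[0]
    out = np.empty((n, 2))
    if k == 0:
        out[:, 0] = 0.2 * x[:, 0]
        p2 = expit(-0.2 + 0.4 * x[:, 1])
    else:
        out[:, 0] = 0.3 + 0.4 * b[:, 1] + 0.7 * l_prev[:, 0] - 0.6 * a_prev
        p2 = expit(-0.2 + 0.4 * b[:, 1] + l_prev[:, 1] - 0.6 * a_prev)
    out[:, 0] += rng.standard_normal(n)
    out[:, 1] = rng.random(n) < p2
    return out


def _make_study_sample_a(delta):
    def sample_a(rng, k, x, b, l, a_prev):
        ap = 0.0 if a_prev is None else a_prev
        p = expit(
            -1.0
            + delta[0] * x[:, 0]
            + delta[1] * x[:, 1]
            + delta[2] * b[:, 0]
            + delta[3] * l[:, 0]
            + delta[4] * l[:, 1]
            + ap
        )
        return (rng.random(x.shape[0]) < p).astype(float)

    return sample_a


def _study_risk_score(k, x, b, l_hist):
    l = l_hist[-1]
    return 0.3 * b[:, 0] + 0.5 * b[:, 1] + l[:, 0] + l[:, 1]


def study_config(
    delta_level: str = "low",
    rho_level: str = "low",
    *,
    m: int = 5000,
    m_big: int = 100_000,
    restart_fraction: float = 0.10,
):
    """The illustrative study design: a Cox MSM with K=9 and two confounding dials.

    ``delta_level`` scales how strongly the treatment model depends on
    confounders; ``rho_level`` sets the copula correlation (-0.5 weak,
    -0.9 strong).  Returns ``(MsmSpec, DgpConfig)``.  Deterministic: no RNG
    is consumed while building the configuration.
    """
    if delta_level not in _DELTAS:
        raise ValueError(f"delta_level must be one of {tuple(_DELTAS)}, got {delta_level!r}")
    if rho_level not in _RHOS:
        raise ValueError(f"rho_level must be one of {tuple(_RHOS)}, got {rho_level!r}")
    delta = _DELTAS[delta_level]
    rho = _RHOS[rho_level]
    name = f"delta_{delta_level}__rho_{rho_level}"
    msm = MsmSpec(
        family="cox",
        K=STUDY_K,
        beta=STUDY_BETA.copy(),
        hazard_fn=_study_hazard,
        piecewise_constant=True,
        design_fn=_study_design,
        param_names=("beta1", "beta2", "beta3", "beta4", "beta5"),
        manifest={"fixture": name, "beta": STUDY_BETA.tolist(), "K": STUDY_K,
                  "log_baseline_hazard": STUDY_LOG_BASELINE},
    )
    cens_scale = float(np.exp(-STUDY_LOG_CENS_RATE))
    dgp = DgpConfig(
        sample_x=_study_sample_x,
        sample_b=_study_sample_b,
        sample_l=_study_sample_l,
        sample_a=_make_study_sample_a(delta),
        risk_score=_study_risk_score,
        rho=np.full(STUDY_K + 1, rho),
        sample_censoring=lambda rng, n: rng.exponential(cens_scale, n),
        m=m,
        m_big=m_big,
        restart_fraction=restart_fraction,
        history_depth=1,
        x_names=("x1", "x2"),
        b_names=("b1", "b2"),
        l_names=("l1", "l2"),
        observed_b=("b1",),  # b2 is a generated but unobserved common cause
        manifest={
            "fixture": name,
            "delta_level": delta_level,
            "rho_level": rho_level,
            "delta": delta.tolist(),
            "rho": rho,
            "log_censoring_rate": STUDY_LOG_CENS_RATE,
            "m": m,
            "m_big": m_big,
            "restart_fraction": restart_fraction,
        },
    )
    return msm, dgp


# --------------------------------------------------------------------------
# Named-config registry and YAML round trip
# --------------------------------------------------------------------------

_REGISTRY: dict[str, Callable] = {}


def register_config(name: str, builder: Callable) -> None:
    """Register ``builder(**overrides) -> (MsmSpec, DgpConfig)`` under ``name``."""
    _REGISTRY[name] = builder


def available_configs() -> tuple:
    return tuple(sorted(_REGISTRY))


for _d in ("low", "high"):
    for _r in ("low", "high"):
        register_config(
            f"delta_{_d}__rho_{_r}",
            (lambda d, r: (lambda **kw: study_config(d, r, **kw)))(_d, _r),
        )


def named_config(name: str, **overrides):
    """Build a registered configuration by its fixture name."""
    try:
        builder = _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown config {name!r}; available: {available_configs()}"
        ) from None
    return builder(**overrides)


def config_to_yaml(msm: MsmSpec, dgp: DgpConfig, scenario: dict | None = None,
                   seeds: dict | None = None, path=None) -> str:
    """Serialize a fixture-backed configuration to YAML (keys: msm, dgp, scenario, seeds)."""
    doc = {
        "msm": dict(msm.manifest),
        "dgp": dict(dgp.manifest),
        "scenario": dict(scenario or {}),
        "seeds": dict(seeds or {}),
    }
    text = yaml.safe_dump(doc, sort_keys=True)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def config_from_yaml(source):
    """Rebuild ``(MsmSpec, DgpConfig, scenario, seeds)`` from YAML text/file/stream."""
    if isinstance(source, str) and "\n" not in source and not source.strip().startswith("{"):
        with open(source) as fh:
            doc = yaml.safe_load(fh)
    elif isinstance(source, io.IOBase):
        doc = yaml.safe_load(source)
    else:
        doc = yaml.safe_load(source)
    name = doc["dgp"]["fixture"]
    overrides = {
        k: doc["dgp"][k]
        for k in ("m", "m_big", "restart_fraction")
        if k in doc["dgp"]
    }
    msm, dgp = named_config(name, **overrides)
    return msm, dgp, doc.get("scenario", {}), doc.get("seeds", {})


# --------------------------------------------------------------------------
# Validation diagnostics
# --------------------------------------------------------------------------

def validate_config(msm: MsmSpec, dgp: DgpConfig, n_probe: int = 256) -> list[str]:
    """Probe a configuration and return a list of diagnostic strings.

    An empty list means all invariants held on the probe evaluations:
    copula correlations in (-1, 0], pool sizes sane, risk scores finite,
    discrete hazards in [0, 1], continuous hazards (notably the additive
    family) non-negative on probed states, and treatment probabilities
    strictly inside (0, 1).  Diagnostics, not exceptions: callers decide.
    """
    diags: list[str] = []
    if np.any(dgp.rho <= -1.0) or np.any(dgp.rho > 0.0):
        diags.append(f"rho out of range (-1, 0]: {dgp.rho}")
    if dgp.m < 2:
        diags.append(f"match pool size m must be >= 2, got {dgp.m}")
    if dgp.m_big < dgp.m:
        diags.append(f"m_big ({dgp.m_big}) must be >= m ({dgp.m})")
    if not 0.0 < dgp.restart_fraction < 1.0:
        diags.append(f"restart_fraction must be in (0, 1), got {dgp.restart_fraction}")
    if msm.family not in FAMILIES:
        diags.append(f"unknown MSM family {msm.family!r}")
        return diags

    rng = np.random.default_rng(1234)  # fixed probe stream: validation is deterministic
    try:
        x = np.atleast_2d(dgp.sample_x(rng, n_probe))
        b = np.atleast_2d(dgp.sample_b(rng, x))
        l_hist: list[np.ndarray] = []
        l_prev = None
        a_prev = None
        a_hist: list[np.ndarray] = []
        for k in range(msm.K + 1):
            l = np.atleast_2d(dgp.sample_l(rng, k, x, b, l_prev, a_prev))
            l_hist.append(l)
            if dgp.history_depth is not None:
                l_hist = l_hist[-dgp.history_depth:]
            a = np.asarray(dgp.sample_a(rng, k, x, b, l, a_prev), dtype=float)
            h = np.asarray(dgp.risk_score(k, x, b, l_hist), dtype=float)
            if not np.all(np.isfinite(h)):
                diags.append(f"risk score not finite at visit {k}")
            a_hist.append(a)
            for a_forced in (np.zeros(n_probe), np.ones(n_probe)):
                probe_hist = a_hist[:-1] + [a_forced]
                if msm.family == "discrete_logistic":
                    g = np.asarray(msm.hazard_fn(k + 1, probe_hist, x, msm.beta))
                    if np.any((g < 0.0) | (g > 1.0)):
                        diags.append(f"discrete hazard outside [0, 1] at visit {k + 1}")
                else:
                    for t in (k + 0.25, k + 0.75):
                        lam = np.asarray(msm.hazard_fn(t, probe_hist, x, msm.beta))
                        if np.any(lam < 0.0):
                            diags.append(
                                f"negative hazard (family={msm.family}) at t={t}"
                            )
            l_prev, a_prev = l, a
        # treatment probabilities strictly inside (0, 1): resample many times
        draws = np.stack(
            [dgp.sample_a(rng, 0, x, b, l_hist[-1], None) for _ in range(8)]
        )
        if np.all(draws == draws[0]):
            # cannot distinguish degenerate from unlucky; only flag exact degeneracy
            if np.all(draws == 0) or np.all(draws == 1):
                diags.append("treatment sampler looks degenerate (p in {0, 1})")
    except Exception as exc:  # pragma: no cover - defensive
        diags.append(f"probe simulation failed: {exc!r}")
    # deduplicate, preserve order
    seen: dict[str, None] = {}
    for d in diags:
        seen.setdefault(d, None)
    return list(seen)
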