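"""Shared fixtures: small closed-form configurations with known risk-score CDFs."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.special import expit, ndtr

from msmsim import DgpConfig, MsmSpec


class FixedUniformRng:
    """Stand-in generator returning a constant for uniform draws (rank jitter tests)."""

    def __init__(self, value: float):
        self.value = value

    def random(self, size=None):
        return self.value if size is None else np.full(size, self.value)


def make_k1_config(rho: float = -0.6, K: int = 1):
    """Discrete-time config with closed-form risk-score CDFs.

    X ~ Bernoulli(0.5); B ~ N(0,1); L_0 ~ N(0.5 X, 1); for k >= 1,
    L_k ~ N(0.4 A_{k-1}, 1) (fresh draws, independent of B and survival, so
    the survivor-conditional CDF stays the unconditional normal law).
    Risk scores: h_0 = B + L_0 (so H_0 | X ~ N(0.5 X, 2)), h_k = L_k for
    k >= 1 (H_k | A_{k-1} ~ N(0.4 A_{k-1}, 1)).  Treatment depends on L_k
    and X, so there is genuine time-dependent confounding whenever rho < 0.
    MSM: g_{k+1} = expit(-2 + 0.8 X - 0.7 a_k).
    """

    def sample_x(rng, n):
        return (rng.random(n) < 0.5).astype(float)[:, None]

    def sample_b(rng, x):
        return rng.standard_normal((x.shape[0], 1))

    def sample_l(rng, k, x, b, l_prev, a_prev):
        n = x.shape[0]
        mean = 0.5 * x[:, 0] if k == 0 else 0.4 * a_prev
        return (mean + rng.standard_normal(n))[:, None]

    def sample_a(rng, k, x, b, l, a_prev):
        p = expit(-0.3 + 0.8 * l[:, 0] + 0.3 * x[:, 0])
        return (rng.random(x.shape[0]) < p).astype(float)

    def risk_score(k, x, b, l_hist):
        if k == 0:
            return b[:, 0] + l_hist[-1][:, 0]
        return l_hist[-1][:, 0]

    def hazard(k_next, a_hist, x, beta):
        return expit(beta[0] + beta[1] * x[:, 0] + beta[2] * a_hist[-1])

    def cdf0(h, x, a_hist):
        return ndtr((h - 0.5 * x[:, 0]) / np.sqrt(2.0))

    def cdf_later(h, x, a_hist):
        return ndtr(h - 0.4 * a_hist[-2])

    msm = MsmSpec(
        family="discrete_logistic",
        K=K,
        beta=np.array([-2.0, 0.8, -0.7]),
        hazard_fn=hazard,
    )
    dgp = DgpConfig(
        sample_x=sample_x,
        sample_b=sample_b,
        sample_l=sample_l,
        sample_a=sample_a,
        risk_score=risk_score,
        rho=np.full(K + 1, rho),
        m=500,
        m_big=5000,
        exact_cdf=[cdf0] + [cdf_later] * K,
        x_names=("x1",),
        b_names=("b1",),
        l_names=("l1",),
    )
    return msm, dgp


def make_k1_cox_config(rho: float = -0.6):
    """Continuous-time (Cox) sibling of the K=1 config, same covariate laws."""
    msm_d, dgp = make_k1_config(rho=rho)

    def hazard(t, a_hist, x, beta):
        return np.exp(beta[0] + beta[1] * x[:, 0] + beta[2] * a_hist[-1])

    msm = MsmSpec(
        family="cox",
        K=1,
        beta=np.array([-1.2, 0.3, -0.5]),
        hazard_fn=hazard,
        piecewise_constant=True,
    )
    return msm, dgp


def make_high_mortality_config(K: int = 3, g: float = 0.6, rho: float = -0.8):
    """Per-visit hazard ~0.6 with iid confounders and closed-form CDFs.

    Used to exercise match-pool depletion and the large-pool restart: with
    m = 200 the distinct original matches drop below 10% by visit 3.
    """

    def sample_x(rng, n):
        return np.zeros((n, 1))

    def sample_b(rng, x):
        return rng.standard_normal((x.shape[0], 1))

    def sample_l(rng, k, x, b, l_prev, a_prev):
        return rng.standard_normal((x.shape[0], 1))

    def sample_a(rng, k, x, b, l, a_prev):
        return (rng.random(x.shape[0]) < 0.5).astype(float)

    def risk_score(k, x, b, l_hist):
        return l_hist[-1][:, 0]

    def hazard(k_next, a_hist, x, beta):
        return np.full(x.shape[0], beta[0])

    def cdf(h, x, a_hist):
        return ndtr(h)

    msm = MsmSpec(family="discrete_logistic", K=K, beta=np.array([g]), hazard_fn=hazard)
    dgp = DgpConfig(
        sample_x=sample_x,
        sample_b=sample_b,
        sample_l=sample_l,
        sample_a=sample_a,
        risk_score=risk_score,
        rho=np.full(K + 1, rho),
        m=200,
        m_big=5000,
        exact_cdf=[cdf] * (K + 1),
    )
    return msm, dgp


@pytest.fixture(scope="session")
def k1_config():
    return make_k1_config()


@pytest.fixture(scope="session")
def k1_cox_config():
    return make_k1_cox_config()


@pytest.fixture(scope="session")
def high_mortality_config():
    return make_high_mortality_config()


@pytest.fixture(scope="session")
def study_pp_high():
    """One simulated, censored person-period dataset, (delta_high, rho_high), n=1000."""
    import msmsim as ms

    msm, dgp = ms.study_config("high", "high", m=500)
    rng = np.random.default_rng(np.random.SeedSequence([77]))
    batch = ms.simulate_batch_extended(msm, dgp, 1000, rng)
    batch = ms.apply_censoring(batch, dgp, rng)
    df = ms.build_person_period(batch, observed_b=dgp.observed_b)
    return msm, dgp, df
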