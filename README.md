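# msmsim

Simulate longitudinal survival data that are *exactly* compatible with a
marginal structural model (MSM), and evaluate how well IPTW analyses recover
the MSM's parameters.

## Who this is for

Methodologists running simulation studies of causal survival estimators.
Evaluating, say, a weighted Cox fit requires data with time-dependent
confounding for which the Cox MSM is *correctly specified* — and naively
sampling the outcome from a hazard regression on the measured history does
not deliver that, because the MSM marginalizes over the time-varying
confounders L_k and over baseline variables B it does not condition on.

## The construction

For visits k = 0..K with treatment A_k, confounders L_k, baseline
covariates X (in the MSM) and B (not in the MSM), the target model is

    P(Y_{k+1} = 0 | X, survival; do(Ā_k = ā_k)) = g_{k+1}(ā_k, X; β)

for a discrete-time logistic hazard, or a Cox / additive hazards model
λ^{ā_k}(t | X; β) in continuous time.  The simulator channels the outcome's
dependence on (B, L̄_k) through a user-chosen scalar risk score
H_k = h_k(X, B, L̄_k).  Its survivor-conditional quantile
U_H = F_{H_k}(H_k | X, Y_k = 1) is Uniform(0,1), and a Gaussian copula with
correlation ρ_k ∈ (−1, 0] produces a latent

    Z_Y ~ Normal(ρ_k Φ⁻¹(U_H), 1 − ρ_k²),   U_Y = Φ(Z_Y),

with failure iff U_Y < g_{k+1}(ā_k, X; β).  Since U_Y is uniform given X,
the marginal hazard is exactly g — the MSM holds by construction for any
h_k and ρ_k.  When F_{H_k} is not known in closed form, each individual is
simulated alongside m − 1 matches sharing its X and treatment path, and the
quantiles are estimated by jittered within-pool ranks, U = (R − W)/m, with
failed matches replaced by copies of surviving ones and a large-pool
restart when the original matches thin out.  See `docs/methods.md` for the
full account.

## Worked example

Simulate the built-in study configuration (Cox MSM, K = 9, true
β = (0.5, 0.5, −1, −0.4, 0), weak confounding) and compare the unweighted
("naive") fit with the stabilized-IPTW fit:

```python
import numpy as np, pandas as pd
import msmsim as ms

msm, dgp = ms.study_config("low", "low", m=1000, m_big=20_000)
rng = np.random.default_rng(np.random.SeedSequence([2026]))
batch = ms.simulate_batch_extended(msm, dgp, 5000, rng)   # match-pool algorithm
batch = ms.apply_censoring(batch, dgp, rng)               # Exp(exp(-3.6)) censoring
df = ms.build_person_period(batch, observed_b=dgp.observed_b)

naive = ms.fit_cox_msm(df, msm.design_fn, variance="model")
sw = ms.stabilized_weights(df)
iptw = ms.fit_cox_msm(df, msm.design_fn, weights=sw, variance="sandwich")
print(pd.DataFrame({"truth": msm.beta,
                    "naive": naive.params.values.round(3),
                    "iptw": iptw.params.values.round(3),
                    "iptw_se": iptw.se.values.round(3)},
                   index=msm.param_names))
```

prints

```
       truth  naive   iptw  iptw_se
beta1    0.5  0.485  0.480    0.036
beta2    0.5  0.453  0.454    0.077
beta3   -1.0 -0.414 -0.927    0.124
beta4   -0.4 -0.428 -0.404    0.075
beta5    0.0 -0.059 -0.092    0.151
```

The naive treatment coefficient (beta3 = −0.414) is badly confounded —
biased toward the null by about +0.6 log-hazard-ratio units — while the
IPTW estimate (−0.927, sandwich SE 0.124) covers the truth; the mean
stabilized weight is 0.988.  About 26% of these individuals have an
observed failure before random or administrative (t = 10) censoring.

A full scenario of the simulation study (bias / CI coverage / power over
replicated datasets) runs from the command line:

```bash
msmsim study --scenario delta_low__rho_low -n 1000 --n-reps 200 \
       --seed 11 --out scratch/low_low
msmsim simulate --scenario delta_high__rho_high -n 500 --seed 3 --out scratch/data
msmsim validate --scenario delta_low__rho_high
```

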