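# Methods

## The problem

Marginal structural models (MSMs) specify the hazard of a *potential*
survival time — the outcome an individual would have if their treatment
history were set by intervention — optionally conditional on baseline
covariates X.  Evaluating estimators of MSM parameters (for instance
inverse-probability-of-treatment-weighted Cox fits) by simulation requires
generating longitudinal observational data with time-dependent confounding
for which the chosen MSM is *correctly specified*.  That is not automatic:
sampling the outcome from a regression on the full measured history almost
never yields the requested marginal hazard, because the MSM marginalizes
over the time-varying confounders and the baseline variables B that it does
not condition on.

`msmsim` implements a copula-based construction that makes the MSM hold by
construction, for discrete-time logistic hazards and for continuous-time
Cox and additive-hazard models, with discrete or continuous treatment.

## The construction

Notation: visits k = 0..K, administrative censoring at K+1; treatment A_k;
confounders L_k; baseline covariates X (in the MSM) and B (not in the MSM);
survival indicators Y_k = I(T ≥ k); the MSM hazard is

    P(Y_{k+1} = 0 | X, Ȳ_k = 1; intervene Ā_k = ā_k) = g_{k+1}(ā_k, X; β).

At each visit the dependence of the outcome on (B, L̄_k) is channelled
through a scalar *risk score* H_k = h_k(X, B, L̄_k) chosen by the user.  Its
survivor-conditional quantile U_H = F_{H_k}(H_k | X, Y_k = 1) is
Uniform(0,1) given X among survivors.  A bivariate Gaussian copula with
correlation ρ_k ∈ (−1, 0] links the normal score Z_H = Φ⁻¹(U_H) to a latent
outcome score

    Z_Y ~ Normal(ρ_k Z_H, 1 − ρ_k²),   U_Y = Φ(Z_Y),

and the individual fails in the next interval iff U_Y < g_{k+1}(ā_k, X; β)
(strict inequality).  Because Z_Y is marginally standard normal given X,
U_Y is uniform and the marginal hazard is exactly g_{k+1}: the MSM is
correctly specified whatever h_k and ρ_k are.  ρ_k = 0 removes all
dependence of the outcome on (B, L̄_k) given (X, Ā_k); ρ_k → −1 makes the
outcome a deterministic threshold in the risk quantile (failure iff
U_H > 1 − g, which preserves the marginal).  Only the *ranking* induced by
h_k matters: any strictly increasing transform of the risk score leaves the
construction unchanged.

The implied conditional failure probability is

    P(fail | X, B, L̄_k) = Φ( (Φ⁻¹(g) − ρ Φ⁻¹(U_H)) / sqrt(1 − ρ²) ),

increasing in U_H, and integrating to g over U_H ~ Uniform(0,1)
(`conditional_failure_prob`; the identity is asserted to 1e-8 by
quadrature in the tests).

## Rank-estimated risk-score CDFs (match pools)

The survivor-conditional CDF F_{H_k}(· | X, Y_k = 1) is rarely available in
closed form, so the default simulator estimates it *while* simulating.
Each sampled individual is simulated together with m − 1 matches sharing
its X and (imposed) treatment path but drawing their own B and confounder
histories.  At visit k the pool quantile of member j is

    U_j = (R_j − W_j) / m,    W_j ~ Uniform(0,1),

where R_j is the ascending within-pool rank of the risk score — a uniform
jitter of the empirical CDF that makes U_j exactly Uniform(0,1) for
exchangeable scores.  Matches that fail are replaced by copies of uniformly
chosen surviving matches, so the pool stays a sample from the
survivor-conditional law; provenance indices track how many distinct
original matches remain.  When fewer than `restart_fraction` (default 10%)
of the originals survive, the matches are discarded and rebuilt at size
`m_big` by replaying the match generation from visit 0 under the realized
treatment path, with the same rank/copula/replacement machinery at every
replayed visit; the sampled individual's realized data are kept verbatim.
A pool whose matches all die in one visit is treated as the extreme case of
the same rule (immediate restart); `PoolDepletedError` is raised only if an
`m_big` pool depletes.  Only the sampled individual's trajectory is
returned; match data are discarded.

Defaults m = 5000 and m_big = 100000 follow the original study design; the
pool-size sensitivity finding that m = 1000 with m_big = 20000 is adequate
is what the reduced "desk" profile (used by the test suite and the
acceptance script) relies on.

Ties among risk scores (probability zero for continuous scores, but
possible with degenerate user configurations) are broken by a uniformly
random permutation among the tied values.  Quantiles are clipped to
(1e-12, 1 − 1e-12) before Φ⁻¹.  Hazards g = 0 and g = 1 short-circuit the
latent draw comparison via infinite thresholds.

## Continuous time

For Cox or additive-hazard MSMs the interval failure probability is
g_{k+1} = 1 − exp(−∫_k^{k+1} λ^{ā_k}(t|x) dt); the integral is closed-form
for rates declared piecewise-constant on visit intervals (the default) and
32-point Gauss–Legendre quadrature otherwise.  The failure time within
(k, k+1] is obtained by inverting the interval CDF at the latent uniform,
T = G⁻¹(U_Y) with G(t) = 1 − exp(−∫_k^t λ ds) — closed form for constant
rates, bisection (tol 1e-10) otherwise.  This localization is the package's
own construction: it nests the discrete thresholding rule (failure iff
U_Y < g), reuses the same latent draw (so discretizing the continuous
output reproduces the discrete algorithm draw-for-draw on shared seeds),
and preserves the marginal hazard given X at every t.  Negative rates from
an additive-hazard specification raise immediately.

## The study configuration

`study_config(delta_level, rho_level)` encodes the illustrative study: a
Cox MSM with K = 9,

    λ^{ā_k}(t|X) = exp(−3.3) · exp(0.5 X1 + 0.5 X2 − a_k − 0.4 X1 a_k + 0 · X2 a_k),

so β = (0.5, 0.5, −1, −0.4, 0) and only X1 is a true effect modifier.
Covariates: X1 ~ N(0,1); X2 ~ Bernoulli(0.5); B1 | X ~ N(−0.2 + 0.4 X2, 1);
B2 | X ~ N(0.2 X1, 1); L01 ~ N(0.2 X1, 1); L02 ~ Bern(expit(−0.2 + 0.4 X2));
for k ≥ 1, Lk1 ~ N(0.3 + 0.4 B2 + 0.7 L_{k−1,1} − 0.6 A_{k−1}, 1) and
Lk2 ~ Bern(expit(−0.2 + 0.4 B2 + L_{k−1,2} − 0.6 A_{k−1})).  Treatment is
binary with P(A_k = 1 | ·) = expit(−1 + δ1 X1 + δ2 X2 + δ3 B1 + δ4 Lk1 +
δ5 Lk2 + A_{k−1}), with the convention A_{−1} := 0 so the model is defined
at k = 0.  δ_low = (0.1, 0.15, 0.1, 0.3, 0.3), δ_high = (0.2, 0.3, 0.2,
0.6, 0.6).  The risk score is h = 0.3 b1 + 0.5 b2 + l_{k1} + l_{k2} at
every visit and ρ_k ≡ −0.5 (low) or −0.9 (high).  Random censoring is
exponential with rate exp(−3.6), independent of everything else (no
censoring weights are therefore needed in the analyses).  B2 is generated
but treated as unobserved: it is a shared cause of the confounders and the
outcome but not of treatment.  Under these settings about 21–25% of
individuals have an observed failure and about 20–21% are randomly
censored before time 10.

## Fitting layer

Person-period (counting-process) rows (id, k, tstart = k, tstop =
min(k+1, t_obs), event) carry the visit-k covariates, current and lagged
treatment.  Stabilized IPT weights use pooled logistic regressions over all
visits: denominator A_k ~ (X1, X2, B1, Lk1, Lk2, A_{k−1}), numerator
A_k ~ (X1, X2, A_{k−1}); the weight on the interval (k, k+1] is the
cumulative product of probability ratios up to visit k.  Conditioning the
numerator on X is required because the MSM is conditional on X; the lagged
treatment mirrors the generating model's form.

The Cox MSM (covariates X1, X2, a_k, X1·a_k, X2·a_k) is fitted by the
weighted counting-process partial likelihood implemented in
`msmsim.coxph` (Newton–Raphson, Breslow baseline).  Variances: model-based
(inverse information) for the naive unweighted fit; the Lin–Wei "simple"
sandwich — score residuals summed within individual, weights treated as
fixed — for the IPTW fit.  Breslow rather than Efron tie handling is a
deliberate simplification: failure times are continuous here, so ties have
probability zero and the two coincide on generated data; the choice is
recorded for reproducibility.  The implementation agrees with lifelines
(unweighted coefficients and model SEs) and with R `survival::coxph`
(weighted clustered sandwich) to ~1e-7 on shared data; those oracles are
exercised in the test suite.  The percentile bootstrap resamples
individuals with replacement and re-estimates the weights inside every
resample before refitting, so weight-estimation uncertainty enters the CI;
resamples without events are redrawn and counted.  The
weight-uncertainty-corrected sandwich estimator is deliberately out of
scope (it shrinks the variance estimate and would not improve coverage).

Discrete-time MSMs are fitted as weighted pooled logistic regressions of
the per-visit event flag (statsmodels GLM, cluster-robust by individual).

## Study harness

`run_scenario` crosses δ ∈ {low, high}, ρ ∈ {low, high} and n ∈ {250, 500,
1000}.  Replicate seeds derive from (base_seed, scenario_id, replicate_id),
so all methods within a replicate see the same dataset and reruns are
exact.  Aggregates: bias = mean(β̂) − β with MC SE sd/√n_reps; coverage and
power (CI excludes 0) with binomial MC SEs computed from the number of
replicates.  Because the true β5 is 0, power for the β5 test is identically
1 − coverage(β5); the harness asserts this.  Failed replicates are counted
and reported, never silently dropped.

## Problem sizes used by the tests and the acceptance script

The shipped checks use the reduced profile: 200 replicates of n = 1000
with m = 1000 / m_big = 20000 for the bias/coverage/power tables; 10^5
individuals (m = 1000) for the parameter-recovery check; 10^5 individuals
at m = 5000 on a K = 1 configuration with closed-form CDFs for the
exact-vs-rank-estimated comparison; 10^4 individuals per setting for the
marginal event/censoring rates.  These sizes keep every Monte Carlo
tolerance at 3 combined SEs while remaining desk-scale.  The
percentile-bootstrap coverage column of the full study is not reproduced
at that scale (1000 bootstrap refits inside each of 200 replicates); the
bootstrap itself is exercised on single datasets in the tests.

## What the generator does and does not emulate

The synthetic data reproduce the study conditions exactly: equally spaced
common visit times, a binary treatment, independent exponential censoring,
and confounding whose strength is set by (δ, ρ).  Real longitudinal
cohorts add features outside this design — individual-specific visit
times, dependent censoring, dynamic treatment rules, non-Gaussian outcome
dependence — so passing tests certify the algorithmic construction and the
estimators' behaviour under the stated design, not performance on any
particular real dataset.

## Known limitations

* Restart regeneration replays matches from visit 0 under the realized
  treatment path; this is the package's interpretation of the restart rule
  and is validated against the closed-form oracle on high-mortality
  configurations rather than against a reference implementation.
* The batched simulator draws from a single RNG stream per chunk; results
  are reproducible given (seed, n, m, chunk size) but individual i's
  trajectory depends on the batch composition, unlike the per-individual
  entry point, which gives each individual its own generator.
* Per-stratum CDF pre-estimation for small (X, Ā) support, discrete risk
  scores, non-Gaussian copulas, unequally spaced visits and dynamic
  regimes are out of scope.
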