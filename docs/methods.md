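# Methods

## Model and data structure

Each of n cohort subjects carries a failure time T_i and censoring time
C_i, of which only X_i = min(T_i, C_i) and Δ_i = 1{T_i ≤ C_i} are
observed.  Failure times follow a Cox proportional-hazards model
λ(t | Z_i) = λ₀(t) exp(α' Z_i) with p-dimensional covariates Z_i and a
sparse coefficient vector α.  Under the case-cohort design Z_i is
observed only when Δ_i = 1 (case) or ξ_i = 1 (subcohort member), with
ξ_i ~ Bernoulli(π) independent of everything else.  Times and the two
indicators are observed for everyone.

Screening conditions on an index set C of covariates taken as active a
priori.  For each candidate j ∉ C the working model is a marginal Cox
model on (Z_C, Z_j); its candidate coefficient, standardized by the
model-based standard error, is the ranking statistic.

## Estimation

**Weights.** The sampling probability of a censored subject at time t
is estimated by π̂(t) = Σ(1−Δ_i)ξ_i Y_i(t) / Σ(1−Δ_i)Y_i(t) with
Y_i(t) = 1{X_i ≥ t} (at-risk convention: a subject is at risk at its
own event time).  The weight w_i(t) = Δ_i + (1−Δ_i)ξ_i/π̂(t) is only
ever needed at observed event times, because the estimating equation
integrates counting-process jumps; π̂ is treated as a step function and
never interpolated.  If no noncase is at risk at a late event time,
π̂ falls back to the design π when known, else to the last defined
value (with a warning); if the data contain no sampled noncases at all,
the fallback is 1 — every weight is then 0 or 1 and the value never
enters a sum.

**Estimating equation.** The weighted score replaces each risk-set
moment of the Cox partial likelihood with its w_i(t)-weighted version.
It is the exact gradient of the weighted log pseudo-partial likelihood
(the weights do not depend on β), and the negative Jacobian I_j(β) —
the weighted analogue of the observed information, including the
cross-moment (outer-product) term — is used both for Newton steps and
for the variance σ̂_j² = [I_j(β̂)⁻¹] bottom-right element, with the
candidate always ordered last.

**Solver.** Damped Newton–Raphson from β = 0, step-halving line search
on the score max-norm (up to 8 halvings), per-step infinity-norm cap of
2 to keep early iterations stable, convergence at score max-norm
≤ 1e−8, at most 50 iterations.  Ties in event times are handled
Breslow-style (tied events share one risk-set denominator); the
simulated times are continuous, so ties have probability zero there.
Covariates are centered before fitting — a pure shift that leaves the
score, information and coefficients unchanged while keeping exp() in
range even with coefficients near 10.

**Degenerate fits.** Non-convergence or an (effectively) singular
information matrix — condition number above 1e12, as for a constant
candidate — never aborts a screen: the fit is flagged, σ̂_j² is set to
+∞ and the utility to 0, ranking the candidate last.  With thousands of
candidates a screen must survive individual pathological coordinates.

**Batching.** All p − q candidate fits share the same risk-set geometry
and the same π̂ (which does not depend on j).  Subjects with observed
covariates are sorted by descending time so every risk set is a prefix,
and each weighted risk-set sum splits into a case part and a sampled-
noncase part scaled by the per-event scalar 1/π̂(t); both are prefix
cumulative sums, so one Newton iteration for all candidates is a
handful of vectorized array operations.  A warm start (the
conditioning-set-only model fitted once, candidates started from it)
shortens the Newton path without changing the root.  The single-fit
interface `solve_wee` runs the same engine with one candidate.

## Screening rules

Candidates are ranked by M_{C,j} = |β̂_j|/σ̂_j descending, exact ties
broken by ascending covariate index (deterministic; relevant only for
pathological ties such as blocks of utility 0).  Selection is by model
size d0 (default ⌈n_cc/log n_cc⌉ with natural log and n_cc the
case-cohort sample size — the printed reference value ⌈155/log 155⌉=31
forces this reading) or by a utility threshold γ; size mode is the
default.  Conditioning covariates are always part of the final model
but are never ranked.

Comparators implemented with the same machinery: MWSIS (empty
conditioning set), NCWSIS (weights ≡ 1 on the observed subset, i.e.
the case-cohort data treated as a simple random sample), and an
SRS benchmark that screens a simple random sample of the full cohort
with the same size as the case-cohort sample.  On unmasked data the
weighted and unweighted procedures coincide (up to floating-point
summation order, ≈ 1e−12 relative).

## Synthetic cohorts

The generator emulates two canonical designs.  Covariates are standard
normal with common pairwise correlation ρ, drawn by the one-factor
representation Z = √ρ·W + √(1−ρ)·ε (exact in distribution, no p×p
factorization): either all p covariates exchangeable with
α = (1,1,1,1,−2,0,…) — the fifth covariate's marginal association is
exactly cancelled, making it hidden — or the first p−1 exchangeable
with an independent last covariate and α = (10,0,…,0,1), hiding the
last covariate behind the dominant first one.  Failure times use the
inverse cumulative hazard: with constant baseline λ₀,
T = E/(λ₀ exp(α'Z)), E ~ Exp(1); a non-constant baseline would invert
Λ₀ the same way.  Censoring is Uniform(0, τ).

**Censoring calibration.** τ is found by Monte-Carlo bisection on a
common-random-numbers sample (default 20 000 draws, rate tolerance
0.005): the failure rate is a monotone step function of τ on a fixed
sample, so bisection converges.  Default target failure rates and
cohort sizes follow the study designs (20% at n = 500, 25% at n = 300,
5%/10% at n = 1000).

**Subcohort sampling.** π defaults to ratio·FR/(1−FR) for a target
sampled-noncase : case ratio (default 1:1, giving expected case-cohort
sizes of 200 at n = 500/FR 20% and 100 at n = 1000/FR 5%); any π,
e.g. an externally chosen 0.37, can be supplied directly.

What the generator does *not* emulate: covariate measurement error,
non-proportional hazards, informative censoring, stratified or
without-replacement subcohort sampling, and real-data correlation
structures beyond exchangeable.  Passing tests therefore demonstrate
correctness of the estimator and selection machinery under the stated
sampling model, not robustness to violations of it.

## Replication harness

`run_design_cell` repeats cohort generation → case-cohort sampling →
screening over independent replications (per-replication streams
spawned from one master seed; results are reproducible and independent
of scheduling) and aggregates: minimum model size S = |C| + max rank of
the active covariates outside C (median and IQR as q75 − q25 with
linear interpolation — the quantile convention is fixed and documented
here), per-covariate selection proportion Pe and all-active proportion
Pa at size d0.  d0 is recomputed per replication from the realized
(random) case-cohort size; Pa ≤ min Pe is asserted in every summary.
Replication failures are counted and reported, not fatal.  Default
500 replications; the shipped study scripts and acceptance checks use
100, where the extreme proportions (0.000/1.000) and median model sizes
are already stable while a cell completes in under a minute.

The conditioning-set experiment (`figure1_experiment`) shares each
simulated sample across conditioning sets and reports, per set, the
utility sample of the hidden covariate, a pooled sample of inactive
utilities, and a separation diagnostic defined as the probability that
the hidden covariate's utility exceeds that of a randomly chosen
inactive covariate.

## Known limitations

- The variance σ̂_j² is the model-based inverse information, matching
  the screening statistic's definition; it is not a sandwich estimator
  and should not be used for confidence intervals under misspecified
  marginal models.
- Non-extreme selection proportions at 100 replications carry binomial
  noise of roughly ±0.05 and drift with the seed; only the extreme
  outcomes are treated as sharp checks.
- The π̂ fallback at late event times is a pragmatic device for finite
  samples; the estimand is only defined while noncases remain at risk.
- Monotone-likelihood candidates (risk score separating events) drift
  to large |β̂| with large σ̂; they end flagged or down-ranked, but no
  explicit separation test is performed.
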