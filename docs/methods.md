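# Methods

## Models and estimators

All four estimators model the observed study effects as
`y_i = μ + u_i + ε_i` with `Var(y_i | μ) = γ(σ_i² + τ²)` and differ in
which variance components they free:

* **FE** (γ=1, τ²=0): inverse-variance weighted least squares, weights
  `w_i = 1/σ_i²`; `μ̂ = Σw_i y_i / Σw_i`, `Var(μ̂) = 1/Σw_i`.
* **RE** (γ=1, τ²≥0): joint maximum likelihood of (μ, τ²) under
  `Var(y_i) = σ_i² + τ²`. Implemented by profile likelihood: for fixed τ²
  the ML μ is the weighted mean with `w_i = 1/(σ_i²+τ²)`, so a 1-D bounded
  Brent search over τ² ∈ [0, max(10·var(y), 1)] (absolute tolerance 1e−10)
  suffices. The τ² = 0 boundary is always evaluated explicitly; this
  handles the frequent boundary solution and makes
  `loglik(RE) ≥ loglik(FE)` an exact, testable identity. ML — not REML,
  DerSimonian–Laird, or Paule–Mandel — is deliberate: it is the estimator
  whose selection behaviour is under study, and it is what the likelihood
  in AIC/BIC refers to.
* **UWLS-FE** (γ free, τ²=0): γ cancels from the weighted mean, so the
  point estimate equals FE's exactly. With Cochran's
  `Q = Σ(y_i − μ̂)²/σ_i²`, the reported scale is `γ̂ = H² = Q/(N−1)` and
  `SE = √γ̂ · SE_FE`. γ̂ is floored at 1e−12 (degenerate zero-dispersion
  datasets) and **not** truncated at 1: γ̂ < 1 shrinks the interval, which
  is the "excessive homogeneity" behaviour whose consequences the study
  measures.
* **UWLS-RE** (γ, τ² free): two-step. Step 1 takes τ̂² from the RE ML fit;
  step 2 treats it as fixed, uses weights `v_i = 1/(σ_i²+τ̂²)` (point
  estimate therefore identical to RE's), and estimates the scale from the
  weighted residual sum `Q* = Σv_i(y_i − μ̂)²` as `γ̂ = Q*/(N−1)`,
  `SE = √γ̂ / √Σv_i`. Not joint ML, by construction.

**Likelihood convention for the information criteria.** Each model's ℓ is
its own Gaussian likelihood maximized over its free parameters, with scale
parameters plugged in at their ML values (divide-by-N: γ̂_ML = Q/N, giving
the closed form ℓ = −(N/2)[log 2π + log γ̂_ML + 1] − ½Σlog base-variance),
while the *reported* γ̂ keeps the divide-by-(N−1) convention so that it
coincides with H². Parameter counts are k = 1 (FE), 2 (RE), 2 (UWLS-FE),
3 (UWLS-RE). This keeps AIC/BIC comparisons likelihood-coherent across
nested models; an alternative convention (treating the step-1 τ̂² of
UWLS-RE as not counted, k = 2) was considered and rejected because charging
the model for every fitted parameter is the standard IC accounting and the
full simulation reproduces the target selection rates without it.

**Intervals** use normal quantiles (`μ̂ ± z₀.₉₇₅·SE`), matching
conventional meta-analysis software. Small-sample t or Knapp–Hartung
adjustments are out of scope; the undercoverage of UWLS intervals at
N = 3–10 is a finding, not an artifact to correct.

## Simulation design

The generator's defaults are the study conditions:

* grid: μ ∈ {0, 0.25, 0.50, 1.00} × γ ∈ {0.5, 1, 1.5} ×
  τ² ∈ {0, 0.01, 0.10} × N ∈ {3, 5, 10} — 108 DGPs typed
  12 FE / 24 RE / 24 UWLS-FE / 48 UWLS-RE;
* σ_i profiles fixed per N (0.30/0.40/0.50 at N=3, 0.20…0.60 at N=5,
  0.15…0.60 at N=10), representative of reported sampling SDs in medical
  meta-analyses;
* 1000 replicate datasets per DGP (108 000 total) in the main experiment;
* draws `u_i ~ N(0, γτ²)` and `ε_i ~ N(0, γσ_i²)` per study; estimators
  receive the **unscaled** σ_i — γ is latent.

For the sample-size sweep (N up to 5000) the N = 10 σ-profile is tiled
N/10 times. This preserves the empirical dispersion shape; results at
N ≥ 100 are conditional on that choice, since any profile extension is
necessarily an extrapolation.

What the generator does *not* emulate: skewed or heavy-tailed effect
distributions, correlated estimates within a meta-analysis, σ_i reported
with error, publication-bias selection mechanisms. Passing tests therefore
demonstrate estimator/criterion behaviour under clean Gaussian worlds with
the stated variance structure — the regime where AIC/BIC have their best
chance — and not robustness to those further realities.

## Aggregation

Metrics are two-stage: bias, RMSE, and coverage are computed within each
DGP over its replicates, then the 108 per-DGP values are averaged with
equal weight (overall and within each of the four type subgroups). The
staging matters for RMSE — the mean of per-DGP RMSEs is not the pooled
RMSE. Model-selection rates use strict-inequality preference (ties, a
measure-zero event, count against the focal model) and argmin winners with
the deterministic tie order FE, RE, UWLS-FE, UWLS-RE.

The reweighted path replaces the equal DGP weights with a supplied vector,
e.g. match counts from `mahalanobis_match`: each fitted
(μ̂, γ̂, τ̂², N) point from a real corpus is assigned to its nearest grid
DGP under the Mahalanobis metric with covariance estimated from the full
pooled cloud on raw coordinates (a log-γ or otherwise transformed matching
space would be defensible; raw coordinates with full-cloud covariance were
chosen and the affine-invariance of the metric is property-tested). A
singular covariance falls back to diagonal variance scaling (zero
variances replaced by 1) with a logged warning; distance ties break toward
the lowest dgp_id. Within each reporting group weights are renormalised
over that group's DGPs, and a zero-weight group falls back to equal
weights. Reproducing corpus-derived weights themselves requires the
external corpus and is out of scope; the pipeline accepts any
`dgp_id,weight` CSV.

## Randomness and reproducibility

One master seed; every (experiment, dgp, replicate) cell gets an
independently keyed `SeedSequence` substream. Results are therefore
byte-identical across runs and independent of execution order, and the
design is embarrassingly parallel even though the shipped runner is
single-process (a full main experiment takes ~2 minutes on one CPU, so
parallelism is unnecessary).

## Problem sizes used in the shipped checks

The packaged end-to-end checks run the main experiment at its full size
(108 × 1000) and the sweep at sizes 3 and 5 with 1000 replicates; the
N = 5000 sweep point uses 200 replicates per DGP — the documented
reduced-replicate mode, with correspondingly widened Monte Carlo
tolerances (±5 percentage points instead of ±3).

## Numerical notes and limitations

* RE's profile search is a bounded scalar optimization; agreement with a
  zoomed grid-search oracle to 1e−4 and with an independent reference ML
  implementation to ~1e−6 is tested.
* Exact float comparison classifies γ = 1 and τ² = 0 in the grid — safe
  because grid values are assigned constants.
* The FE/UWLS-FE and RE/UWLS-RE point-estimate identities hold bitwise
  (identical arithmetic paths), and tests assert them with `==`.
* Known limitation: with N = 2 studies the UWLS scale estimate has one
  degree of freedom and is extremely noisy; fits are allowed (the methods
  are defined for N ≥ 2) but no claims are made about that regime.
* Fit failures inside an experiment are logged with (dgp, replicate,
  model), excluded from that model's aggregates, and counted in an
  exclusions table; on the factorial grid no fit has been observed to
  fail.
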