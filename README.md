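# metaselect

Monte Carlo evaluation of meta-analysis estimators and of AIC/BIC model
selection in the small-sample, weak-signal settings typical of medical
research syntheses.

## The problem

A meta-analysis pools effect estimates `y_i` (with reported sampling
variances `σ_i²`) from `N` primary studies into one estimate of the
population mean effect `μ`. The candidate models differ only in what they
assume about `Var(y_i)`:

| model   | Var(y_i)            | free parameters (k) |
|---------|---------------------|---------------------|
| FE      | σ_i²                | μ (1)               |
| RE      | σ_i² + τ²           | μ, τ² (2)           |
| UWLS-FE | γ·σ_i²              | μ, γ (2)            |
| UWLS-RE | γ·(σ_i² + τ²)       | μ, τ², γ (3)        |

Here τ² is additive between-study heterogeneity of true effects and γ is a
multiplicative distortion of the reported sampling variances (numerically
equal to the heterogeneity statistic H² = Q/(N−1), where Q is Cochran's
statistic). γ cancels from the weighted mean, so UWLS-FE shares FE's point
estimate and UWLS-RE shares RE's; only the standard errors differ, rescaled
by √γ̂ with no truncation at 1 — γ̂ < 1 ("excessive homogeneity") *shrinks*
the intervals.

Information criteria (AIC = 2k − 2ℓ, BIC = k·log N − 2ℓ) are widely used to
pick among these models, but medical meta-analyses are tiny (median ≈ 5
studies). This package simulates meta-analyses from a calibrated factorial
grid of 108 data-generating processes — μ ∈ {0, 0.25, 0.5, 1} ×
γ ∈ {0.5, 1, 1.5} × τ² ∈ {0, 0.01, 0.1} × N ∈ {3, 5, 10}, each with fixed
realistic σ_i profiles — where the true model type is *known*, and measures
(a) how often AIC/BIC select the correct model, and (b) the bias, RMSE, and
95%-interval coverage of each estimator. The headline finding it
reproduces: AIC/BIC systematically favour UWLS-FE in small samples even
when it is not the true model, while RE delivers the most reliable
coverage.

It is intended for meta-analysis methodologists and for practitioners who
want to fit all four estimators to their own data (`metaselect fit`).

## Worked example

Fit all four estimators to a five-study meta-analysis:

```bash
cat > meta.csv <<'CSV'
effect,standard_error
0.80,0.20
-0.30,0.30
0.55,0.40
1.20,0.50
0.05,0.60
CSV
metaselect fit meta.csv
```

```
model,mu_hat,se_mu,tau2_hat,gamma_hat,loglik,n_params,ci_low,ci_high
FE,0.5096382136800452,0.14265511030964223,0.0,1.0,-5.608354086073725,1,0.23003933526255793,0.7892370920975326
RE,0.4575392495964413,0.24347956865426307,0.15384313131410396,1.0,-4.039968608628445,2,-0.019671935937261742,0.9347504351301443
UWLS_FE,0.5096382136800452,0.24599912461777731,0.0,2.973667836505245,-4.327649916434773,2,0.027488789200821095,0.9917876381592694
UWLS_RE,0.4575392495964413,0.26319218215422285,0.15384313131410396,1.1684790289128442,-4.034408992068774,3,-0.05830794843834097,0.9733864476312236
```

Reading this: the inverse-variance (FE) pooled effect is 0.510 with SE
0.143. The data are overdispersed relative to the reported variances
(γ̂ = H² ≈ 2.97), so UWLS-FE keeps the same point estimate but inflates the
SE by √2.97 to 0.246. RE attributes the extra spread to between-study
heterogeneity (τ̂² ≈ 0.154 by maximum likelihood), shifting the estimate to
0.458 and widening its interval; UWLS-RE then finds only mild residual
scale distortion (γ̂ ≈ 1.17) on top of that. RE attains the highest
log-likelihood, but with k = 2 it does not automatically win on AIC/BIC —
which is precisely the selection behaviour the simulation study
quantifies.

Run the full simulation study and the sample-size sweep:

```bash
metaselect -v run-main  --seed 1 --out-dir results/        # 108 DGPs x 1000 reps
metaselect -v run-sweep --seed 1 --sizes 3 --sizes 100 --out-dir results/
```

These write long-format CSVs (`table4.csv`, `table5.csv`, `table6.csv`,
`table7a.csv`, plus per-dataset `estimates.csv` and the `grid.csv` design)
into the output directory. A YAML config (`master_seed`,
`replicates_per_dgp`, `sweep_sizes`, `ci_level`) can replace the flags, and
a `dgp_id,weight` CSV (e.g. produced by `metaselect.mahalanobis_match` from
a fitted parameter cloud) adds a reweighted performance table
(`table7b.csv`).

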