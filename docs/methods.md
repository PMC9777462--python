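# Methods

This note records the statistical model, the numerical choices, and the
design decisions behind `labsieve`, together with what the synthetic
cohorts do and do not establish about real hospital data.

## Problem setting

The input is a retrospective laboratory extract: one row per measurement
(case, analyte, value, unit, optional timestamp) and per-case ICD-10 code
lists. The outcome is binary — whether any code falls in a target category
range, by default I20–I25 (myocardial ischemia); primary and secondary
diagnoses are not distinguished. The cohort is restricted to cases with a
measured troponin T value, which operationalizes "worked up for myocardial
ischemia" and makes the troponin column fully observed. Repeated
measurements of one analyte within a stay are reduced to the earliest by
timestamp (the presentation value, the diagnostically relevant one); this
reduction is a package choice, as is rejecting analytes whose records carry
conflicting units rather than attempting conversion. Two-level categorical
analytes (arterial/venous collection type) are encoded 0/1; more levels are
rejected.

## Sparsity tiers

Per-analyte coverage is the fraction of cohort cases with an observed
value, computed after the troponin cohort filter. A tier with maximum
missingness m keeps analytes with coverage ≥ 1 − m, boundary inclusive
("measured in at least 80% of cases" → the 20% tier). Tiers are nested by
construction; cases are never dropped for incompleteness — missingness is
handled by imputation.

## Multiple imputation

Each tier is completed by chained equations. Missing cells are initialized
by draws from the analyte's observed empirical distribution; each sweep
then visits incomplete analytes in descending-coverage order (ties broken
by analyte id) and redraws their missing cells from the posterior
predictive of a Bayesian linear regression of the observed values on all
other currently-completed analytes *plus the outcome label*. Including the
outcome in the imputation model is the standard congeniality argument:
omitting it biases analyte–outcome associations toward null, which is
exactly what the downstream selection measures.

The regression is a conjugate normal–inverse-gamma draw stabilized by a
tiny ridge (10⁻⁶ of the mean Gram-diagonal) so rank-deficient designs
degrade gracefully instead of failing; the ridge is numerical, not a
substantive prior. Analytes whose observed values are strictly positive
with IQR exceeding the median — the typical right-skewed lab value — are
log-transformed for the regressions and back-transformed afterwards.

Defaults: M = 5 chains, 20 sweeps, seeds derived per chain. Convergence is
monitored per analyte on the mean of its imputed cells per sweep, over the
second half of the sweeps, with the Gelman–Rubin statistic

    W = mean within-chain variance,  B = n · var(chain means),
    V̂ = ((n−1)/n) W + B/n,  R̂ = √(V̂/W),

flagged converged when R̂ < 1.1 (conventional threshold). Identical chains
give exactly √((n−1)/n); chains that are internally constant but disagree
return +∞ ("not converged"); all-equal constants are reported degenerate.
The monitored statistic is a package choice — any smooth functional of the
imputations would do; the mean of imputed cells is the most interpretable.
With the default 20 sweeps the 10-sweep monitoring window is short, so R̂
on a well-mixed analyte fluctuates noticeably around 1; runs that need a
tight convergence read-out should use ~40 sweeps, which empirically brings
all monitored R̂ under 1.05 on the default synthetic cohorts.

## Variable selection: ODA/BMA probit

For completed data the model is a spike-and-slab probit regression on
standardized analytes (the same log transform as in imputation is applied
to skewed analytes before standardization, making the design congenial with
the generator's latent-linear outcome):

    P(yᵢ=1) = Φ(α + xᵢᵀβ),  βⱼ|γⱼ=1 ~ N(0, τ²),  γⱼ ~ Bern(π),

defaults π = 0.5, τ² = 1 on the standardized scale, intercept always
included with variance 10⁶. The π = 0.5 prior is the natural agnostic
default; the preference for small models does not need an explicit penalty
because the marginal likelihood of a noise coordinate is maximized by the
spike (Occam shrinkage) — with π = 0.5 and n ≥ 500, null-analyte inclusion
probabilities settle well below 0.5.

The sampler augments the n standardized rows X_o with p pseudo-rows
X_a = chol(diag(D) − X_oᵀX_o), D = (λ_max(X_oᵀX_o) + ε)·1 with
ε = 10⁻³ λ_max — the smallest uniform diagonal dominating the Gram matrix,
inflated just enough to keep the Cholesky factorization strictly positive
definite (on failure ε is inflated 10×, then the run errors). Because the
intercept column is orthogonal to the centered X_o and absent from the
augmented rows, the combined design has a fully diagonal cross-product and
each Gibbs iteration is:

1. draw latent utilities Zᵢ ~ N(α + xᵢᵀβ, 1) truncated by yᵢ (inverse-CDF
   sampling phrased in whichever normal tail keeps accuracy at large |η|);
2. draw augmented responses Z_a ~ N(X_a β, 1);
3. form per-coordinate estimates β̂ⱼ = (complete column j)ᵀ(complete
   response)/dⱼ — independent across j by orthogonality;
4. draw each γⱼ ~ Bernoulli(ρⱼ) with
   ρⱼ = π N(β̂ⱼ; 0, 1/dⱼ+τ²) / [π N(β̂ⱼ; 0, 1/dⱼ+τ²) + (1−π) N(β̂ⱼ; 0, 1/dⱼ)]
   (evaluated in log space), then βⱼ from its conjugate normal conditional
   (point mass at 0 when γⱼ = 0), and α from its normal conditional;
5. after burn-in, accumulate the Rao-Blackwellized inclusion estimate as
   the running mean of the conditional ρⱼ, and count visited models.

Defaults: 20 000 iterations, 5 000 burn-in, seed per (tier, chain) derived
from the base seed through a `SeedSequence`. A linear-outcome variant
(observed y used directly as the complete response, unit residual variance,
y pre-scaled) exists for oracle testing. Occam's-window pruning of the
visited model list (keep models within a factor C of the best) is provided
as a secondary, stricter read-out; the per-analyte ρⱼ is the pipeline's
primary output.

## Exact oracle

The sampler is validated against exhaustive enumeration of all 2ᵖ models
sharing the identical prior object. For the linear outcome the per-model
marginal likelihood is the closed-form Gaussian marginal, evaluated in the
(|S|+1)-dimensional factor space via the Woodbury and determinant-lemma
identities (cost O(2ᵖp³), guarded at p ≤ 12). For probit, the marginal
likelihood integral over (α, β_S) — at most 4 dimensions, p ≤ 3 — is
computed by mode-adapted tensor Gauss–Hermite quadrature: Newton with
analytic gradient/Hessian finds the posterior mode of the log-concave
integrand, and the Gauss–Hermite grid (32 nodes per dimension, 20 when
4-dimensional) is placed in the mode-centered, Hessian-scaled frame. This
is quadrature of the exact integrand, not a Laplace approximation; on these
near-Gaussian integrands the error is far below the 0.02 agreement bound
used in the tests. Sampler-vs-oracle agreement within ±0.02 per analyte at
20 000 post-burn iterations holds across random instances (p ≤ 10 linear,
p ≤ 3 probit).

## Pooling and reporting

The sampler runs once per imputation chain, giving M inclusion estimates
per analyte per tier; pooling is their mean with a normal-approximation
95% interval mean ± 1.96·sd/√M truncated to [0, 1]. A percentile interval
would be degenerate at M = 5, hence the normal form. The interval is
reported absent when the chains agree exactly — notably the unanimous
100%-inclusion case — or when M = 1. An analyte with pooled ρ ≥ 0.95
(boundary inclusive) is *highly predictive*; the cross-tier report marks
tiers where the analyte was not modeled with "—" rather than 0, and totals
count flags over tiers.

## Synthetic cohorts

The generator draws a shared standard-normal severity factor per case;
each analyte's standardized latent value is loading·severity plus
independent noise (default loading 0.3; 0.5 for the troponin analog). The
outcome is probit in the latent values: η = Σ cⱼ zⱼ, with the intercept
solved by root finding so the sample prevalence hits its target (default
0.1, chosen for test power; a realistic emergency-cohort prevalence is
nearer 0.05). Native values are monotone maps of the latents: lognormal
analytes get σ_log = asinh(IQR/2·median)/z₀.₇₅ so sample median and IQR
converge to their targets; normal analytes use IQR/1.349 as the SD. The
default panel has ~30 analytes whose median/IQR targets follow published
myocardial-ischemia cohort values where available, a nested 8/16/23/30
coverage profile mirroring published tier widths, and four true predictors
(troponin analog 2.0, potassium 0.7, rdw 0.5, urea 0.5 on the standardized
scale — the dominant-analyte structure of the motivating cohort). Nonzero
coefficients are restricted to continuous, non-derived analytes so the
probit model in the transformed design is exactly correctly specified.

Missingness is applied per analyte: MCAR hides cells independently at rate
1 − coverage; MAR-on-severity makes the *observation* probability increase
with the latent severity (sicker patients get the rarer tests), logistic
with unit slope and an offset solved to match the marginal rate. The
troponin analog is never hidden. The CKD-EPI eGFR,

    141 · min(Scr/κ,1)ᵃ · max(Scr/κ,1)⁻¹·²⁰⁹ · 0.993^Age · 1.018(female) · 1.159(black),

is computed deterministically from the creatinine column (µmol/L ÷ 88.4 →
mg/dL) and drawn demographics. Direct evaluation of this formula for a
53-year-old non-black woman with Scr 0.8 mg/dL gives ≈ 84.2 mL/min/1.73 m²;
a widely circulated worked example quotes 88 for the same inputs, which is
inconsistent with the formula as printed — this package implements the
formula.

What the synthetic cohorts do **not** emulate: real between-analyte
correlation structure beyond a single factor, measurement error, panel
ordering practice (test sets arrive in correlated blocks), temporal
dynamics within a stay, or ICD coding noise. Passing the recovery tests
therefore shows the machinery is correct and well calibrated under the
stated generative model, not that real-data conclusions are automatic.

## Problem sizes and determinism

The default analysis scale used throughout the tests and the acceptance
script is a 2000-case cohort, four tiers, M = 5 chains × 20 sweeps, and
20 000-iteration sampler runs (6 000 for the 10-seed recovery study, where
the Monte-Carlo error of the Rao-Blackwellized estimate is already far
below the margins being tested). Every random stage is seeded from the
base seed and the (tier, chain) indices via `SeedSequence`, so results are
bit-reproducible; observed cells are never modified by any stage.

## Known limitations

- Binary encoded analytes are imputed on the linear scale (no rounding to
  {0,1}); for the probit design this is harmless but the completed matrices
  are not guaranteed to contain only valid category codes.
- The Gelman–Rubin read-out at the default 20 sweeps is noisy (see above).
- ODA mixing slows when predictors are very highly correlated; the
  augmented Gram diagonal λ_max + ε grows with correlation, shrinking
  per-iteration coordinate information. The oracle agreement tests cover
  moderate correlation only.
- Occam's-window output is estimated from visited-model counts and is
  unreliable when p is large enough that few models recur.
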