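# Methods

## Generative model

`treatbias.dgp` simulates a longitudinal cohort around the causal structure
genetic variant → phenotype ← confounder → treatment → later phenotype,
with optional arrows variant → treatment (mediation via prescription) and
variant × treatment → phenotype (effect modification).

Per subject, with `g_eff` the allele count (additive) or the carrier
indicator (dominant generation):

* genotype: Binomial(2, maf), identical to the Hardy–Weinberg trinomial
  ((1−p)², 2p(1−p), p²);
* confounder: lag-1 Gaussian process, `U_0 ~ N(0,1)`,
  `U_t = ρ U_{t−1} + √(1−ρ²) ε_t`, so every margin is N(0,1) and the
  whole path is multivariate normal with two parameters;
* phenotype: first-order Markov recursion
  `Y_t = ω₀,t + λ_t g_eff + ω₁ D_{t−1} + ω₂ U_{t−1} + ω₃,t Y_{t−1} +
  ω₄ g_eff D_{t−1} + e_t`, residuals `e_t = σ·N(0,1)` or `σ·t(2)`
  (the t(2) variant is deliberately *not* variance-standardised — its
  variance is infinite — so σ is a scale, not an SD, there);
* treatment: Bernoulli with logistic probability in the current phenotype,
  confounder, previous treatment (persistence a₃) and optionally the
  genotype (α_G); at baseline of a randomized design the probability is
  `expit(a₀)` alone.  `D_t` governs the interval ending at t+1, i.e. the
  phenotype responds to the treatment decided in the *previous* period —
  the lag convention that avoids mixing cause and effect.

Draws are made in a fixed order (genotypes, confounder innovations,
residuals, treatment uniforms) from a single `numpy` Generator, so a
scenario flagged for coarse observation produces bitwise-identical cohorts
to its fully observed twin; the observation filter
(`mask_observations`) only drops and relabels periods afterwards.

### Scenario presets

| preset | design | iterated |
|---|---|---|
| S1 | T=1, randomized at baseline, λ=0.5, ω₁=−10 | ω₄ ∈ {0.5, …, 5} |
| S2A | T=1, prescription on Y₀ and U₀ (e^a₁=1.2, e^a₂=1.5), ω₁=−10 | λ ∈ {0, 0.2, …, 1.8} |
| S2B | as S2A with λ=0.5 | ω₁ ∈ {0, −4, …, −36} |
| S3A | T=5, time-varying treatment with persistence e^a₃=4 | λ ∈ {0, 0.5} |
| S3B | generation identical to S3A; estimation sees only t ∈ {0, 5} | λ ∈ {0, 0.5} |

Parameters not pinned down by the study designs use fixed package
defaults: n = 1000 subjects per replication, maf = 0.3, ω₀ ≡ 0, ω₂ = 1,
ω₃ ≡ 0.5, σ = 1, ρ = 0.5, a₃ = log 4.  These are plausible mid-range
magnitudes; the calibration properties the package asserts (null
unbiasedness, nominal coverage, the bias sign patterns) are insensitive to
them, whereas the absolute non-null bias magnitudes are not and are
therefore never asserted as point values.  The intercept a₀ is set at
preset construction to `−(a₁·E[Y₀] + α_G·E[g_eff])`, centring the
baseline linear predictor so roughly half the cohort starts treated.

## Estimators

All strategies consume the long cohort table and emit a point estimate,
standard error, 95% Wald interval and two-sided p-value (normal reference;
at n = 1000 the t-vs-normal distinction is immaterial).  Failures — a
monomorphic variant, an empty stratum, a singular design, a non-converged
likelihood — are flagged results, never exceptions.

**Marginal** regresses the last observed phenotype on genotype.
**Prior-to-treatment** regresses the baseline phenotype on genotype and is
the only strategy scored against λ₀ rather than γ (it cannot estimate γ
unless nobody is treated).

**Summed per-period strategies** (conditional 1, untreated subgroup,
constant addition, censored regression) fit one model per post-baseline
period t = 1..T and report `γ̂ = Σ_{t=1..T} λ̂_t`.  The baseline fit is not
part of the sum: each per-period fit omits the phenotype history, so its
genotype coefficient already absorbs the carried-forward effect of earlier
periods (for T = 1 the sum is exactly the single final-measurement fit of
the classical single-visit correction methods — and that is what makes the
untreated-subgroup strategy unbiased under pure effect modification, where
the stratum fit picks up λ₁ + ω₃λ₀ = γ).  Under time-varying treatment
this same absorption is the mechanism by which the summed strategies
*over*-estimate γ, since every λ̂_t counts the cumulative effect again.

* conditional 1 adds the lagged treatment indicator to each period fit; a
  period with only one treatment level degrades to a plain marginal fit
  (the degenerate column is dropped; only a degenerate genotype fails).
* untreated restricts each period fit to subjects untreated in the
  preceding interval (minimum three subjects and two genotype groups per
  stratum, otherwise the strategy fails — the realistic failure mode when
  treatment is near-universal).
* constant adds `correction · D_{t−1}` to the phenotype before the
  marginal fit; the default correction +10 encodes an assumed treatment
  effect of −10.
* censored fits a Gaussian likelihood in which a treated subject's
  observation is a right-censored reading of the untreated level:
  censored rows contribute `log S((y−μ)/σ)`, uncensored rows the normal
  density, with genotype the only regressor and a common σ per period.

**Conditional models 2 and 3** add the lagged confounder and phenotype
(and, for model 3, the genotype-by-treatment product) to each period fit;
the genotype main effect is then the period effect at the treatment
reference level.  The life-time effect is composed through the Markov
recursion (`compose_lifetime`):

```
γ̂ = λ̂_T + Σ_{t<T} λ̂_t · Π_{s=t+1..T} ω̂₃,s
```

The cumulative product is the lag-1 path from Y_t to Y_T; the flat sum
`λ̂_T + Σ λ̂_t ω̂₃,t` would only be correct for T = 1.  The baseline model
regresses Y₀ on genotype alone (Y₀ has no treatment history, so there is
nothing to condition on).

## Standard errors

* Marginal, prior-to-treatment and the per-period building blocks use
  classical OLS covariance.
* The summed strategies default to subject-level influence-function
  ("cluster") variances: the influence of subject i on λ̂_t is
  `ψ_it = [(X'X)^{-1} x_i ε_i]_λ` (for the censored fits,
  `ψ_it = [I^{-1} s_i]_λ` with observed information I and per-row score
  s_i), and `Var(Σ_t λ̂_t) = Σ_i (Σ_t ψ_it)²`.  Because the same subjects
  enter every period fit and those fits omit the phenotype history, the
  per-period estimates are positively correlated; summing their variances
  as if independent (available as `se_method="independent"`) understates
  the sampling variance so badly that even under the strict null the
  nominal 95% intervals cover only ~82–90%.  The clustered form restores
  nominal null coverage for every strategy and doubles as a sandwich
  variance for the censored fits, whose likelihood is misspecified under
  informative censoring.
* Conditional models 2/3 use the delta method over the per-period
  `(λ̂_t, ω̂₃,t)` blocks, taken independent across periods — justified
  because those fits condition on the preceding phenotype, leaving
  serially independent residuals.  A subject-level nonparametric bootstrap
  (200 resamples by default) is available as `se_method="bootstrap"` and
  agrees with the delta method to within a few percent on the scenario-3
  designs.

## Analytic truths

`true_gamma` evaluates the life-time effect from the configuration; it is
cross-checked against a brute-force oracle that simulates the noise-free
recursion with treatment forced to its reference level and regresses the
final phenotype on genotype.

For the two-period designs, the expectation of the marginal slope
decomposes exactly via `cov(Y₁, G) = λ₁ var G + ω₁ cov(D₀, G) +
ω₃ λ₀ var G + ω₄ cov(G D₀, G)`, giving

* mediation term `α_total · ω₁`, with `α_total = cov(D₀, G)/var(G)` the
  total genotype-to-treatment path coefficient on the linear-probability
  scale.  Because treatment follows a logistic model there is no closed
  form; `g_treatment_paths` computes it from one large simulated cohort
  (default n = 400 000) under the scenario's *actual* noise — suppressing
  the residuals would change `E[expit(·)]` and hence the coefficient.
* interaction term `ω₄ · cov(G D₀, G)/var(G)`; under randomization the
  weight reduces to the treated fraction, so the bias is
  `ω₄ · P(D=1)` — independent of λ₀ and ω₃, which enter γ* and γ equally
  and cancel.  (At λ₀ = 0.5 and 50% randomization this coincides
  numerically with the textbook expression `λ₀ω₄`, which is why both
  forms fit that canonical design.)

## Replication engine

`run_replications` spawns one child seed per replication from the master
seed (`numpy.random.SeedSequence`), so any replication is reproducible in
isolation and summaries are invariant to the joblib worker count.  Each
replication simulates, applies the observation mask if any, runs the
requested strategies and records results; failures are rows, not errors.
`summarise` scores non-failed replications per strategy: bias, RMSE
(satisfying `rmse² = bias² + var(estimate)` exactly), 95% CI coverage of
the strategy's own truth, rejection rate at α = 0.05, failure counts, and
the Monte-Carlo SE of the bias.

## Numerical choices

* Censored likelihood: maximised by BFGS with an analytic gradient from an
  OLS warm start, followed by Newton polish steps with the numerically
  differentiated Hessian (which is also the observed information used for
  the covariance); convergence requires the gradient max-norm below
  `1e−6·(1+|loglik|)` — a scale-aware form, since the log-likelihood is a
  sum over a thousand rows.  All-censored periods, singular designs and
  genuine non-convergence fail the strategy for that replication.
* Rank handling: degenerate non-genotype columns are dropped from any
  design; a rank-deficient cross-product or degenerate genotype flags
  failure.  Least squares is solved by `numpy.linalg.lstsq` with its
  default singular-value tolerance.
* Survivor terms use `scipy.special.log_ndtr` throughout, and the hazard
  is evaluated as `exp(logφ − log S)` for stability deep in the tail.
* CSV output uses 6 significant digits, '.' decimals, UTF-8, mandatory
  header.

## Problem sizes

The packaged studies use 2000 replications of n = 1000 for the scenario-3
calibration tables (the full-precision studies behind the canonical
results used 10 000; the CLI exposes `--reps` for that), 150–300
replications per grid point for the scenario-1/2 pattern checks, and
n = 400 000 single cohorts for the large-sample path coefficients.  At
2000 replications the Monte-Carlo SE of a 95% coverage estimate is about
0.005, so calibration assertions use ±3·MC-SE bands (coverage within
[0.935, 0.965], rejection within [0.035, 0.065]).

## What the simulator does and does not emulate

It emulates: prescription guided by the measured phenotype and a
confounder, treatment persistence, first-order phenotype carry-over,
heavy-tailed residuals, and dominant-generation misspecification
(generation may be dominant, estimators always code additively).  It does
not emulate: multiple drugs or dosage, adherence, missing data or
measurement error, genotyping error, multi-variant architectures, or any
specific disease–treatment pair.  Passing tests therefore demonstrate the
causal mechanisms and the relative behaviour of the strategies, not
absolute effect sizes for any empirical cohort; real EHR data add missing
visits, irregular measurement times and imperfect confounder capture that
this generator deliberately leaves out.

## Known limitations

* The summed strategies' clustered variance treats periods symmetrically;
  it is consistent for the sum but does not produce the full joint
  covariance of the period effects.
* The censored regression models censoring as subject-specific right
  censoring at the observed value; a treatment that *raises* the
  phenotype would need the mirrored (left-censored) likelihood, which is
  not implemented.
* With a treatment effect an order of magnitude larger than the residual
  scale (the default −10 vs σ = 1), censored observations carry almost no
  likelihood information and the censored strategy behaves like the
  untreated-subgroup fit; its characteristic excess bias under informative
  censoring only emerges when the treatment effect is comparable to σ
  (e.g. the ω₁ = 0 end of the S2B grid).
* `decompose` covers the two-period, additively generated designs; the
  multi-period marginal expectation is available only by simulation.
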