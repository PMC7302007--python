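# Methods

## Model and derivation

For a trait `Y`, a binary exposure `E` and a SNP `G` coded 0/1/2, the joint
interaction model is

    g(E[Y | G, E]) = α + β·G + γ·E + δ·G×E,

with `g` the identity (quantitative) or logit (binary) link. Because `E`
is binary, the model is saturated in `E`: conditioning on `E = 0` gives a
stratum model with genetic slope `β`, and on `E = 1` one with slope
`β + δ`. For ordinary least squares (and for logistic maximum likelihood,
whose likelihood factorizes over the strata) this makes the stratified
point estimates *exact* functions of the joint fit:

    β̂_unexp = β̂,    β̂_exp = β̂ + δ̂.

Their variances follow from the delta method on the joint coefficient
covariance: `Var(β̂ + δ̂) = σ_β̂² + σ_δ̂² + 2·cov(β̂, δ̂)`. Meta-analysis
output carries the correlation `r` between the two estimates rather than
their covariance, so the converter forms `cov = r·σ_β̂·σ_δ̂`; when a file
carries a covariance column instead, it is used directly. For
`r ∈ [−1, 1]` the variance expression is a completed square
(`(σ_β̂ + r σ_δ̂)² + (1−r²)σ_δ̂² ≥ 0`), so the derived SE is always real; a
negative value can only arise from a corrupt explicit covariance and is
reported as a computation error naming the variant.

Averaging the two stratum regressions with weights `1−μ_E` and `μ_E`
(`μ_E = N_e/N`, the exposure frequency) gives the marginal model's genetic
effect, `β̂_marg = β̂ + δ̂·μ_E`, with
`σ_marg² = σ_β̂² + μ_E²σ_δ̂² + 2μ_E·cov(β̂, δ̂)`. Unlike the stratified
identities this step assumes genotype–exposure independence
(`E[G|E=0] = E[G|E=1]`); the bias studies below quantify what happens when
it fails. `μ_E ∈ {0, 1}` is rejected as a degenerate design (one stratum
is empty and the marginal model coincides with the other stratum); the
conversion is continuous in `μ_E`, approaching the unexposed (exposed)
statistics as `μ_E → 0` (`→ 1`), which the tests check at ε = 1e−8.

Wald statistics use the standard-normal reference (`z = β̂/σ̂`, two-sided
p), appropriate for the large-`N` meta-analysis setting where residual
degrees of freedom are unavailable; p-values are clamped into (0, 1] at
the smallest positive double. A zero or missing SE yields missing (NA) z
and p while the effect estimate is kept.

## Sample-size inference and filtering

Per-variant genotyping missingness means each variant's sample size `N_v`
can be below `N`. Stratum sizes are inferred proportionally:
`n_exp = N_v·(N_e/N)` and `n_unexp = N_v − n_exp`, reported as unrounded
reals (they are expectations under exposure-balanced missingness; the
subtraction form makes the two sum back to `N_v` exactly for the
integer-valued sizes meta-analysis files carry). When missingness is
*not* exposure-balanced, the study-wide `μ_E` misrepresents the variant's
genotyped subsample; variants with `N_v` below the 0.9-quantile of the
`N_v` distribution divided by 1.5 are therefore flagged and, by default,
excluded. The quantile uses linear interpolation between order statistics
(the numpy default convention), verified in the tests against a
brute-force sort-based oracle. Filtering is a flag: the writer drops
flagged rows by default, `--keep-filtered` retains them, `--no-filter`
disables the rule.

## Input handling

Input is tab-delimited with a header (gzip transparent). Default column
names follow the METAL interaction-output lineage
(`MarkerName, Effect, StdErr, IntEffect, IntStdErr, IntCor, N`) and every
role is remappable (`--col role=NAME`), since consortium files vary.
Rows with a missing or non-positive `N_v` cannot be sized or filtered and
are dropped with a count ("hard-invalid"); rows with missing or
out-of-range effect fields (|r| > 1, negative SE) are written with NA
statistics and counted rather than silently dropped, since meta-analysis
outputs routinely contain partial rows. Duplicate variant ids are
processed row-wise; the method is row-local. Numbers are serialized with
6 significant digits; two runs on the same input are byte-identical.

## Simulation study

`simulate_replicate` draws, per replicate: MAF ~ U(0.01, 0.5), genotypes
`G ~ Binomial(2, MAF)`; exposure probability p ~ U(0.1, 0.5),
`E ~ Bernoulli(p)`; effect magnitudes |β_G|, |β_E|, |β_GE| ~ U(0.05, 0.2)
with equiprobable random signs; and a quantitative trait
`Y = β_G·G + β_E·E + β_GE·G×E + ε`, `ε ~ N(0, σ²)` with σ = 1 by default
(so effects are small fractions of phenotypic variance, as in typical
GWAS; no other value is implied by the design). Binary traits draw
`Y ~ Bernoulli(logistic(α + β_G·G + β_E·E + β_GE·G×E + ε))` with the
conventional negative sign in the logistic exponent; a `logit_sign`
option flips it, which only mirrors all effect signs and leaves every
agreement metric unchanged. Randomness is keyed by
`SeedSequence([scenario_seed, replicate_index])`, so identical scenarios
give bit-identical reports and replicates are independent.

Per replicate, the "true" statistics are regressions on the
individual-level data — stratified (Y on G within E = 0 and within E = 1)
and marginal (Y on G and E) — and the "estimated" statistics come from
applying the closed-form converter to the joint interaction fit of the
same data. Linear fits use closed-form OLS (normal-equation solve with
covariance s²(XᵀX)⁻¹; the design matrices have 2–4 well-conditioned
columns), cross-checked against statsmodels OLS in the tests; logistic
fits use statsmodels. Replicates with an empty stratum or a constant
genotype in a stratum cannot be fitted and are skipped and counted.

Agreement is the intraclass correlation coefficient, two-way
random-effects, absolute agreement, single measurement (ICC(2,1)):
"absolute agreement" penalizes systematic shifts between the true and
estimated statistics, which consistency-type ICCs would forgive. It is
computed for Wald statistics, effect sizes and SEs separately, since
different bias mechanisms hit different quantities.

### Study scales

The headline accuracy study uses 1000 replicates of 10,000 individuals
(10,000 replicates for the binary-trait variant). The bias and null
studies use 50,000 individuals × 10,000 replicates as scenario defaults;
the packaged tests and the acceptance script run them at reduced scale —
600 replicates of 10,000 individuals for the bias quintile checks, 2,000
replicates of 5,000 for type-I-error calibration, 1,500 of 4,000 for the
heteroscedastic null — chosen so the full validation completes in minutes
on one core while keeping Monte-Carlo error far below the effect sizes
being detected (a binomial 99% band at 2,000 replicates is ±1.3 percentage
points around 5%, versus observed departures of ±4 points under
heteroscedasticity).

### Bias mechanisms

Bias knobs are upper bounds of per-replicate uniform draws, giving each
study a spread of bias magnitudes to stratify into quintiles:

* **G–E correlation** (`ge_corr`, default cap 0.25): the exposure is drawn
  conditionally on genotype, `E | G ~ Bernoulli(logistic(a + b·G))`, with
  `(a, b)` solved by 2-d root-finding on the exact three-atom genotype
  expectations so that the exposure frequency and the point-biserial
  corr(G, E) hit their targets; the target correlation is capped at 80% of
  the Fréchet (comonotone-coupling) maximum for the drawn marginals, which
  a small MAF can make binding. Result: stratified ICCs stay ≈ 1 (the
  stratified identities never used independence), the marginal ICC decays
  with the correlation quintile.
* **Misspecified exposure proportion**: per replicate a retained fraction
  ~ U(0.5, 1) of individuals is kept and an additional fraction
  ~ U(0, 0.5) of retained *exposed* individuals is removed; all models are
  fitted on the subsample while the converter is fed the full-cohort
  `μ_E`, mimicking exposure-imbalanced genotype missingness. The bias
  magnitude is `|μ_E − m_E| / μ_E` with `m_E` the subsample exposure mean.
  Only the marginal analysis degrades, monotonically in the quintile —
  which is exactly why the relative-sample-size filter exists.
* **Heteroscedasticity** (`exposed_extra_noise_sd`, default cap 1.0; 1.5
  in tests to make the mechanism plainly visible at reduced replicate
  counts): extra noise ~ N(0, s²), s ~ U(0, cap), is added to exposed
  individuals' phenotypes. Effect estimates stay unbiased, but the joint
  fit's single pooled residual variance lies between the two stratum
  variances, so the derived SE *underestimates* the truth in the
  higher-variance stratum (inflating its Wald statistics and null
  rejection rate) and *overestimates* it in the lower-variance stratum
  (deflating them), with |error| growing across variance-gap quintiles.
  The direction follows from the pooled-variance algebra and is confirmed
  numerically; the marginal analysis is essentially unaffected (its
  implicit weighting matches the marginal fit's own pooled variance).

The null study (β_G = β_GE = 0, β_E still active) reports empirical
rejection rates at α = 0.05 for true and estimated statistics per
analysis, and the proportion of replicates significant under a
Bonferroni-adjusted threshold (α divided by the number of replicates,
mirroring a per-SNP screening correction) with exactly one of the two
methods.

## What the simulations do and do not show

The generator emulates a single-SNP, single-cohort screen with a clean
binary exposure: Hardy–Weinberg genotypes, no linkage disequilibrium, no
covariates or population structure, no meta-analytic heterogeneity between
cohorts, exposure measured without error. Passing validation therefore
shows the *conversion* is faithful to what a stratified analysis of the
same data would give — it does not certify the joint model itself against
confounding, nor cover biases (e.g. cross-cohort exposure-frequency
differences) that never enter the generator. Real-consortium validation
against individual-level lipid screens is outside this package's scope
(the underlying data are not public).

## Known limitations

* The marginal derivation degrades with genotype–exposure dependence;
  the dependence cannot be detected from joint summary statistics alone,
  so affected variants must be identified from external sources.
* The converter is scale-agnostic: for binary traits it operates on the
  log-odds scale of the reported coefficients and does not attempt a
  logistic refit.
* The SE formulas trust the reported `r`; files that round it coarsely
  propagate that rounding into `σ_exp` and `σ_marg`.
* Stratum sample sizes are expectations under proportional missingness,
  not genotype counts.
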