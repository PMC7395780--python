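# Methods

This note records the statistical models the package implements, the
defaults and numerical choices behind them, what the synthetic-data
generator does and does not emulate, and the design decisions that were
genuinely open.

## Harmonization

Outcome records are oriented onto the exposure's effect allele per SNP:
identical allele pairs are copied, swapped pairs negate the outcome beta and
mirror its effect-allele frequency (EAF), and strand complements are
complemented before either rule applies. Pairs that match none of these are
dropped as allele mismatches — never silently kept — and every input SNP
ends up either retained or dropped-with-reason, so the two sets partition
the input. Palindromic variants (A/T, C/G) cannot be strand-resolved from
alleles; the default policy orients them by EAF agreement and drops them
when either study's EAF lies in [0.42, 0.58] (the common two-sample MR
default window; configurable) or is missing. Duplicated rsIDs keep the
first occurrence (instrument selection has already collapsed duplicates to
the smallest p-value). No liftover, variant normalization, or proxy lookup
is attempted, and LD clumping is out of scope: inputs are declared
pre-pruned, which the CLI's `--assume-independent` flag acknowledges.

## Estimators

All estimators work on the additive scale (log-odds for binary outcomes);
odds ratios appear only in the reporting layer. Confidence intervals use
the normal 97.5% quantile 1.959964 throughout (summary-data convention; a t
quantile is not used because the weights are estimated, not sampled).

* **IVW** — precision-weighted mean of the Wald ratios with first-order
  weights. The default variance model is multiplicative random effects:
  the fixed-effect SE is inflated by `max(1, sqrt(Q/(k-1)))`, so
  homogeneous data fall back to the fixed-effect SE exactly. A single SNP
  degenerates to its Wald ratio.
* **MR-Egger** — weighted least squares of outcome on exposure betas with
  an intercept, weights 1/se²(β̂_ZY), rows oriented to non-negative
  exposure betas first. The residual variance in the coefficient
  covariance is floored at 1 for the same homogeneous-fallback reason. The
  intercept's two-sided test against zero is the formal directional
  pleiotropy test.
* **SIMEX-Egger** — measurement error in the exposure betas attenuates the
  Egger slope toward the null (diagnosed by I²_GX; values below 0.9 merit
  correction). For each inflation factor λ ∈ {0, 0.5, 1, 1.5, 2} (default)
  the exposure betas are perturbed with additive noise of variance
  λ·se²(β̂_ZX) over 1000 simulations (default), per-λ mean slope and
  intercept are fit by a quadratic in λ, and the fit is extrapolated to
  λ = −1 (zero measurement error). Standard errors come from a delete-one
  jackknife over the simulation draws and are flagged approximate: they
  capture simulation noise around the extrapolation, not full sampling
  uncertainty. With all exposure SEs zero the correction is the identity
  and the naive fit is returned directly.
* **Weighted median** — interpolates the inverse-variance-weighted
  cumulative distribution of sorted ratios at 50% (cumulative weight
  s_j = Σ_{i≤j} w_i − w_j/2). SE by parametric bootstrap: betas redrawn
  from N(observed, se), ratio weights recomputed per draw; `n_boot = 0`
  skips the bootstrap when only point estimates are needed.
* **Weighted mode** — argmax over a 512-point grid (spanning the ratio
  range ± 3 bandwidths) of a weighted normal-kernel density with plug-in
  bandwidth `0.9·min(sd, mad/0.6745)·k^(−1/5)` scaled by a bandwidth
  factor (default 1). When the median absolute deviation is zero but the
  ratios are not constant (a majority cluster plus outliers), the sd branch
  is used so the bandwidth stays positive; fully constant ratios return the
  common value. SE by the same parametric bootstrap.

All bootstrap and SIMEX draws take explicit integer seeds (default 0), so
every stochastic output is reproducible.

## Diagnostics

Cochran's Q uses the first-order weights about the IVW estimate and is
referred to chi-square(k−1). The radial outlier screen regresses
ratio·√w on √w through the origin (whose slope is the IVW estimate),
refers each SNP's contribution Q_j = w_j(r_j − slope)² to chi-square(1),
and flags SNPs below the chosen per-SNP level in a single pass; it refuses
to flag every SNP. I²_GX is computed from the exposure-side Q statistic
with weights 1/se²(β̂_ZX) on the Egger-oriented (absolute) betas, clipped
to [0, 1]. The F-statistic uses `F = R²(n − k − 1)/((1 − R²)k)` with R²
supplied by the user (recomputing R² needs individual-level genotypes,
which are out of scope); F < 10 raises the conventional weak-instrument
flag.

## Mediation

The difference method on the log-odds scale: total from univariable IVW,
direct from multivariable IVW (no-intercept WLS of outcome betas on the
exposure and mediator beta columns, weights 1/se²(β̂_ZY), residual variance
floored at 1, one mediator at a time), indirect = total − direct, and
proportion mediated PM = 1 − direct/total. The delta-method variance of
direct/total is `var_D/t² + d²·var_T/t⁴ − 2d·cov/t³`. Because total and
direct are estimated from overlapping instruments their covariance is
positive but unknown from summary output alone; by default it is set to 0
(with a logged warning), and a seeded SNP-resampling bootstrap
(`cov_bootstrap`) can estimate it. PM is reported unclipped — values
outside [0, 100]% are meaningful and shown.

One design choice deserves emphasis. The univariable analyses screen
radial outliers before estimation, and only surviving SNPs enter the
multivariable fit. In the mediation pipeline this screen defaults to a
*Bonferroni* per-SNP level (0.05/k) rather than the 0.05 used for general
diagnostics. Simulation showed why: per-SNP screening at 0.05 removes a
non-trivial fraction of SNPs selected on the very residual the
multivariable fit regresses on (the mediator-specific effect plus outcome
noise), which truncates the mediator's independent variation, couples the
retained mediator effects to the outcome noise, and biases the direct
effect — by enough to distort the proportion mediated substantially when
mediation is strong. Restricting the screen to gross outliers removes the
artifact while preserving its purpose.

A degenerate all-zero mediator column is dropped from the design, in which
case the "direct" effect equals univariable IVW exactly; genuinely
collinear exposure/mediator columns (weighted design condition number above
1e8) raise an error naming the collinearity.

## Power

For a binary outcome with n participants, case fraction K, instruments
explaining R² of the exposure, and alternative odds ratio OR:

    power = Φ( √(n·R²·K(1−K)) · |ln OR| − z_{1−α/2} ).

This is the standard normal-approximation non-centrality argument: the
effective sample size of a log-odds coefficient scales with K(1−K). Power
is monotone in n, R², and |ln OR|, symmetric under OR ↔ 1/OR, and tends to
α/2 as OR → 1. The test suite cross-checks the formula against a
Monte-Carlo Wald-test rejection rate. At the T2D design (n = 149,821,
K = 0.2326, R² = 0.003) the formula gives 89% power at OR 0.7, consistent
with the ≥ 80% design requirement down to OR 0.3 by monotonicity.

## Synthetic data

`simulate_two_sample` draws true SNP-exposure effects γ_j ~ N(mean, sd),
derives sampling SEs from the standard GWAS approximation
`se ≈ 1/√(2·n·maf(1−maf))` with minor allele frequencies uniform on the
configured range, and for binary outcomes divides the effective sample
size by K(1−K) so log-odds SEs have realistic scale. Observed exposure
betas add N(0, se_x) noise; true outcome effects are θ·γ_j plus a per-SNP
pleiotropic effect α_j on the configured invalid fraction, observed with
N(0, se_y) noise. Pleiotropy scenarios: none, balanced (mean-zero α),
directional (non-zero mean, independent of γ — InSiDE holds), and
InSiDE-violating (α correlated with γ at a configurable correlation).
Alleles are assigned randomly from non-palindromic pairs (palindromic pairs
optionally, for harmonization tests), and a configurable fraction of
outcome rows is emitted allele-swapped so harmonization is always
exercised. Defaults mirror the schooling design: a ~294k exposure GWAS and
effects of ~0.02 SD give per-SNP F around 50.

`simulate_mediation` adds a mediator with true effects δ·γ_j + κ_j, where
κ_j ~ N(0, κ_sd²) is the mediator-specific genetic component that makes
the multivariable fit identifiable; outcome effects are
θ_direct·γ_j + τ·(δγ_j + κ_j), so θ_total = θ_direct + δτ and the implied
proportion mediated is δτ/θ_total, recorded in the truth block. Defaults
(γ ~ 0.03 ± 0.02, κ_sd = 0.015, τ = 0.3, mediator GWAS of 500k, T2D-like
outcome with K = 0.23) keep instruments strong (per-SNP F in the hundreds)
so multivariable regression-dilution bias is negligible, and keep the
mediator-channel heterogeneity mild relative to outcome sampling error —
matching a study whose Q statistics show no evidence of heterogeneity.
Recovery tests that span PM from 0.1 to 0.9 hold τ fixed and vary the
exposure→mediator path δ, which keeps the pleiotropy footprint constant
across the grid.

What the generator does **not** emulate: LD between instruments (they are
independent by construction, as after pruning), winner's curse from
selecting instruments in the same sample that estimated them, sample
overlap between exposure and outcome GWAS, allele-frequency differences
between ancestries, and individual-level binary-trait sampling (log-odds
effects are drawn directly). Passing calibration tests therefore
demonstrates correctness of the estimators under the stated two-sample
assumptions, not robustness to those unmodeled features of real data.

## Numerical choices and degenerate inputs

Residual variances in Egger and multivariable fits are floored at 1, never
shrunk, so under-dispersed data keep fixed-effect uncertainty. Zero
exposure betas are excluded from ratio-based estimators with a warning
(undefined ratio). The weighted-mode grid is 512 points by default
(configurable); its argmax agrees with a 10× finer grid to within grid
spacing. SIMEX λ grids always include 0 (the naive fit). Identical-SNP
degeneracies fall back to the common ratio with a note. Bootstrap draws
that produce a zero exposure beta are nudged to the smallest positive
float rather than dropped, keeping draw counts fixed.

## Known limitations

Egger SEs use normal quantiles, not t. The SIMEX jackknife SE understates
total uncertainty (it is labelled approximate in the result). The
zero-covariance delta method for the proportion mediated is not
conservative in every configuration — when cov(total, direct) > 0 it
overstates the variance of direct/total, but the bootstrap option should
be preferred when interval width matters. F-statistics depend entirely on
the user-supplied R² and sample size. No MR-PRESSO, Steiger filtering,
bidirectional MR, leave-one-out analysis, or Rucker model selection is
implemented.
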