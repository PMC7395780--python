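# summr

Two-sample Mendelian randomization (MR) from GWAS summary statistics, built
around the question of whether more years of schooling causally protect
against type 2 diabetes (T2D) and its risk factors. The package covers the
full inferential pipeline such a study needs: harmonization of
summary-statistic tables, the inverse-variance-weighted (IVW) estimator and
its pleiotropy-robust companions (MR-Egger with SIMEX dilution correction,
weighted median, weighted mode), heterogeneity and radial outlier
diagnostics, multivariable-MR mediation with delta-method intervals,
binary-outcome power analysis, and a synthetic summary-statistics generator
with known ground truth so every stage is testable without any data
download.

## The model

Two-sample MR treats genetic variants as instruments for a modifiable
exposure. For SNP *j*, let β̂<sub>ZX,j</sub> be its estimated effect on the
exposure (from GWAS sample 1) and β̂<sub>ZY,j</sub> its effect on the
outcome (from GWAS sample 2). Each SNP yields a Wald ratio

    β̂_XY,j = β̂_ZY,j / β̂_ZX,j,     se(β̂_XY,j) = se(β̂_ZY,j) / |β̂_ZX,j|

and the IVW estimate is their precision-weighted average with first-order
weights w<sub>j</sub> = β̂²<sub>ZX,j</sub>/se²(β̂<sub>ZY,j</sub>) —
algebraically, weighted least squares of β̂<sub>ZY</sub> on β̂<sub>ZX</sub>
through the origin. IVW is unbiased only when every instrument acts on the
outcome exclusively through the exposure; the sensitivity estimators relax
that exclusion restriction in different directions (Egger permits a
directional pleiotropic intercept under InSiDE, the weighted median
tolerates up to half invalid weight, the weighted mode trusts the largest
homogeneous ratio cluster). Mediation uses the difference method on the
log-odds scale: total effect from univariable IVW, direct effect from
multivariable MR conditioning on the mediator, indirect = total − direct,
proportion mediated = indirect/total with a delta-method standard error.

## Worked example

A fully synthetic study shaped like the schooling→T2D test (17 instruments,
exposure variance explained ≈ 0.003, true OR 0.39):

```python
import summr

cfg = summr.published_test_config("t2d", seed=7)
study = summr.simulate_two_sample(cfg)
hs = summr.harmonize(study.exposure, study.outcome)
hs = summr.radial_outliers(hs, alpha=0.05 / hs.n_snp).kept
for res in summr.all_estimators(hs, n_boot=500, seed=0, simex=False):
    orr, lo, hi = res.odds_ratio()
    print(f"{res.method:>14}  OR {orr:0.2f} (95% CI {lo:0.2f}, {hi:0.2f})  p={res.pval:0.2g}")
```

prints

```
           IVW  OR 0.42 (95% CI 0.33, 0.55)  p=5.8e-11
         Egger  OR 0.51 (95% CI 0.19, 1.36)  p=0.18
WeightedMedian  OR 0.38 (95% CI 0.27, 0.55)  p=2.7e-07
  WeightedMode  OR 0.29 (95% CI 0.15, 0.54)  p=0.00011
```

All four estimators agree in direction and magnitude with the generating
OR of 0.39, which is the triangulation argument the pipeline is built for:
estimators with different pleiotropy assumptions telling the same story.
The accompanying diagnostics for this run — Egger intercept −0.0035
(p = 0.70), Cochran's Q = 10.2 on 16 df (p = 0.86), I²<sub>GX</sub> = 64% —
show no directional pleiotropy and no heterogeneity, with enough
exposure-side measurement error that the Egger slope would merit a SIMEX
check (`summr.simex_egger`). The same battery is available from the shell:

```sh
summr simulate --k 50 --theta 0.4 --seed 3 --outdir data/
summr mr --exposure data/exposure.tsv --outcome data/outcome.tsv \
         --assume-independent --out-prefix results/mr --plots
summr power --n-outcome 149821 --cases 34840 --r2 0.003 --out power.csv
```

Inputs are assumed already pruned for linkage disequilibrium
(`--assume-independent` acknowledges this); no reference-panel clumping is
performed.

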