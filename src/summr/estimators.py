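"""Causal-effect estimators for two-sample MR: Wald ratios, IVW, MR-Egger
(with SIMEX dilution correction), weighted median, and weighted mode.

All estimators consume a :class:`~summr.sumstats.HarmonizedSet` of aligned
SNP-exposure effects (beta_ZX) and SNP-outcome effects (beta_ZY) and work on
the additive scale throughout (log-odds for binary outcomes); exponentiation
to odds ratios happens only in the reporting layer.  Per-SNP causal estimates
are Wald ratios beta_ZY / beta_ZX with first-order standard errors
se(beta_ZY) / |beta_ZX|; the inverse-variance-weighted (IVW) estimate is
their precision-weighted average, algebraically identical to a weighted
least-squares fit of beta_ZY on beta_ZX through the origin.

The sensitivity estimators relax the exclusion restriction in different ways:
MR-Egger allows a directional pleiotropic intercept under InSiDE; the
weighted median is consistent when at least half the weight comes from valid
instruments; the weighted mode is consistent when the largest homogeneous
cluster of ratios is valid.  The SIMEX variant of Egger corrects the slope
and intercept for regression dilution caused by measurement error in the
SNP-exposure effects (diagnosed by I2_GX).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diagnostics import cochran_q, isq_gx
from .sumstats import HarmonizedSet, NoInstrumentsError

log = logging.getLogger(__name__)

#: 97.5% normal quantile used for all 95% confidence intervals.
Z95 = 1.959964

DEFAULT_SIMEX_LAMBDAS = (0.0, 0.5, 1.0, 1.5, 2.0)


@dataclass
class MRResult:
    """One estimator's output on the additive (log-odds / SD) scale."""

    method: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snp: int
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_pval: float | None = None
    q: float | None = None
    q_df: int | None = None
    q_pval: float | None = None
    i2_gx: float | None = None
    note: str | None = None

    def odds_ratio(self) -> tuple[float, float, float]:
        """(OR, CI low, CI high) for binary outcomes."""
        return (float(np.exp(self.estimate)), float(np.exp(self.ci_low)),
                float(np.exp(self.ci_high)))


def _skipped(method: str, n_snp: int, reason: str) -> MRResult:
    log.warning("%s skipped: %s", method, reason)
    return MRResult(method=method, estimate=np.nan, se=np.nan, ci_low=np.nan,
                    ci_high=np.nan, pval=np.nan, n_snp=n_snp, note=reason)


def _finish(method: str, estimate: float, se: float, n_snp: int, **kw) -> MRResult:
    z = estimate / se if se > 0 else np.nan
    return MRResult(
        method=method, estimate=float(estimate), se=float(se),
        ci_low=float(estimate - Z95 * se), ci_high=float(estimate + Z95 * se),
        pval=float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else np.nan,
        n_snp=n_snp, **kw)


def _arrays(hs: HarmonizedSet):
    tab = hs.table
    return (tab["beta_exposure"].to_numpy(float),
            tab["se_exposure"].to_numpy(float),
            tab["beta_outcome"].to_numpy(float),
            tab["se_outcome"].to_numpy(float))


def wald_ratios(hs: HarmonizedSet) -> pd.DataFrame:
    """Per-SNP Wald ratios beta_ZY/beta_ZX with first-order SEs se_ZY/|beta_ZX|.

    SNPs with beta_exposure exactly zero have an undefined ratio and are
    excluded with a warning.
    """
    bx, _, by, sey = _arrays(hs)
    keep = bx != 0
    if not keep.all():
        for snp in hs.table.loc[~keep, "snp_id"]:
            log.warning("wald_ratios: %s excluded (beta_exposure = 0)", snp)
    return pd.DataFrame({
        "snp_id": hs.table.loc[keep, "snp_id"].to_numpy(),
        "ratio": by[keep] / bx[keep],
        "ratio_se": sey[keep] / np.abs(bx[keep]),
    })


def _drop_zero_bx(hs: HarmonizedSet) -> HarmonizedSet:
    bx = hs.table["beta_exposure"].to_numpy(float)
    if np.any(bx == 0):
        return hs.subset(bx != 0, reason="beta_exposure = 0")
    return hs


def ivw(hs: HarmonizedSet, variance_model: str = "multiplicative_random") -> MRResult:
    """Inverse-variance-weighted meta-analysis of the Wald ratios.

    First-order weights ``w_j = beta_ZX_j^2 / se_ZY_j^2``.  Under the default
    multiplicative random-effects model the fixed-effect SE is inflated by
    ``max(1, sqrt(Q/(k-1)))``, so homogeneous data fall back to the
    fixed-effect SE.  A single SNP degenerates to its Wald ratio.
    """
    if variance_model not in ("fixed", "multiplicative_random"):
        raise ValueError("variance_model must be 'fixed' or 'multiplicative_random'")
    hs = _drop_zero_bx(hs)
    k = hs.n_snp
    if k == 0:
        raise NoInstrumentsError("IVW requires at least one SNP")
    bx, _, by, sey = _arrays(hs)
    r = by / bx
    w = bx**2 / sey**2
    estimate = float((w * r).sum() / w.sum())
    se_fixed = float(w.sum() ** -0.5)
    if k == 1:
        return _finish("WaldSingle", estimate, se_fixed, 1)
    qs = cochran_q(hs, estimate)
    scale = 1.0
    if variance_model == "multiplicative_random":
        scale = max(1.0, np.sqrt(qs.q / qs.df))
    return _finish("IVW", estimate, se_fixed * scale, k,
                   q=qs.q, q_df=qs.df, q_pval=qs.pval)


def _wls_line(x: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Weighted least squares of y on x with intercept.

    Returns (slope, intercept, var_slope, var_intercept) with the residual
    variance floored at 1 (multiplicative random effects)."""
    W = w.sum()
    xb = (w * x).sum() / W
    yb = (w * y).sum() / W
    dx = x - xb
    sxx = (w * dx**2).sum()
    slope = (w * dx * (y - yb)).sum() / sxx
    intercept = yb - slope * xb
    resid = y - intercept - slope * x
    phi = max(1.0, (w * resid**2).sum() / (len(x) - 2))
    return slope, intercept, phi / sxx, phi * (1.0 / W + xb**2 / sxx)


def _wls_line_many(X: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Vectorized WLS with intercept for many x-columns sharing y and w.

    ``X`` has shape (k, m); returns slope and intercept arrays of length m."""
    W = w.sum()
    xb = (w[:, None] * X).sum(axis=0) / W
    yb = (w * y).sum() / W
    dx = X - xb
    sxx = (w[:, None] * dx**2).sum(axis=0)
    sxy = (w[:, None] * dx * (y[:, None] - yb)).sum(axis=0)
    slope = sxy / sxx
    return slope, yb - slope * xb


def _oriented(hs: HarmonizedSet):
    """Orient rows so beta_exposure >= 0 (joint sign flip), as Egger requires."""
    bx, sex, by, sey = _arrays(hs)
    s = np.where(bx < 0, -1.0, 1.0)
    return bx * s, sex, by * s, sey


def egger(hs: HarmonizedSet) -> MRResult:
    """MR-Egger: WLS of beta_ZY on beta_ZX with an intercept, weights 1/se_ZY^2.

    The slope estimates the causal effect under InSiDE; the intercept
    estimates the average directional pleiotropic effect, and its two-sided
    test against zero is the formal test for directional pleiotropy.  Rows
    are oriented to non-negative beta_exposure before fitting.
    """
    if hs.n_snp < 3:
        return _skipped("Egger", hs.n_snp, "MR-Egger needs at least 3 SNPs")
    x, sex, y, sey = _oriented(hs)
    w = 1.0 / sey**2
    slope, intercept, var_slope, var_int = _wls_line(x, y, w)
    se_int = np.sqrt(var_int)
    i2 = None
    if np.all(np.isfinite(sex)) and np.all(sex > 0):
        i2 = isq_gx(hs)
    res = _finish("Egger", slope, np.sqrt(var_slope), hs.n_snp, i2_gx=i2)
    res.intercept = float(intercept)
    res.intercept_se = float(se_int)
    res.intercept_pval = float(2 * stats.norm.sf(abs(intercept / se_int)))
    return res


def simex_egger(
    hs: HarmonizedSet,
    lambdas: Sequence[float] = DEFAULT_SIMEX_LAMBDAS,
    n_sim: int = 1000,
    seed: int = 0,
) -> MRResult:
    """Simulation-extrapolation correction of MR-Egger for regression dilution.

    Measurement error in beta_ZX attenuates the Egger slope toward the null
    (diagnosed by I2_GX < 0.9).  SIMEX re-fits Egger after inflating that
    error by each factor ``lambda`` (added noise variance lambda * se_ZX^2),
    models the mean slope/intercept as a quadratic in lambda, and
    extrapolates to lambda = -1 (zero measurement error).  Standard errors
    come from a delete-one jackknife over the simulation draws and should be
    treated as approximate.
    """
    if hs.n_snp < 3:
        return _skipped("EggerSIMEX", hs.n_snp, "SIMEX-Egger needs at least 3 SNPs")
    sex = hs.table["se_exposure"].to_numpy(float)
    if np.any(~np.isfinite(sex)):
        raise ValueError("SIMEX requires se_exposure for every SNP")
    lambdas = np.asarray(sorted(set(float(l) for l in lambdas) | {0.0}))
    if np.any(lambdas < 0):
        raise ValueError("lambdas must be non-negative")
    naive = egger(hs)
    if np.all(sex == 0):
        return replace(naive, method="EggerSIMEX",
                       note="no exposure measurement error; correction is the identity")

    x, sex, y, sey = _oriented(hs)
    w = 1.0 / sey**2
    rng = np.random.default_rng(seed)
    pos = lambdas[lambdas > 0]
    slope_sims = np.empty((len(pos), n_sim))
    int_sims = np.empty((len(pos), n_sim))
    for i, lam in enumerate(pos):
        eps = rng.standard_normal((len(x), n_sim))
        X = x[:, None] + np.sqrt(lam) * sex[:, None] * eps
        slope_sims[i], int_sims[i] = _wls_line_many(X, y, w)

    def _extrapolate(sims: np.ndarray, at_zero: float):
        means = np.concatenate([[at_zero], sims.mean(axis=1)])
        coef = np.polyfit(lambdas, means, 2)
        point = float(np.polyval(coef, -1.0))
        # Jackknife over simulation draws: leave-one-out per-lambda means.
        loo = (sims.sum(axis=1, keepdims=True) - sims) / (n_sim - 1)
        Y = np.vstack([np.full(n_sim, at_zero), loo])
        coefs = np.polyfit(lambdas, Y, 2)
        theta = np.polynomial.polynomial.polyval(-1.0, coefs[::-1])
        var = (n_sim - 1) / n_sim * ((theta - theta.mean()) ** 2).sum()
        return point, float(np.sqrt(var))

    slope, slope_se = _extrapolate(slope_sims, naive.estimate)
    intercept, int_se = _extrapolate(int_sims, naive.intercept)
    res = _finish("EggerSIMEX", slope, slope_se, hs.n_snp, i2_gx=naive.i2_gx,
                  note="SE from jackknife over SIMEX draws (approximate)")
    res.intercept = intercept
    res.intercept_se = int_se
    res.intercept_pval = float(2 * stats.norm.sf(abs(intercept / int_se))) \
        if int_se > 0 else np.nan
    return res


def _weighted_median_point(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values)
    v = values[order]
    w = weights[order] / weights.sum()
    s = np.cumsum(w) - 0.5 * w
    return float(np.interp(0.5, s, v))


def _ratio_bootstrap(hs: HarmonizedSet, n_boot: int, seed: int, point_fn) -> float:
    """Parametric bootstrap SE: redraw betas from N(observed, se), re-estimate."""
    bx, sex, by, sey = _arrays(hs)
    sex = np.nan_to_num(sex)
    rng = np.random.default_rng(seed)
    ests = np.empty(n_boot)
    for b in range(n_boot):
        bxs = rng.normal(bx, sex)
        bys = rng.normal(by, sey)
        bxs[bxs == 0] = np.finfo(float).tiny
        r = bys / bxs
        w = bxs**2 / sey**2
        ests[b] = point_fn(r, w)
    return float(ests.std(ddof=1))


def weighted_median(hs: HarmonizedSet, n_boot: int = 1000, seed: int = 0) -> MRResult:
    """Weighted median of the Wald ratios (consistent if >= 50% of weight is valid).

    The estimate interpolates the inverse-variance-weighted cumulative
    distribution of sorted ratios at 50%; the SE is the spread of the
    estimate over ``n_boot`` parametric bootstrap draws (``n_boot = 0`` skips
    the bootstrap and returns only the point estimate).
    """
    hs = _drop_zero_bx(hs)
    if hs.n_snp < 3:
        return _skipped("WeightedMedian", hs.n_snp, "weighted median needs at least 3 SNPs")
    bx, _, by, sey = _arrays(hs)
    r = by / bx
    w = bx**2 / sey**2
    estimate = _weighted_median_point(r, w)
    note = None
    if np.allclose(r, r[0]):
        note = "all ratios identical; zero bootstrap spread"
    if n_boot <= 0:
        return _finish("WeightedMedian", estimate, np.nan, hs.n_snp, note=note)
    se = _ratio_bootstrap(hs, n_boot, seed, _weighted_median_point)
    return _finish("WeightedMedian", estimate, se, hs.n_snp, note=note)


def _weighted_mode_point(bandwidth_factor: float, grid_size: int):
    def point(values: np.ndarray, weights: np.ndarray) -> float:
        k = len(values)
        sd = values.std(ddof=1)
        mad = np.median(np.abs(values - np.median(values))) / 0.6745
        spreads = [s for s in (sd, mad) if s > 0]
        if not spreads:
            return float(values[0])
        h = bandwidth_factor * 0.9 * min(spreads) * k ** (-1 / 5)
        grid = np.linspace(values.min() - 3 * h, values.max() + 3 * h, grid_size)
        dens = (weights[:, None] * np.exp(-0.5 * ((grid[None, :] - values[:, None]) / h) ** 2)).sum(axis=0)
        return float(grid[np.argmax(dens)])
    return point


def weighted_mode(hs: HarmonizedSet, bandwidth_factor: float = 1.0,
                  n_boot: int = 1000, seed: int = 0,
                  grid_size: int = 512) -> MRResult:
    """Weighted mode of the Wald ratios (consistent if the largest homogeneous
    cluster of ratios is valid).

    The mode is the argmax over a dense grid of a weighted normal-kernel
    density of the ratios; the plug-in bandwidth is
    ``bandwidth_factor * 0.9 * min(sd, mad/0.6745) * k^(-1/5)`` (whichever
    spread measure is positive).  SE by parametric bootstrap as for the
    weighted median.
    """
    if bandwidth_factor <= 0:
        raise ValueError("bandwidth_factor must be positive")
    hs = _drop_zero_bx(hs)
    if hs.n_snp < 3:
        return _skipped("WeightedMode", hs.n_snp, "weighted mode needs at least 3 SNPs")
    bx, _, by, sey = _arrays(hs)
    r = by / bx
    w = bx**2 / sey**2
    point_fn = _weighted_mode_point(bandwidth_factor, grid_size)
    estimate = point_fn(r, w)
    note = None
    if np.allclose(r, r[0]):
        note = "all ratios identical; bandwidth degenerate"
    if n_boot <= 0:
        return _finish("WeightedMode", estimate, np.nan, hs.n_snp, note=note)
    se = _ratio_bootstrap(hs, n_boot, seed, point_fn)
    return _finish("WeightedMode", estimate, se, hs.n_snp, note=note)


def all_estimators(hs: HarmonizedSet, n_boot: int = 1000, seed: int = 0,
                   simex: bool = True, n_sim: int = 1000) -> list[MRResult]:
    """Run the full estimator battery (IVW, Egger, SIMEX-Egger, median, mode)."""
    results = [ivw(hs), egger(hs)]
    if simex:
        sex = hs.table["se_exposure"].to_numpy(float)
        if hs.n_snp >= 3 and np.all(np.isfinite(sex)):
            results.append(simex_egger(hs, n_sim=n_sim, seed=seed))
    results.append(weighted_median(hs, n_boot=n_boot, seed=seed))
    results.append(weighted_mode(hs, n_boot=n_boot, seed=seed))
    return results
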