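"""Heterogeneity, instrument-strength, dilution, and outlier diagnostics.

These statistics gate the causal estimators: Cochran's Q flags heterogeneity
between per-SNP Wald ratios (a symptom of pleiotropy), radial regression
localizes that heterogeneity to individual outlying SNPs, I2_GX quantifies
how much SNP-exposure measurement error dilutes the MR-Egger slope, and the
F-statistic summarizes instrument strength (F < 10 is conventionally weak).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import HarmonizedSet

#: Conventional weak-instrument threshold on the F-statistic.
WEAK_F_THRESHOLD = 10.0


@dataclass
class QStats:
    """Cochran's Q heterogeneity statistic with per-SNP contributions."""

    q: float
    df: int
    pval: float
    per_snp_q: np.ndarray = field(repr=False)


@dataclass
class StrengthStats:
    """Instrument-strength summary: variance explained, F, and weak flag."""

    r2: float
    f_stat: float
    weak: bool
    i2_gx: float | None = None


@dataclass
class RadialResult:
    """Outcome of a single-pass radial-regression outlier screen."""

    outlier_ids: list[str]
    kept: HarmonizedSet
    radial_estimate: float
    per_snp_q: np.ndarray = field(repr=False)
    pvals: np.ndarray = field(repr=False)


def _ratios_and_weights(hs: HarmonizedSet):
    tab = hs.table
    bx = tab["beta_exposure"].to_numpy(float)
    by = tab["beta_outcome"].to_numpy(float)
    sey = tab["se_outcome"].to_numpy(float)
    if np.any(bx == 0):
        raise ValueError("beta_exposure = 0 leaves the Wald ratio undefined")
    return by / bx, bx**2 / sey**2


def cochran_q(hs: HarmonizedSet, beta_ivw: float) -> QStats:
    """Cochran's Q of the Wald ratios about ``beta_ivw`` with first-order weights.

    Under homogeneity Q ~ chi-square(k-1); inflation beyond its df suggests
    heterogeneous per-SNP effects, i.e. potential pleiotropy.
    """
    if hs.n_snp < 2:
        raise ValueError("Cochran's Q needs at least 2 SNPs")
    r, w = _ratios_and_weights(hs)
    per = w * (r - beta_ivw) ** 2
    q = float(per.sum())
    df = hs.n_snp - 1
    return QStats(q=q, df=df, pval=float(stats.chi2.sf(q, df)), per_snp_q=per)


def radial_outliers(hs: HarmonizedSet, alpha: float = 0.05) -> RadialResult:
    """Single-pass radial (modified first-order-weight) outlier screen.

    Regressing ``ratio * sqrt(w)`` on ``sqrt(w)`` through the origin recovers
    the IVW estimate; each SNP's contribution ``Q_j = w_j (r_j - slope)^2`` is
    referred to chi-square(1), and SNPs with upper-tail p below ``alpha`` are
    flagged.  Refuses to flag every SNP.
    """
    if hs.n_snp < 3:
        raise ValueError("radial outlier screen needs at least 3 SNPs")
    r, w = _ratios_and_weights(hs)
    slope = float((w * r).sum() / w.sum())
    per = w * (r - slope) ** 2
    pvals = stats.chi2.sf(per, 1)
    flagged = pvals < alpha
    if flagged.all():
        raise ValueError("every SNP flagged as a radial outlier; refusing to empty the set")
    outlier_ids = hs.table.loc[flagged, "snp_id"].tolist()
    kept = hs.subset(~flagged, reason="radial outlier")
    return RadialResult(outlier_ids=outlier_ids, kept=kept, radial_estimate=slope,
                        per_snp_q=per, pvals=pvals)


def isq_gx(hs: HarmonizedSet) -> float:
    """I2_GX: fraction of SNP-exposure effect spread not due to sampling error.

    Computed as ``max(0, (Q_GX - (k-1)) / Q_GX)`` where Q_GX is Cochran's Q of
    the exposure betas weighted by their inverse variances.  Values below 0.9
    indicate meaningful regression dilution of the MR-Egger slope, for which a
    SIMEX correction is recommended.  Returned on the [0, 1] scale.
    """
    if hs.n_snp < 2:
        raise ValueError("I2_GX needs at least 2 SNPs")
    sex = hs.table["se_exposure"].to_numpy(float)
    if np.any(~np.isfinite(sex)) or np.any(sex <= 0):
        raise ValueError("I2_GX requires a positive se_exposure for every SNP")
    bx = np.abs(hs.table["beta_exposure"].to_numpy(float))
    v = 1.0 / sex**2
    m = (v * bx).sum() / v.sum()
    q_gx = float((v * (bx - m) ** 2).sum())
    if q_gx == 0.0:
        return 0.0
    return max(0.0, (q_gx - (hs.n_snp - 1)) / q_gx)


def instrument_strength(r2: float, n: int, k: int,
                        hs: HarmonizedSet | None = None) -> StrengthStats:
    """F-statistic from variance explained ``r2``, sample size ``n``, and ``k`` SNPs.

    ``F = r2 (n - k - 1) / ((1 - r2) k)``.  ``r2`` is taken as reported by the
    exposure GWAS (individual-level genotypes are out of scope here).  If a
    harmonized set is supplied its I2_GX is attached.
    """
    if not (0.0 <= r2 < 1.0):
        raise ValueError("r2 must lie in [0, 1)")
    if not n > k + 1 or k < 1:
        raise ValueError("need n > k + 1 and k >= 1")
    f = r2 * (n - k - 1) / ((1.0 - r2) * k)
    i2 = isq_gx(hs) if hs is not None else None
    return StrengthStats(r2=r2, f_stat=float(f), weak=f < WEAK_F_THRESHOLD, i2_gx=i2)
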