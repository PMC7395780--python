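"""Multivariable MR direct effects and difference-method mediation.

The mediation decomposition follows the difference method on the additive
(log-odds) scale: the *total* effect of the exposure on the outcome comes
from univariable IVW, the *direct* effect (not through the mediator) from a
multivariable MR fit that conditions on the SNP-mediator associations, and
the *indirect* effect is total minus direct.  The proportion mediated is
indirect/total, with a delta-method standard error for the ratio
direct/total.  Results are exponentiated to odds ratios only for reporting.

Because total and direct effects are estimated from overlapping instruments
they are correlated; when that covariance is unknown the delta method is
evaluated at covariance zero (documented as a conservative-in-spirit but not
guaranteed choice), and a seeded SNP-level nonparametric bootstrap is
available to estimate it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .diagnostics import radial_outliers
from .estimators import Z95, MRResult, ivw
from .sumstats import AssociationRecord, HarmonizedSet, harmonize

log = logging.getLogger(__name__)

_MV_COLUMNS = ["snp_id", "beta_exposure", "se_exposure", "beta_mediator",
               "se_mediator", "beta_outcome", "se_outcome"]


@dataclass
class MVHarmonizedSet:
    """Per-SNP exposure/mediator/outcome effects on a common effect allele."""

    table: pd.DataFrame
    exposure_label: str = "exposure"
    mediator_label: str = "mediator"
    outcome_label: str = "outcome"

    @property
    def n_snp(self) -> int:
        return len(self.table)


@dataclass
class MVMRResult:
    """Direct effects from multivariable IVW (WLS without intercept)."""

    direct_exposure: float
    direct_exposure_se: float
    direct_mediator: float | None
    direct_mediator_se: float | None
    n_snp: int


@dataclass
class MediationResult:
    """Difference-method decomposition on the log-odds scale (one mediator)."""

    total: float
    total_se: float
    direct: float
    direct_se: float
    indirect: float
    indirect_se: float
    proportion_mediated: float
    pm_se: float
    pm_ci: tuple[float, float]
    cov_td: float = 0.0

    @property
    def or_total(self) -> float:
        return float(np.exp(self.total))

    @property
    def or_direct(self) -> float:
        return float(np.exp(self.direct))


def harmonize_mv(
    exposure: Sequence[AssociationRecord],
    mediator: Sequence[AssociationRecord],
    outcome: Sequence[AssociationRecord],
    palindrome_policy: str = "infer_by_eaf",
) -> MVHarmonizedSet:
    """Mutually harmonize exposure, mediator, and outcome onto one effect allele.

    Both the mediator and the outcome are aligned to the exposure's effect
    alleles; only SNPs retained in both pairwise harmonizations survive.
    """
    hs_out = harmonize(exposure, outcome, palindrome_policy=palindrome_policy)
    hs_med = harmonize(exposure, mediator, palindrome_policy=palindrome_policy)
    med = hs_med.table[["snp_id", "beta_outcome", "se_outcome"]].rename(
        columns={"beta_outcome": "beta_mediator", "se_outcome": "se_mediator"})
    merged = hs_out.table.merge(med, on="snp_id", how="inner")
    return MVHarmonizedSet(table=merged[_MV_COLUMNS].reset_index(drop=True))


def mvmr_direct_effect(mv: MVHarmonizedSet, condition_limit: float = 1e8) -> MVMRResult:
    """Multivariable IVW: WLS of beta_outcome on (beta_exposure, beta_mediator).

    No intercept; weights 1/se_outcome^2; the coefficient on beta_exposure is
    the direct effect of the exposure conditional on the mediator.  The
    residual variance is floored at 1 so homogeneous data keep fixed-effect
    standard errors.  An all-zero mediator column is dropped, in which case
    the fit degenerates to univariable IVW.
    """
    if mv.n_snp < 4:
        raise ValueError("multivariable MR needs at least 4 SNPs")
    tab = mv.table
    y = tab["beta_outcome"].to_numpy(float)
    w = 1.0 / tab["se_outcome"].to_numpy(float) ** 2
    bx = tab["beta_exposure"].to_numpy(float)
    bm = tab["beta_mediator"].to_numpy(float)

    use_mediator = not np.allclose(bm, 0.0)
    X = np.column_stack([bx, bm]) if use_mediator else bx[:, None]
    cond = np.linalg.cond(np.sqrt(w)[:, None] * X)
    if cond > condition_limit:
        raise ValueError(
            f"collinear SNP-effect design (condition number {cond:.3g}); "
            "exposure and mediator instruments are not separable")

    fit = sm.WLS(y, X, weights=w).fit()
    # Floor the residual variance at 1 (multiplicative random effects).
    cov = fit.normalized_cov_params * max(1.0, fit.scale)
    se = np.sqrt(np.diag(cov))
    return MVMRResult(
        direct_exposure=float(fit.params[0]),
        direct_exposure_se=float(se[0]),
        direct_mediator=float(fit.params[1]) if use_mediator else None,
        direct_mediator_se=float(se[1]) if use_mediator else None,
        n_snp=mv.n_snp,
    )


def mediate(total: tuple[float, float], direct: tuple[float, float],
            cov_td: float | None = None) -> MediationResult:
    """Difference-method mediation from (estimate, SE) pairs on the log scale.

    ``indirect = total - direct``; ``PM = indirect/total = 1 - direct/total``.
    The delta-method variance of direct/total is
    ``var_D/t^2 + d^2 var_T/t^4 - 2 d cov/t^3``; ``cov_td`` defaults to 0
    when unknown.  PM is reported unclipped (values outside [0, 1] are
    meaningful and shown).
    """
    t, t_se = float(total[0]), float(total[1])
    d, d_se = float(direct[0]), float(direct[1])
    if t == 0:
        raise ValueError("total effect is zero; proportion mediated undefined")
    if cov_td is None:
        cov_td = 0.0
        log.warning("mediate: covariance between total and direct unknown; "
                    "delta-method interval computed at cov = 0")
    var_t, var_d = t_se**2, d_se**2
    pm = 1.0 - d / t
    pm_var = var_d / t**2 + d**2 * var_t / t**4 - 2 * d * cov_td / t**3
    pm_se = float(np.sqrt(max(pm_var, 0.0)))
    return MediationResult(
        total=t, total_se=t_se, direct=d, direct_se=d_se,
        indirect=t - d, indirect_se=float(np.sqrt(max(var_t + var_d - 2 * cov_td, 0.0))),
        proportion_mediated=float(pm), pm_se=pm_se,
        pm_ci=(float(pm - Z95 * pm_se), float(pm + Z95 * pm_se)),
        cov_td=float(cov_td),
    )


@dataclass
class MediationStudy:
    """Inputs for one exposure -> mediator -> outcome mediation analysis."""

    name: str
    exposure: Sequence[AssociationRecord]
    mediator: Sequence[AssociationRecord]
    outcome: Sequence[AssociationRecord]


def run_mediation(
    study: MediationStudy,
    palindrome_policy: str = "infer_by_eaf",
    screen_outliers: bool = True,
    radial_alpha: float | None = None,
    cov_bootstrap: int = 0,
    seed: int = 0,
) -> tuple[MediationResult, MRResult, MVMRResult]:
    """Full pipeline for one mediator: total (univariable IVW after an
    optional radial outlier screen), direct (MVMR on the surviving SNPs),
    and the difference-method decomposition.

    The outlier screen defaults to a Bonferroni per-SNP level (0.05/k): in a
    mediation analysis the screen must only remove gross outliers, because
    mass single-test screening selects on the same residual the multivariable
    fit regresses on and can bias the direct effect.  ``cov_bootstrap > 0``
    estimates the total/direct covariance by resampling instruments with
    replacement (seeded); otherwise the delta method is evaluated at
    covariance zero.
    """
    hs = harmonize(study.exposure, study.outcome, palindrome_policy=palindrome_policy,
                   outcome_label=study.name)
    if screen_outliers and hs.n_snp >= 3:
        alpha = radial_alpha if radial_alpha is not None else 0.05 / hs.n_snp
        hs = radial_outliers(hs, alpha=alpha).kept
    total = ivw(hs)

    mv = harmonize_mv(study.exposure, study.mediator, study.outcome,
                      palindrome_policy=palindrome_policy)
    keep = mv.table["snp_id"].isin(hs.table["snp_id"]).to_numpy()
    mv = MVHarmonizedSet(table=mv.table.loc[keep].reset_index(drop=True))
    direct = mvmr_direct_effect(mv)

    cov_td = None
    if cov_bootstrap > 0:
        cov_td = _bootstrap_cov(hs, mv, n_boot=cov_bootstrap, seed=seed)
    med = mediate((total.estimate, total.se),
                  (direct.direct_exposure, direct.direct_exposure_se),
                  cov_td=cov_td)
    return med, total, direct


def _bootstrap_cov(hs: HarmonizedSet, mv: MVHarmonizedSet,
                   n_boot: int, seed: int) -> float:
    """SNP-resampling bootstrap covariance of (total, direct) estimates."""
    rng = np.random.default_rng(seed)
    tab = mv.table
    k = len(tab)
    totals = np.empty(n_boot)
    directs = np.empty(n_boot)
    y = tab["beta_outcome"].to_numpy(float)
    w = 1.0 / tab["se_outcome"].to_numpy(float) ** 2
    bx = tab["beta_exposure"].to_numpy(float)
    bm = tab["beta_mediator"].to_numpy(float)
    for b in range(n_boot):
        idx = rng.integers(0, k, size=k)
        wb, yb, bxb, bmb = w[idx], y[idx], bx[idx], bm[idx]
        totals[b] = (wb * bxb * yb).sum() / (wb * bxb**2).sum()
        X = np.column_stack([bxb, bmb])
        try:
            directs[b] = np.linalg.lstsq(np.sqrt(wb)[:, None] * X,
                                         np.sqrt(wb) * yb, rcond=None)[0][0]
        except np.linalg.LinAlgError:  # pragma: no cover - degenerate resample
            directs[b] = np.nan
    ok = np.isfinite(directs)
    return float(np.cov(totals[ok], directs[ok])[0, 1])


def mediation_table(
    studies: Sequence[MediationStudy],
    palindrome_policy: str = "infer_by_eaf",
    screen_outliers: bool = True,
    radial_alpha: float | None = None,
    cov_bootstrap: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Assemble a mediation report (one total/direct pair per mediator).

    Columns mirror a per-mediator mediation table: odds ratios with 95% CIs
    and p-values for total and direct effects, plus the proportion mediated
    (percent) with its delta-method interval.  Per-study failures are
    recorded in the ``error`` column without aborting the remaining studies.
    """
    rows = []
    for study in studies:
        try:
            med, total, direct = run_mediation(
                study, palindrome_policy=palindrome_policy,
                screen_outliers=screen_outliers, radial_alpha=radial_alpha,
                cov_bootstrap=cov_bootstrap, seed=seed)
        except (ValueError, KeyError) as exc:
            log.error("mediation for %s failed: %s", study.name, exc)
            rows.append({"mediator": study.name, "error": str(exc)})
            continue
        d_z = med.direct / med.direct_se if med.direct_se > 0 else np.nan
        from scipy import stats as _st
        rows.append({
            "mediator": study.name,
            "n_snp": total.n_snp,
            "or_total": med.or_total,
            "or_total_low": float(np.exp(total.ci_low)),
            "or_total_high": float(np.exp(total.ci_high)),
            "p_total": total.pval,
            "or_direct": med.or_direct,
            "or_direct_low": float(np.exp(med.direct - Z95 * med.direct_se)),
            "or_direct_high": float(np.exp(med.direct + Z95 * med.direct_se)),
            "p_direct": float(2 * _st.norm.sf(abs(d_z))) if np.isfinite(d_z) else np.nan,
            "proportion_mediated_pct": 100 * med.proportion_mediated,
            "pm_ci_low_pct": 100 * med.pm_ci[0],
            "pm_ci_high_pct": 100 * med.pm_ci[1],
            "error": "",
        })
    return pd.DataFrame(rows)
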