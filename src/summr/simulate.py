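"""Synthetic two-sample and mediation summary statistics with known truth.

The generator emulates the statistical structure of two-sample MR inputs:
per-SNP true exposure effects ``gamma_j``, observed with sampling error whose
scale follows the standard GWAS approximation ``se ~ 1/sqrt(2 n maf(1-maf))``
(phenotype in SD units), and outcome effects

    Gamma_j = theta * gamma_j + alpha_j * [j invalid],

observed with their own sampling error.  ``alpha_j`` is the per-SNP
horizontal-pleiotropy effect under four scenarios: none, balanced (mean 0),
directional (non-zero mean, independent of gamma: InSiDE holds), and
InSiDE-violating (alpha correlated with gamma).  Binary-trait effects are
generated directly on the log-odds scale; no individual-level sampling is
performed because the downstream pipeline consumes only summary statistics.
A configurable fraction of outcome rows is emitted allele-swapped so the
harmonization step is exercised end to end.

A three-trait extension generates exposure -> mediator -> outcome systems
with a known proportion mediated for validating the multivariable-MR
mediation pipeline.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .sumstats import AssociationRecord

PLEIOTROPY_SCENARIOS = ("none", "balanced", "directional", "inside_violating")

_NONPALINDROMIC_PAIRS = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass
class SimConfig:
    """Ground-truth parameters for a simulated two-sample study.

    Defaults mirror a schooling-on-disease design: ~300k-person exposure GWAS,
    150k-person outcome GWAS, and SNP-exposure effects of a few hundredths of
    an SD, which yields strong instruments (per-SNP F around 50).
    """

    k: int = 50
    theta: float = 0.0
    gamma_mean: float = 0.02
    gamma_sd: float = 0.005
    maf_range: tuple[float, float] = (0.1, 0.5)
    n_exposure: int = 293723
    n_outcome: int = 150000
    pleiotropy: str = "none"
    alpha_mean: float = 0.0
    alpha_sd: float = 0.0
    inside_corr: float = 0.0
    invalid_fraction: float = 0.0
    swap_fraction: float = 0.3
    palindromic_fraction: float = 0.0
    case_fraction_outcome: float | None = None
    seed: int = 0
    label: str | None = None

    def __post_init__(self) -> None:
        if self.k < 3:
            raise ValueError("k must be at least 3")
        if not 0.0 <= self.invalid_fraction <= 1.0:
            raise ValueError("invalid_fraction must lie in [0, 1]")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must be a subset of (0, 0.5]")
        if self.pleiotropy not in PLEIOTROPY_SCENARIOS:
            raise ValueError(f"pleiotropy must be one of {PLEIOTROPY_SCENARIOS}")
        if not -1.0 <= self.inside_corr <= 1.0:
            raise ValueError("inside_corr must lie in [-1, 1]")


@dataclass
class SyntheticStudy:
    """Simulated summary statistics plus the ground truth that generated them."""

    exposure: list[AssociationRecord]
    outcome: list[AssociationRecord]
    truth: dict = field(repr=False)


def _se_from_n_maf(n: int, maf: np.ndarray,
                   case_fraction: float | None = None) -> np.ndarray:
    """Sampling SE of a per-allele effect.

    SD-scale trait: ``1/sqrt(2 n maf(1-maf))``.  Binary trait on the log-odds
    scale with case fraction K: the effective sample size shrinks by
    ``K(1-K)``, giving ``1/sqrt(2 n maf(1-maf) K(1-K))``.
    """
    out = 1.0 / np.sqrt(2.0 * n * maf * (1.0 - maf))
    if case_fraction is not None:
        if not 0.0 < case_fraction < 1.0:
            raise ValueError("case_fraction must be strictly inside (0, 1)")
        out = out / np.sqrt(case_fraction * (1.0 - case_fraction))
    return out


def _draw_alpha(cfg: SimConfig, gamma: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    if cfg.pleiotropy == "none":
        return np.zeros(cfg.k)
    if cfg.pleiotropy == "balanced":
        return rng.normal(0.0, cfg.alpha_sd, cfg.k)
    if cfg.pleiotropy == "directional":
        return rng.normal(cfg.alpha_mean, cfg.alpha_sd, cfg.k)
    # inside_violating: alpha correlated with gamma at inside_corr
    rho = cfg.inside_corr
    z = (gamma - cfg.gamma_mean) / cfg.gamma_sd if cfg.gamma_sd > 0 else np.zeros(cfg.k)
    eps = rng.standard_normal(cfg.k)
    return cfg.alpha_mean + cfg.alpha_sd * (rho * z + np.sqrt(1.0 - rho**2) * eps)


def _pick_alleles(k: int, palindromic_fraction: float, rng: np.random.Generator):
    pal = rng.random(k) < palindromic_fraction
    ea = np.empty(k, dtype=object)
    oa = np.empty(k, dtype=object)
    for i in range(k):
        pool = _PALINDROMIC_PAIRS if pal[i] else _NONPALINDROMIC_PAIRS
        ea[i], oa[i] = pool[rng.integers(len(pool))]
    return ea, oa


def _records(snp_ids, ea, oa, eaf, beta, se, n, swap_mask) -> list[AssociationRecord]:
    recs = []
    for i, snp in enumerate(snp_ids):
        if swap_mask[i]:
            recs.append(AssociationRecord(
                snp_id=snp, effect_allele=oa[i], other_allele=ea[i],
                eaf=float(1.0 - eaf[i]), beta=float(-beta[i]), se=float(se[i]),
                pval=_pval(beta[i], se[i]), n=n))
        else:
            recs.append(AssociationRecord(
                snp_id=snp, effect_allele=ea[i], other_allele=oa[i],
                eaf=float(eaf[i]), beta=float(beta[i]), se=float(se[i]),
                pval=_pval(beta[i], se[i]), n=n))
    return recs


def _pval(beta: float, se: float) -> float:
    from scipy import stats
    return float(max(2 * stats.norm.sf(abs(beta / se)), 1e-300))


def simulate_two_sample(cfg: SimConfig) -> SyntheticStudy:
    """Generate one two-sample study; byte-identical for a fixed seed."""
    rng = np.random.default_rng(cfg.seed)
    k = cfg.k
    snp_ids = [f"rs{i + 1}" for i in range(k)]
    maf = rng.uniform(*cfg.maf_range, k)
    gamma = rng.normal(cfg.gamma_mean, cfg.gamma_sd, k)

    n_invalid = int(round(cfg.invalid_fraction * k))
    invalid = np.zeros(k, dtype=bool)
    if n_invalid:
        invalid[rng.choice(k, n_invalid, replace=False)] = True
    alpha = _draw_alpha(cfg, gamma, rng)

    se_x = _se_from_n_maf(cfg.n_exposure, maf)
    se_y = _se_from_n_maf(cfg.n_outcome, maf, cfg.case_fraction_outcome)
    beta_x = gamma + rng.normal(0.0, se_x)
    gamma_out = cfg.theta * gamma + alpha * invalid
    beta_y = gamma_out + rng.normal(0.0, se_y)

    ea, oa = _pick_alleles(k, cfg.palindromic_fraction, rng)
    eaf_exp = maf
    eaf_out = np.clip(maf + rng.normal(0.0, 0.005, k), 1e-3, 1 - 1e-3)
    swap = rng.random(k) < cfg.swap_fraction

    exposure = _records(snp_ids, ea, oa, eaf_exp, beta_x, se_x,
                        cfg.n_exposure, np.zeros(k, dtype=bool))
    outcome = _records(snp_ids, ea, oa, eaf_out, beta_y, se_y,
                       cfg.n_outcome, swap)
    truth = {
        "config": dataclasses.asdict(cfg),
        "gamma": gamma, "alpha": alpha, "invalid": invalid,
        "maf": maf, "se_exposure": se_x, "se_outcome": se_y,
        "swapped": swap, "theta": cfg.theta,
    }
    return SyntheticStudy(exposure=exposure, outcome=outcome, truth=truth)


@dataclass
class MedSimConfig:
    """Ground truth for an exposure -> mediator -> outcome system.

    The outcome model per SNP is
    ``beta_ZY = theta_direct * gamma + tau * beta_ZM_true`` with
    ``beta_ZM_true = delta * gamma + kappa`` and mediator-specific genetic
    effects ``kappa ~ N(0, kappa_sd^2)``; hence
    ``theta_total = theta_direct + delta * tau`` and the implied proportion
    mediated is ``delta * tau / theta_total``.  Defaults use deliberately
    strong instruments (per-SNP F in the hundreds) so multivariable-MR
    regression-dilution bias stays negligible.
    """

    k: int = 60
    gamma_mean: float = 0.03
    gamma_sd: float = 0.02
    kappa_sd: float = 0.015
    delta: float = 0.5
    tau: float = 0.3
    theta_direct: float = 0.35
    maf_range: tuple[float, float] = (0.1, 0.5)
    n_exposure: int = 293723
    n_mediator: int = 500000
    n_outcome: int = 150000
    case_fraction_outcome: float | None = 0.23
    swap_fraction: float = 0.2
    seed: int = 0

    @property
    def theta_total(self) -> float:
        return self.theta_direct + self.delta * self.tau

    @property
    def pm(self) -> float:
        if self.theta_total == 0:
            raise ValueError("theta_total is zero; proportion mediated undefined")
        return self.delta * self.tau / self.theta_total


@dataclass
class MediationSimulation:
    exposure: list[AssociationRecord]
    mediator: list[AssociationRecord]
    outcome: list[AssociationRecord]
    truth: dict = field(repr=False)


def simulate_mediation(cfg: MedSimConfig) -> MediationSimulation:
    """Generate three harmonizable association lists with known mediation truth."""
    rng = np.random.default_rng(cfg.seed)
    k = cfg.k
    snp_ids = [f"rs{i + 1}" for i in range(k)]
    maf = rng.uniform(*cfg.maf_range, k)
    gamma = rng.normal(cfg.gamma_mean, cfg.gamma_sd, k)
    kappa = rng.normal(0.0, cfg.kappa_sd, k)

    se_x = _se_from_n_maf(cfg.n_exposure, maf)
    se_m = _se_from_n_maf(cfg.n_mediator, maf)
    se_y = _se_from_n_maf(cfg.n_outcome, maf, cfg.case_fraction_outcome)

    bm_true = cfg.delta * gamma + kappa
    by_true = cfg.theta_direct * gamma + cfg.tau * bm_true

    beta_x = gamma + rng.normal(0.0, se_x)
    beta_m = bm_true + rng.normal(0.0, se_m)
    beta_y = by_true + rng.normal(0.0, se_y)

    ea, oa = _pick_alleles(k, 0.0, rng)
    no_swap = np.zeros(k, dtype=bool)
    swap_m = rng.random(k) < cfg.swap_fraction
    swap_y = rng.random(k) < cfg.swap_fraction

    exposure = _records(snp_ids, ea, oa, maf, beta_x, se_x, cfg.n_exposure, no_swap)
    mediator = _records(snp_ids, ea, oa, maf, beta_m, se_m, cfg.n_mediator, swap_m)
    outcome = _records(snp_ids, ea, oa, maf, beta_y, se_y, cfg.n_outcome, swap_y)
    truth = {
        "config": dataclasses.asdict(cfg),
        "gamma": gamma, "kappa": kappa,
        "theta_total": cfg.theta_total, "theta_direct": cfg.theta_direct,
        "pm": cfg.pm,
    }
    return MediationSimulation(exposure=exposure, mediator=mediator,
                               outcome=outcome, truth=truth)


# Per-test instrument counts, exposure variance explained, and IVW point
# estimates (log scale) of the 11 schooling-on-T2D-and-risk-factor tests,
# used to parameterize demonstration simulations of matching size and
# instrument strength.
PUBLISHED_TESTS: dict[str, dict] = {
    "t2d":                  {"k": 17, "r2": 0.003, "theta": float(np.log(0.39)), "n_outcome": 149821, "cases": 34840},
    "sibling_diabetes":     {"k": 64, "r2": 0.008, "theta": float(np.log(0.97)), "n_outcome": 362826, "cases": 31073},
    "mother_diabetes":      {"k": 62, "r2": 0.009, "theta": float(np.log(0.97)), "n_outcome": 423892, "cases": 40091},
    "father_diabetes":      {"k": 60, "r2": 0.008, "theta": float(np.log(0.98)), "n_outcome": 400687, "cases": 38850},
    "overweight":           {"k": 54, "r2": 0.007, "theta": float(np.log(0.60)), "n_outcome": 158855, "cases": 93015},
    "physical_activity":    {"k": 49, "r2": 0.006, "theta": float(np.log(0.77)), "n_outcome": 440266, "cases": None},
    "high_blood_pressure":  {"k": 45, "r2": 0.006, "theta": float(np.log(0.94)), "n_outcome": 461880, "cases": 124227},
    "gestational_diabetes": {"k": 69, "r2": 0.009, "theta": 0.0,                 "n_outcome": 462933, "cases": 240},
    "pcos":                 {"k": 68, "r2": 0.009, "theta": 0.0,                 "n_outcome": 462933, "cases": 571},
    "hdl":                  {"k": 52, "r2": 0.007, "theta": 0.14,                "n_outcome": 187167, "cases": None},
    "triglycerides":        {"k": 52, "r2": 0.007, "theta": -0.19,               "n_outcome": 177861, "cases": None},
}


def published_test_config(test_name: str, seed: int = 0) -> SimConfig:
    """SimConfig whose SNP count, instrument strength, and causal effect match
    one of the 11 published schooling tests (for end-to-end demo runs).

    The mean SNP-exposure effect is back-solved from the reported variance
    explained: ``r2 ~ k * E[2 maf(1-maf)] * E[gamma^2]``.
    """
    if test_name not in PUBLISHED_TESTS:
        raise KeyError(
            f"unknown test {test_name!r}; valid names: {sorted(PUBLISHED_TESTS)}")
    row = PUBLISHED_TESTS[test_name]
    lo, hi = 0.1, 0.5
    # E[maf(1-maf)] for maf ~ U(lo, hi)
    e_pq = ((hi**2 / 2 - hi**3 / 3) - (lo**2 / 2 - lo**3 / 3)) / (hi - lo)
    gamma_mean = float(np.sqrt(row["r2"] / (row["k"] * 2.0 * e_pq)))
    case_fraction = (row["cases"] / row["n_outcome"]
                     if row["cases"] is not None else None)
    return SimConfig(
        k=row["k"], theta=row["theta"], gamma_mean=gamma_mean,
        gamma_sd=gamma_mean / 4.0, maf_range=(lo, hi),
        n_exposure=293723, n_outcome=row["n_outcome"],
        case_fraction_outcome=case_fraction,
        seed=seed, label=test_name,
    )
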