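"""Statistical power for two-sample MR with a binary outcome.

Uses the normal-approximation non-centrality argument behind the standard MR
power calculators: with an outcome GWAS of ``n`` individuals, case fraction
``K``, and instruments explaining ``r2`` of the exposure variance, the Wald
statistic for a true log odds ratio ``b = ln(OR)`` per SD of exposure is
approximately normal with mean ``sqrt(n * r2 * K * (1 - K)) * b``, so

    power = Phi( sqrt(n * r2 * K(1-K)) * |ln OR| - z_{1-alpha/2} ).

Power is monotone in ``n``, ``r2``, and ``|ln OR|``, symmetric under
OR -> 1/OR, and tends to alpha/2 as OR -> 1.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

Z = stats.norm.ppf  # quantile shortcut


@dataclass(frozen=True)
class PowerParams:
    """Design parameters for a binary-outcome two-sample MR power calculation."""

    n_outcome: int
    case_fraction: float
    r2_gx: float
    or_alt: float
    alpha: float = 0.05

    def validate(self) -> None:
        if self.n_outcome <= 1:
            raise ValueError("n_outcome must exceed 1")
        if not 0.0 < self.case_fraction < 1.0:
            raise ValueError("case_fraction must be strictly inside (0, 1)")
        if not 0.0 < self.r2_gx < 1.0:
            raise ValueError("r2_gx must be in (0, 1)")
        if self.or_alt <= 0.0:
            raise ValueError("or_alt must be positive")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")


def binary_outcome_power(p: PowerParams) -> float:
    """Power to detect ``p.or_alt`` at two-sided level ``p.alpha``. Deterministic."""
    p.validate()
    k = p.case_fraction
    ncp = np.sqrt(p.n_outcome * p.r2_gx * k * (1.0 - k)) * abs(np.log(p.or_alt))
    return float(stats.norm.cdf(ncp - Z(1.0 - p.alpha / 2.0)))


def power_curve(p: PowerParams, or_grid: Sequence[float]) -> pd.DataFrame:
    """Element-wise power over a grid of alternative odds ratios."""
    if len(or_grid) == 0:
        raise ValueError("or_grid must be non-empty")
    rows = [{"odds_ratio": float(o),
             "power": binary_outcome_power(replace(p, or_alt=float(o)))}
            for o in or_grid]
    return pd.DataFrame(rows)
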