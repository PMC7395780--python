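"""Diagnostic plots: effect scatter with fitted lines, Wald-ratio forest,
radial Q plot, and the power curve."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .diagnostics import RadialResult
from .estimators import MRResult, wald_ratios
from .sumstats import HarmonizedSet


def scatter_plot(hs: HarmonizedSet, results: Sequence[MRResult],
                 path: str | Path) -> None:
    """SNP-exposure vs SNP-outcome effects with one fitted line per estimator."""
    tab = hs.table
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.errorbar(tab["beta_exposure"], tab["beta_outcome"],
                xerr=tab["se_exposure"], yerr=tab["se_outcome"],
                fmt="o", ms=3, lw=0.6, color="0.4", ecolor="0.7")
    xs = np.linspace(0, tab["beta_exposure"].abs().max() * 1.05, 50)
    for res in results:
        if not np.isfinite(res.estimate):
            continue
        icept = res.intercept or 0.0
        ax.plot(xs, icept + res.estimate * xs, label=res.method, lw=1.2)
    ax.axhline(0, color="k", lw=0.5)
    ax.set_xlabel(f"SNP effect on {hs.exposure_label}")
    ax.set_ylabel(f"SNP effect on {hs.outcome_label}")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def forest_plot(hs: HarmonizedSet, path: str | Path,
                overall: MRResult | None = None) -> None:
    """Forest plot of per-SNP Wald ratios with 95% intervals."""
    wr = wald_ratios(hs).sort_values("ratio").reset_index(drop=True)
    ypos = np.arange(len(wr))
    fig, ax = plt.subplots(figsize=(5, 0.18 * len(wr) + 1.5))
    ax.errorbar(wr["ratio"], ypos, xerr=1.959964 * wr["ratio_se"],
                fmt="o", ms=3, lw=0.8, color="0.2")
    if overall is not None and np.isfinite(overall.estimate):
        ax.axvline(overall.estimate, color="C3", lw=1,
                   label=f"{overall.method} = {overall.estimate:.3f}")
        ax.legend(fontsize=7)
    ax.axvline(0, color="k", lw=0.5)
    ax.set_yticks(ypos)
    ax.set_yticklabels(wr["snp_id"], fontsize=6)
    ax.set_xlabel("Wald ratio (causal effect per SD exposure)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def radial_plot(hs: HarmonizedSet, rad: RadialResult, path: str | Path) -> None:
    """Radial IVW plot: ratio * sqrt(w) against sqrt(w); outliers highlighted."""
    tab = hs.table
    bx = tab["beta_exposure"].to_numpy(float)
    by = tab["beta_outcome"].to_numpy(float)
    sey = tab["se_outcome"].to_numpy(float)
    sqw = np.abs(bx) / sey
    yv = (by / bx) * sqw
    is_out = tab["snp_id"].isin(rad.outlier_ids).to_numpy()
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(sqw[~is_out], yv[~is_out], "o", ms=4, color="0.3", label="kept")
    if is_out.any():
        ax.plot(sqw[is_out], yv[is_out], "o", ms=5, color="C3", label="outlier")
    xs = np.linspace(0, sqw.max() * 1.05, 20)
    ax.plot(xs, rad.radial_estimate * xs, "-", lw=1, color="C0",
            label=f"radial IVW = {rad.radial_estimate:.3f}")
    ax.set_xlabel(r"$\sqrt{w_j}$")
    ax.set_ylabel(r"$\hat\beta_j \sqrt{w_j}$")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def power_plot(curve: pd.DataFrame, path: str | Path) -> None:
    """Power against the alternative odds ratio."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(curve["odds_ratio"], curve["power"], "-o", ms=3)
    ax.axhline(0.8, color="0.6", ls="--", lw=0.8)
    ax.set_xlabel("Odds ratio per SD exposure")
    ax.set_ylabel("Power")
    ax.set_ylim(0, 1.02)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
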