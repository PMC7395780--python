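"""GWAS summary-statistic input, validation, instrument selection, and allele harmonization.

Two-sample MR works from per-SNP association records estimated in two
non-overlapping GWAS samples: one for the exposure, one for the outcome.
Before any Wald ratio can be formed the two tables must be aligned so that
every effect size refers to the same effect allele on the same strand.  This
module provides that plumbing: a validated :class:`AssociationRecord`, readers
for delimited/spreadsheet summary tables, genome-wide-significance instrument
selection, and the harmonization step producing a :class:`HarmonizedSet` of
aligned (beta_exposure, beta_outcome) pairs.

Harmonization rules
-------------------
For each SNP shared between the two tables the outcome alleles are compared to
the exposure alleles:

* identical (effect/other match) -> copy the outcome effect;
* swapped (effect <-> other) -> negate the outcome beta, flip its EAF;
* strand complements of either of the above -> complement first, then apply;
* anything else -> dropped as an allele mismatch, never silently kept.

Palindromic SNPs (A/T or C/G) cannot be strand-resolved from alleles alone.
The default policy orients them by comparing effect-allele frequencies between
the two studies and drops them when either frequency falls inside an
ambiguity window around 0.5 (or when EAF is unavailable).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: Conventional genome-wide significance threshold for instrument selection.
GENOME_WIDE_P = 5e-8

#: EAF window around 0.5 inside which a palindromic SNP cannot be oriented
#: by frequency.
DEFAULT_AMBIGUITY_WINDOW = (0.42, 0.58)

PALINDROME_POLICIES = ("drop_all", "infer_by_eaf", "keep")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Fixed column order of a written harmonized table.
HARMONIZED_COLUMNS = [
    "snp_id",
    "beta_exposure",
    "se_exposure",
    "beta_outcome",
    "se_outcome",
    "eaf_exposure",
    "eaf_outcome",
    "keep_flag",
    "drop_reason",
]


class NoInstrumentsError(ValueError):
    """Raised when an operation that needs at least one SNP receives none."""


def reverse_complement(allele: str) -> str:
    """Strand complement of an allele string (reverse-complemented for indels)."""
    return allele.translate(_COMPLEMENT)[::-1]


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True for A/T and C/G variants (and longer self-complementary pairs)."""
    return reverse_complement(effect_allele) == other_allele


@dataclass(frozen=True)
class AssociationRecord:
    """One SNP's association with one trait.

    ``beta`` is the additive effect per copy of ``effect_allele``: log-odds
    for binary traits, SD units for continuous ones (the schooling exposure is
    per SD of education, one SD = 3.6 years).
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    eaf: float | None = None
    pval: float | None = None
    n: int | None = None

    def validate(self) -> None:
        if not self.snp_id:
            raise ValueError("empty snp_id")
        for name, allele in (("effect_allele", self.effect_allele),
                             ("other_allele", self.other_allele)):
            if not allele or any(b not in "ACGT" for b in allele):
                raise ValueError(f"{name} {allele!r} is not a string over A/C/G/T")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"effect and other allele identical ({self.effect_allele})")
        if not math.isfinite(self.beta):
            raise ValueError(f"non-finite beta {self.beta!r}")
        if not (math.isfinite(self.se) and self.se > 0):
            raise ValueError(f"standard error must be > 0, got {self.se!r}")
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            raise ValueError(f"eaf {self.eaf!r} outside [0, 1]")
        if self.pval is not None and not (0.0 < self.pval <= 1.0):
            raise ValueError(f"p-value {self.pval!r} outside (0, 1]")


#: Default file-column -> record-field mapping (identity on canonical names,
#: plus the headers most GWAS downloads use).
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "snp_id": "snp_id", "SNP": "snp_id", "rsid": "snp_id", "MarkerName": "snp_id",
    "effect_allele": "effect_allele", "EA": "effect_allele", "A1": "effect_allele",
    "other_allele": "other_allele", "OA": "other_allele", "A2": "other_allele",
    "eaf": "eaf", "EAF": "eaf", "FREQ": "eaf",
    "beta": "beta", "BETA": "beta", "b": "beta",
    "se": "se", "SE": "se",
    "pval": "pval", "P": "pval", "pvalue": "pval", "p": "pval",
    "n": "n", "N": "n",
}

_MANDATORY_FIELDS = ("snp_id", "effect_allele", "other_allele", "beta", "se")


def _to_float(value) -> float | None:
    if value is None:
        return None
    try:
        out = float(value)
    except (TypeError, ValueError):
        return math.nan
    return None if math.isnan(out) else out


def read_summary_stats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    delimiter: str | None = None,
    sheet: str | int | None = None,
) -> list[AssociationRecord]:
    """Read a delimited (or XLSX) summary-statistics table into records.

    Parameters
    ----------
    path
        TSV/CSV file with a header row, or an ``.xlsx`` workbook (``sheet``
        selects the worksheet).
    column_map
        Mapping of file column names to record fields (``snp_id``,
        ``effect_allele``, ``other_allele``, ``beta``, ``se`` mandatory;
        ``eaf``, ``pval``, ``n`` optional).  Defaults to a map covering
        common GWAS headers.
    delimiter
        Field separator; default tab for anything that is not ``.csv``.

    Rows that fail validation (zero SE, malformed alleles, ...) are excluded
    and reported through the module logger with their 1-based data row number.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path, sheet_name=sheet if sheet is not None else 0)
    else:
        if delimiter is None:
            delimiter = "," if path.suffix.lower() == ".csv" else "\t"
        df = pd.read_csv(path, sep=delimiter)

    cmap = dict(column_map) if column_map is not None else DEFAULT_COLUMN_MAP
    rename = {col: cmap[col] for col in df.columns if col in cmap}
    df = df.rename(columns=rename)

    for fieldname in _MANDATORY_FIELDS:
        if fieldname not in df.columns:
            raise KeyError(
                f"mandatory column for field {fieldname!r} missing from {path.name}; "
                f"available columns: {list(df.columns)}"
            )

    records: list[AssociationRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row = row._asdict()
        try:
            rec = AssociationRecord(
                snp_id=str(row["snp_id"]),
                effect_allele=str(row["effect_allele"]).upper().strip(),
                other_allele=str(row["other_allele"]).upper().strip(),
                beta=float(row["beta"]),
                se=float(row["se"]),
                eaf=_to_float(row.get("eaf")),
                pval=_to_float(row.get("pval")),
                n=int(row["n"]) if row.get("n") is not None and not pd.isna(row.get("n")) else None,
            )
            rec.validate()
        except (ValueError, TypeError) as exc:
            log.warning("%s: row %d excluded: %s", path.name, i, exc)
            continue
        records.append(rec)
    return records


def write_summary_stats(records: Iterable[AssociationRecord], path: str | Path,
                        delimiter: str = "\t") -> None:
    """Write records to a delimited file with canonical column names."""
    df = pd.DataFrame([{
        "snp_id": r.snp_id, "effect_allele": r.effect_allele,
        "other_allele": r.other_allele, "eaf": r.eaf, "beta": r.beta,
        "se": r.se, "pval": r.pval, "n": r.n,
    } for r in records])
    df.to_csv(path, sep=delimiter, index=False)


def select_instruments(
    records: Sequence[AssociationRecord],
    p_threshold: float = GENOME_WIDE_P,
) -> list[AssociationRecord]:
    """Keep SNPs associated below ``p_threshold`` (default genome-wide 5e-8).

    Duplicate rsIDs collapse to the smallest-p record.  Records without a
    p-value cannot be selected and are excluded with a warning.  The input is
    assumed already pruned for linkage disequilibrium.
    """
    best: dict[str, AssociationRecord] = {}
    order: list[str] = []
    for rec in records:
        if rec.pval is None:
            log.warning("instrument selection: %s has no p-value, excluded", rec.snp_id)
            continue
        if rec.pval >= p_threshold:
            continue
        prev = best.get(rec.snp_id)
        if prev is None:
            best[rec.snp_id] = rec
            order.append(rec.snp_id)
        elif rec.pval < prev.pval:
            best[rec.snp_id] = rec
    if not best:
        raise NoInstrumentsError(
            f"no SNPs pass p < {p_threshold:g}; downstream estimators need at least one"
        )
    return [best[s] for s in order]


@dataclass
class HarmonizedSet:
    """Aligned per-SNP exposure/outcome effect pairs after harmonization.

    ``table`` holds the retained rows (columns ``snp_id``, ``beta_exposure``,
    ``se_exposure``, ``beta_outcome``, ``se_outcome``, ``eaf_exposure``,
    ``eaf_outcome``, ``palindromic``); ``dropped`` records every excluded SNP
    with a human-readable reason so retained + dropped partitions the input.
    """

    table: pd.DataFrame
    dropped: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["snp_id", "reason"]))
    exposure_label: str = "exposure"
    outcome_label: str = "outcome"

    @property
    def n_snp(self) -> int:
        return len(self.table)

    def subset(self, keep_mask: np.ndarray, reason: str) -> "HarmonizedSet":
        """New set retaining rows where ``keep_mask`` is True; the rest are
        moved to ``dropped`` with ``reason``."""
        keep_mask = np.asarray(keep_mask, dtype=bool)
        removed = self.table.loc[~keep_mask, ["snp_id"]].assign(reason=reason)
        dropped = pd.concat([self.dropped, removed], ignore_index=True)
        return HarmonizedSet(
            table=self.table.loc[keep_mask].reset_index(drop=True),
            dropped=dropped,
            exposure_label=self.exposure_label,
            outcome_label=self.outcome_label,
        )

    def to_frame(self) -> pd.DataFrame:
        """Full accounting table in the fixed output column order."""
        kept = self.table.copy()
        kept["keep_flag"] = True
        kept["drop_reason"] = ""
        drop = self.dropped.copy()
        drop = drop.rename(columns={"reason": "drop_reason"})
        drop["keep_flag"] = False
        out = pd.concat([kept, drop], ignore_index=True)
        for col in HARMONIZED_COLUMNS:
            if col not in out.columns:
                out[col] = np.nan
        return out[HARMONIZED_COLUMNS]

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _dedupe(records: Sequence[AssociationRecord], dropped: list[tuple[str, str]]
            ) -> dict[str, AssociationRecord]:
    out: dict[str, AssociationRecord] = {}
    for rec in records:
        if rec.snp_id in out:
            dropped.append((rec.snp_id, "duplicate snp_id"))
        else:
            out[rec.snp_id] = rec
    return out


def _align_outcome(exp: AssociationRecord, out: AssociationRecord,
                   policy: str, window: tuple[float, float]):
    """Orient one outcome record onto the exposure's effect allele.

    Returns ``(beta, eaf, palindromic)`` on success or a drop-reason string.
    """
    ea, oa = exp.effect_allele, exp.other_allele
    if is_palindromic(ea, oa):
        if {out.effect_allele, out.other_allele} != {ea, oa}:
            return "allele mismatch"
        # Letter-level orientation first; strand flip is then a pure sign issue.
        flipped = out.effect_allele == oa
        beta = -out.beta if flipped else out.beta
        eaf = None if out.eaf is None else (1.0 - out.eaf if flipped else out.eaf)
        if policy == "keep":
            return beta, eaf, True
        if policy == "drop_all":
            return "palindromic"
        # infer_by_eaf
        if exp.eaf is None or eaf is None:
            return "palindromic, ambiguous eaf"
        lo, hi = window
        if lo <= exp.eaf <= hi or lo <= eaf <= hi:
            return "palindromic, ambiguous eaf"
        if (exp.eaf - 0.5) * (eaf - 0.5) < 0:
            # Frequencies disagree across studies: the outcome file reports the
            # other strand's allele as "effect"; flip.
            beta, eaf = -beta, 1.0 - eaf
        return beta, eaf, True

    cea = reverse_complement(out.effect_allele)
    coa = reverse_complement(out.other_allele)
    for a, b, flipped in (
        (out.effect_allele, out.other_allele, False),
        (out.other_allele, out.effect_allele, True),
        (cea, coa, False),
        (coa, cea, True),
    ):
        if (a, b) == (ea, oa):
            beta = -out.beta if flipped else out.beta
            eaf = None if out.eaf is None else (1.0 - out.eaf if flipped else out.eaf)
            return beta, eaf, False
    return "allele mismatch"


def harmonize(
    exposure: Sequence[AssociationRecord],
    outcome: Sequence[AssociationRecord],
    palindrome_policy: str = "infer_by_eaf",
    ambiguity_window: tuple[float, float] = DEFAULT_AMBIGUITY_WINDOW,
    exposure_label: str = "exposure",
    outcome_label: str = "outcome",
) -> HarmonizedSet:
    """Align outcome effects onto the exposure's effect alleles.

    Every exposure SNP is accounted for: it either appears in the retained
    table or in ``dropped`` with a reason (absent from outcome, allele
    mismatch, palindromic ambiguity, duplicate).
    """
    if palindrome_policy not in PALINDROME_POLICIES:
        raise ValueError(f"palindrome_policy must be one of {PALINDROME_POLICIES}")

    dropped: list[tuple[str, str]] = []
    exp_by_id = _dedupe(exposure, dropped)
    out_by_id = _dedupe(outcome, [])  # outcome duplicates resolved silently to first

    rows = []
    for snp_id, exp in exp_by_id.items():
        out = out_by_id.get(snp_id)
        if out is None:
            dropped.append((snp_id, "absent from outcome"))
            continue
        aligned = _align_outcome(exp, out, palindrome_policy, ambiguity_window)
        if isinstance(aligned, str):
            dropped.append((snp_id, aligned))
            continue
        beta_out, eaf_out, palindromic = aligned
        rows.append({
            "snp_id": snp_id,
            "beta_exposure": exp.beta,
            "se_exposure": exp.se,
            "beta_outcome": beta_out,
            "se_outcome": out.se,
            "eaf_exposure": np.nan if exp.eaf is None else exp.eaf,
            "eaf_outcome": np.nan if eaf_out is None else eaf_out,
            "palindromic": palindromic,
        })

    table = pd.DataFrame(rows, columns=[
        "snp_id", "beta_exposure", "se_exposure", "beta_outcome", "se_outcome",
        "eaf_exposure", "eaf_outcome", "palindromic"])
    drop_df = pd.DataFrame(dropped, columns=["snp_id", "reason"])
    if table.empty:
        log.warning("harmonization retained no SNPs (%d dropped)", len(drop_df))
    return HarmonizedSet(table=table, dropped=drop_df,
                         exposure_label=exposure_label, outcome_label=outcome_label)


def harmonized_from_arrays(
    beta_exposure, se_exposure, beta_outcome, se_outcome,
    snp_ids: Sequence[str] | None = None,
    exposure_label: str = "exposure", outcome_label: str = "outcome",
) -> HarmonizedSet:
    """Build a :class:`HarmonizedSet` directly from aligned effect arrays.

    Convenience constructor for simulations and tests where alleles are
    already consistent by construction.
    """
    beta_exposure = np.asarray(beta_exposure, dtype=float)
    k = beta_exposure.size
    if snp_ids is None:
        snp_ids = [f"snp{i}" for i in range(1, k + 1)]
    table = pd.DataFrame({
        "snp_id": list(snp_ids),
        "beta_exposure": beta_exposure,
        "se_exposure": np.broadcast_to(np.asarray(se_exposure, dtype=float), (k,)).copy(),
        "beta_outcome": np.asarray(beta_outcome, dtype=float),
        "se_outcome": np.broadcast_to(np.asarray(se_outcome, dtype=float), (k,)).copy(),
        "eaf_exposure": np.nan,
        "eaf_outcome": np.nan,
        "palindromic": False,
    })
    return HarmonizedSet(table=table, exposure_label=exposure_label,
                         outcome_label=outcome_label)
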