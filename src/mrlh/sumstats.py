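"""GWAS summary statistics: schema, validation and tab-delimited I/O.

A summary-statistics table holds one GWAS's per-variant association records.
For continuous traits ``beta`` is the per-effect-allele change in trait SD
units (or natural units if the source was not standardized); for binary
traits it is the per-allele log odds ratio.  The canonical column set is

    variant_id chrom pos effect_allele other_allele eaf beta se pval n
    n_cases n_controls

with 1-based, inclusive coordinates.  ``eaf``, ``n``, ``n_cases`` and
``n_controls`` are optional per record ("NA" on disk).  Reported p-values are
stored as given and never recomputed; a consistency check against the normal
approximation |beta/se| only warns, because published files often carry more
precision in p than beta/se imply.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FormatError

logger = logging.getLogger(__name__)

#: canonical column order used on disk and in memory
CANONICAL_COLUMNS = [
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
    "n_cases",
    "n_controls",
]

MANDATORY_COLUMNS = [
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "beta",
    "se",
    "pval",
]

VALID_ALLELES = frozenset("ACGT")


@dataclass
class SummaryStatsTable:
    """One GWAS's per-variant association records.

    Parameters
    ----------
    trait_name
        Label for the scanned trait (e.g. ``"TLM"``).
    trait_type
        ``"continuous"`` or ``"binary"``.
    records
        DataFrame with the canonical columns, one row per variant,
        ``variant_id`` unique.
    sd_unit
        Optional trait SD in natural units (e.g. kg) when betas are reported
        per trait SD.
    """

    trait_name: str
    trait_type: str = "continuous"
    records: pd.DataFrame = field(default_factory=pd.DataFrame)
    sd_unit: float | None = None

    def __post_init__(self) -> None:
        if self.trait_type not in ("continuous", "binary"):
            raise FormatError(f"unknown trait_type {self.trait_type!r}")
        if len(self.records) == 0 and list(self.records.columns) != CANONICAL_COLUMNS:
            self.records = _empty_frame()
        missing = [c for c in CANONICAL_COLUMNS if c not in self.records.columns]
        if missing:
            raise FormatError(f"records missing canonical column(s): {missing}")
        self.records = self.records[CANONICAL_COLUMNS].reset_index(drop=True)
        if self.records["variant_id"].duplicated().any():
            dups = self.records.loc[self.records["variant_id"].duplicated(), "variant_id"]
            raise FormatError(f"duplicate variant_id(s): {sorted(set(dups))[:5]}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def variant_ids(self) -> pd.Index:
        return pd.Index(self.records["variant_id"])

    def get(self, variant_id: str) -> pd.Series:
        """Return the record for one variant (raises KeyError if absent)."""
        idx = self.records.index[self.records["variant_id"] == variant_id]
        if len(idx) == 0:
            raise KeyError(variant_id)
        return self.records.loc[idx[0]]

    def subset(self, ids: Sequence[str]) -> "SummaryStatsTable":
        """Restrict to ``ids``, preserving current row order."""
        keep = self.records["variant_id"].isin(set(ids))
        return SummaryStatsTable(
            trait_name=self.trait_name,
            trait_type=self.trait_type,
            records=self.records.loc[keep].reset_index(drop=True),
            sd_unit=self.sd_unit,
        )


def _empty_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "variant_id": pd.Series(dtype=str),
            "chrom": pd.Series(dtype=str),
            "pos": pd.Series(dtype=np.int64),
            "effect_allele": pd.Series(dtype=str),
            "other_allele": pd.Series(dtype=str),
            "eaf": pd.Series(dtype=float),
            "beta": pd.Series(dtype=float),
            "se": pd.Series(dtype=float),
            "pval": pd.Series(dtype=float),
            "n": pd.Series(dtype=float),
            "n_cases": pd.Series(dtype=float),
            "n_controls": pd.Series(dtype=float),
        }
    )


def validate_records(df: pd.DataFrame, *, context: str = "") -> pd.DataFrame:
    """Drop rows violating the record invariants, logging a count per rule.

    Rules: alleles must be distinct single A/C/G/T letters; se > 0;
    pval in (0, 1]; eaf, when present, strictly inside (0, 1).  A p-value
    inconsistent with |beta/se| by more than a factor of 2 (on the p scale)
    triggers a warning only.
    """
    df = df.copy()
    n0 = len(df)
    ea = df["effect_allele"].astype(str).str.upper()
    oa = df["other_allele"].astype(str).str.upper()
    df["effect_allele"], df["other_allele"] = ea, oa
    ok_alleles = ea.isin(VALID_ALLELES) & oa.isin(VALID_ALLELES) & (ea != oa)
    ok_se = pd.to_numeric(df["se"], errors="coerce") > 0
    pv = pd.to_numeric(df["pval"], errors="coerce")
    ok_p = (pv > 0) & (pv <= 1)
    eaf = pd.to_numeric(df["eaf"], errors="coerce")
    ok_eaf = eaf.isna() | ((eaf > 0) & (eaf < 1))
    keep = ok_alleles & ok_se & ok_p & ok_eaf
    for rule, mask in (
        ("allele", ok_alleles),
        ("se", ok_se),
        ("pval", ok_p),
        ("eaf", ok_eaf),
    ):
        bad = int((~mask).sum())
        if bad:
            logger.warning("%sdropped %d record(s) failing the %s invariant", context, bad, rule)
    df = df.loc[keep].reset_index(drop=True)
    if len(df):
        z = np.abs(df["beta"].to_numpy(float) / df["se"].to_numpy(float))
        implied = 2.0 * stats.norm.sf(z)
        given = df["pval"].to_numpy(float)
        with np.errstate(divide="ignore"):
            incons = np.abs(np.log(np.maximum(given, 1e-300)) - np.log(np.maximum(implied, 1e-300))) > np.log(2.0)
        # only meaningful away from the floating-point floor
        incons &= (implied > 1e-280) | (given > 1e-280)
        if incons.any():
            logger.warning(
                "%s%d record(s) have p-values inconsistent with |beta/se| by more than 2x "
                "(kept as given)",
                context,
                int(incons.sum()),
            )
    if n0 and len(df) < n0:
        logger.info("%sretained %d/%d records after validation", context, len(df), n0)
    return df


def read_summary_stats(
    path,
    dialect: Mapping[str, str] | None = None,
    *,
    trait_name: str | None = None,
    trait_type: str = "continuous",
    sd_unit: float | None = None,
) -> SummaryStatsTable:
    """Read a tab-delimited summary-statistics file.

    ``dialect`` maps canonical column names to the file's column names, e.g.
    ``{"variant_id": "SNP", "pval": "P"}``; unmapped canonical names are
    looked up verbatim.  Rows failing record invariants are dropped with a
    logged count; an empty table after validation is an error.
    """
    raw = pd.read_csv(path, sep="\t", dtype={0: str}, na_values=["NA"], low_memory=False)
    dialect = dict(dialect or {})
    rename = {}
    for canon in CANONICAL_COLUMNS:
        src = dialect.get(canon, canon)
        if src in raw.columns:
            rename[src] = canon
        elif canon in MANDATORY_COLUMNS:
            raise FormatError(f"missing mandatory column {src!r} (for {canon!r}) in {path}")
    df = raw.rename(columns=rename)
    for canon in CANONICAL_COLUMNS:
        if canon not in df.columns:
            df[canon] = np.nan
    df = df[CANONICAL_COLUMNS]
    df["variant_id"] = df["variant_id"].astype(str)
    df["chrom"] = df["chrom"].astype(str)
    df["pos"] = pd.to_numeric(df["pos"]).astype(np.int64)
    for col in ("eaf", "beta", "se", "pval", "n", "n_cases", "n_controls"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df = validate_records(df, context=f"{path}: ")
    if len(df) == 0:
        raise FormatError(f"{path}: no valid records after validation")
    return SummaryStatsTable(
        trait_name=trait_name or str(path), trait_type=trait_type, records=df, sd_unit=sd_unit
    )


def write_summary_stats(table: SummaryStatsTable, path) -> None:
    """Write a table tab-delimited with canonical columns.

    Rows are sorted by (chrom, pos, variant_id) so two writes of the same
    table are byte-identical; missing optional fields become "NA".
    """
    df = table.records.sort_values(["chrom", "pos", "variant_id"], kind="mergesort")
    out = df.copy()
    for col in ("eaf", "beta", "se", "pval"):
        out[col] = [_fmt_float(v) for v in df[col]]
    for col in ("n", "n_cases", "n_controls"):
        out[col] = ["NA" if pd.isna(v) else str(int(v)) for v in df[col]]
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def _fmt_float(v) -> str:
    if pd.isna(v):
        return "NA"
    return format(float(v), ".10g")
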