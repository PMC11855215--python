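"""Allele harmonization of exposure / outcome association records.

All associations feeding an MR estimator must be expressed per copy of the
same effect allele.  Records matched by variant_id are aligned to the (first)
exposure's effect allele:

* identical allele pairs are kept;
* swapped effect/other alleles flip the other record's beta sign and eaf;
* non-palindromic pairs matching only after base complementing are strand
  corrected (then kept or flipped);
* palindromic variants (A/T, C/G) carry no strand information in their
  alleles, so orientation is inferred from allele frequencies — but only
  when both records' minor allele frequencies are below 0.42; nearer 0.5
  the frequencies are uninformative and the variant is dropped;
* irreconcilable allele pairs (or chrom/pos disagreement at a matched id)
  are dropped as mismatches.

The per-variant action log ({kept, flipped, strand_corrected,
dropped_palindromic, dropped_mismatch}) partitions the instrument list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import HarmonizationError
from .instruments import InstrumentSet
from .sumstats import SummaryStatsTable

logger = logging.getLogger(__name__)

PALINDROMIC_MAF_MAX = 0.42

KEPT = "kept"
FLIPPED = "flipped"
STRAND_CORRECTED = "strand_corrected"
DROPPED_PALINDROMIC = "dropped_palindromic"
DROPPED_MISMATCH = "dropped_mismatch"

ACTIONS = (KEPT, FLIPPED, STRAND_CORRECTED, DROPPED_PALINDROMIC, DROPPED_MISMATCH)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _is_palindromic(ea: str, oa: str) -> bool:
    return _COMPLEMENT.get(ea) == oa


def _flip_record(rec: Mapping) -> dict:
    out = dict(rec)
    out["effect_allele"], out["other_allele"] = rec["other_allele"], rec["effect_allele"]
    out["beta"] = -rec["beta"]
    eaf = rec.get("eaf", np.nan)
    out["eaf"] = 1.0 - eaf if pd.notna(eaf) else np.nan
    return out


def align_alleles(
    exposure_rec: Mapping,
    other_rec: Mapping,
    *,
    maf_ambiguous: float = PALINDROMIC_MAF_MAX,
    both_sides: bool = True,
) -> tuple[dict | None, str]:
    """Align ``other_rec`` to ``exposure_rec``'s effect allele.

    Returns (aligned record or None, action).  ``both_sides=False`` applies
    the palindromic ambiguity threshold to the exposure frequency only (the
    common tooling default); the default applies it to both records.
    """
    ea_x = str(exposure_rec["effect_allele"]).upper()
    oa_x = str(exposure_rec["other_allele"]).upper()
    ea_y = str(other_rec["effect_allele"]).upper()
    oa_y = str(other_rec["other_allele"]).upper()
    for al in (ea_x, oa_x, ea_y, oa_y):
        if al not in _COMPLEMENT:
            logger.warning("non-ACGT allele %r at %s", al, exposure_rec.get("variant_id"))
            return None, DROPPED_MISMATCH

    if _is_palindromic(ea_x, oa_x):
        if {ea_y, oa_y} != {ea_x, oa_x}:
            return None, DROPPED_MISMATCH
        eaf_x = exposure_rec.get("eaf", np.nan)
        eaf_y = other_rec.get("eaf", np.nan)
        if pd.isna(eaf_x) or pd.isna(eaf_y):
            return None, DROPPED_PALINDROMIC
        maf_x = min(eaf_x, 1.0 - eaf_x)
        maf_y = min(eaf_y, 1.0 - eaf_y)
        ambiguous = maf_x >= maf_ambiguous or (both_sides and maf_y >= maf_ambiguous)
        if ambiguous:
            return None, DROPPED_PALINDROMIC
        # allele labels carry no strand information for palindromes; the
        # stated effect-allele frequencies decide the orientation alone
        if (eaf_x < 0.5) != (eaf_y < 0.5):
            rec = _flip_record(other_rec)
            rec["effect_allele"], rec["other_allele"] = ea_x, oa_x
            return rec, FLIPPED
        rec = dict(other_rec)
        rec["effect_allele"], rec["other_allele"] = ea_x, oa_x
        return rec, KEPT

    # non-palindromic
    if (ea_y, oa_y) == (ea_x, oa_x):
        return dict(other_rec), KEPT
    if (ea_y, oa_y) == (oa_x, ea_x):
        return _flip_record(other_rec), FLIPPED
    cea, coa = _COMPLEMENT[ea_y], _COMPLEMENT[oa_y]
    if (cea, coa) == (ea_x, oa_x):
        rec = dict(other_rec)
        rec["effect_allele"], rec["other_allele"] = cea, coa
        return rec, STRAND_CORRECTED
    if (cea, coa) == (oa_x, ea_x):
        rec = _flip_record(other_rec)
        rec["effect_allele"], rec["other_allele"] = ea_x, oa_x
        return rec, STRAND_CORRECTED
    return None, DROPPED_MISMATCH


@dataclass
class HarmonizedData:
    """Aligned per-variant association matrix for MR estimation.

    ``table`` has one row per retained variant, sorted by (chrom, pos):
    columns variant_id, chrom, pos, then beta_<exposure>/se_<exposure> per
    exposure and beta_outcome/se_outcome.  ``actions`` records the fate of
    every instrument (the action counts partition the instrument list).
    """

    exposure_names: list[str]
    outcome_name: str
    outcome_type: str
    table: pd.DataFrame
    actions: pd.DataFrame  # columns: variant_id, action

    def __len__(self) -> int:
        return len(self.table)

    def gamma(self, exposure: str | int = 0) -> np.ndarray:
        name = self.exposure_names[exposure] if isinstance(exposure, int) else exposure
        return self.table[f"beta_{name}"].to_numpy(float)

    def se_gamma(self, exposure: str | int = 0) -> np.ndarray:
        name = self.exposure_names[exposure] if isinstance(exposure, int) else exposure
        return self.table[f"se_{name}"].to_numpy(float)

    @property
    def Gamma(self) -> np.ndarray:
        return self.table["beta_outcome"].to_numpy(float)

    @property
    def se_Gamma(self) -> np.ndarray:
        return self.table["se_outcome"].to_numpy(float)

    def action_counts(self) -> dict[str, int]:
        counts = self.actions["action"].value_counts().to_dict()
        return {a: int(counts.get(a, 0)) for a in ACTIONS}

    def write(self, path) -> None:
        merged = self.table.merge(self.actions, on="variant_id", how="right")
        merged.to_csv(path, sep="\t", index=False, na_rep="NA")


def _records_by_id(table: SummaryStatsTable) -> dict[str, dict]:
    return {r["variant_id"]: r for r in table.records.to_dict("records")}


def _positions_conflict(a: Mapping, b: Mapping) -> bool:
    return str(a["chrom"]) != str(b["chrom"]) or int(a["pos"]) != int(b["pos"])


def harmonize_univariable(
    exposure: SummaryStatsTable,
    outcome: SummaryStatsTable,
    instruments: InstrumentSet,
    *,
    maf_ambiguous: float = PALINDROMIC_MAF_MAX,
    both_sides: bool = True,
) -> HarmonizedData:
    """Align each instrument's outcome record to the exposure's effect allele."""
    return _harmonize([exposure], outcome, instruments, maf_ambiguous, both_sides)


def harmonize_multivariable(
    exposures: tuple[SummaryStatsTable, SummaryStatsTable],
    outcome: SummaryStatsTable,
    instruments: InstrumentSet,
    *,
    maf_ambiguous: float = PALINDROMIC_MAF_MAX,
    both_sides: bool = True,
) -> HarmonizedData:
    """Three-way harmonization anchored on the first exposure's effect allele.

    A variant is retained only if alignable across both exposures and the
    outcome; any failure drops it for all traits.
    """
    return _harmonize(list(exposures), outcome, instruments, maf_ambiguous, both_sides)


def _harmonize(
    exposures: list[SummaryStatsTable],
    outcome: SummaryStatsTable,
    instruments: InstrumentSet,
    maf_ambiguous: float,
    both_sides: bool,
) -> HarmonizedData:
    anchor = exposures[0]
    anchor_recs = _records_by_id(anchor)
    missing_anchor = [v for v in instruments.ids if v not in anchor_recs]
    if missing_anchor:
        raise HarmonizationError(
            f"instrument(s) missing from exposure table {anchor.trait_name!r}: {missing_anchor[:5]}"
        )
    other_maps = [_records_by_id(t) for t in exposures[1:]] + [_records_by_id(outcome)]
    other_names = [t.trait_name for t in exposures[1:]] + ["outcome"]

    rows, action_rows = [], []
    for vid in instruments.ids:
        x = anchor_recs[vid]
        row = {
            "variant_id": vid,
            "chrom": x["chrom"],
            "pos": x["pos"],
            f"beta_{anchor.trait_name}": x["beta"],
            f"se_{anchor.trait_name}": x["se"],
        }
        action = KEPT
        for recs, name in zip(other_maps, other_names):
            rec = recs.get(vid)
            if rec is None or _positions_conflict(x, rec):
                action = DROPPED_MISMATCH
                break
            aligned, act = align_alleles(
                x, rec, maf_ambiguous=maf_ambiguous, both_sides=both_sides
            )
            if aligned is None:
                action = act
                break
            key = "outcome" if name == "outcome" else name
            row[f"beta_{key}"] = aligned["beta"]
            row[f"se_{key}"] = aligned["se"]
            # a flip anywhere outranks "kept" in the log; a drop outranks all
            if act != KEPT and action == KEPT:
                action = act
        action_rows.append({"variant_id": vid, "action": action})
        if action in (DROPPED_MISMATCH, DROPPED_PALINDROMIC):
            continue
        rows.append(row)

    actions = pd.DataFrame(action_rows, columns=["variant_id", "action"])
    if not rows:
        raise HarmonizationError(
            f"harmonization retained zero variants "
            f"(actions: {actions['action'].value_counts().to_dict()})"
        )
    table = pd.DataFrame(rows).sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    dropped = int((actions["action"].isin([DROPPED_MISMATCH, DROPPED_PALINDROMIC])).sum())
    if dropped:
        logger.info(
            "harmonization dropped %d/%d instrument(s)", dropped, len(instruments.ids)
        )
    return HarmonizedData(
        exposure_names=[t.trait_name for t in exposures],
        outcome_name=outcome.trait_name,
        outcome_type=outcome.trait_type,
        table=table,
        actions=actions,
    )
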