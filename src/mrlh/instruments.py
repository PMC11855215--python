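"""Instrument selection: significance/frequency filters and greedy LD clumping.

Defaults follow standard two-sample MR practice: genome-wide significance
p < 5e-8, minor allele frequency > 0.01, clumping in a +/-10 Mb window at
r^2 < 0.001 against an external LD reference panel.  All thresholds are
strict inequalities.  For multivariable MR the two exposures' significant
variants are pooled and the pooled list is clumped ranking variants by their
p-value for the designated ranking exposure (here: lean mass, whose GWAS is
far smaller than the large height meta-analysis, so ranking by it avoids the
larger study monopolizing index variants).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError, NoInstrumentsError
from .panel import GenotypePanel, ld_r2
from .sumstats import SummaryStatsTable

logger = logging.getLogger(__name__)


@dataclass
class ClumpParams:
    """Filtering and clumping thresholds (all comparisons strict)."""

    p_threshold: float = 5e-8
    maf_min: float = 0.01
    window_bp: int = 10_000_000  # +/- window around the index variant
    r2_max: float = 0.001

    def __post_init__(self) -> None:
        if not (0 < self.p_threshold <= 1):
            raise ConfigError("p_threshold must lie in (0, 1]")
        if not (0 <= self.maf_min < 0.5):
            raise ConfigError("maf_min must lie in [0, 0.5)")
        if self.window_bp < 0:
            raise ConfigError("window_bp must be >= 0")
        if not (0 <= self.r2_max <= 1):
            raise ConfigError("r2_max must lie in [0, 1]")


@dataclass
class InstrumentSet:
    """Post-filter, post-clump variant list with selection provenance.

    ``provenance`` has one row per clumping candidate: variant_id, status
    ("index" or "removed"), claimed_by (index variant that removed it, "" for
    index rows) and source ("+"-joined exposures that qualified the variant).
    """

    exposures: list[str]
    ids: list[str]
    provenance: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["variant_id", "status", "claimed_by", "source"])
    )

    def __post_init__(self) -> None:
        if len(set(self.ids)) != len(self.ids):
            raise ConfigError("instrument ids must be unique")

    def __len__(self) -> int:
        return len(self.ids)

    def write(self, path) -> None:
        self.provenance.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path, exposures: list[str] | None = None) -> "InstrumentSet":
        prov = pd.read_csv(path, sep="\t", dtype={"variant_id": str}).fillna({"claimed_by": "", "source": ""})
        ids = prov.loc[prov["status"] == "index", "variant_id"].tolist()
        return cls(exposures=exposures or [], ids=ids, provenance=prov)


def filter_candidates(
    table: SummaryStatsTable,
    params: ClumpParams,
    outcome_ids: Iterable[str],
) -> SummaryStatsTable:
    """Keep genome-wide-significant, common variants available in the outcome.

    Retains records with pval < p_threshold, min(eaf, 1-eaf) > maf_min and
    variant_id present in ``outcome_ids``; row order is preserved.  Raises
    :class:`NoInstrumentsError` (naming the per-filter survivor counts) if
    nothing survives.
    """
    df = table.records
    outcome_ids = set(outcome_ids)
    sig = df["pval"].to_numpy(float) < params.p_threshold
    maf = np.minimum(df["eaf"].to_numpy(float), 1.0 - df["eaf"].to_numpy(float))
    common = maf > params.maf_min
    avail = df["variant_id"].isin(outcome_ids).to_numpy()
    keep = sig & common & avail
    if not keep.any():
        raise NoInstrumentsError(
            f"no instruments for {table.trait_name!r}: "
            f"{int(sig.sum())} significant, {int(common.sum())} MAF-passing, "
            f"{int(avail.sum())} available in outcome, 0 jointly"
        )
    out = table.subset(df.loc[keep, "variant_id"])
    logger.info(
        "%s: %d/%d candidate instruments survive filtering", table.trait_name, len(out), len(df)
    )
    return out


def _rank_order(df: pd.DataFrame, pvals: np.ndarray) -> np.ndarray:
    """Selection order: ascending p, ties broken by (chrom, pos, variant_id)."""
    order = pd.DataFrame(
        {
            "p": pvals,
            "chrom": df["chrom"].to_numpy(),
            "pos": df["pos"].to_numpy(),
            "variant_id": df["variant_id"].to_numpy(),
        }
    )
    return order.sort_values(["p", "chrom", "pos", "variant_id"], kind="mergesort").index.to_numpy()


def greedy_clump(
    candidates: SummaryStatsTable,
    panel: GenotypePanel,
    params: ClumpParams,
    rank_pvals: Mapping[str, float] | None = None,
    *,
    source: Mapping[str, str] | None = None,
    exposures: list[str] | None = None,
) -> InstrumentSet:
    """Greedy index-variant clumping against an LD reference panel.

    Repeatedly selects the unclaimed variant with the lowest ranking p-value
    as an index and removes all unclaimed variants on the same chromosome
    within +/-window_bp whose r^2 with the index is >= r2_max.  Candidates
    absent from the panel are dropped with a warning (never assumed
    independent).  ``rank_pvals``, when given, overrides the candidates' own
    p-values for ordering.
    """
    df = candidates.records
    present = df["variant_id"].apply(lambda v: v in panel).to_numpy()
    if (~present).any():
        logger.warning(
            "%s: dropping %d clumping candidate(s) absent from the LD panel",
            candidates.trait_name,
            int((~present).sum()),
        )
    df = df.loc[present].reset_index(drop=True)
    if len(df) == 0:
        raise NoInstrumentsError("no clumping candidates present in the LD panel")

    if rank_pvals is not None:
        pvals = np.array([rank_pvals.get(v, np.inf) for v in df["variant_id"]], dtype=float)
    else:
        pvals = df["pval"].to_numpy(float)

    ld = ld_r2(panel, df["variant_id"].tolist())
    chrom = df["chrom"].to_numpy()
    pos = df["pos"].to_numpy(np.int64)
    ids = df["variant_id"].to_numpy()
    order = _rank_order(df, pvals)

    unclaimed = np.ones(len(df), dtype=bool)
    status = np.array(["removed"] * len(df), dtype=object)
    claimed_by = np.array([""] * len(df), dtype=object)
    kept: list[str] = []
    for i in order:
        if not unclaimed[i]:
            continue
        unclaimed[i] = False
        status[i] = "index"
        kept.append(ids[i])
        window = (
            unclaimed
            & (chrom == chrom[i])
            & (np.abs(pos - pos[i]) <= params.window_bp)
            & (ld.r2[i] >= params.r2_max)
        )
        claimed_by[window] = ids[i]
        unclaimed[window] = False

    src = source or {}
    prov = pd.DataFrame(
        {
            "variant_id": ids,
            "status": status,
            "claimed_by": claimed_by,
            "source": [src.get(v, candidates.trait_name) for v in ids],
        }
    )
    logger.info(
        "clumping retained %d/%d candidates (window %d bp, r2 < %g)",
        len(kept),
        len(df),
        params.window_bp,
        params.r2_max,
    )
    return InstrumentSet(
        exposures=exposures or [candidates.trait_name], ids=kept, provenance=prov
    )


def select_mvmr_instruments(
    exposure_tables: tuple[SummaryStatsTable, SummaryStatsTable],
    panel: GenotypePanel,
    params: ClumpParams,
    ranking_exposure: str,
    outcome_ids: Iterable[str],
) -> InstrumentSet:
    """Pooled-then-clumped instrument selection for multivariable MR.

    Variants significant (and MAF-passing) for either exposure are pooled;
    the pool is restricted to variants with records in both exposure tables
    and the outcome; the pooled list is clumped ranking by the
    ``ranking_exposure``'s p-values.  Pool variants lacking a ranking-
    exposure record are dropped and logged.
    """
    names = [t.trait_name for t in exposure_tables]
    if ranking_exposure not in names:
        raise ConfigError(f"ranking exposure {ranking_exposure!r} not among {names}")
    outcome_ids = set(outcome_ids)

    qualifying: dict[str, set[str]] = {}
    for tbl in exposure_tables:
        df = tbl.records
        maf = np.minimum(df["eaf"].to_numpy(float), 1.0 - df["eaf"].to_numpy(float))
        keep = (df["pval"].to_numpy(float) < params.p_threshold) & (maf > params.maf_min)
        qualifying[tbl.trait_name] = set(df.loc[keep, "variant_id"])
    pooled = qualifying[names[0]] | qualifying[names[1]]
    if not pooled:
        raise NoInstrumentsError("no variants significant for either exposure")

    in_both = set(exposure_tables[0].variant_ids) & set(exposure_tables[1].variant_ids)
    usable = pooled & in_both & outcome_ids
    n_dropped = len(pooled) - len(usable)
    if n_dropped:
        logger.info(
            "MVMR pool: dropped %d/%d variant(s) missing from an exposure or the outcome",
            n_dropped,
            len(pooled),
        )
    if not usable:
        raise NoInstrumentsError("no pooled instruments available across all datasets")

    rank_tbl = exposure_tables[names.index(ranking_exposure)]
    rank_pvals = dict(zip(rank_tbl.records["variant_id"], rank_tbl.records["pval"]))
    missing_rank = sorted(v for v in usable if v not in rank_pvals)
    if missing_rank:
        logger.warning(
            "MVMR pool: dropping %d variant(s) without a %s p-value for ranking",
            len(missing_rank),
            ranking_exposure,
        )
        usable -= set(missing_rank)

    source = {
        v: "+".join(n for n in names if v in qualifying[n]) for v in usable
    }
    base = exposure_tables[0].subset([v for v in exposure_tables[0].records["variant_id"] if v in usable])
    return greedy_clump(
        base,
        panel,
        params,
        rank_pvals=rank_pvals,
        source=source,
        exposures=names,
    )
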