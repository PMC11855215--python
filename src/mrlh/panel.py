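"""Hard-call genotype panels and pairwise LD.

A :class:`GenotypePanel` is the LD reference (the stand-in for an external
haplotype panel such as 1000 Genomes Europeans): variant metadata plus a
samples x variants matrix of hard-call dosages in {0, 1, 2}, with -1 marking
missing calls.  LD is the squared Pearson correlation of dosages over samples
complete for each pair of variants; no imputation is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, MonomorphicVariantError

logger = logging.getLogger(__name__)

MISSING = -1

PANEL_META_COLUMNS = ["variant_id", "chrom", "pos", "effect_allele", "other_allele"]


@dataclass
class GenotypePanel:
    """Variant metadata plus a hard-call dosage matrix (samples x variants)."""

    variants: pd.DataFrame  # columns PANEL_META_COLUMNS, one row per variant
    genotypes: np.ndarray  # int8, shape (n_samples, n_variants), -1 = missing

    def __post_init__(self) -> None:
        missing = [c for c in PANEL_META_COLUMNS if c not in self.variants.columns]
        if missing:
            raise FormatError(f"panel metadata missing column(s): {missing}")
        self.variants = self.variants[PANEL_META_COLUMNS].reset_index(drop=True)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2 or self.genotypes.shape[1] != len(self.variants):
            raise FormatError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{len(self.variants)} variants"
            )
        self._index = pd.Index(self.variants["variant_id"])
        if self._index.has_duplicates:
            raise FormatError("duplicate variant_id in panel")

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def variant_ids(self) -> pd.Index:
        return self._index

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def call_rate(self) -> pd.Series:
        """Per-variant fraction of non-missing calls."""
        ok = (self.genotypes != MISSING).mean(axis=0)
        return pd.Series(ok, index=self._index, name="call_rate")

    def dense_float(self) -> np.ndarray:
        """Cached float32 view of the dosage matrix (complete calls only).

        Used by the association scans; raises if any call is missing, since
        the scan formulas assume complete data.
        """
        cached = getattr(self, "_f32", None)
        if cached is None:
            if (self.genotypes == MISSING).any():
                raise FormatError("dense_float requires a panel without missing calls")
            cached = self.genotypes.astype(np.float32)
            self._f32 = cached
        return cached

    def column_stats(self) -> tuple[np.ndarray, np.ndarray]:
        """Cached per-variant (sum, sum of squares) of dosages as float64."""
        cached = getattr(self, "_colstats", None)
        if cached is None:
            gsum = self.genotypes.sum(axis=0, dtype=np.int64).astype(float)
            # dosages are 0/1/2: sum(g^2) = sum(g) + 2 * #(g == 2)
            n2 = (self.genotypes == 2).sum(axis=0, dtype=np.int64).astype(float)
            cached = (gsum, gsum + 2.0 * n2)
            self._colstats = cached
        return cached

    def dosages(self, ids: Sequence[str]) -> np.ndarray:
        """Float dosage matrix for ``ids`` with NaN for missing calls."""
        locs = self._index.get_indexer(list(ids))
        if (locs < 0).any():
            absent = [i for i, l in zip(ids, locs) if l < 0]
            raise KeyError(f"variant(s) not in panel: {absent[:5]}")
        g = self.genotypes[:, locs].astype(float)
        g[g == MISSING] = np.nan
        return g


@dataclass
class LDMatrix:
    """Symmetric matrix of squared Pearson correlations between dosages."""

    ids: list
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        if self.r2.shape != (len(self.ids), len(self.ids)):
            raise FormatError("LD matrix shape does not match id list")

    def lookup(self, id_a: str, id_b: str) -> float:
        ia, ib = self.ids.index(id_a), self.ids.index(id_b)
        return float(self.r2[ia, ib])


def ld_r2(panel: GenotypePanel, ids: Sequence[str]) -> LDMatrix:
    """Pairwise r^2 between dosages, over samples complete for each pair.

    Raises :class:`MonomorphicVariantError` for any variant with zero dosage
    variance among its complete cases.
    """
    ids = list(ids)
    g = panel.dosages(ids)
    # monomorphism check on complete cases per variant
    for k, vid in enumerate(ids):
        col = g[:, k]
        col = col[~np.isnan(col)]
        if col.size == 0 or np.var(col) == 0.0:
            raise MonomorphicVariantError(vid)
    if not np.isnan(g).any():
        gc = g - g.mean(axis=0)
        denom = np.sqrt((gc**2).sum(axis=0))
        r = (gc.T @ gc) / np.outer(denom, denom)
    else:
        r = _pairwise_complete_corr(g)
    r = np.clip(r, -1.0, 1.0)
    r2 = r * r
    np.fill_diagonal(r2, 1.0)
    return LDMatrix(ids=ids, r2=r2)


def _pairwise_complete_corr(g: np.ndarray) -> np.ndarray:
    m = g.shape[1]
    r = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            mask = ~np.isnan(g[:, i]) & ~np.isnan(g[:, j])
            xi, xj = g[mask, i], g[mask, j]
            if xi.size < 2 or np.var(xi) == 0 or np.var(xj) == 0:
                rij = 0.0
            else:
                rij = float(np.corrcoef(xi, xj)[0, 1])
            r[i, j] = r[j, i] = rij
    return r


def read_genotype_panel(path) -> GenotypePanel:
    """Read a tab-delimited panel: metadata columns then one column/sample."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"], dtype={"chrom": str})
    missing = [c for c in PANEL_META_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"panel file missing column(s): {missing}")
    meta = df[PANEL_META_COLUMNS].copy()
    meta["pos"] = meta["pos"].astype(np.int64)
    sample_cols = [c for c in df.columns if c not in PANEL_META_COLUMNS]
    if not sample_cols:
        raise FormatError("panel file has no sample columns")
    geno = df[sample_cols].to_numpy(dtype=float).T  # samples x variants
    geno = np.where(np.isnan(geno), MISSING, geno)
    bad = ~np.isin(geno, (0, 1, 2, MISSING))
    if bad.any():
        raise FormatError("panel contains dosages outside {0,1,2,NA}")
    return GenotypePanel(variants=meta, genotypes=geno.astype(np.int8))


def write_genotype_panel(panel: GenotypePanel, path, sample_prefix: str = "S") -> None:
    cols = {
        f"{sample_prefix}{i + 1}": ["NA" if v == MISSING else int(v) for v in panel.genotypes[i, :]]
        for i in range(panel.n_samples)
    }
    out = pd.concat([panel.variants, pd.DataFrame(cols)], axis=1)
    out.to_csv(path, sep="\t", index=False)


def read_vcf_panel(path) -> GenotypePanel:
    """Minimal VCF reader: GT hard calls only, biallelic SNVs, no dosages.

    Requires cyvcf2.  Phasing is ignored; any genotype containing a missing
    allele becomes a missing call.
    """
    from cyvcf2 import VCF

    ids, chroms, poss, eas, oas, rows = [], [], [], [], [], []
    vcf = VCF(str(path), gts012=True)
    for var in vcf:
        if len(var.ALT) != 1:
            logger.warning("skipping multiallelic record %s", var.ID or var.POS)
            continue
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        chroms.append(str(var.CHROM))
        poss.append(int(var.POS))
        # dosage counts the ALT allele; report ALT as effect allele
        eas.append(var.ALT[0])
        oas.append(var.REF)
        gt = np.asarray(var.gt_types, dtype=np.int8)  # 0,1,2 and 3=missing
        gt[gt == 3] = MISSING
        rows.append(gt)
    if not rows:
        raise FormatError(f"{path}: no usable biallelic records")
    meta = pd.DataFrame(
        {
            "variant_id": ids,
            "chrom": chroms,
            "pos": np.asarray(poss, dtype=np.int64),
            "effect_allele": eas,
            "other_allele": oas,
        }
    )
    return GenotypePanel(variants=meta, genotypes=np.vstack(rows).T)


def write_ld_matrix(ld: LDMatrix, path) -> None:
    pd.DataFrame(ld.r2, index=ld.ids, columns=ld.ids).to_csv(path, sep="\t")


def read_ld_matrix(path) -> LDMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return LDMatrix(ids=[str(i) for i in df.index], r2=df.to_numpy(dtype=float))
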