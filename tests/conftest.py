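"""Shared fixtures and small builders for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mrlh.harmonize import HarmonizedData
from mrlh.panel import GenotypePanel
from mrlh.sumstats import CANONICAL_COLUMNS, SummaryStatsTable


def make_table(rows: list[dict], trait_name="trait", trait_type="continuous") -> SummaryStatsTable:
    """Build a SummaryStatsTable from partial row dicts (defaults filled in)."""
    full = []
    for i, row in enumerate(rows):
        base = {
            "variant_id": f"rs{i + 1}",
            "chrom": "1",
            "pos": 1000 * (i + 1),
            "effect_allele": "A",
            "other_allele": "G",
            "eaf": 0.3,
            "beta": 0.1,
            "se": 0.01,
            "pval": 1e-9,
            "n": 1000,
            "n_cases": np.nan,
            "n_controls": np.nan,
        }
        base.update(row)
        full.append(base)
    df = pd.DataFrame(full, columns=CANONICAL_COLUMNS)
    return SummaryStatsTable(trait_name=trait_name, trait_type=trait_type, records=df)


def make_panel(genotypes: np.ndarray, ids=None, chrom=None, pos=None) -> GenotypePanel:
    """Build a GenotypePanel from a samples x variants dosage array."""
    g = np.asarray(genotypes, dtype=np.int8)
    m = g.shape[1]
    meta = pd.DataFrame(
        {
            "variant_id": ids if ids is not None else [f"rs{i + 1}" for i in range(m)],
            "chrom": chrom if chrom is not None else ["1"] * m,
            "pos": pos if pos is not None else [1000 * (i + 1) for i in range(m)],
            "effect_allele": ["A"] * m,
            "other_allele": ["G"] * m,
        }
    )
    return GenotypePanel(variants=meta, genotypes=g)


def make_harmonized(
    gammas, se_g, Gammas, se_G, *, gammas2=None, se_g2=None, outcome_type="continuous"
) -> HarmonizedData:
    """Build HarmonizedData directly from association arrays."""
    j = len(gammas)
    table = pd.DataFrame(
        {
            "variant_id": [f"rs{i + 1}" for i in range(j)],
            "chrom": ["1"] * j,
            "pos": [1000 * (i + 1) for i in range(j)],
            "beta_X": np.asarray(gammas, float),
            "se_X": np.asarray(se_g, float),
            "beta_outcome": np.asarray(Gammas, float),
            "se_outcome": np.asarray(se_G, float),
        }
    )
    names = ["X"]
    if gammas2 is not None:
        table["beta_X2"] = np.asarray(gammas2, float)
        table["se_X2"] = np.asarray(se_g2, float)
        names.append("X2")
    actions = pd.DataFrame({"variant_id": table["variant_id"], "action": "kept"})
    return HarmonizedData(
        exposure_names=names,
        outcome_name="outcome",
        outcome_type=outcome_type,
        table=table,
        actions=actions,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
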