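"""Using the estimators directly on published-style summary data.

The estimators need nothing but harmonized per-variant association arrays —
no simulation.  This example types in a small harmonized table (log-odds
outcome associations, as a case-control GWAS would report) and runs every
univariable estimator plus the Wald ratio of the strongest instrument.
"""

import numpy as np
import pandas as pd

from mrlh.estimators import (
    ivw_random_effects,
    mr_egger,
    to_odds_scale,
    wald_ratio,
    weighted_median,
)
from mrlh.harmonize import HarmonizedData

gamma = np.array([0.061, 0.074, 0.049, 0.088, 0.055, 0.067, 0.092, 0.058])
se_g = np.array([0.008, 0.009, 0.007, 0.010, 0.008, 0.009, 0.011, 0.008])
Gamma = np.array([-0.015, -0.012, -0.008, -0.021, -0.011, -0.017, -0.019, -0.009])
se_G = np.array([0.006, 0.007, 0.006, 0.008, 0.006, 0.007, 0.008, 0.006])

table = pd.DataFrame(
    {
        "variant_id": [f"rs{i}" for i in range(1, 9)],
        "chrom": ["1"] * 8,
        "pos": np.arange(1, 9) * 10_000,
        "beta_exposure": gamma,
        "se_exposure": se_g,
        "beta_outcome": Gamma,
        "se_outcome": se_G,
    }
)
harm = HarmonizedData(
    exposure_names=["exposure"],
    outcome_name="disease",
    outcome_type="binary",
    table=table,
    actions=pd.DataFrame({"variant_id": table["variant_id"], "action": "kept"}),
)

strongest = int(np.argmax(np.abs(gamma / se_g)))
single = to_odds_scale(
    wald_ratio(gamma[strongest], se_g[strongest], Gamma[strongest], se_G[strongest],
               outcome_type="binary")
)
print(f"wald ratio (strongest instrument rs{strongest + 1}): "
      f"OR {single.odds_ratio:.2f} ({single.or_ci_low:.2f}-{single.or_ci_high:.2f})")

for est in (
    ivw_random_effects(harm),
    mr_egger(harm),
    weighted_median(harm, n_boot=1000, seed=7),
):
    o = to_odds_scale(est)
    extra = ""
    if est.method == "egger":
        extra = f"  intercept {est.intercept:+.4f} (p={est.intercept_p:.2f})"
    print(
        f"{est.method:<16} OR {o.odds_ratio:.2f} "
        f"({o.or_ci_low:.2f}-{o.or_ci_high:.2f}) p={o.pval:.3g}{extra}"
    )
print(
    "\nAll estimators agree on a protective direction (OR < 1 per exposure\n"
    "unit); a near-zero Egger intercept is consistent with no directional\n"
    "pleiotropy in this hand-typed table."
)
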