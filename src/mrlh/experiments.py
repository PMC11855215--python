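"""Seed-replicate simulation studies of estimator behaviour.

Each study runs the full pipeline — genotype + phenotype simulation, GWAS
scans, instrument filtering and clumping against a fresh LD panel,
harmonization, estimation — once per seed under a named scenario and returns
one row per replicate.  These studies back both the test suite and
``scripts/acceptance.py``; problem sizes are desk-scale study conditions
(see the scenario builders), with the smaller sizes noted per study.
"""

from __future__ import annotations

import logging

import pandas as pd

from . import scenarios
from .errors import MRLHError
from .estimators import (
    conditional_f,
    ivw_random_effects,
    mr_egger,
    mvmr_regression,
    weighted_median,
)
from .harmonize import harmonize_multivariable, harmonize_univariable
from .instruments import ClumpParams, filter_candidates, greedy_clump, select_mvmr_instruments
from .simulate import SimulationConfig, make_study_set

logger = logging.getLogger(__name__)

TRUE_EFFECT = 0.10  # causal effect recovered in the calibration studies


def derive_seed(base_seed: int, replicate: int) -> int:
    """Stable per-replicate sampling seed (kept below 2^31)."""
    return int((base_seed * 1_000_003 + replicate * 7_919 + 1) % (2**31 - 1))


def _config(seed: int, n: int, n_panel: int, standardize: bool) -> SimulationConfig:
    return SimulationConfig(
        n_exposure=n,
        n_exposure_large=n,
        n_outcome=n,
        n_panel=n_panel,
        seed=seed,
        standardize=standardize,
    )


def _uni_ivw(tables, panel, exposure_role, outcome_role, params):
    cands = filter_candidates(
        tables[exposure_role], params, tables[outcome_role].variant_ids
    )
    inst = greedy_clump(cands, panel, params)
    harm = harmonize_univariable(tables[exposure_role], tables[outcome_role], inst)
    return harm


def recovery_study(
    n_seeds: int = 100,
    base_seed: int = 1,
    *,
    n: int = 20_000,
    m: int = 600,
    n_panel: int = 5_000,
    effect: float = TRUE_EFFECT,
    n_boot: int = 200,
) -> pd.DataFrame:
    """Parameter recovery under the clean scenario: T -> C with known effect.

    Per seed: IVW, MR-Egger and weighted-median estimates of the lean-mass
    effect on the continuous outcome, CI coverage of the true effect, and the
    Egger intercept p-value (whose test should attain nominal size here).
    """
    model = scenarios.recovery(m=m, effect=effect)
    params = ClumpParams()
    rows = []
    for i in range(n_seeds):
        cfg = _config(derive_seed(base_seed, i), n, n_panel, standardize=False)
        study = make_study_set(cfg, model, roles=["tlm", "cognition"])
        harm = _uni_ivw(study.tables, study.panel, "tlm", "cognition", params)
        ivw = ivw_random_effects(harm)
        egger = mr_egger(harm)
        wm = weighted_median(harm, n_boot=n_boot, seed=derive_seed(base_seed, i))
        rows.append(
            {
                "seed": i,
                "n_snps": ivw.n_snps,
                "ivw_beta": ivw.beta,
                "ivw_se": ivw.se,
                "covered": ivw.ci_low <= effect <= ivw.ci_high,
                "egger_beta": egger.beta,
                "egger_intercept_p": egger.intercept_p,
                "wm_beta": wm.beta,
            }
        )
    return pd.DataFrame(rows)


def null_calibration_study(
    n_seeds: int = 200,
    base_seed: int = 2,
    *,
    n: int = 10_000,
    m: int = 300,
    n_panel: int = 3_000,
) -> pd.DataFrame:
    """Size of the IVW test under the global null (no exposure-outcome effect).

    Run at a reduced problem size (n = 10,000, m = 300) since only the test
    statistic's null distribution is at stake.
    """
    model = scenarios.null(m=m)
    params = ClumpParams()
    rows = []
    for i in range(n_seeds):
        cfg = _config(derive_seed(base_seed, i), n, n_panel, standardize=False)
        study = make_study_set(cfg, model, roles=["tlm", "cognition"])
        harm = _uni_ivw(study.tables, study.panel, "tlm", "cognition", params)
        ivw = ivw_random_effects(harm)
        z = ivw.beta / ivw.se
        rows.append({"seed": i, "z": z, "reject": abs(z) > 1.96, "n_snps": ivw.n_snps})
    return pd.DataFrame(rows)


def confounding_study(
    n_seeds: int = 50,
    base_seed: int = 3,
    *,
    n: int = 20_000,
    m: int = 600,
    n_panel: int = 5_000,
) -> pd.DataFrame:
    """The height-confounds-lean-mass scenario: attenuation and collider arms.

    Per seed, under ``paper_pattern`` (theta_T = phi_T = 0, protective
    height):

    * univariable IVW of lean mass on the continuous outcome (biased away
      from zero through the height paths of shared instruments);
    * MVMR direct effects of lean mass and height with conditional F
      (lean mass should recover ~0);
    * univariable IVW of lean mass on the binary outcome (log-odds scale);
    * the same using the residualized lean-mass GWAS (the collider arm,
      expected to reverse sign).
    """
    model = scenarios.paper_pattern(m=m)
    params = ClumpParams()
    rows = []
    roles = ["tlm", "height_0.5m", "tlm_residual", "ad", "cognition"]
    for i in range(n_seeds):
        cfg = _config(derive_seed(base_seed, i), n, n_panel, standardize=True)
        study = make_study_set(cfg, model, roles=roles)
        t, p = study.tables, study.panel

        uni_cog = ivw_random_effects(_uni_ivw(t, p, "tlm", "cognition", params))
        uni_ad = ivw_random_effects(_uni_ivw(t, p, "tlm", "ad", params))
        res_ad = ivw_random_effects(_uni_ivw(t, p, "tlm_residual", "ad", params))

        pair = (t["tlm"], t["height_0.5m"])
        inst = select_mvmr_instruments(
            pair, p, params, t["tlm"].trait_name, t["cognition"].variant_ids
        )
        harm = harmonize_multivariable(pair, t["cognition"], inst)
        mv = mvmr_regression(harm)
        rows.append(
            {
                "seed": i,
                "uni_tlm_cog_beta": uni_cog.beta,
                "uni_tlm_cog_se": uni_cog.se,
                "uni_tlm_ad_logor": uni_ad.beta,
                "res_tlm_ad_logor": res_ad.beta,
                "mvmr_tlm_beta": float(mv.beta[0]),
                "mvmr_height_beta": float(mv.beta[1]),
                "mvmr_tlm_se": float(mv.se[0]),
                "cond_f_tlm": float(mv.conditional_f[0]),
                "cond_f_height": float(mv.conditional_f[1]),
                "n_snps_mvmr": mv.n_snps,
            }
        )
    return pd.DataFrame(rows)


def pleiotropy_study(
    n_seeds: int = 50,
    base_seed: int = 4,
    *,
    n: int = 20_000,
    m: int = 600,
    n_panel: int = 5_000,
    effect: float = TRUE_EFFECT,
    n_boot: int = 200,
) -> pd.DataFrame:
    """40% directionally pleiotropic instruments: IVW vs weighted median.

    The weighted median should beat IVW in absolute bias in almost every
    replicate, since instruments carrying a majority of the weight remain
    valid.
    """
    model = scenarios.pleiotropy(m=m, effect=effect)
    params = ClumpParams()
    rows = []
    for i in range(n_seeds):
        cfg = _config(derive_seed(base_seed, i), n, n_panel, standardize=False)
        study = make_study_set(cfg, model, roles=["tlm", "cognition"])
        harm = _uni_ivw(study.tables, study.panel, "tlm", "cognition", params)
        ivw = ivw_random_effects(harm)
        wm = weighted_median(harm, n_boot=n_boot, seed=derive_seed(base_seed, i))
        rows.append(
            {
                "seed": i,
                "ivw_beta": ivw.beta,
                "wm_beta": wm.beta,
                "ivw_abs_bias": abs(ivw.beta - effect),
                "wm_abs_bias": abs(wm.beta - effect),
            }
        )
    return pd.DataFrame(rows)


def conditional_f_study(
    fracs: tuple[float, ...] = (0.0, 0.3, 0.6, 0.9),
    n_seeds: int = 12,
    base_seed: int = 5,
    *,
    n: int = 10_000,
    m: int = 300,
    n_panel: int = 3_000,
) -> pd.DataFrame:
    """Conditional F as exposures' causal variants become shared.

    For each shared fraction, MVMR instruments are selected and the
    per-exposure conditional F-statistics recorded; their means should fall
    monotonically as the fraction rises.  Run at reduced size (n = 10,000,
    m = 300).
    """
    params = ClumpParams()
    rows = []
    for frac in fracs:
        model = scenarios.shared_fraction(frac, m=m)
        for i in range(n_seeds):
            cfg = _config(derive_seed(base_seed, i), n, n_panel, standardize=True)
            study = make_study_set(cfg, model, roles=["tlm", "height_0.5m", "cognition"])
            t, p = study.tables, study.panel
            pair = (t["tlm"], t["height_0.5m"])
            try:
                inst = select_mvmr_instruments(
                    pair, p, params, t["tlm"].trait_name, t["cognition"].variant_ids
                )
                harm = harmonize_multivariable(pair, t["cognition"], inst)
                f = conditional_f(harm)
            except MRLHError as exc:  # pragma: no cover - defensive
                logger.warning("conditional-F replicate failed (frac=%s, seed=%d): %s", frac, i, exc)
                continue
            rows.append(
                {
                    "shared_frac": frac,
                    "seed": i,
                    "cond_f_tlm": float(f[0]),
                    "cond_f_height": float(f[1]),
                    "n_snps": len(harm),
                }
            )
    return pd.DataFrame(rows)
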