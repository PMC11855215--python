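"""Covariate-adjusted GWAS exposures and collider bias.

Compares univariable MR of the binary outcome on three lean-mass GWASs from
the same cohort: unadjusted, with height as a per-variant covariate, and on
lean mass residualized on height.  Because height and lean mass share a
confounder, conditioning on height (either way) injects a spurious negative
height component into each variant's adjusted lean-mass association; variants
acting through height then flip the sign of the MR estimate.
"""

from mrlh import scenarios
from mrlh.estimators import ivw_random_effects, to_odds_scale
from mrlh.harmonize import harmonize_univariable
from mrlh.instruments import ClumpParams, filter_candidates, greedy_clump
from mrlh.simulate import SimulationConfig, make_study_set

model = scenarios.paper_pattern(m=120)
config = SimulationConfig(n_exposure=16_000, n_outcome=16_000, n_panel=2000, seed=4)
roles = ["tlm", "tlm_covariate", "tlm_residual", "ad"]
study = make_study_set(config, model, roles=roles)

params = ClumpParams(p_threshold=1e-4, r2_max=0.01)
print(f"{'exposure GWAS':<16} {'n_snps':>6} {'OR':>6} {'95% CI':>14} {'p':>9}")
for role in ("tlm", "tlm_covariate", "tlm_residual"):
    table = study[role]
    cands = filter_candidates(table, params, study["ad"].variant_ids)
    inst = greedy_clump(cands, study.panel, params)
    harm = harmonize_univariable(table, study["ad"], inst)
    est = to_odds_scale(ivw_random_effects(harm))
    print(
        f"{table.trait_name:<16} {est.n_snps:>6} {est.odds_ratio:>6.2f} "
        f"{est.or_ci_low:>6.2f}-{est.or_ci_high:<7.2f} {est.pval:>9.3g}"
    )
print(
    "\nThe unadjusted exposure looks protective (OR < 1, inherited from\n"
    "height); the residualized exposure reverses to adverse (OR > 1) —\n"
    "a collider artefact of adjusting one heritable trait for another, not\n"
    "a real effect of lean mass."
)
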