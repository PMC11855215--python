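"""Multivariable MR with conditional F-statistics.

Pools lean-mass and height instruments (clumped ranking by the lean-mass
p-values), harmonizes all three datasets to a common effect allele and
estimates each exposure's direct effect on the continuous outcome jointly.
Under the simulated truth the direct lean-mass effect is zero and the direct
height effect positive, so MVMR should attenuate lean mass while height
survives — together with per-exposure conditional F-statistics measuring the
instrument signal unique to each exposure.
"""

from mrlh import scenarios
from mrlh.estimators import mvmr_regression
from mrlh.harmonize import harmonize_multivariable
from mrlh.instruments import ClumpParams, select_mvmr_instruments
from mrlh.simulate import SimulationConfig, make_study_set

model = scenarios.paper_pattern(m=120)
config = SimulationConfig(n_exposure=12_000, n_outcome=12_000, n_panel=2000, seed=3)
study = make_study_set(config, model, roles=["tlm", "height_0.5m", "cognition"])

params = ClumpParams(p_threshold=1e-4, r2_max=0.01)
pair = (study["tlm"], study["height_0.5m"])
instruments = select_mvmr_instruments(
    pair, study.panel, params, ranking_exposure="TLM",
    outcome_ids=study["cognition"].variant_ids,
)
by_source = instruments.provenance.loc[
    instruments.provenance.status == "index", "source"
].value_counts()
print(f"{len(instruments)} pooled instruments by qualifying exposure:")
print(by_source.to_string(), "\n")

harm = harmonize_multivariable(pair, study["cognition"], instruments)
est = mvmr_regression(harm)
for k, name in enumerate(est.exposures):
    flag = "  (< 10: weak!)" if est.conditional_f[k] < 10 else ""
    print(
        f"{name:<12} direct beta {est.beta[k]:+.3f} "
        f"(95% CI {est.ci_low[k]:+.3f}..{est.ci_high[k]:+.3f}) "
        f"p={est.pval[k]:.3g}  conditional F={est.conditional_f[k]:.1f}{flag}"
    )
print(
    "\nLean mass attenuates towards zero once height is modelled jointly,\n"
    "while height keeps a positive direct effect — the attenuation pattern\n"
    "that exposes height as a confounder of the lean-mass association."
)
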