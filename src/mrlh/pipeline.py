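"""End-to-end analysis arms: univariable MR, MVMR, adjusted-GWAS comparison.

An :class:`AnalysisPlan` names the datasets (either a synthetic scenario or
user-supplied summary-statistics files), the arms to run, and every
threshold; ``run_plan`` executes the arms and writes a results table, a
markdown rendering, a structured log and an echo of the effective
configuration, so a run can be reconstructed from its output directory.

Arms:

* ``univariable`` — per exposure/outcome pair: significance + MAF filter,
  greedy LD clumping, harmonization, then IVW, MR-Egger and weighted median
  (odds-scale columns added for binary outcomes);
* ``mvmr`` — pooled instrument selection ranked by the lean-mass p-values,
  three-way harmonization, regression-based MVMR with per-exposure
  conditional F-statistics, run once per height dataset;
* ``adjusted_gwas`` — univariable MR of the unadjusted, covariate-adjusted
  and residualized lean-mass GWASs against both outcomes side by side (the
  comparison that exposes collider bias from covariate-adjusted GWASs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, MRLHError
from .estimators import (
    MREstimate,
    ivw_random_effects,
    mr_egger,
    mvmr_regression,
    to_odds_scale,
    weighted_median,
)
from .harmonize import harmonize_multivariable, harmonize_univariable
from .instruments import ClumpParams, filter_candidates, greedy_clump, select_mvmr_instruments
from .panel import GenotypePanel, read_genotype_panel, read_vcf_panel
from .scenarios import dump_config
from .simulate import SimulationConfig, StudySet, TrueModel, make_study_set
from .sumstats import SummaryStatsTable, read_summary_stats

logger = logging.getLogger(__name__)

ARMS = ("univariable", "mvmr", "adjusted_gwas")
DEFAULT_METHODS = ("ivw", "egger", "weighted_median")

EXPOSURE_ROLES = ("tlm", "height_0.5m", "height_1.5m")
OUTCOME_ROLES = ("ad", "cognition")
ADJUSTED_ROLES = ("tlm", "tlm_covariate", "tlm_residual")

RESULT_COLUMNS = [
    "arm",
    "exposure",
    "outcome",
    "adjustment",
    "method",
    "n_snps",
    "beta",
    "se",
    "ci_low",
    "ci_high",
    "pval",
    "odds_ratio",
    "or_ci_low",
    "or_ci_high",
    "egger_intercept",
    "egger_intercept_p",
    "q",
    "q_df",
    "cond_f",
]


@dataclass
class AnalysisPlan:
    """Everything needed to reproduce one analysis run."""

    arms: list[str] = field(default_factory=lambda: list(ARMS))
    clump: ClumpParams = field(default_factory=ClumpParams)
    methods: tuple[str, ...] = DEFAULT_METHODS
    n_boot: int = 1000
    seed: int = 0
    # exactly one of the two dataset sources:
    scenario: tuple[TrueModel, SimulationConfig] | None = None
    files: dict[str, str] | None = None  # role -> path; "panel" -> panel path

    def __post_init__(self) -> None:
        if not self.arms:
            raise ConfigError("plan has no arms")
        unknown = [a for a in self.arms if a not in ARMS]
        if unknown:
            raise ConfigError(f"unknown arm(s) {unknown}; choose from {ARMS}")
        if (self.scenario is None) == (self.files is None):
            raise ConfigError("exactly one of scenario/files must be given")
        if self.files is not None:
            missing = [p for p in self.files.values() if not Path(p).exists()]
            if missing:
                raise ConfigError(f"plan names missing file(s): {missing}")


def _roles_for_arms(arms: list[str]) -> list[str]:
    roles: set[str] = set(OUTCOME_ROLES)
    if "univariable" in arms:
        roles |= set(EXPOSURE_ROLES)
    if "mvmr" in arms:
        roles |= {"tlm", "height_0.5m", "height_1.5m"}
    if "adjusted_gwas" in arms:
        roles |= set(ADJUSTED_ROLES)
    return sorted(roles)


def load_study(plan: AnalysisPlan) -> StudySet | tuple[dict[str, SummaryStatsTable], GenotypePanel]:
    """Materialize the plan's datasets: simulate the scenario or read files."""
    if plan.scenario is not None:
        model, config = plan.scenario
        roles = [r for r in _roles_for_arms(plan.arms) if r in config.roles]
        return make_study_set(config, model, roles=roles)
    tables: dict[str, SummaryStatsTable] = {}
    for role, path in plan.files.items():
        if role == "panel":
            continue
        tables[role] = read_summary_stats(
            path,
            trait_name=role,
            trait_type="binary" if role == "ad" else "continuous",
        )
    if "panel" not in plan.files:
        raise ConfigError("files plan must include a 'panel' entry")
    ppath = plan.files["panel"]
    reader = read_vcf_panel if str(ppath).endswith((".vcf", ".vcf.gz")) else read_genotype_panel
    panel = reader(ppath)
    return tables, panel


def _tables_panel(study) -> tuple[dict[str, SummaryStatsTable], GenotypePanel]:
    if isinstance(study, StudySet):
        return study.tables, study.panel
    return study


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, MRLHError) and not getattr(exc, "_staged", False):
                exc._staged = True
                exc.args = (f"[{name}] {exc.args[0] if exc.args else ''}",)
            return False

    return _Ctx()


def univariable_mr(
    exposure: SummaryStatsTable,
    outcome: SummaryStatsTable,
    panel: GenotypePanel,
    params: ClumpParams,
    methods: tuple[str, ...] = DEFAULT_METHODS,
    n_boot: int = 1000,
    seed: int = 0,
) -> dict[str, MREstimate]:
    """Filter, clump, harmonize and estimate for one exposure/outcome pair."""
    with _stage("filter"):
        cands = filter_candidates(exposure, params, outcome.variant_ids)
    with _stage("clump"):
        inst = greedy_clump(cands, panel, params)
    with _stage("harmonize"):
        harm = harmonize_univariable(exposure, outcome, inst)
    logger.info(
        "%s -> %s: %d instruments after clumping, %d after harmonization (%s)",
        exposure.trait_name,
        outcome.trait_name,
        len(inst),
        len(harm),
        harm.action_counts(),
    )
    out: dict[str, MREstimate] = {}
    with _stage("estimate"):
        if "ivw" in methods:
            out["ivw"] = ivw_random_effects(harm)
        if "egger" in methods:
            out["egger"] = mr_egger(harm)
        if "weighted_median" in methods:
            out["weighted_median"] = weighted_median(harm, n_boot=n_boot, seed=seed)
    if outcome.trait_type == "binary":
        out = {k: to_odds_scale(v) for k, v in out.items()}
    return out


def _estimate_row(arm, exposure, outcome, adjustment, method, est: MREstimate) -> dict:
    return {
        "arm": arm,
        "exposure": exposure,
        "outcome": outcome,
        "adjustment": adjustment,
        "method": method,
        "n_snps": est.n_snps,
        "beta": est.beta,
        "se": est.se,
        "ci_low": est.ci_low,
        "ci_high": est.ci_high,
        "pval": est.pval,
        "odds_ratio": est.odds_ratio,
        "or_ci_low": est.or_ci_low,
        "or_ci_high": est.or_ci_high,
        "egger_intercept": est.intercept,
        "egger_intercept_p": est.intercept_p,
        "q": est.q,
        "q_df": est.q_df,
        "cond_f": np.nan,
    }


def run_univariable_analysis(plan: AnalysisPlan, study=None) -> pd.DataFrame:
    """Univariable MR of every available exposure against both outcomes."""
    tables, panel = _tables_panel(study if study is not None else load_study(plan))
    rows = []
    for exp_role in EXPOSURE_ROLES:
        if exp_role not in tables:
            continue
        for out_role in OUTCOME_ROLES:
            if out_role not in tables:
                continue
            ests = univariable_mr(
                tables[exp_role],
                tables[out_role],
                panel,
                plan.clump,
                plan.methods,
                plan.n_boot,
                plan.seed,
            )
            for method, est in ests.items():
                rows.append(
                    _estimate_row("univariable", tables[exp_role].trait_name,
                                  tables[out_role].trait_name, "none", method, est)
                )
    return _finalize(rows)


def run_mvmr_analysis(plan: AnalysisPlan, study=None) -> pd.DataFrame:
    """MVMR of lean mass + height per height dataset, with conditional F."""
    tables, panel = _tables_panel(study if study is not None else load_study(plan))
    rows = []
    for height_role in ("height_0.5m", "height_1.5m"):
        if height_role not in tables or "tlm" not in tables:
            continue
        pair = (tables["tlm"], tables[height_role])
        for out_role in OUTCOME_ROLES:
            if out_role not in tables:
                continue
            outcome = tables[out_role]
            with _stage("mvmr-select"):
                inst = select_mvmr_instruments(
                    pair, panel, plan.clump, tables["tlm"].trait_name, outcome.variant_ids
                )
            with _stage("mvmr-harmonize"):
                harm = harmonize_multivariable(pair, outcome, inst)
            with _stage("mvmr-estimate"):
                est = mvmr_regression(harm)
            if outcome.trait_type == "binary":
                est = to_odds_scale(est)
            for k, exp_name in enumerate(est.exposures):
                if est.conditional_f[k] < 10:
                    logger.warning(
                        "conditional F for %s (vs %s) is %.1f < 10: potential weak-instrument bias",
                        exp_name,
                        outcome.trait_name,
                        est.conditional_f[k],
                    )
                rows.append(
                    {
                        "arm": "mvmr",
                        "exposure": exp_name,
                        "outcome": outcome.trait_name,
                        "adjustment": f"mvmr[{pair[0].trait_name}+{pair[1].trait_name}]",
                        "method": "mvmr",
                        "n_snps": est.n_snps,
                        "beta": float(est.beta[k]),
                        "se": float(est.se[k]),
                        "ci_low": float(est.ci_low[k]),
                        "ci_high": float(est.ci_high[k]),
                        "pval": float(est.pval[k]),
                        "odds_ratio": None if est.odds_ratio is None else float(est.odds_ratio[k]),
                        "or_ci_low": None if est.or_ci_low is None else float(est.or_ci_low[k]),
                        "or_ci_high": None if est.or_ci_high is None else float(est.or_ci_high[k]),
                        "egger_intercept": None,
                        "egger_intercept_p": None,
                        "q": est.q,
                        "q_df": est.q_df,
                        "cond_f": float(est.conditional_f[k]),
                    }
                )
    return _finalize(rows)


def run_adjustment_comparison(plan: AnalysisPlan, study=None) -> pd.DataFrame:
    """Univariable MR of unadjusted vs covariate vs residual lean-mass GWASs."""
    tables, panel = _tables_panel(study if study is not None else load_study(plan))
    adjustment_of = {"tlm": "none", "tlm_covariate": "covariate", "tlm_residual": "residual"}
    rows = []
    for exp_role in ADJUSTED_ROLES:
        if exp_role not in tables:
            continue
        for out_role in OUTCOME_ROLES:
            if out_role not in tables:
                continue
            ests = univariable_mr(
                tables[exp_role],
                tables[out_role],
                panel,
                plan.clump,
                plan.methods,
                plan.n_boot,
                plan.seed,
            )
            for method, est in ests.items():
                rows.append(
                    _estimate_row(
                        "adjusted_gwas",
                        tables[exp_role].trait_name,
                        tables[out_role].trait_name,
                        adjustment_of[exp_role],
                        method,
                        est,
                    )
                )
    return _finalize(rows)


_ARM_RUNNERS = {
    "univariable": run_univariable_analysis,
    "mvmr": run_mvmr_analysis,
    "adjusted_gwas": run_adjustment_comparison,
}


def _finalize(rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    return df.sort_values(
        ["arm", "exposure", "outcome", "adjustment", "method"], kind="mergesort"
    ).reset_index(drop=True)


def render_results_table(results: pd.DataFrame, fmt: str = "tsv", path=None) -> str:
    """Render results as TSV (exact values) or markdown (3 significant figures)."""
    if len(results) == 0:
        raise ConfigError("results table is empty")
    if fmt == "tsv":
        text = results.to_csv(sep="\t", index=False, na_rep="NA")
    elif fmt == "markdown":
        disp = results.copy()
        for col in disp.columns:
            if disp[col].dtype.kind in "fc":
                disp[col] = disp[col].map(lambda v: "NA" if pd.isna(v) else format(v, ".3g"))
        disp = disp.fillna("NA")
        header = "| " + " | ".join(disp.columns) + " |"
        sep = "| " + " | ".join("---" for _ in disp.columns) + " |"
        body = ["| " + " | ".join(str(v) for v in row) + " |" for row in disp.itertuples(index=False)]
        text = "\n".join([header, sep, *body]) + "\n"
    else:
        raise ConfigError(f"unknown format {fmt!r} (use 'tsv' or 'markdown')")
    if path is not None:
        Path(path).write_text(text)
    return text


def run_plan(plan: AnalysisPlan, outdir=None) -> pd.DataFrame:
    """Execute every arm of the plan; optionally write the output bundle."""
    handler = None
    root = logging.getLogger("mrlh")
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        handler = logging.FileHandler(outdir / "run.log", mode="w")
        handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
        handler.setLevel(logging.INFO)
        root.addHandler(handler)
        root.setLevel(min(root.level or logging.INFO, logging.INFO))
    try:
        study = load_study(plan)
        parts = [_ARM_RUNNERS[arm](plan, study=study) for arm in plan.arms]
        results = _finalize(pd.concat(parts, ignore_index=True).to_dict("records"))
        if outdir is not None:
            render_results_table(results, "tsv", outdir / "results.tsv")
            render_results_table(results, "markdown", outdir / "results.md")
            if plan.scenario is not None:
                dump_config(plan.scenario[1], outdir / "config-echo.yaml")
        return results
    finally:
        if handler is not None:
            root.removeHandler(handler)
            handler.close()
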