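"""Synthetic GWAS generation under an explicit causal structural model.

The generative model mirrors the body-composition setting the package is
aimed at: a height-like trait H, a lean-mass-like trait T causally downstream
of H, a continuous cognitive outcome C and a binary liability outcome (AD),
with an unmeasured confounder U:

    H  = sum_j a_j G_j            + delta_H * U + e_H
    T  = lambda * H + sum_j b_j G_j + delta_T * U + e_T
    C  = theta_H * H + theta_T * T + sum_j c_j G_j + delta_C * U + e_C
    AD ~ Bernoulli(logistic(alpha + phi_H * H + phi_T * T
                            + sum_j d_j G_j + delta_AD * U))

``a``/``b`` are per-variant effects on height / directly on lean mass
(variants may carry both — shared loci are what drives the genetic
correlation between the two traits); ``c``/``d`` are direct (pleiotropic)
variant effects on the outcomes, zero unless a pleiotropy scenario asks for
them.  The binary outcome uses a logistic link so per-variant log-odds
effects are exactly recoverable.

Genotypes are drawn by a Gaussian copula: within an LD block the latent
haplotype normals follow an AR(1) correlation with parameter ``rho``
(adjacent variants), blocks are mutually independent, and each variant's two
haplotype indicators give a Hardy-Weinberg Binomial(2, maf) dosage.  The
realized dosage correlation is somewhat attenuated relative to ``rho``
(threshold correlation of a bivariate normal), which is documented rather
than corrected.

Association scans reproduce what a GWAS pipeline would do: per-variant OLS
(optionally with a covariate, or on a pre-residualized phenotype) for
continuous traits, per-variant logistic ML with Wald SEs for binary traits.
Covariates such as age/sex/PCs of real GWASs are not simulated; exogenous
noise absorbs them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError
from .panel import GenotypePanel
from .sumstats import SummaryStatsTable, _empty_frame

logger = logging.getLogger(__name__)

ADJUSTMENT_MODES = ("none", "covariate", "residual")

# allele pairs cycled across variants; the last two are palindromic so the
# harmonization machinery sees realistic strand-ambiguous variants
_ALLELE_CYCLE = [("A", "G"), ("C", "T"), ("A", "C"), ("T", "G"), ("A", "T"), ("C", "G")]


@dataclass
class TrueModel:
    """The generative causal structure (see module docstring for equations)."""

    maf: np.ndarray  # (m,) minor/effect allele frequencies, in (0, 0.5]
    a: np.ndarray  # per-variant effects on H
    b: np.ndarray  # per-variant direct effects on T
    lam: float = 0.0  # causal effect of H on T
    delta_h: float = 0.0  # confounder loading on H
    delta_t: float = 0.0  # confounder loading on T
    delta_c: float = 0.0  # confounder loading on C
    delta_ad: float = 0.0  # confounder loading on AD liability
    theta_h: float = 0.0  # direct effect of H on C
    theta_t: float = 0.0  # direct effect of T on C
    phi_h: float = 0.0  # direct log-odds effect of H on AD
    phi_t: float = 0.0  # direct log-odds effect of T on AD
    alpha: float = -1.0  # liability intercept (controls case fraction)
    sigma_h: float = 1.0
    sigma_t: float = 1.0
    sigma_c: float = 1.0
    c: np.ndarray | None = None  # direct pleiotropic effects on C
    d: np.ndarray | None = None  # direct pleiotropic effects on AD liability

    def __post_init__(self) -> None:
        self.maf = np.asarray(self.maf, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        m = self.m
        if not (self.a.shape == self.b.shape == (m,)):
            raise ConfigError("maf, a, b must have equal length")
        if np.any(self.maf <= 0) or np.any(self.maf >= 1):
            raise ConfigError("maf must lie strictly in (0,1)")
        for name in ("sigma_h", "sigma_t", "sigma_c"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        self.c = np.zeros(m) if self.c is None else np.asarray(self.c, dtype=float)
        self.d = np.zeros(m) if self.d is None else np.asarray(self.d, dtype=float)
        if self.c.shape != (m,) or self.d.shape != (m,):
            raise ConfigError("c and d must have length m")

    @property
    def m(self) -> int:
        return self.maf.shape[0]


#: default cohort roles -> cohort label; roles sharing a label share samples.
#: Exposure scans may overlap each other but never the outcome cohorts
#: (two-sample design).
DEFAULT_ROLES: dict[str, str] = {
    "tlm": "exposure",
    "height_0.5m": "exposure",
    "tlm_covariate": "exposure",
    "tlm_residual": "exposure",
    "height_1.5m": "exposure_large",
    "ad": "outcome_ad",
    "cognition": "outcome_cog",
}

_EXPOSURE_ROLES = {"tlm", "height_0.5m", "tlm_covariate", "tlm_residual", "height_1.5m"}
_OUTCOME_ROLES = {"ad", "cognition"}

# stable per-cohort stream indices so a cohort's draw does not depend on
# which roles were requested
_COHORT_STREAM = {
    "exposure": 1,
    "exposure_large": 2,
    "outcome_ad": 3,
    "outcome_cog": 4,
    "panel": 5,
}


@dataclass
class SimulationConfig:
    """Sampling parameters: cohort sizes, overlap plan, LD structure, seed.

    Defaults are the package's desk-scale study conditions: 20,000 samples
    per cohort (the larger height cohort 3x that, echoing the real
    0.5M-vs-1.5M sample-size contrast), 600 variants in LD blocks of 10 with
    within-block latent correlation 0.4, and an LD reference panel of 5,000
    independent samples.
    """

    n_exposure: int = 20_000
    n_exposure_large: int = 60_000
    n_outcome: int = 20_000
    n_panel: int = 5_000
    block_size: int = 10
    rho: float = 0.4
    seed: int = 0
    standardize: bool = True
    roles: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_ROLES))
    role_n: Mapping[str, int] = field(default_factory=dict)  # optional per-role subset sizes

    def __post_init__(self) -> None:
        for name in ("n_exposure", "n_exposure_large", "n_outcome", "n_panel"):
            if getattr(self, name) < 100:
                raise ConfigError(f"{name} must be >= 100")
        if not (0 <= self.rho < 1):
            raise ConfigError("rho must lie in [0, 1)")
        if self.block_size < 1:
            raise ConfigError("block_size must be >= 1")
        unknown = set(self.roles) - (_EXPOSURE_ROLES | _OUTCOME_ROLES)
        if unknown:
            raise ConfigError(f"unknown role(s): {sorted(unknown)}")
        exp_cohorts = {c for r, c in self.roles.items() if r in _EXPOSURE_ROLES}
        out_cohorts = {c for r, c in self.roles.items() if r in _OUTCOME_ROLES}
        if exp_cohorts & out_cohorts:
            raise ConfigError(
                "overlap plan assigns an exposure role and an outcome role to the same "
                f"cohort: {sorted(exp_cohorts & out_cohorts)} (two-sample design forbids this)"
            )

    def cohort_n(self, cohort: str) -> int:
        sizes = {
            "exposure": self.n_exposure,
            "exposure_large": self.n_exposure_large,
            "outcome_ad": self.n_outcome,
            "outcome_cog": self.n_outcome,
            "panel": self.n_panel,
        }
        if cohort not in sizes:
            raise ConfigError(f"unknown cohort {cohort!r}")
        return sizes[cohort]


@dataclass
class Phenotypes:
    """Per-sample trait values drawn from the structural model."""

    h: np.ndarray
    t: np.ndarray
    c: np.ndarray
    ad: np.ndarray
    u: np.ndarray


def _variant_metadata(m: int, block_size: int, blocks_per_chrom: int = 3) -> pd.DataFrame:
    """Deterministic variant ids, positions and alleles for a simulated panel."""
    j = np.arange(m)
    block = j // block_size
    offset = j % block_size
    chrom = (block // blocks_per_chrom + 1).astype(int)
    pos = (block % blocks_per_chrom) * 1_500_000 + offset * 1_000 + 1
    pairs = [_ALLELE_CYCLE[i % len(_ALLELE_CYCLE)] for i in j]
    return pd.DataFrame(
        {
            "variant_id": [f"rs{i + 1}" for i in j],
            "chrom": chrom.astype(str),
            "pos": pos.astype(np.int64),
            "effect_allele": [p[0] for p in pairs],
            "other_allele": [p[1] for p in pairs],
        }
    )


def simulate_genotypes(
    config: SimulationConfig,
    model: TrueModel,
    *,
    n: int | None = None,
    rng: np.random.Generator | None = None,
) -> GenotypePanel:
    """Draw a hard-call genotype panel under the block-AR(1) Gaussian copula.

    Marginals are Hardy-Weinberg at each variant's MAF; within a block the
    latent haplotype normals have AR(1) correlation ``rho``; blocks are
    independent.  The reported effect allele is the minor allele whose
    frequency is ``model.maf``.
    """
    n = int(n if n is not None else config.n_exposure)
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    m, bs = model.m, config.block_size
    thresholds = stats.norm.ppf(model.maf)
    geno = np.empty((n, m), dtype=np.int8)
    for start in range(0, m, bs):
        stop = min(start + bs, m)
        width = stop - start
        if config.rho > 0 and width > 1:
            lags = np.abs(np.subtract.outer(np.arange(width), np.arange(width)))
            corr = config.rho**lags
            chol = np.linalg.cholesky(corr).astype(np.float32)
            z1 = rng.standard_normal((n, width), dtype=np.float32) @ chol.T
            z2 = rng.standard_normal((n, width), dtype=np.float32) @ chol.T
        else:
            z1 = rng.standard_normal((n, width), dtype=np.float32)
            z2 = rng.standard_normal((n, width), dtype=np.float32)
        thr = thresholds[start:stop].astype(np.float32)
        geno[:, start:stop] = (z1 < thr).astype(np.int8) + (z2 < thr).astype(np.int8)
    return GenotypePanel(variants=_variant_metadata(m, bs), genotypes=geno)


def simulate_phenotypes(
    panel: GenotypePanel,
    model: TrueModel,
    seed: int | np.random.Generator = 0,
) -> Phenotypes:
    """Draw per-sample H, T, C and AD from the structural equations."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    g = panel.dense_float()
    n = g.shape[0]

    def gdot(v: np.ndarray) -> np.ndarray:
        if not np.any(v):
            return np.zeros(n)
        return (g @ v.astype(np.float32)).astype(np.float64)

    u = rng.standard_normal(n)
    h = gdot(model.a) + model.delta_h * u + model.sigma_h * rng.standard_normal(n)
    t = (
        model.lam * h
        + gdot(model.b)
        + model.delta_t * u
        + model.sigma_t * rng.standard_normal(n)
    )
    c = (
        model.theta_h * h
        + model.theta_t * t
        + gdot(model.c)
        + model.delta_c * u
        + model.sigma_c * rng.standard_normal(n)
    )
    liability = model.alpha + model.phi_h * h + model.phi_t * t + gdot(model.d) + model.delta_ad * u
    p = 1.0 / (1.0 + np.exp(-liability))
    ad = (rng.random(n) < p).astype(np.int8)
    return Phenotypes(h=h, t=t, c=c, ad=ad, u=u)


# ---------------------------------------------------------------------------
# association scans


def _linear_scan(panel: GenotypePanel, y: np.ndarray, x: np.ndarray | None) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-variant OLS of y on dosage (optionally + covariate x).

    Works entirely through per-variant sufficient statistics (centered
    cross-products obtained from one matrix-vector product per phenotype), so
    no samples x variants temporary is formed.  With a covariate the fit uses
    Frisch-Waugh-Lovell — y and each dosage column residualized on (1, x) —
    with n - 3 error df.
    """
    g = panel.dense_float()
    n = g.shape[0]
    gsum, gsq = panel.column_stats()
    gmean = gsum / n
    sgg = gsq - n * gmean**2  # centered sum of squares per variant
    yc = y - y.mean()
    syy = float(yc @ yc)
    sgy = (yc.astype(np.float32) @ g).astype(np.float64)  # == sum (g - gmean) * yc
    df = n - 2
    if x is not None:
        xc = x - x.mean()
        sxx = float(xc @ xc)
        sxy = float(xc @ yc)
        sgx = (xc.astype(np.float32) @ g).astype(np.float64)
        sgy = sgy - sgx * sxy / sxx
        sgg = sgg - sgx**2 / sxx
        syy = syy - sxy**2 / sxx
        df = n - 3
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = sgy / sgg
        rss = syy - beta * sgy
        se = np.sqrt(np.maximum(rss, 0.0) / df / sgg)
    return beta, se


def _logistic_scan(
    g: np.ndarray,
    y: np.ndarray,
    x: np.ndarray | None,
    *,
    max_iter: int = 30,
    tol: float = 1e-6,
    chunk: int = 150,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-variant logistic ML (Newton/IRLS), Wald SEs.

    Returns (beta, se, ok) where ok flags converged, non-separated fits.
    The per-variant design is [1, dosage] or [1, dosage, covariate].
    Elementwise work is float32; score/information sums accumulate float64.
    """
    n, m = g.shape
    g = g.astype(np.float32, copy=False)
    yf = y.astype(np.float32)
    p_dim = 2 if x is None else 3
    beta_out = np.full(m, np.nan)
    se_out = np.full(m, np.nan)
    ok_out = np.zeros(m, dtype=bool)
    ybar = float(np.clip(y.mean(), 1e-12, 1 - 1e-12))
    b0_init = np.log(ybar / (1 - ybar))
    for start in range(0, m, chunk):
        stop = min(start + chunk, m)
        gch = g[:, start:stop]
        k = stop - start
        # columns of the design beyond the intercept
        cols = [gch] if x is None else [gch, np.broadcast_to(x.astype(np.float32)[:, None], (n, k))]
        params = np.zeros((k, p_dim))
        params[:, 0] = b0_init
        cov_diag = np.full(k, np.nan)
        for _ in range(max_iter):
            p32 = params.astype(np.float32)
            eta = p32[:, 0][None, :] + cols[0] * p32[:, 1][None, :]
            if p_dim == 3:
                eta = eta + cols[1] * p32[:, 2][None, :]
            mu = 1.0 / (1.0 + np.exp(-eta))
            w = mu * (1.0 - mu)
            resid = yf[:, None] - mu
            # score vector and Hessian per variant (float64 accumulation)
            score = np.empty((k, p_dim))
            score[:, 0] = resid.sum(axis=0, dtype=np.float64)
            score[:, 1] = (cols[0] * resid).sum(axis=0, dtype=np.float64)
            info = np.empty((k, p_dim, p_dim))
            info[:, 0, 0] = w.sum(axis=0, dtype=np.float64)
            info[:, 0, 1] = info[:, 1, 0] = (w * cols[0]).sum(axis=0, dtype=np.float64)
            info[:, 1, 1] = (w * cols[0] ** 2).sum(axis=0, dtype=np.float64)
            if p_dim == 3:
                score[:, 2] = (cols[1] * resid).sum(axis=0, dtype=np.float64)
                info[:, 0, 2] = info[:, 2, 0] = (w * cols[1]).sum(axis=0, dtype=np.float64)
                info[:, 1, 2] = info[:, 2, 1] = (w * cols[0] * cols[1]).sum(axis=0, dtype=np.float64)
                info[:, 2, 2] = (w * cols[1] ** 2).sum(axis=0, dtype=np.float64)
            try:
                step = np.linalg.solve(info, score[:, :, None])[:, :, 0]
            except np.linalg.LinAlgError:
                break
            params = params + step
            if np.nanmax(np.abs(step)) < tol:
                break
            if not np.isfinite(params).all():
                break
        finite = np.isfinite(params).all(axis=1)
        sane = finite & (np.abs(params[:, 1]) < 15)
        if sane.any():
            try:
                covs = np.linalg.inv(info[sane])
                cov_diag[sane] = covs[:, 1, 1]
            except np.linalg.LinAlgError:
                sane = np.zeros(k, dtype=bool)
        good = sane & (cov_diag > 0)
        beta_out[start:stop][good] = params[good, 1]
        se_out[start:stop][good] = np.sqrt(cov_diag[good])
        ok_out[start:stop] = good
    return beta_out, se_out, ok_out


def association_scan(
    panel: GenotypePanel,
    phenotype: np.ndarray,
    *,
    trait_type: str = "continuous",
    trait_name: str = "trait",
    adjustment: str = "none",
    adjust_on: np.ndarray | None = None,
    standardize: bool = False,
    seed: int | None = None,  # accepted for interface symmetry; scans are deterministic
) -> SummaryStatsTable:
    """Per-variant association scan of ``phenotype`` on the panel's dosages.

    ``adjustment="covariate"`` enters ``adjust_on`` into every per-variant
    model; ``adjustment="residual"`` first residualizes the phenotype on
    ``adjust_on`` over the full sample and then scans unadjusted.  With
    ``standardize=True`` (continuous traits) betas and SEs are divided by the
    sample SD of the raw phenotype — matching the convention of adjusted lean
    mass GWASs, which standardize by the SD of the unadjusted trait.
    """
    if adjustment not in ADJUSTMENT_MODES:
        raise ConfigError(f"unknown adjustment mode {adjustment!r}")
    if (adjustment != "none") != (adjust_on is not None):
        raise ConfigError("adjust_on is required iff adjustment != 'none'")
    y = np.asarray(phenotype, dtype=float)
    if y.shape[0] != panel.n_samples:
        raise ConfigError("phenotype length does not match panel samples")
    raw_sd = float(np.std(y, ddof=1))
    covariate = None
    if adjustment == "residual":
        x = np.asarray(adjust_on, dtype=float)
        xc = x - x.mean()
        y = y - y.mean() - xc * (xc @ (y - y.mean())) / float(xc @ xc)
    elif adjustment == "covariate":
        covariate = np.asarray(adjust_on, dtype=float)

    dropped: list[str] = []
    if trait_type == "continuous":
        beta, se = _linear_scan(panel, y, covariate)
        ok = np.isfinite(beta) & np.isfinite(se) & (se > 0)
        if standardize:
            beta, se = beta / raw_sd, se / raw_sd
        n_col = float(panel.n_samples)
        n_cases = n_controls = np.nan
    elif trait_type == "binary":
        yb = y.astype(np.int8)
        beta, se, ok = _logistic_scan(panel.dense_float(), yb, covariate)
        dropped = [vid for vid, o in zip(panel.variant_ids, ok) if not o]
        if dropped:
            logger.warning(
                "%s: dropped %d variant(s) with separated/non-converged logistic fits: %s",
                trait_name,
                len(dropped),
                dropped[:5],
            )
        n_col = float(panel.n_samples)
        n_cases, n_controls = float(yb.sum()), float((1 - yb).sum())
    else:
        raise ConfigError(f"unknown trait_type {trait_type!r}")

    with np.errstate(invalid="ignore", divide="ignore"):
        z = beta / se
    pval = 2.0 * stats.norm.sf(np.abs(z))
    pval = np.maximum(pval, 5e-324)  # keep p strictly positive
    eaf = panel.column_stats()[0] / (2.0 * panel.n_samples)
    df = panel.variants.copy()
    df["eaf"] = eaf
    df["beta"] = beta
    df["se"] = se
    df["pval"] = pval
    df["n"] = n_col
    df["n_cases"] = n_cases
    df["n_controls"] = n_controls
    df = df.loc[ok & (df["eaf"] > 0) & (df["eaf"] < 1)].reset_index(drop=True)
    if len(df) == 0:
        df = _empty_frame()
    return SummaryStatsTable(trait_name=trait_name, trait_type=trait_type, records=df)


# ---------------------------------------------------------------------------
# study sets


@dataclass
class StudySet:
    """A named collection of GWAS tables plus the LD reference panel."""

    tables: dict[str, SummaryStatsTable]
    panel: GenotypePanel
    config: SimulationConfig
    model: TrueModel

    def __getitem__(self, role: str) -> SummaryStatsTable:
        return self.tables[role]


def _cohort_rng(config: SimulationConfig, cohort: str) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), _COHORT_STREAM[cohort]])


def make_study_set(
    config: SimulationConfig,
    model: TrueModel,
    roles: Iterable[str] | None = None,
) -> StudySet:
    """Generate the study's GWAS tables plus an LD reference panel.

    Default roles mirror the real dataset roster: a lean mass GWAS, two
    height GWASs of different sample size, a binary (AD) and a continuous
    (cognition) outcome GWAS on non-overlapping cohorts, and covariate- and
    residual-adjusted lean mass GWASs on the lean-mass cohort.  Passing a
    subset of roles skips the unneeded cohorts; draws are seeded per cohort,
    so a role's table is identical whichever subset requested it.
    """
    requested = list(roles) if roles is not None else list(config.roles)
    unknown = [r for r in requested if r not in config.roles]
    if unknown:
        raise ConfigError(f"role(s) not in the overlap plan: {unknown}")
    cohorts_needed = sorted({config.roles[r] for r in requested})

    sims: dict[str, tuple[GenotypePanel, Phenotypes]] = {}
    for cohort in cohorts_needed:
        rng = _cohort_rng(config, cohort)
        pnl = simulate_genotypes(config, model, n=config.cohort_n(cohort), rng=rng)
        sims[cohort] = (pnl, simulate_phenotypes(pnl, model, rng))

    def cohort_data(role: str) -> tuple[GenotypePanel, Phenotypes]:
        pnl, phen = sims[config.roles[role]]
        n_use = config.role_n.get(role)
        if n_use is None:
            return pnl, phen
        if n_use > pnl.n_samples:
            raise ConfigError(
                f"role {role!r} requests {n_use} samples but cohort "
                f"{config.roles[role]!r} has only {pnl.n_samples}"
            )
        sub = GenotypePanel(variants=pnl.variants, genotypes=pnl.genotypes[:n_use])
        phen_sub = Phenotypes(
            h=phen.h[:n_use], t=phen.t[:n_use], c=phen.c[:n_use], ad=phen.ad[:n_use], u=phen.u[:n_use]
        )
        return sub, phen_sub

    std = config.standardize
    tables: dict[str, SummaryStatsTable] = {}
    for role in requested:
        pnl, phen = cohort_data(role)
        if role == "tlm":
            tables[role] = association_scan(
                pnl, phen.t, trait_name="TLM", standardize=std
            )
        elif role == "height_0.5m":
            tables[role] = association_scan(
                pnl, phen.h, trait_name="height_0.5M", standardize=std
            )
        elif role == "height_1.5m":
            tables[role] = association_scan(
                pnl, phen.h, trait_name="height_1.5M", standardize=std
            )
        elif role == "tlm_covariate":
            tables[role] = association_scan(
                pnl,
                phen.t,
                trait_name="TLM_covariate",
                adjustment="covariate",
                adjust_on=phen.h,
                standardize=std,
            )
        elif role == "tlm_residual":
            tables[role] = association_scan(
                pnl,
                phen.t,
                trait_name="TLM_residual",
                adjustment="residual",
                adjust_on=phen.h,
                standardize=std,
            )
        elif role == "ad":
            tables[role] = association_scan(pnl, phen.ad.astype(float), trait_type="binary", trait_name="AD")
        elif role == "cognition":
            tables[role] = association_scan(
                pnl, phen.c, trait_name="cognition", standardize=std
            )
    ld_panel = simulate_genotypes(config, model, n=config.n_panel, rng=_cohort_rng(config, "panel"))
    return StudySet(tables=tables, panel=ld_panel, config=config, model=model)


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    """Copy of ``config`` with a new seed (convenience for replicate studies)."""
    return replace(config, seed=int(seed))
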