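"""Summary-data MR estimators and diagnostics.

Implements the standard two-sample toolkit from first principles on the
harmonized (gamma_hat, Gamma_hat) arrays:

* Wald ratio with first-order (optionally second-order) delta-method SE;
* random-effects IVW: weighted zero-intercept regression of Gamma on gamma
  with weights 1/se(Gamma)^2 and multiplicative overdispersion
  sigma_hat = max(1, sqrt(Q/df)) (under-dispersion floored at 1);
* MR-Egger: the same regression with a free intercept after orienting every
  variant to a positive exposure association; the intercept estimates
  average directional pleiotropy;
* weighted median with a parametric bootstrap SE;
* regression-based multivariable MR (weighted multiple regression of Gamma
  on the K exposure association vectors, no intercept) with per-exposure
  conditional F-statistics computed from the summary-data Q construction,
  F_k = Q_k / (J - K + 1), ignoring cross-exposure sampling covariance
  (limitation recorded in the estimate metadata);
* odds-scale conversion for binary outcomes.

Throughout: 95% CIs use the fixed 1.96 normal multiplier and p-values are
two-sided normal — the summary-data convention.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .errors import CollinearityError, EstimatorInputError, UndefinedRatioError
from .harmonize import HarmonizedData

Z95 = 1.96


def _p_two_sided(beta: float, se: float) -> float:
    return float(2.0 * stats.norm.sf(abs(beta) / se)) if se > 0 else float("nan")


@dataclass
class MREstimate:
    """A univariable causal-effect estimate (per exposure SD / unit)."""

    method: str
    beta: float
    se: float
    n_snps: int
    outcome_type: str = "continuous"
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None
    q: float | None = None
    q_df: int | None = None
    odds_ratio: float | None = None
    or_ci_low: float | None = None
    or_ci_high: float | None = None
    notes: str = ""

    @property
    def ci_low(self) -> float:
        return self.beta - Z95 * self.se

    @property
    def ci_high(self) -> float:
        return self.beta + Z95 * self.se

    @property
    def pval(self) -> float:
        return _p_two_sided(self.beta, self.se)


@dataclass
class MVMREstimate:
    """Per-exposure direct-effect estimates from multivariable MR."""

    exposures: list[str]
    beta: np.ndarray
    se: np.ndarray
    n_snps: int
    conditional_f: np.ndarray
    q: float
    q_df: int
    outcome_type: str = "continuous"
    notes: str = "conditional F from the summary-data Q construction, no cross-exposure covariance"
    odds_ratio: np.ndarray | None = None
    or_ci_low: np.ndarray | None = None
    or_ci_high: np.ndarray | None = None

    @property
    def ci_low(self) -> np.ndarray:
        return self.beta - Z95 * self.se

    @property
    def ci_high(self) -> np.ndarray:
        return self.beta + Z95 * self.se

    @property
    def pval(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.beta) / self.se)


@dataclass
class HeterogeneityStats:
    """Cochran's Q with its df and the multiplicative dispersion scale."""

    q: float
    df: int

    @property
    def sigma(self) -> float:
        if self.df <= 0:
            return 1.0
        return max(1.0, float(np.sqrt(self.q / self.df)))


def wald_ratio(
    gamma: float,
    se_gamma: float,
    Gamma: float,
    se_Gamma: float,
    *,
    outcome_type: str = "continuous",
    second_order: bool = False,
) -> MREstimate:
    """Single-instrument ratio estimate Gamma/gamma with delta-method SE."""
    if gamma == 0:
        raise UndefinedRatioError("Wald ratio undefined: exposure association is zero")
    beta = Gamma / gamma
    se = se_Gamma / abs(gamma)
    if second_order:
        se = float(np.sqrt(se_Gamma**2 / gamma**2 + Gamma**2 * se_gamma**2 / gamma**4))
    return MREstimate(
        method="wald_ratio", beta=float(beta), se=float(se), n_snps=1, outcome_type=outcome_type
    )


def ivw_random_effects(data: HarmonizedData) -> MREstimate:
    """Multiplicative random-effects IVW (zero-intercept weighted regression)."""
    g, G, seG = data.gamma(0), data.Gamma, data.se_Gamma
    j = g.shape[0]
    if j < 2:
        raise EstimatorInputError("IVW needs >= 2 variants; use wald_ratio for a single instrument")
    w = 1.0 / seG**2
    swg2 = float(np.sum(w * g * g))
    beta = float(np.sum(w * g * G) / swg2)
    het = HeterogeneityStats(q=float(np.sum(w * (G - beta * g) ** 2)), df=j - 1)
    se = het.sigma / np.sqrt(swg2)
    return MREstimate(
        method="ivw",
        beta=beta,
        se=float(se),
        n_snps=j,
        outcome_type=data.outcome_type,
        q=het.q,
        q_df=het.df,
    )


def mr_egger(data: HarmonizedData) -> MREstimate:
    """MR-Egger regression; the intercept estimates directional pleiotropy."""
    g, G, seG = data.gamma(0), data.Gamma, data.se_Gamma
    j = g.shape[0]
    if j < 3:
        raise EstimatorInputError("MR-Egger needs >= 3 variants")
    # orient all exposure associations positive (estimate is invariant to
    # joint sign flips; the intercept is not, hence the convention)
    sign = np.where(g < 0, -1.0, 1.0)
    g, G = g * sign, G * sign
    w = 1.0 / seG**2
    X = np.column_stack([np.ones(j), g])
    xtwx = X.T @ (w[:, None] * X)
    xtwy = X.T @ (w * G)
    try:
        coef = np.linalg.solve(xtwx, xtwy)
    except np.linalg.LinAlgError as exc:
        raise CollinearityError("Egger design is singular") from exc
    resid = G - X @ coef
    het = HeterogeneityStats(q=float(np.sum(w * resid**2)), df=j - 2)
    cov = het.sigma**2 * np.linalg.inv(xtwx)
    se_int, se_slope = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
    return MREstimate(
        method="egger",
        beta=float(coef[1]),
        se=se_slope,
        n_snps=j,
        outcome_type=data.outcome_type,
        intercept=float(coef[0]),
        intercept_se=se_int,
        intercept_p=_p_two_sided(float(coef[0]), se_int),
        q=het.q,
        q_df=het.df,
    )


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios, kind="stable")
    r, w = ratios[order], weights[order]
    w = w / w.sum()
    cum = np.cumsum(w) - 0.5 * w  # cumulative midpoints
    return float(np.interp(0.5, cum, r))


def weighted_median(data: HarmonizedData, n_boot: int = 1000, seed: int = 0) -> MREstimate:
    """Weighted median of the per-variant ratio estimates.

    Consistent as long as instruments carrying >= 50% of the weight are
    valid.  Weights are inverse-variance weights of the first-order ratio
    SEs; the SE is the SD of the estimator over ``n_boot`` parametric
    bootstrap replicates drawn from the per-variant sampling distributions.
    """
    g, seg, G, seG = data.gamma(0), data.se_gamma(0), data.Gamma, data.se_Gamma
    j = g.shape[0]
    if j < 3:
        raise EstimatorInputError("weighted median needs >= 3 variants")
    if n_boot < 100:
        raise EstimatorInputError("n_boot must be >= 100")
    ratios = G / g
    weights = (g / seG) ** 2
    est = _weighted_median(ratios, weights)
    rng = np.random.default_rng(seed)
    g_star = rng.normal(g, seg, size=(n_boot, j))
    G_star = rng.normal(G, seG, size=(n_boot, j))
    boots = np.empty(n_boot)
    for b in range(n_boot):
        gb = g_star[b]
        gb = np.where(gb == 0.0, np.finfo(float).tiny, gb)
        boots[b] = _weighted_median(G_star[b] / gb, (gb / seG) ** 2)
    return MREstimate(
        method="weighted_median",
        beta=est,
        se=float(np.std(boots, ddof=1)),
        n_snps=j,
        outcome_type=data.outcome_type,
    )


def _weighted_design(data: HarmonizedData) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    X = np.column_stack([data.gamma(k) for k in range(len(data.exposure_names))])
    return X, data.Gamma, 1.0 / data.se_Gamma**2


def mvmr_regression(data: HarmonizedData) -> MVMREstimate:
    """Weighted multiple regression of Gamma on the exposure associations."""
    X, G, w = _weighted_design(data)
    j, k = X.shape
    if j < k + 1:
        raise EstimatorInputError(f"MVMR needs >= {k + 1} variants, got {j}")
    Xw = X * np.sqrt(w)[:, None]
    if np.linalg.matrix_rank(Xw, tol=1e-10 * np.abs(Xw).max()) < k:
        raise CollinearityError(
            "exposure association vectors are collinear; the direct effects are not "
            "separately identified (check that the two exposure tables differ)"
        )
    xtwx = X.T @ (w[:, None] * X)
    beta = np.linalg.solve(xtwx, X.T @ (w * G))
    resid = G - X @ beta
    het = HeterogeneityStats(q=float(np.sum(w * resid**2)), df=j - k)
    cov = het.sigma**2 * np.linalg.inv(xtwx)
    return MVMREstimate(
        exposures=list(data.exposure_names),
        beta=beta,
        se=np.sqrt(np.diag(cov)),
        n_snps=j,
        conditional_f=conditional_f(data),
        q=het.q,
        q_df=het.df,
        outcome_type=data.outcome_type,
    )


def conditional_f(data: HarmonizedData) -> np.ndarray:
    """Per-exposure conditional instrument-strength F-statistics.

    For exposure k, the other exposures' association vectors are regressed
    out of gamma_k (weights 1/se(gamma_k)^2, no intercept); the weighted
    residual sum of squares Q_k scaled by (J - K + 1) measures the
    instrument signal unique to exposure k.  Values below 10 flag potential
    weak-instrument bias.  Cross-exposure sampling covariance is ignored.
    """
    K = len(data.exposure_names)
    J = len(data)
    if J < K + 1:
        raise EstimatorInputError(f"conditional F needs >= {K + 1} variants, got {J}")
    out = np.empty(K)
    for k in range(K):
        gk = data.gamma(k)
        wk = 1.0 / data.se_gamma(k) ** 2
        others = [i for i in range(K) if i != k]
        if others:
            Z = np.column_stack([data.gamma(i) for i in others])
            ztwz = Z.T @ (wk[:, None] * Z)
            try:
                coef = np.linalg.solve(ztwz, Z.T @ (wk * gk))
            except np.linalg.LinAlgError as exc:
                raise CollinearityError("conditional-F projection is singular") from exc
            resid = gk - Z @ coef
        else:
            resid = gk
        qk = float(np.sum(wk * resid**2))
        out[k] = qk / (J - K + 1)
    return out


def to_odds_scale(est: MREstimate | MVMREstimate):
    """Attach OR and OR CI fields (binary outcomes only); p is unchanged."""
    if est.outcome_type != "binary":
        raise EstimatorInputError(
            "odds-scale conversion applies to binary-outcome (log-odds) estimates only"
        )
    if isinstance(est, MVMREstimate):
        return replace(
            est,
            odds_ratio=np.exp(est.beta),
            or_ci_low=np.exp(est.beta - Z95 * est.se),
            or_ci_high=np.exp(est.beta + Z95 * est.se),
        )
    return replace(
        est,
        odds_ratio=float(np.exp(est.beta)),
        or_ci_low=float(np.exp(est.beta - Z95 * est.se)),
        or_ci_high=float(np.exp(est.beta + Z95 * est.se)),
    )
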