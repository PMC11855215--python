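# Methods

This note documents the generative model, the estimators, the numerical
conventions and the deliberate design choices behind `mrlh`, in the spirit of
a model-description appendix.  Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## 1. The structural model

The simulator draws individual-level data from

```
H   = Σⱼ aⱼ Gⱼ                + δ_H·U + ε_H            (height)
T   = λ·H + Σⱼ bⱼ Gⱼ          + δ_T·U + ε_T            (lean mass)
C   = θ_H·H + θ_T·T + Σⱼ cⱼ Gⱼ + δ_C·U + ε_C           (cognition, continuous)
AD  ~ Bernoulli( logistic(α + φ_H·H + φ_T·T + Σⱼ dⱼ Gⱼ + δ_AD·U) )
```

with U ~ N(0,1) an unmeasured confounder and all noise independent across
individuals.  Variants may affect height only (aⱼ ≠ 0), lean mass only
(bⱼ ≠ 0) or both ("shared" loci, bⱼ = κ·aⱼ); shared loci plus the causal
path λ generate the strong genetic correlation between the two traits that
motivates the whole analysis.  cⱼ/dⱼ are direct variant-outcome effects,
zero except in pleiotropy scenarios.

**Why a confounder loading on height (δ_H).**  The collider mechanism that
makes height-adjusted lean-mass GWASs misleading requires covariance between
T and H that the instruments' own effects do not mirror.  Writing
b = cov(T,H)/Var(H), a height-only variant's association with the
residualized trait T − bH is (λ − b)·aⱼ.  If the only T–H covariance comes
from causation (b = λ) the term vanishes; if it comes from shared loci the
same loci also carry compensating direct effects, and one can show the
residual-scan IVW slope can never change sign.  Only a common cause of both
traits (δ_H·δ_T > 0 — shared developmental/environmental factors, a
realistic feature of body-size traits) makes b exceed λ enough that
height-acting variants flip sign in the adjusted scan while keeping their
outcome associations, reversing the MR estimate.  δ_H defaults to 0 and is
switched on in the confounding scenario.

**Logistic liability.**  The binary outcome uses a logistic (not probit)
link so that per-variant log-odds effects are exactly the quantities a
case-control GWAS estimates; marginal per-variant effects are mildly
attenuated by non-collapsibility, which affects all arms equally.

**What is deliberately not simulated:** age/sex/PC covariates (absorbed into
exogenous noise), realistic human LD maps, imputation, relatedness,
population stratification, sex chromosomes.  Passing tests therefore
demonstrate estimator correctness and the causal/collider logic, not
robustness to ancestry artefacts or cryptic relatedness.

## 2. Genotypes and GWAS scans

Genotypes are hard calls from a Gaussian copula: per haplotype, latent
normals with AR(1) correlation ρ within an LD block (blocks independent) are
thresholded at Φ⁻¹(MAF), and the two haplotype indicators are summed, giving
Hardy–Weinberg Binomial(2, MAF) marginals.  The realized dosage correlation
is attenuated relative to ρ (threshold correlation of a bivariate normal,
e.g. ρ = 0.4 yields dosage r ≈ 0.2–0.35 depending on the frequencies); this
is documented rather than corrected because only the qualitative block
structure matters for clumping.

Blocks of 10 variants are laid out 3 per chromosome, 1.5 Mb apart, so the
±10 Mb clumping window spans same-chromosome blocks whose LD is ≈ 0.

Association scans do what a GWAS pipeline would do, vectorized over
variants: per-variant OLS for continuous traits (covariate mode via
Frisch–Waugh–Lovell with n−3 error df; residual mode residualizes the
phenotype on the covariate over the full sample first), and per-variant
logistic maximum likelihood (Newton iterations, Wald SEs) for binary traits,
with non-converged or separated fits dropped and logged.  Standardization
divides betas and SEs by the sample SD of the **raw** phenotype — also for
the adjusted scans, matching how adjusted lean-mass GWASs are standardized
in practice.  Elementwise numerics are float32 with float64 accumulation;
per-variant estimates are accurate to ~10⁻⁵ relative, far below any
statistical scale in use.

## 3. Instrument selection and harmonization

Filtering keeps variants with p < 5×10⁻⁸, MAF > 0.01 and a record in the
outcome dataset; all thresholds are strict inequalities by convention.
Greedy clumping repeatedly takes the unclaimed variant with the smallest
(ranking) p-value as an index and removes unclaimed variants on the same
chromosome within ±10 Mb with r² ≥ 0.001 against it, computed from a
reference genotype panel over pairwise-complete samples; candidates missing
from the panel are dropped, never assumed independent.  Ties in p are broken
by (chrom, pos, variant_id) for determinism.  For MVMR the two exposures'
qualifying variants are pooled, restricted to variants present in both
exposures and the outcome, and clumped ranking by the lean-mass p-values
(the smaller exposure GWAS; ranking by the much larger height GWAS would let
it monopolize every index variant).  Pool variants without a lean-mass
p-value are dropped and counted.

Harmonization aligns every record to the exposure's effect allele: direct
match, label swap (negate beta, complement eaf), strand complement, or — for
palindromic A/T and C/G variants, whose labels carry no strand information —
frequency-based inference: orientation is decided by whether the two
effect-allele frequencies fall on the same side of 0.5, and the variant is
dropped as ambiguous when either record's MAF ≥ 0.42.  Applying the 0.42
rule to **both** records is a deliberately conservative reading (common
tooling checks only the exposure side); the one-sided behaviour is available
via `both_sides=False`.  Records lacking a frequency drop their palindromic
variants.  A chrom/pos disagreement at a matched id is treated as a build
mix-up and dropped.  The per-variant action log partitions the instrument
list exactly and is written with every harmonized table.

## 4. Estimators

All estimators operate on the harmonized arrays and are implemented from
their normal equations (tested to 10⁻¹⁰ against independent least-squares
oracles):

* IVW: β̂ = Σwγ̂Γ̂ / Σwγ̂², w = 1/se(Γ̂)²; Q on J−1 df;
  se = σ̂/√(Σwγ̂²) with σ̂ = max(1, √(Q/df)).  The floor at 1 (multiplicative
  random effects, under-dispersion ignored) is the standard random-effects
  convention and makes the estimator mildly conservative when Q/df < 1.
* MR-Egger: variants oriented to γ̂ > 0, weighted regression with intercept,
  same σ̂ floor applied to both SEs; the intercept's two-sided normal test is
  the pleiotropy diagnostic.
* Weighted median: ratio estimates sorted, weights normalized, the estimate
  interpolates linearly between the ratios bracketing cumulative weight 0.5
  (cumulative midpoints Sⱼ − wⱼ/2); SE from a parametric bootstrap (default
  1000 replicates, seeded) drawing γ̂*, Γ̂* from their reported sampling
  distributions.
* MVMR: weighted multiple regression without intercept; Q on J−K df; same
  dispersion floor; a rank check raises an explicit collinearity error when
  the exposure association vectors are proportional.
* Conditional F: for exposure k, γ̂ₖ is regressed (weights 1/se(γ̂ₖ)², no
  intercept) on the other exposures' association vectors; F_k = Q_k/(J−K+1)
  with Q_k the weighted residual sum of squares.  This is the summary-data
  Q-based construction; cross-exposure sampling covariance (nonzero when
  exposure GWASs share samples) is ignored, which is recorded in the
  estimate's metadata — with overlapping exposure cohorts the statistic is
  an approximation.
* Ratio SEs use the first-order delta method by default; the second-order
  form is available behind a flag and agrees within 10 % whenever
  se(γ̂)/|γ̂| < 0.1 and the outcome z-score is moderate.

Conventions: 95 % CIs use the fixed 1.96 normal multiplier (not
t-quantiles), p-values are two-sided normal, binary-outcome estimates carry
both log-odds and OR columns, p-values from input files are stored as given
and only checked (warning on >2× disagreement with |beta/se|).

## 5. Scenarios and their parameters

All scenarios share the genetic layout: m = 600 variants (default) in blocks
of 10 with ρ = 0.4; per block one height-only, one shared (κ = 0.7) and one
lean-mass-only causal variant; MAF ~ U(0.05, 0.5); effect magnitudes
U(0.05, 0.08) per genotype SD with random signs.  At the default cohort size
n = 20,000 this gives instrument z-scores ≈ 7–11 — the strongly-instrumented
regime of modern anthropometric GWASs, scaled down from cohorts 20–80×
larger.  Winner's-curse inflation of selected γ̂ is < 1 % here, keeping
ratio-estimator bias well below the recovery tolerance.

* `recovery` (estimator calibration): θ_T = 0.10, θ_H = 0, δ_H = 0;
  run unstandardized so the IVW estimand is exactly 0.10.
* `null`: the same with θ_T = 0.
* `paper_pattern` (default analysis scenario): λ = 0.3, δ_H = δ_T = 0.7,
  θ_H = 0.1, φ_H = −0.2, θ_T = φ_T = 0, α = −0.7 (≈ 33 % cases).  Outcome
  effects are ~1.5–2× the per-SD associations reported for real data; at
  desk-scale n the directional findings would otherwise drown in sampling
  noise.  With these values a height-only variant's residual-scan z is ≈ 7
  (so the collider arm has instruments) while a shared variant's is ≈ 1 (so
  it drops out), which is what produces a clean sign reversal.
* `pleiotropy`: recovery plus direct outcome effects of 0.03 per genotype SD
  on the lean-mass-signal variants of 40 % of blocks, oriented along each
  variant's lean-mass-increasing allele (directional pleiotropy in the
  Egger/InSIDE sense — an allele-fixed direction would cancel out of the IVW
  slope when exposure-effect signs are random).  The size puts the invalid
  instruments' ratio displacement (≈ 0.46) well above the per-instrument
  ratio noise (≈ 0.11 at n = 20,000), the regime in which the weighted
  median's majority-valid guarantee is informative.
* `shared_fraction(f)` (conditional-F sweep): one causal variant per block
  affecting both exposures with effect-vector correlation f (lean-mass
  effect = κ·(f·height effect + √(1−f²)·independent draw)).  This keeps the
  instrument roster and marginal strength fixed while varying only
  collinearity, so the mean conditional F falls monotonically in f; designs
  that instead vary the *count* of literally shared variants confound the
  sweep with instrument-number dilution.

Cohort plan: lean-mass and height scans share one exposure cohort (as in a
single-biobank setting), the large height analogue uses its own 3× cohort,
and each outcome is scanned on its own cohort never overlapping the
exposures — the two-sample design that keeps weak-instrument bias directed
towards the null.  The LD reference panel is a further independent cohort
(default 5,000 samples; large enough that sampling noise in r² stays an
order of magnitude below the 0.001 clumping threshold).

## 6. Replicate studies and problem sizes

The calibration studies (shared by the acceptance tests and
`scripts/acceptance.py`) run the full pipeline per seed:

| study | scenario | replicates | per-cohort n | m |
|---|---|---|---|---|
| recovery / Egger size | recovery | 100 | 20,000 | 600 |
| null size | null | 200 | 10,000 | 300 |
| confounding + collider | paper_pattern | 50 | 20,000 | 600 |
| pleiotropy ordering | pleiotropy | 50 | 20,000 | 600 |
| conditional-F sweep | shared_fraction | 12 × 4 fracs | 10,000 | 300 |

The null and sweep studies use the smaller sizes because only the test
statistic's null behaviour, respectively a monotone trend of means, is at
stake.  Per-replicate seeds derive deterministically from a single base
seed; all randomness flows through `numpy.random.Generator`.

## 7. Degenerate inputs and numerical edge cases

Zero exposure association → explicit undefined-ratio error; one instrument →
IVW refers the caller to the Wald ratio; fewer than 3 → Egger/weighted
median refuse; collinear MVMR design → explicit error; monomorphic panel
variant → error naming the variant; perfectly separated logistic fits →
variant dropped and logged; zero survivors of filtering or harmonization →
errors carrying the per-rule counts.  Bootstrap draws hitting γ̂* = 0 are
nudged by the smallest positive float rather than discarded, keeping the
replicate count exact.

## 8. Known limitations

Conditional F ignores cross-exposure sampling covariance (see §4).  The
simulator's LD is block-wise AR(1), far simpler than human LD; clumping
behaviour on real panels (long-range LD, MHC) is untested.  MR-PRESSO,
mode-based and contamination-mixture estimators, Steiger filtering,
correlated-instrument IVW and non-linear MR are out of scope.  Real-data
mode reads user-supplied summary statistics and panels but ships no
downloader.
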