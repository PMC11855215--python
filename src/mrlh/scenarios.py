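"""Named generative scenarios and scenario-file (YAML) handling.

Each builder returns a :class:`~mrlh.simulate.TrueModel` describing one study
condition.  Causal variants are laid out deterministically — within every LD
block of 10, position 1 carries a height-only effect, position 4 a shared
(height + lean-mass) effect and position 7 a lean-mass-only effect — so each
block contributes at most one clumped instrument per exposure.  Effect sizes
are drawn per genotype SD with magnitudes U(0.05, 0.08) and random signs,
giving instrument z-scores of roughly 7-11 at the default 20,000-sample
cohorts: desk-scale analogues of the strongly-instrumented real GWASs.

``paper_pattern`` is the default analysis scenario: height causally raises
lean mass (lambda), a confounder loads on both height and lean mass (this
phenotypic height-lean-mass covariance beyond the causal path is what makes
height-adjusted lean mass GWASs collider-biased), height protects against
the binary outcome and improves the continuous outcome, and lean mass has no
direct outcome effect.  Outcome effect magnitudes are ~1.5-2x the per-SD
estimates reported for real data, compensating for the 20-80x smaller
cohorts so that directional findings are resolvable at desk scale.
"""

from __future__ import annotations

from dataclasses import asdict
import numpy as np
import yaml

from .errors import ConfigError
from .simulate import SimulationConfig, TrueModel

HEIGHT_OFFSET, SHARED_OFFSET, TLM_OFFSET = 1, 4, 7


def _effect_magnitudes(rng: np.random.Generator, size: int) -> np.ndarray:
    return rng.uniform(0.05, 0.08, size=size) * rng.choice([-1.0, 1.0], size=size)


def _base_genetics(
    m: int,
    block_size: int,
    seed: int,
    *,
    kappa: float = 0.7,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw (maf, a, b): per-variant frequencies and trait effects.

    Effects are specified per genotype SD and converted to per-allele units
    via 1/sqrt(2 p (1-p)).  Per block: a height-only variant, a shared
    variant (b = kappa * a) and a lean-mass-only variant.
    """
    if m % block_size:
        raise ConfigError("m must be a multiple of block_size")
    rng = np.random.default_rng(seed)
    maf = rng.uniform(0.05, 0.5, size=m)
    v = 2.0 * maf * (1.0 - maf)
    scale = 1.0 / np.sqrt(v)
    a = np.zeros(m)
    b = np.zeros(m)
    idx = np.arange(m)
    height_idx = idx[idx % block_size == HEIGHT_OFFSET]
    shared_idx = idx[idx % block_size == SHARED_OFFSET]
    tlm_idx = idx[idx % block_size == TLM_OFFSET]
    a[height_idx] = _effect_magnitudes(rng, height_idx.size) * scale[height_idx]
    a[shared_idx] = _effect_magnitudes(rng, shared_idx.size) * scale[shared_idx]
    b[shared_idx] = kappa * a[shared_idx]
    b[tlm_idx] = _effect_magnitudes(rng, tlm_idx.size) * scale[tlm_idx]
    return maf, a, b


def paper_pattern(m: int = 600, block_size: int = 10, seed: int = 7) -> TrueModel:
    """Height confounds lean mass: the default four-arm analysis scenario.

    theta_T = phi_T = 0 (no direct lean-mass effect on either outcome),
    theta_H = 0.1 (continuous outcome, per unit H), phi_H = -0.2 log odds
    (protective), lambda = 0.3, and a confounder loading 0.7 on both height
    and lean mass.  Univariable lean-mass MR is therefore biased, MVMR should
    recover the null direct lean-mass effect, and MR on the residualized
    lean-mass GWAS reverses sign.
    """
    maf, a, b = _base_genetics(m, block_size, seed)
    return TrueModel(
        maf=maf,
        a=a,
        b=b,
        lam=0.3,
        delta_h=0.7,
        delta_t=0.7,
        delta_c=0.1,
        delta_ad=0.1,
        theta_h=0.1,
        theta_t=0.0,
        phi_h=-0.2,
        phi_t=0.0,
        alpha=-0.7,
        sigma_h=0.3,
        sigma_t=0.45,
        sigma_c=1.0,
    )


def recovery(
    m: int = 600, block_size: int = 10, seed: int = 7, effect: float = 0.10
) -> TrueModel:
    """Clean estimator-calibration scenario: T -> C with effect ``effect``.

    No height path to the outcome and no confounder loading on height, so
    every valid lean-mass instrument identifies the same causal effect.
    Intended to be run with ``standardize=False`` so the IVW estimand is
    exactly ``effect`` per unit of T.
    """
    maf, a, b = _base_genetics(m, block_size, seed)
    return TrueModel(
        maf=maf,
        a=a,
        b=b,
        lam=0.3,
        delta_h=0.0,
        delta_t=0.3,
        delta_c=0.3,
        delta_ad=0.0,
        theta_h=0.0,
        theta_t=effect,
        phi_h=0.0,
        phi_t=0.0,
        alpha=-0.7,
        sigma_h=0.7,
        sigma_t=0.66,
        sigma_c=1.0,
    )


def null(m: int = 600, block_size: int = 10, seed: int = 7) -> TrueModel:
    """Global null: heritable exposures, zero exposure-outcome effects."""
    return recovery(m, block_size, seed, effect=0.0)


def pleiotropy(
    m: int = 600,
    block_size: int = 10,
    seed: int = 7,
    effect: float = 0.10,
    pleio_frac: float = 0.4,
    pleio_effect: float = 0.03,
) -> TrueModel:
    """Recovery scenario plus directional pleiotropy on the continuous outcome.

    A fraction ``pleio_frac`` of the lean-mass signal blocks (both their
    shared and lean-mass-only variants) carry a direct effect of
    ``pleio_effect`` per genotype SD on C, oriented along each variant's
    lean-mass-increasing allele — directional pleiotropy in the MR-Egger
    sense, violating the exclusion restriction for those instruments.
    """
    model = recovery(m, block_size, seed, effect=effect)
    v = 2.0 * model.maf * (1.0 - model.maf)
    c = np.zeros(m)
    n_blocks = m // block_size
    t_effect = model.lam * model.a + model.b  # total variant effect on T
    # deterministic choice: every block with index mod 10 below 10*frac
    cutoff = int(round(10 * pleio_frac))
    for blk in range(n_blocks):
        if blk % 10 < cutoff:
            for off in (SHARED_OFFSET, TLM_OFFSET):
                j = blk * block_size + off
                c[j] = np.sign(t_effect[j]) * pleio_effect / np.sqrt(v[j])
    model.c = c
    return model


def shared_fraction(
    frac: float, m: int = 300, block_size: int = 10, seed: int = 7, kappa: float = 0.8
) -> TrueModel:
    """Instrument-overlap sweep scenario for the conditional-F diagnostic.

    Every LD block carries one causal variant affecting both exposures; its
    lean-mass effect mixes a component proportional to its height effect
    (weight ``frac``) with an independent component (weight
    sqrt(1 - frac^2)), so the two exposures' effect vectors have correlation
    ``frac`` while the instrument roster and per-exposure instrument
    strength stay fixed.  As ``frac`` rises towards 1 the association
    vectors become collinear and each exposure's conditional F falls towards
    zero.
    """
    if not (0 <= frac < 1):
        raise ConfigError("frac must lie in [0, 1)")
    if m % block_size:
        raise ConfigError("m must be a multiple of block_size")
    rng = np.random.default_rng(seed)
    maf = rng.uniform(0.05, 0.5, size=m)
    v = 2.0 * maf * (1.0 - maf)
    scale = 1.0 / np.sqrt(v)
    a = np.zeros(m)
    b = np.zeros(m)
    idx = np.arange(m)
    causal = idx[idx % block_size == HEIGHT_OFFSET]
    u = _effect_magnitudes(rng, causal.size)  # height effects, per genotype SD
    w = _effect_magnitudes(rng, causal.size)  # independent lean-mass component
    a[causal] = u * scale[causal]
    b[causal] = kappa * (frac * u + np.sqrt(1.0 - frac**2) * w) * scale[causal]
    return TrueModel(
        maf=maf,
        a=a,
        b=b,
        lam=0.2,
        delta_t=0.3,
        delta_c=0.3,
        theta_h=0.0,
        theta_t=0.0,
        alpha=-0.7,
        sigma_h=0.8,
        sigma_t=0.8,
        sigma_c=1.0,
    )


SCENARIOS = {
    "paper_pattern": paper_pattern,
    "recovery": recovery,
    "null": null,
    "pleiotropy": pleiotropy,
    "shared_fraction": shared_fraction,
}


def build_scenario(name: str, **kwargs) -> TrueModel:
    if name not in SCENARIOS:
        raise ConfigError(f"unknown scenario {name!r}; choose from {sorted(SCENARIOS)}")
    return SCENARIOS[name](**kwargs)


def load_scenario(path) -> tuple[TrueModel, SimulationConfig]:
    """Load a YAML scenario file.

    Schema::

        model:
          preset: paper_pattern       # one of SCENARIOS
          # remaining keys are passed to the preset builder
          m: 600
        config:
          n_exposure: 20000
          seed: 1
          ...

    Alternatively ``model`` may give explicit ``maf``/``a``/``b`` lists plus
    scalar structural parameters instead of a preset.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    model_spec = dict(doc.get("model") or {})
    cfg_spec = dict(doc.get("config") or {})
    if "preset" in model_spec:
        name = model_spec.pop("preset")
        model = build_scenario(name, **model_spec)
    else:
        for key in ("maf", "a", "b", "c", "d"):
            if key in model_spec:
                model_spec[key] = np.asarray(model_spec[key], dtype=float)
        model = TrueModel(**model_spec)
    config = SimulationConfig(**cfg_spec)
    return model, config


def dump_config(config: SimulationConfig, path) -> None:
    """Echo the effective sampling configuration to a YAML file."""
    payload = asdict(config)
    payload["roles"] = dict(payload["roles"])
    payload["role_n"] = dict(payload["role_n"])
    with open(path, "w") as fh:
        yaml.safe_dump({"config": payload}, fh, sort_keys=True)
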