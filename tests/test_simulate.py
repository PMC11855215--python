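"""The synthetic GWAS generator: genotypes, phenotypes, association scans."""

import numpy as np
import pytest
from scipy import stats

from mrlh import scenarios
from mrlh.errors import ConfigError
from mrlh.simulate import (
    Phenotypes,
    SimulationConfig,
    TrueModel,
    association_scan,
    make_study_set,
    simulate_genotypes,
    simulate_phenotypes,
)


def flat_model(m, maf=0.3, **kwargs):
    base = dict(
        maf=np.full(m, maf), a=np.zeros(m), b=np.zeros(m), sigma_h=1.0, sigma_t=1.0, sigma_c=1.0
    )
    base.update(kwargs)
    return TrueModel(**base)


class TestSimulateGenotypes:
    def test_independent_blocks_have_near_zero_ld(self):
        model = flat_model(20)
        cfg = SimulationConfig(n_exposure=5000, block_size=1, rho=0.0, seed=3)
        panel = simulate_genotypes(cfg, model, n=5000)
        g = panel.genotypes.astype(float)
        r = np.corrcoef(g.T)
        off = r[np.triu_indices(20, 1)] ** 2
        assert off.size >= 100
        assert np.mean(np.abs(off)) < 0.01

    def test_deterministic_under_seed(self):
        model = flat_model(30)
        cfg = SimulationConfig(n_exposure=500, seed=9)
        p1 = simulate_genotypes(cfg, model)
        p2 = simulate_genotypes(cfg, model)
        assert np.array_equal(p1.genotypes, p2.genotypes)

    def test_allele_frequency_matches_maf(self):
        model = flat_model(10, maf=0.3)
        cfg = SimulationConfig(n_exposure=50_000, seed=5)
        panel = simulate_genotypes(cfg, model, n=50_000)
        freq = panel.genotypes.mean(axis=0) / 2
        # binomial sampling error: 3 sigma = 3*sqrt(p(1-p)/(2n)) ~ 0.0043
        assert np.all(np.abs(freq - 0.3) < 0.01)

    def test_hardy_weinberg_marginals(self):
        model = flat_model(6, maf=0.25)
        cfg = SimulationConfig(n_exposure=50_000, rho=0.6, seed=8)
        panel = simulate_genotypes(cfg, model, n=50_000)
        counts = np.array([(panel.genotypes == k).mean(axis=0) for k in (0, 1, 2)])
        expected = np.array([0.75**2, 2 * 0.25 * 0.75, 0.25**2])
        assert np.allclose(counts, expected[:, None], atol=0.012)

    def test_within_block_correlation_positive_between_blocks_null(self):
        model = flat_model(20, maf=0.4)
        cfg = SimulationConfig(n_exposure=20_000, block_size=10, rho=0.5, seed=2)
        panel = simulate_genotypes(cfg, model, n=20_000)
        g = panel.genotypes.astype(float)
        r = np.corrcoef(g.T)
        assert r[0, 1] > 0.2  # adjacent within block (attenuated from rho)
        assert abs(r[0, 15]) < 0.03  # across blocks


class TestSimulatePhenotypes:
    def test_confounder_drives_h_t_correlation(self):
        m = 4
        model = flat_model(m, delta_h=0.6, delta_t=0.8, lam=0.0)
        cfg = SimulationConfig(n_exposure=50_000, seed=4)
        panel = simulate_genotypes(cfg, model, n=50_000)
        phen = simulate_phenotypes(panel, model, seed=11)
        var_h = 0.6**2 + 1.0
        var_t = 0.8**2 + 1.0
        predicted = 0.6 * 0.8 / np.sqrt(var_h * var_t)
        assert abs(np.corrcoef(phen.h, phen.t)[0, 1] - predicted) < 0.02

    def test_null_structure_gives_no_c_h_correlation(self):
        model = flat_model(4, delta_h=0.5, delta_t=0.5)
        cfg = SimulationConfig(n_exposure=20_000, seed=6)
        panel = simulate_genotypes(cfg, model, n=20_000)
        phen = simulate_phenotypes(panel, model, seed=12)
        r = np.corrcoef(phen.c, phen.h)[0, 1]
        assert abs(r) < 3 / np.sqrt(20_000)

    def test_case_fraction_matches_liability_intercept(self):
        model = flat_model(4, alpha=-2.0)
        cfg = SimulationConfig(n_exposure=50_000, seed=7)
        panel = simulate_genotypes(cfg, model, n=50_000)
        phen = simulate_phenotypes(panel, model, seed=13)
        expected = 1 / (1 + np.exp(2.0))  # ~0.119
        se = np.sqrt(expected * (1 - expected) / 50_000)
        assert abs(phen.ad.mean() - expected) < 3 * se


class TestAssociationScan:
    def test_null_variants_reject_at_nominal_rate(self):
        # 300 independent null variants stand in for replicate scans
        model = flat_model(300)
        cfg = SimulationConfig(n_exposure=2000, block_size=1, rho=0.0, seed=21)
        panel = simulate_genotypes(cfg, model, n=2000)
        phen = simulate_phenotypes(panel, model, seed=22)
        tbl = association_scan(panel, phen.t, trait_name="T")
        rej = (tbl.records["pval"] < 0.05).mean()
        band = 2.576 * np.sqrt(0.05 * 0.95 / 300)
        assert abs(rej - 0.05) < band + 1e-12

    def test_recovers_known_standardized_effect(self):
        m = 10
        maf = np.full(m, 0.3)
        v = np.sqrt(2 * 0.3 * 0.7)
        b = np.zeros(m)
        b[3] = 0.05 / v  # standardized (per genotype SD) effect 0.05
        model = TrueModel(maf=maf, a=np.zeros(m), b=b, sigma_t=1.0)
        cfg = SimulationConfig(n_exposure=20_000, block_size=1, rho=0.0, seed=23)
        panel = simulate_genotypes(cfg, model, n=20_000)
        phen = simulate_phenotypes(panel, model, seed=24)
        tbl = association_scan(panel, phen.t, trait_name="T")
        rec = tbl.get("rs4")
        assert abs(rec["beta"] * v - 0.05) < 3 * rec["se"] * v

    def test_irrelevant_covariate_leaves_betas_unchanged(self, rng):
        model = flat_model(100)
        cfg = SimulationConfig(n_exposure=4000, block_size=1, rho=0.0, seed=25)
        panel = simulate_genotypes(cfg, model, n=4000)
        phen = simulate_phenotypes(panel, model, seed=26)
        x = rng.standard_normal(4000)  # independent of dosage and phenotype
        plain = association_scan(panel, phen.t, trait_name="T")
        adj = association_scan(panel, phen.t, trait_name="T", adjustment="covariate", adjust_on=x)
        delta = np.abs(plain.records["beta"].to_numpy() - adj.records["beta"].to_numpy())
        assert delta.mean() < 0.005

    def test_residual_equals_covariate_when_adjust_on_exogenous(self):
        # adjust_on shares no genetic basis with the scanned trait
        model = flat_model(40, b=0.08 * np.ones(40), delta_t=0.0)
        cfg = SimulationConfig(n_exposure=20_000, block_size=1, rho=0.0, seed=27)
        panel = simulate_genotypes(cfg, model, n=20_000)
        phen = simulate_phenotypes(panel, model, seed=28)
        rng = np.random.default_rng(29)
        x = rng.standard_normal(20_000) + 0.5 * rng.standard_normal(20_000)
        cov = association_scan(panel, phen.t, adjustment="covariate", adjust_on=x)
        res = association_scan(panel, phen.t, adjustment="residual", adjust_on=x)
        delta = np.abs(cov.records["beta"].to_numpy() - res.records["beta"].to_numpy())
        assert delta.mean() < 0.002

    def test_adjusted_scans_are_collider_biased_when_adjust_on_heritable(self):
        # with a confounder loading on both H and T, conditioning on
        # heritable H (either way) turns a height-only variant's direct
        # effect (zero) into a *negative* adjusted association — the
        # collider mechanism; the two adjusted modes agree with each other
        m = 20
        maf = np.full(m, 0.3)
        a = np.zeros(m)
        a[:10] = 0.1
        model = TrueModel(maf=maf, a=a, b=np.zeros(m), lam=0.8, delta_h=0.8, delta_t=0.8)
        cfg = SimulationConfig(n_exposure=20_000, block_size=1, rho=0.0, seed=31)
        panel = simulate_genotypes(cfg, model, n=20_000)
        phen = simulate_phenotypes(panel, model, seed=32)
        plain = association_scan(panel, phen.t)
        res = association_scan(panel, phen.t, adjustment="residual", adjust_on=phen.h)
        cov = association_scan(panel, phen.t, adjustment="covariate", adjust_on=phen.h)
        b_height = plain.records["beta"][:10].mean()
        b_res = res.records["beta"][:10].mean()
        b_cov = cov.records["beta"][:10].mean()
        assert b_height > 0.05  # unadjusted: lambda * a > 0
        assert b_cov < -0.02 and b_res < -0.02  # true direct effect is zero
        # both conditioning strategies implement the same population quantity
        assert b_cov == pytest.approx(b_res, abs=0.005)

    def test_binary_scan_matches_statsmodels_logit(self):
        import statsmodels.api as sm

        model = flat_model(5, alpha=-1.0, phi_t=0.0)
        cfg = SimulationConfig(n_exposure=3000, block_size=1, rho=0.0, seed=33)
        panel = simulate_genotypes(cfg, model, n=3000)
        phen = simulate_phenotypes(panel, model, seed=34)
        tbl = association_scan(panel, phen.ad.astype(float), trait_type="binary", trait_name="AD")
        g = panel.genotypes[:, 2].astype(float)
        fit = sm.Logit(phen.ad, sm.add_constant(g)).fit(disp=0)
        rec = tbl.get("rs3")
        assert rec["beta"] == pytest.approx(fit.params[1], abs=5e-5)
        assert rec["se"] == pytest.approx(fit.bse[1], rel=1e-3)
        assert rec["n_cases"] == phen.ad.sum()

    def test_standardize_divides_by_raw_phenotype_sd(self):
        model = flat_model(5, b=np.full(5, 0.1))
        cfg = SimulationConfig(n_exposure=2000, block_size=1, rho=0.0, seed=35)
        panel = simulate_genotypes(cfg, model, n=2000)
        phen = simulate_phenotypes(panel, model, seed=36)
        raw = association_scan(panel, phen.t)
        std = association_scan(panel, phen.t, standardize=True)
        sd = np.std(phen.t, ddof=1)
        assert np.allclose(std.records["beta"], raw.records["beta"] / sd)
        assert np.allclose(std.records["se"], raw.records["se"] / sd)

    def test_adjust_on_required_iff_adjusting(self):
        model = flat_model(3)
        cfg = SimulationConfig(n_exposure=200, seed=1)
        panel = simulate_genotypes(cfg, model, n=200)
        with pytest.raises(ConfigError):
            association_scan(panel, np.zeros(200) + 1.0, adjustment="residual")
        with pytest.raises(ConfigError):
            association_scan(panel, np.ones(200), adjust_on=np.ones(200))


@pytest.fixture(scope="module")
def small_cfg():
    return SimulationConfig(
        n_exposure=2000, n_exposure_large=6000, n_outcome=2000, n_panel=1000, seed=41
    )


class TestStudySet:
    def test_larger_height_cohort_has_smaller_ses(self, small_cfg):
        model = scenarios.paper_pattern(m=60)
        study = make_study_set(small_cfg, model, roles=["height_0.5m", "height_1.5m"])
        se_small = study["height_0.5m"].records["se"].median()
        se_large = study["height_1.5m"].records["se"].median()
        assert se_large < se_small

    def test_same_seed_gives_identical_collection(self, small_cfg):
        model = scenarios.paper_pattern(m=60)
        s1 = make_study_set(small_cfg, model, roles=["tlm", "ad"])
        s2 = make_study_set(small_cfg, model, roles=["tlm", "ad"])
        for role in ("tlm", "ad"):
            assert s1[role].records.equals(s2[role].records)
        assert np.array_equal(s1.panel.genotypes, s2.panel.genotypes)

    def test_roles_independent_of_subset_requested(self, small_cfg):
        model = scenarios.paper_pattern(m=60)
        alone = make_study_set(small_cfg, model, roles=["cognition"])
        together = make_study_set(small_cfg, model, roles=["tlm", "cognition"])
        assert alone["cognition"].records.equals(together["cognition"].records)

    def test_residual_table_reverses_pure_height_variant(self):
        # closed-form partial regression: with cov(T,H) > lambda*Var(H)
        # (confounder on both traits), a height-only variant's residual-scan
        # beta is (lambda - b)*a_j < 0, opposite its unadjusted TLM beta
        m = 30
        maf = np.full(m, 0.3)
        v = 2 * 0.3 * 0.7
        a = np.zeros(m)
        a[0] = 0.12 / np.sqrt(v)
        model = TrueModel(
            maf=maf, a=a, b=np.zeros(m), lam=0.4, delta_h=0.8, delta_t=0.8,
            sigma_h=0.6, sigma_t=0.6,
        )
        cfg = SimulationConfig(
            n_exposure=40_000, n_outcome=200, n_panel=200, block_size=1, rho=0.0,
            seed=43, standardize=False,
        )
        study = make_study_set(cfg, model, roles=["tlm", "tlm_residual"])
        var_h = a[0] ** 2 * v + 0.8**2 + 0.6**2
        cov_th = 0.4 * var_h + 0.8 * 0.8
        b_coef = cov_th / var_h
        expected_resid = (0.4 - b_coef) * a[0]
        rec_plain = study["tlm"].get("rs1")
        rec_res = study["tlm_residual"].get("rs1")
        assert rec_plain["beta"] > 0
        assert rec_res["beta"] < 0
        assert abs(rec_res["beta"] - expected_resid) < 3 * rec_res["se"]

    def test_overlap_plan_rejects_exposure_outcome_sharing(self):
        roles = dict(tlm="exposure", ad="exposure")
        with pytest.raises(ConfigError, match="two-sample"):
            SimulationConfig(roles=roles)

    def test_role_n_beyond_cohort_size_is_an_error(self, small_cfg):
        import dataclasses

        cfg = dataclasses.replace(small_cfg, role_n={"tlm": 5000})
        model = scenarios.paper_pattern(m=60)
        with pytest.raises(ConfigError, match="requests"):
            make_study_set(cfg, model, roles=["tlm"])


class TestCalibration:
    def test_betas_unbiased_for_model_implied_marginal_effects(self):
        model = scenarios.recovery(m=300)
        cfg = SimulationConfig(n_exposure=20_000, block_size=1, rho=0.0, seed=51, standardize=False)
        panel = simulate_genotypes(cfg, model, n=20_000)
        truth = model.lam * model.a + model.b  # marginal = direct without LD
        zs = []
        for rep in range(4):  # phenotype replicates on one panel
            phen = simulate_phenotypes(panel, model, seed=52 + rep)
            tbl = association_scan(panel, phen.t)
            zs.append((tbl.records["beta"].to_numpy() - truth) / tbl.records["se"].to_numpy())
        assert abs(np.concatenate(zs).mean()) < 0.1

    def test_reported_ses_match_replicate_spread(self):
        model = flat_model(50, b=np.full(50, 0.05))
        betas, ses = [], []
        for seed in range(60):
            cfg = SimulationConfig(n_exposure=1000, block_size=1, rho=0.0, seed=seed)
            panel = simulate_genotypes(cfg, model, n=1000)
            phen = simulate_phenotypes(panel, model, seed=1000 + seed)
            tbl = association_scan(panel, phen.t)
            betas.append(tbl.records["beta"].to_numpy())
            ses.append(tbl.records["se"].to_numpy())
        emp_sd = np.vstack(betas).std(axis=0, ddof=1).mean()
        mean_se = np.vstack(ses).mean()
        assert abs(emp_sd - mean_se) / mean_se < 0.15
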