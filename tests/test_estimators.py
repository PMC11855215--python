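"""MR estimators against independent normal-equations / hand-stepped oracles."""

import numpy as np
import pytest
from scipy import stats

from mrlh.errors import CollinearityError, EstimatorInputError, UndefinedRatioError
from mrlh.estimators import (
    conditional_f,
    ivw_random_effects,
    mr_egger,
    mvmr_regression,
    to_odds_scale,
    wald_ratio,
    weighted_median,
)

from conftest import make_harmonized


def wls_oracle(X, y, w):
    """Weighted least squares via scaled ordinary lstsq (independent route)."""
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    resid = y - X @ coef
    q = float(np.sum(w * resid**2))
    cov_unit = np.linalg.inv((X * w[:, None]).T @ X)
    return coef, q, cov_unit


class TestWaldRatio:
    def test_arithmetic(self):
        est = wald_ratio(0.2, 0.02, 0.1, 0.05)
        assert est.beta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.25)
        assert est.ci_low == pytest.approx(0.5 - 1.96 * 0.25)

    def test_zero_outcome_association(self):
        assert wald_ratio(0.2, 0.02, 0.0, 0.05).beta == 0.0

    def test_zero_exposure_association_raises(self):
        with pytest.raises(UndefinedRatioError):
            wald_ratio(0.0, 0.02, 0.1, 0.05)

    def test_second_order_close_to_first_order_for_strong_instruments(self):
        # strong instrument (se_g/gamma < 0.1) and a moderate outcome z-score:
        # the neglected second-order term is then under 10% of the SE
        rng = np.random.default_rng(0)
        for _ in range(50):
            gamma = rng.uniform(0.1, 0.5) * rng.choice([-1, 1])
            se_g = rng.uniform(0.001, 0.1) * abs(gamma)
            Gamma = 0.3 * gamma
            se_G = abs(Gamma) / rng.uniform(0.5, 3.0)
            first = wald_ratio(gamma, se_g, Gamma, se_G).se
            second = wald_ratio(gamma, se_g, Gamma, se_G, second_order=True).se
            assert second >= first
            assert second / first < 1.1


class TestIVW:
    def test_exact_fit(self):
        g = np.array([0.1, 0.2, 0.3])
        harm = make_harmonized(g, 0.01 * np.ones(3), 0.5 * g, [0.02, 0.03, 0.02])
        est = ivw_random_effects(harm)
        assert est.beta == pytest.approx(0.5, abs=1e-12)
        assert est.q == pytest.approx(0.0, abs=1e-20)
        # under-dispersion floored: se equals the fixed-effect se
        assert est.se == pytest.approx(1.0 / np.sqrt(np.sum((g / harm.se_Gamma) ** 2)))

    def test_single_variant_is_an_error(self):
        harm = make_harmonized([0.1], [0.01], [0.05], [0.02])
        with pytest.raises(EstimatorInputError, match="wald_ratio"):
            ivw_random_effects(harm)

    def test_matches_normal_equations_oracle(self):
        g = np.array([0.10, 0.20, 0.30])
        G = np.array([0.06, 0.09, 0.16])
        seG = np.array([0.02, 0.02, 0.02])
        harm = make_harmonized(g, 0.01 * np.ones(3), G, seG)
        est = ivw_random_effects(harm)
        w = 1.0 / seG**2
        coef, q, cov_unit = wls_oracle(g[:, None], G, w)
        sigma2 = max(1.0, q / 2)
        assert est.beta == pytest.approx(coef[0], rel=1e-10)
        assert est.q == pytest.approx(q, rel=1e-10)
        assert est.se == pytest.approx(np.sqrt(sigma2 * cov_unit[0, 0]), rel=1e-10)

    def test_invariant_to_joint_sign_flips(self):
        rng = np.random.default_rng(5)
        g = rng.normal(0.2, 0.05, 8)
        G = 0.3 * g + rng.normal(0, 0.01, 8)
        harm1 = make_harmonized(g, 0.01 * np.ones(8), G, 0.02 * np.ones(8))
        flip = np.array([1, -1] * 4)
        harm2 = make_harmonized(g * flip, 0.01 * np.ones(8), G * flip, 0.02 * np.ones(8))
        e1, e2 = ivw_random_effects(harm1), ivw_random_effects(harm2)
        assert e1.beta == pytest.approx(e2.beta, rel=1e-12)
        assert e1.se == pytest.approx(e2.se, rel=1e-12)

    def test_overdispersion_inflates_se(self):
        rng = np.random.default_rng(6)
        g = rng.uniform(0.1, 0.3, 20)
        G = 0.2 * g + rng.normal(0, 0.2, 20)  # heterogeneity >> se_G
        harm = make_harmonized(g, 0.01 * np.ones(20), G, 0.02 * np.ones(20))
        est = ivw_random_effects(harm)
        assert est.q / est.q_df > 1
        fixed_se = 1.0 / np.sqrt(np.sum((g / 0.02) ** 2))
        assert est.se == pytest.approx(np.sqrt(est.q / est.q_df) * fixed_se, rel=1e-10)


class TestEgger:
    def test_exact_fit_recovers_intercept_and_slope(self):
        g = np.array([0.1, 0.2, 0.3, 0.4])
        harm = make_harmonized(g, 0.01 * np.ones(4), 0.1 + 0.3 * g, 0.02 * np.ones(4))
        est = mr_egger(harm)
        assert est.intercept == pytest.approx(0.1, abs=1e-12)
        assert est.beta == pytest.approx(0.3, abs=1e-12)
        assert est.q == pytest.approx(0.0, abs=1e-18)

    def test_orientation_invariance(self):
        rng = np.random.default_rng(7)
        g = rng.uniform(0.1, 0.4, 6)
        G = 0.05 + 0.25 * g + rng.normal(0, 0.01, 6)
        harm1 = make_harmonized(g, 0.01 * np.ones(6), G, 0.02 * np.ones(6))
        harm2 = make_harmonized(-g, 0.01 * np.ones(6), -G, 0.02 * np.ones(6))
        e1, e2 = mr_egger(harm1), mr_egger(harm2)
        assert e1.beta == pytest.approx(e2.beta, rel=1e-12)
        assert e1.intercept == pytest.approx(e2.intercept, rel=1e-12)

    def test_matches_weighted_regression_oracle(self):
        g = np.array([0.12, 0.18, 0.25, 0.31, 0.40])
        G = np.array([0.05, 0.04, 0.09, 0.12, 0.10])
        seG = np.array([0.01, 0.02, 0.015, 0.03, 0.02])
        harm = make_harmonized(g, 0.01 * np.ones(5), G, seG)
        est = mr_egger(harm)
        w = 1.0 / seG**2
        X = np.column_stack([np.ones(5), g])
        coef, q, cov_unit = wls_oracle(X, G, w)
        sigma2 = max(1.0, q / 3)
        assert est.intercept == pytest.approx(coef[0], rel=1e-10)
        assert est.beta == pytest.approx(coef[1], rel=1e-10)
        assert est.se == pytest.approx(np.sqrt(sigma2 * cov_unit[1, 1]), rel=1e-10)
        assert est.intercept_se == pytest.approx(np.sqrt(sigma2 * cov_unit[0, 0]), rel=1e-10)

    def test_too_few_variants(self):
        harm = make_harmonized([0.1, 0.2], [0.01, 0.01], [0.05, 0.06], [0.02, 0.02])
        with pytest.raises(EstimatorInputError):
            mr_egger(harm)


class TestWeightedMedian:
    def test_symmetric_midpoint(self):
        g = np.ones(3)
        G = np.array([0.2, 0.5, 0.9])
        harm = make_harmonized(g, 0.01 * np.ones(3), G, 0.02 * np.ones(3))
        est = weighted_median(harm, n_boot=100, seed=1)
        assert est.beta == pytest.approx(0.5)

    def test_constant_ratios(self):
        g = np.array([0.1, 0.2, 0.4])
        harm = make_harmonized(g, 1e-6 * np.ones(3), 0.7 * g, 1e-6 * np.ones(3))
        est = weighted_median(harm, n_boot=100, seed=2)
        assert est.beta == pytest.approx(0.7, abs=1e-9)
        assert est.se < 1e-4

    def test_matches_hand_stepped_interpolation(self):
        # ratios and weights chosen so the 0.5 crossing needs interpolation
        g = np.array([1.0, 1.0, 1.0, 1.0])
        G = np.array([0.1, 0.3, 0.6, 1.0])
        seG = np.array([0.1, 0.05, 0.1, 0.2])
        harm = make_harmonized(g, 1e-6 * np.ones(4), G, seG)
        est = weighted_median(harm, n_boot=100, seed=3)
        # hand computation: weights ~ (g/seG)^2 = (100, 400, 100, 25) -> /625
        w = np.array([100, 400, 100, 25]) / 625
        cum = np.cumsum(w) - w / 2  # [0.08, 0.48, 0.88, 0.98]
        # 0.5 lies between cum[1]=0.48 (ratio 0.3) and cum[2]=0.88 (ratio 0.6)
        expected = 0.3 + (0.5 - cum[1]) / (cum[2] - cum[1]) * (0.6 - 0.3)
        assert est.beta == pytest.approx(expected, rel=1e-12)

    def test_bootstrap_se_reproducible_and_calibrated(self):
        rng = np.random.default_rng(11)
        g = rng.uniform(0.15, 0.4, 25)
        seG = np.full(25, 0.02)
        G = 0.3 * g + rng.normal(0, 0.02, 25)
        harm = make_harmonized(g, 0.01 * np.ones(25), G, seG)
        e1 = weighted_median(harm, n_boot=500, seed=4)
        e2 = weighted_median(harm, n_boot=500, seed=4)
        assert e1.se == e2.se
        # bootstrap SE should be in the ballpark of the IVW se
        ivw = ivw_random_effects(harm)
        assert 0.3 * ivw.se < e1.se < 3 * ivw.se

    def test_too_few_variants_or_boots(self):
        harm = make_harmonized([0.1, 0.2], [0.01] * 2, [0.05, 0.1], [0.02] * 2)
        with pytest.raises(EstimatorInputError):
            weighted_median(harm, n_boot=1000, seed=0)
        harm3 = make_harmonized([0.1, 0.2, 0.3], [0.01] * 3, [0.05, 0.1, 0.2], [0.02] * 3)
        with pytest.raises(EstimatorInputError):
            weighted_median(harm3, n_boot=10, seed=0)


class TestMVMR:
    def test_exact_fit(self):
        rng = np.random.default_rng(13)
        g1 = rng.uniform(0.1, 0.4, 8)
        g2 = rng.uniform(0.1, 0.4, 8)
        harm = make_harmonized(
            g1, 0.01 * np.ones(8), 0.3 * g1, 0.02 * np.ones(8), gammas2=g2, se_g2=0.01 * np.ones(8)
        )
        est = mvmr_regression(harm)
        assert est.beta[0] == pytest.approx(0.3, abs=1e-10)
        assert est.beta[1] == pytest.approx(0.0, abs=1e-10)
        assert est.q == pytest.approx(0.0, abs=1e-16)

    def test_collinear_design_raises(self):
        g1 = np.linspace(0.1, 0.4, 6)
        harm = make_harmonized(
            g1, 0.01 * np.ones(6), 0.2 * g1, 0.02 * np.ones(6), gammas2=2 * g1, se_g2=0.01 * np.ones(6)
        )
        with pytest.raises(CollinearityError):
            mvmr_regression(harm)

    def test_matches_matrix_algebra_oracle(self):
        g1 = np.array([0.11, 0.24, 0.35, 0.18, 0.29, 0.40, 0.15, 0.22])
        g2 = np.array([0.30, 0.12, 0.22, 0.35, 0.10, 0.18, 0.28, 0.07])
        G = np.array([0.05, 0.06, 0.11, 0.07, 0.08, 0.13, 0.06, 0.05])
        seG = np.array([0.02, 0.03, 0.02, 0.025, 0.02, 0.03, 0.02, 0.025])
        harm = make_harmonized(
            g1, 0.01 * np.ones(8), G, seG, gammas2=g2, se_g2=0.015 * np.ones(8)
        )
        est = mvmr_regression(harm)
        X = np.column_stack([g1, g2])
        w = 1.0 / seG**2
        coef, q, cov_unit = wls_oracle(X, G, w)
        sigma2 = max(1.0, q / (8 - 2))
        assert np.allclose(est.beta, coef, rtol=1e-10)
        assert est.q == pytest.approx(q, rel=1e-10)
        assert np.allclose(est.se, np.sqrt(sigma2 * np.diag(cov_unit)), rtol=1e-10)

    def test_too_few_variants(self):
        harm = make_harmonized([0.1, 0.2], [0.01] * 2, [0.05, 0.1], [0.02] * 2,
                               gammas2=[0.3, 0.1], se_g2=[0.01] * 2)
        with pytest.raises(EstimatorInputError):
            mvmr_regression(harm)


class TestConditionalF:
    def test_total_collinearity_drives_f_to_zero(self):
        g1 = np.linspace(0.1, 0.5, 10)
        harm = make_harmonized(
            g1, 0.01 * np.ones(10), 0.2 * g1, 0.02 * np.ones(10),
            gammas2=3 * g1, se_g2=0.03 * np.ones(10),
        )
        f = conditional_f(harm)
        assert np.all(f < 1e-12)

    def test_orthogonal_vectors_match_mean_marginal_f(self):
        # half the instruments load on exposure 1 only, half on exposure 2
        # only; per-loaded-variant marginal F ~ 100 -> conditional F should
        # approach the roster-wide mean marginal F (~50)
        rng = np.random.default_rng(17)
        ratios = []
        for _ in range(50):
            j = 40
            se = 0.01
            g1 = np.zeros(j)
            g2 = np.zeros(j)
            g1[: j // 2] = rng.normal(0.1, 0.005, j // 2)  # (0.1/0.01)^2 = 100
            g2[j // 2 :] = rng.normal(0.1, 0.005, j // 2)
            g1 += rng.normal(0, se, j)
            g2 += rng.normal(0, se, j)
            harm = make_harmonized(
                g1, se * np.ones(j), 0.1 * g1, 0.02 * np.ones(j), gammas2=g2, se_g2=se * np.ones(j)
            )
            f = conditional_f(harm)
            marginal = np.mean((g1 / se) ** 2)
            ratios.append(f[0] / marginal)
        assert abs(np.mean(ratios) - 1) < 0.2

    def test_attached_to_mvmr_estimate(self):
        rng = np.random.default_rng(19)
        g1 = rng.uniform(0.1, 0.4, 12)
        g2 = rng.uniform(0.1, 0.4, 12)
        harm = make_harmonized(
            g1, 0.01 * np.ones(12), 0.2 * g1 + 0.1 * g2, 0.02 * np.ones(12),
            gammas2=g2, se_g2=0.01 * np.ones(12),
        )
        est = mvmr_regression(harm)
        assert np.allclose(est.conditional_f, conditional_f(harm))
        assert np.all(est.conditional_f >= 0)


class TestOddsScale:
    def test_null_estimate(self):
        harm = make_harmonized([0.1, 0.2], [0.01] * 2, [0.0, 0.0], [0.02] * 2, outcome_type="binary")
        est = to_odds_scale(ivw_random_effects(harm))
        assert est.odds_ratio == pytest.approx(1.0)

    def test_closed_form_evaluation(self):
        from mrlh.estimators import MREstimate

        est = MREstimate("ivw", beta=0.0, se=0.1, n_snps=5, outcome_type="binary")
        out = to_odds_scale(est)
        assert out.or_ci_low == pytest.approx(np.exp(-0.196), rel=1e-12)
        assert out.or_ci_high == pytest.approx(np.exp(0.196), rel=1e-12)
        est2 = MREstimate("ivw", beta=-0.21, se=0.06, n_snps=5, outcome_type="binary")
        out2 = to_odds_scale(est2)
        assert out2.odds_ratio == pytest.approx(np.exp(-0.21), rel=1e-12)  # ~0.81
        assert out2.or_ci_low == pytest.approx(np.exp(-0.21 - 1.96 * 0.06), rel=1e-12)  # ~0.72
        assert out2.or_ci_high == pytest.approx(np.exp(-0.21 + 1.96 * 0.06), rel=1e-12)  # ~0.91
        assert 0.80 < out2.odds_ratio < 0.82
        assert out.pval == est.pval

    def test_negation_gives_reciprocal_or(self):
        from mrlh.estimators import MREstimate

        a = to_odds_scale(MREstimate("ivw", 0.3, 0.05, 4, outcome_type="binary"))
        b = to_odds_scale(MREstimate("ivw", -0.3, 0.05, 4, outcome_type="binary"))
        assert a.odds_ratio == pytest.approx(1 / b.odds_ratio, rel=1e-12)
        assert a.or_ci_low == pytest.approx(1 / b.or_ci_high, rel=1e-12)

    def test_continuous_outcome_rejected(self):
        harm = make_harmonized([0.1, 0.2], [0.01] * 2, [0.05, 0.1], [0.02] * 2)
        with pytest.raises(EstimatorInputError):
            to_odds_scale(ivw_random_effects(harm))


def test_pvalue_is_two_sided_normal():
    est = wald_ratio(0.2, 0.01, 0.1, 0.05)
    z = est.beta / est.se
    assert est.pval == pytest.approx(2 * stats.norm.sf(abs(z)), rel=1e-12)
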