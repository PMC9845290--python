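"""The five causal estimators, odds-ratio reporting, and the Bonferroni rule."""

import numpy as np
import pytest

from conftest import make_harmonized
from mrkit.estimators import (
    EstimatorError,
    bonferroni_threshold,
    egger,
    egger_fit,
    ivw,
    ivw_fit,
    max_likelihood,
    max_likelihood_fit,
    raps,
    raps_fit,
    significance_label,
    to_odds_ratio,
    wald_ratio_arrays,
    wald_ratios,
    weighted_median,
    weighted_median_fit,
)
from mrkit.synthetic import SimulationConfig, simulate_effect_arrays


def random_instance(rng, L=10):
    bx = rng.normal(0.05, 0.02, L)
    bx[np.abs(bx) < 1e-3] = 1e-3
    sx = rng.uniform(0.001, 0.01, L)
    by = rng.normal(0.005, 0.01, L)
    sy = rng.uniform(0.001, 0.01, L)
    return bx, sx, by, sy


class TestWaldRatios:
    def test_direct_evaluation(self):
        theta, se = wald_ratio_arrays([0.1], [0.01], [0.05], [0.01])
        assert theta[0] == pytest.approx(0.5)
        assert se[0] == pytest.approx(0.1)

    def test_zero_outcome_effect(self):
        theta, _ = wald_ratio_arrays([0.1], [0.01], [0.0], [0.01])
        assert theta[0] == 0.0

    def test_sign_rule(self):
        theta, se = wald_ratio_arrays([-0.1], [0.01], [0.05], [0.01])
        assert theta[0] == pytest.approx(-0.5) and se[0] > 0

    def test_zero_exposure_effect_excluded_with_warning(self):
        h = make_harmonized([0.0, 0.1], [0.01, 0.01], [0.01, 0.05], [0.01, 0.01])
        with pytest.warns(UserWarning, match="beta_X = 0"):
            theta, se, excluded = wald_ratios(h)
        assert excluded == ["rs0000"] and theta.size == 1


class TestIVW:
    def test_single_snp_equals_wald_ratio(self):
        h = make_harmonized([0.1], [0.01], [0.05], [0.01])
        with pytest.warns(UserWarning, match="single instrument"):
            est = ivw(h)
        assert est.beta == pytest.approx(0.5) and est.se == pytest.approx(0.1)

    def test_homogeneous_ratios_give_scale_one(self):
        bx = np.array([0.1, 0.2, 0.4])
        by = 0.3 * bx
        fit = ivw_fit(bx, 0.01 * np.ones(3), by, np.array([0.01, 0.01, 0.01]))
        assert fit.beta == pytest.approx(0.3)
        assert fit.extra["q"] == pytest.approx(0.0, abs=1e-20)
        assert fit.extra["scale"] == 1.0

    def test_closed_form_fixed_effect_oracle(self, rng):
        bx, sx, by, sy = random_instance(rng)
        fit = ivw_fit(bx, sx, by, sy)
        theta = by / bx
        w = bx**2 / sy**2
        assert fit.beta == pytest.approx(float((w * theta).sum() / w.sum()), abs=1e-10)

    def test_random_effects_never_narrower_than_fixed(self, rng):
        for _ in range(20):
            bx, sx, by, sy = random_instance(rng)
            fit = ivw_fit(bx, sx, by, sy)
            se_fixed = np.sqrt(1.0 / (1.0 / (sy / np.abs(bx)) ** 2).sum())
            assert fit.se >= se_fixed * (1 - 1e-12)


class TestEgger:
    def test_two_snps_error(self):
        h = make_harmonized([0.1, 0.2], [0.01] * 2, [0.05, 0.1], [0.01] * 2)
        with pytest.raises(EstimatorError, match="3 instruments"):
            egger(h)

    def test_recovers_slope_and_intercept_on_exact_line(self):
        bx = np.array([0.05, 0.1, 0.2, 0.4])
        by = 0.02 + 0.3 * bx  # constant directional pleiotropy 0.02
        fit = egger_fit(bx, 0.001 * np.ones(4), by, 0.01 * np.ones(4))
        assert fit.beta == pytest.approx(0.3, abs=1e-10)
        assert fit.extra["intercept"] == pytest.approx(0.02, abs=1e-10)

    def test_orientation_invariance(self, rng):
        bx, sx, by, sy = random_instance(rng)
        flip = rng.random(bx.size) < 0.5
        bx2, by2 = bx.copy(), by.copy()
        bx2[flip], by2[flip] = -bx2[flip], -by2[flip]
        a, b = egger_fit(bx, sx, by, sy), egger_fit(bx2, sx, by2, sy)
        assert a.beta == pytest.approx(b.beta, rel=1e-12)
        assert a.extra["intercept"] == pytest.approx(b.extra["intercept"], rel=1e-12)

    def test_matches_statsmodels_wls_oracle(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        bx, sx, by, sy = random_instance(rng, L=15)
        bx = np.abs(bx)  # already oriented
        fit = egger_fit(bx, sx, by, sy)
        X = sm.add_constant(bx)
        res = sm.WLS(by, X, weights=1.0 / sy**2).fit()
        assert fit.beta == pytest.approx(res.params[1], rel=1e-10)
        assert fit.extra["intercept"] == pytest.approx(res.params[0], rel=1e-10)
        if fit.extra["residual_scale"] > 1:  # statsmodels always scales by phi
            assert fit.se == pytest.approx(res.bse[1], rel=1e-8)
            assert fit.pval == pytest.approx(res.pvalues[1], rel=1e-8)

    def test_large_sample_recovery_of_directional_pleiotropy(self):
        cfg = SimulationConfig(
            n_snps=2000, true_theta=0.1, gamma_sd=0.05,
            pleiotropy_mode="directional", prop_invalid=1.0,
            pleiotropy_mean=0.02, pleiotropy_sd=1e-4, seed=31,
            n_exposure=5_000_000, n_outcome=5_000_000,
        )
        bx, sx, by, sy, *_ = simulate_effect_arrays(cfg)
        fit = egger_fit(bx, sx, by, sy)
        assert fit.extra["intercept"] == pytest.approx(0.02, abs=0.002)
        assert fit.beta == pytest.approx(0.1, abs=0.02)


class TestWeightedMedian:
    def test_hand_oracle_equal_weights(self):
        # ratios 0.1/0.5/0.9 with equal weights: cumulative midpoints hit 0.5
        # exactly at the middle ratio
        h = make_harmonized([0.1, 0.1, 0.1], [0.01] * 3,
                            [0.01, 0.05, 0.09], [0.01] * 3)
        est = weighted_median(h, n_boot=200, seed=1)
        assert est.beta == pytest.approx(0.5)

    def test_identical_ratios_location_identity(self):
        bx = np.array([0.1, 0.2, 0.5])
        fit = weighted_median_fit(bx, 0.01 * np.ones(3), 0.4 * bx,
                                  0.01 * np.ones(3), n_boot=500, seed=3)
        assert fit.beta == pytest.approx(0.4)
        assert fit.se > 0

    def test_seed_is_mandatory(self):
        h = make_harmonized([0.1] * 3, [0.01] * 3, [0.05] * 3, [0.01] * 3)
        with pytest.raises(EstimatorError, match="seed"):
            weighted_median(h)

    def test_bootstrap_reproducible(self):
        h = make_harmonized([0.1, 0.2, 0.3], [0.01] * 3, [0.05, 0.1, 0.14], [0.01] * 3)
        a = weighted_median(h, n_boot=300, seed=7)
        b = weighted_median(h, n_boot=300, seed=7)
        assert a.se == b.se


class TestMaxLikelihood:
    def test_single_snp_equals_wald_ratio(self):
        fit = max_likelihood_fit([0.1], [0.01], [0.05], [0.01])
        assert fit.beta == pytest.approx(0.5, abs=1e-8)

    def test_negligible_exposure_noise_limit_is_fixed_effect_ivw(self, rng):
        bx, _, by, sy = random_instance(rng)
        sx = np.full(bx.size, 1e-12)
        fit = max_likelihood_fit(bx, sx, by, sy)
        w = 1.0 / sy**2
        slope_fe = float((w * bx * by).sum() / (w * bx * bx).sum())
        assert fit.beta == pytest.approx(slope_fe, abs=1e-8)

    def test_agrees_with_ivw_without_pleiotropy(self):
        cfg = SimulationConfig(n_snps=75, true_theta=0.1, gamma_sd=0.03)
        rel = []
        for seed in range(30):
            cfg.seed = seed
            bx, sx, by, sy, *_ = simulate_effect_arrays(cfg)
            ml_b = max_likelihood_fit(bx, sx, by, sy).beta
            ivw_b = ivw_fit(bx, sx, by, sy).beta
            rel.append(abs(ml_b - ivw_b) / abs(ivw_b))
        assert np.mean(rel) < 0.02


class TestRAPS:
    def test_fewer_than_three_snps_error(self):
        with pytest.raises(EstimatorError, match="3 instruments"):
            raps_fit([0.1, 0.2], [0.01] * 2, [0.05, 0.1], [0.01] * 2)

    def test_overdispersion_recovery_within_factor_two(self):
        tau2_true = 0.001
        cfg = SimulationConfig(
            n_snps=200, true_theta=0.1, gamma_sd=0.03,
            pleiotropy_mode="balanced", prop_invalid=1.0,
            pleiotropy_sd=np.sqrt(tau2_true), seed=0,
        )
        est = []
        for seed in range(10):
            cfg.seed = seed
            bx, sx, by, sy, *_ = simulate_effect_arrays(cfg)
            est.append(raps_fit(bx, sx, by, sy).extra["tau2"])
        med = float(np.median(est))
        assert tau2_true / 2 < med < tau2_true * 2

    def test_boundary_tau2_reported_not_error(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        fit = raps_fit(bx, 0.001 * np.ones(4), 0.3 * bx, 0.01 * np.ones(4))
        assert fit.extra["tau2"] == pytest.approx(0.0, abs=1e-8)

    def test_weak_instrument_bias_not_worse_than_ivw(self):
        cfg = SimulationConfig(
            n_snps=150, true_theta=0.1, gamma_sd=0.008,  # per-SNP F around 15
            n_exposure=600_000, n_outcome=460_000,
        )
        ivw_b, raps_b = [], []
        for seed in range(60):
            cfg.seed = seed
            bx, sx, by, sy, *_ = simulate_effect_arrays(cfg)
            ivw_b.append(ivw_fit(bx, sx, by, sy).beta - 0.1)
            raps_b.append(raps_fit(bx, sx, by, sy).beta - 0.1)
        assert abs(np.mean(raps_b)) <= abs(np.mean(ivw_b))


class TestNegationSymmetry:
    def test_negating_outcome_negates_every_estimator(self, harmonized_strong):
        h = harmonized_strong
        neg = make_harmonized(*(lambda a: (a[0], a[1], -a[2], a[3]))(h.arrays()))
        for fn, kw, tol in [
            (ivw, {}, 1e-12),
            (egger, {}, 1e-12),
            (weighted_median, {"n_boot": 100, "seed": 5}, 1e-12),
            (max_likelihood, {}, 1e-6),
            (raps, {}, 1e-3),
        ]:
            a, b = fn(h, **kw), fn(neg, **kw)
            assert b.beta == pytest.approx(-a.beta, rel=tol, abs=1e-7), fn.__name__


class TestReporting:
    def test_odds_ratio_point_and_ci(self):
        or_, lo, hi = to_odds_ratio(0.008, 0.00255)
        assert or_ == pytest.approx(1.008, abs=5e-4)
        assert lo == pytest.approx(1.003, abs=5e-4)
        assert hi == pytest.approx(1.013, abs=5e-4)

    def test_zero_beta_zero_se(self):
        assert to_odds_ratio(0.0, 0.0) == (1.0, 1.0, 1.0)

    def test_negation_mirrors_or(self):
        or_pos, lo_pos, hi_pos = to_odds_ratio(0.3, 0.1)
        or_neg, lo_neg, hi_neg = to_odds_ratio(-0.3, 0.1)
        assert or_neg == pytest.approx(1 / or_pos)
        assert lo_neg == pytest.approx(1 / hi_pos)

    @pytest.mark.parametrize("alpha, m, expected", [(0.05, 5, 0.01), (0.05, 1, 0.05)])
    def test_bonferroni_threshold(self, alpha, m, expected):
        assert bonferroni_threshold(alpha, m) == expected

    def test_bonferroni_invalid_m(self):
        with pytest.raises(EstimatorError):
            bonferroni_threshold(0.05, 0)

    @pytest.mark.parametrize(
        "pval, label",
        [(0.003, "significant"), (0.022, "nominally significant"), (0.3, "ns")],
    )
    def test_significance_classes_with_five_outcomes(self, pval, label):
        assert significance_label(pval, 0.05, 5) == label
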