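"""The eight causal estimators against independent oracles and invariants."""

import numpy as np
import pytest
from scipy import stats

from conftest import build_harmonized
from mrmediate.estimators import (EstimatorConfig, EstimationError,
                                  beta_to_or, ivw, maximum_likelihood,
                                  mode_estimate, mr_egger,
                                  penalized_weighted_median, run_all_methods,
                                  simple_median, wald_ratios, weighted_median,
                                  _profile_negloglik)

FAST = EstimatorConfig(n_boot=200, seed=42)


class TestWaldRatios:
    def test_unit_exposure(self, make_harmonized):
        h = make_harmonized([1.0], [0.01], [0.2], [0.05])
        w = wald_ratios(h)
        assert w.ratio[0] == 0.2 and w.se[0] == 0.05

    def test_negative_exposure_effect(self, make_harmonized):
        h = make_harmonized([-0.5], [0.01], [0.1], [0.05])
        w = wald_ratios(h)
        assert w.ratio[0] == pytest.approx(-0.2)
        assert w.se[0] == pytest.approx(0.1)

    def test_elementwise_against_recomputation(self, make_harmonized):
        rng = np.random.default_rng(3)
        bx, by = rng.normal(1, 0.2, 3), rng.normal(0.3, 0.1, 3)
        sy = rng.uniform(0.01, 0.05, 3)
        w = wald_ratios(make_harmonized(bx, [0.01] * 3, by, sy))
        np.testing.assert_allclose(w.ratio, by / bx)
        np.testing.assert_allclose(w.se, sy / np.abs(bx))

    def test_zero_exposure_effect_names_snp(self, make_harmonized):
        h = make_harmonized([1.0, 0.0], [0.01] * 2, [0.1, 0.1], [0.05] * 2)
        with pytest.raises(EstimationError, match="rs2"):
            wald_ratios(h)


class TestIVW:
    def test_single_snp_equals_wald_ratio(self, make_harmonized):
        est = ivw(make_harmonized([0.5], [0.01], [0.1], [0.05]))
        assert est.method == "wald_ratio"
        assert est.beta == pytest.approx(0.2)

    def test_homogeneous_ratios_no_inflation(self, make_harmonized):
        h = make_harmonized([1, 1, 1], [0.01] * 3, [0.2, 0.2, 0.2],
                            [0.1, 0.2, 0.3])
        est = ivw(h)
        assert est.beta == pytest.approx(0.2)
        assert est.extras["Q"] == pytest.approx(0.0, abs=1e-20)
        assert est.se == pytest.approx(est.extras["se_fixed"])

    def test_closed_form_weighted_mean(self, ivw_toy):
        est = ivw(ivw_toy)
        assert est.beta == pytest.approx(40.0 / 225.0)
        assert est.extras["se_fixed"] == pytest.approx(225.0 ** -0.5)

    def test_random_effects_se_never_below_fixed(self, make_harmonized):
        rng = np.random.default_rng(5)
        for _ in range(20):
            h = make_harmonized(rng.normal(1, 0.1, 6), [0.02] * 6,
                                rng.normal(0.2, 0.2, 6),
                                rng.uniform(0.02, 0.2, 6))
            est = ivw(h)
            assert est.se >= est.extras["se_fixed"] - 1e-15


class TestEgger:
    def test_exact_fit_recovers_line(self, make_harmonized):
        bx = np.array([0.2, 0.5, 0.9])
        h = make_harmonized(bx, [0.01] * 3, 0.05 + 0.2 * bx, [0.05] * 3)
        est = mr_egger(h)
        assert est.beta == pytest.approx(0.2, abs=1e-12)
        assert est.extras["intercept"] == pytest.approx(0.05, abs=1e-12)
        assert est.extras["Q"] == pytest.approx(0.0, abs=1e-18)

    def test_constant_exposure_design_is_singular(self, make_harmonized):
        h = make_harmonized([0.5] * 3, [0.01] * 3, [0.1, 0.2, 0.3], [0.05] * 3)
        with pytest.raises(EstimationError, match="singular"):
            mr_egger(h)

    def test_fewer_than_three_instruments_rejected(self, make_harmonized):
        with pytest.raises(EstimationError, match="3"):
            mr_egger(make_harmonized([1, 1], [0.01] * 2, [0.1, 0.2], [0.05] * 2))

    def test_matches_statsmodels_wls(self, make_harmonized):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(9)
        bx = np.abs(rng.normal(0.5, 0.2, 4))
        by = rng.normal(0.1 + 0.3 * bx, 0.05)
        sy = rng.uniform(0.03, 0.08, 4)
        h = make_harmonized(bx, [0.01] * 4, by, sy)
        est = mr_egger(h)
        fit = sm.WLS(by, sm.add_constant(bx), weights=1.0 / sy ** 2).fit()
        assert est.beta == pytest.approx(fit.params[1], abs=1e-10)
        assert est.extras["intercept"] == pytest.approx(fit.params[0], abs=1e-10)

    def test_orients_exposure_effects_positive(self, make_harmonized):
        bx = np.array([0.2, -0.5, 0.9])
        by = 0.05 * np.sign(bx) + 0.2 * bx  # pleiotropy follows orientation
        h = make_harmonized(bx, [0.01] * 3, by, [0.05] * 3)
        est = mr_egger(h)
        assert est.beta == pytest.approx(0.2, abs=1e-12)
        assert est.extras["intercept"] == pytest.approx(0.05, abs=1e-12)


class TestMedians:
    def test_simple_median_sorting_oracle(self, make_harmonized):
        ratios = np.array([0.7, 0.1, 0.5, 0.3, 0.4])
        h = make_harmonized(np.ones(5), [0.01] * 5, ratios, [0.05] * 5)
        est = simple_median(h, FAST)
        assert est.beta == sorted(ratios)[2]

    def test_identical_ratios_small_bootstrap_se(self, make_harmonized):
        h = make_harmonized(np.ones(4), [1e-6] * 4, np.full(4, 0.3), [1e-6] * 4)
        est = simple_median(h, FAST)
        assert est.beta == pytest.approx(0.3)
        assert est.se < 1e-5

    def test_weighted_reduces_to_simple_under_equal_weights(self, make_harmonized):
        h = make_harmonized(np.ones(5), [0.01] * 5, [0.1, 0.2, 0.3, 0.4, 0.5],
                            [0.05] * 5)
        wm = weighted_median(h, FAST)
        sm_ = simple_median(h, FAST)
        assert wm.beta == pytest.approx(sm_.beta)

    def test_dominant_weight_takes_its_ratio(self, make_harmonized):
        h = make_harmonized(np.ones(4), [0.01] * 4, [0.1, 0.9, 0.8, 0.85],
                            [1e-5, 1.0, 1.0, 1.0])
        assert weighted_median(h, FAST).beta == pytest.approx(0.1, abs=1e-3)

    def test_interpolation_formula_and_wad_grid_oracle(self, make_harmonized):
        # ratios (1,2,4) with weights (0.2,0.3,0.5):
        # cumulative p = (0.1, 0.35, 0.75) -> interpolate 0.5 -> 2.75
        se_out = 1.0 / np.sqrt([0.2, 0.3, 0.5])
        h = make_harmonized(np.ones(3), [0.001] * 3, [1.0, 2.0, 4.0], se_out)
        est = weighted_median(h, FAST)
        assert est.beta == pytest.approx(2.75)
        # the weighted-absolute-deviation objective at the estimate must be
        # within grid resolution of the global grid minimum
        grid = np.linspace(0, 5, 5001)
        w = np.array([0.2, 0.3, 0.5])
        r = np.array([1.0, 2.0, 4.0])
        wad = lambda b: np.sum(w * np.abs(r - b))
        assert wad(est.beta) <= min(wad(g) for g in grid) + 1e-9

    def test_bootstrap_reproducible_under_seed(self, make_harmonized):
        h = make_harmonized(np.ones(5), [0.05] * 5, [0.1, 0.2, 0.3, 0.4, 0.5],
                            [0.05] * 5)
        a = weighted_median(h, EstimatorConfig(n_boot=100, seed=7))
        b = weighted_median(h, EstimatorConfig(n_boot=100, seed=7))
        assert a.se == b.se


class TestPenalizedMedian:
    def test_equals_weighted_median_when_homogeneous(self, make_harmonized):
        h = make_harmonized(np.ones(5), [0.01] * 5,
                            [0.199, 0.2, 0.201, 0.2, 0.199], [0.05] * 5)
        pen = penalized_weighted_median(h, FAST)
        wm = weighted_median(h, FAST)
        assert pen.beta == pytest.approx(wm.beta)

    def test_outlier_downweighted(self, make_harmonized):
        # one gross outlier with the largest weight pulls the plain weighted
        # median away from the consensus; the penalty restores it
        h = make_harmonized(np.ones(5), [0.001] * 5,
                            [0.2, 0.21, 0.19, 0.2, 2.0],
                            [0.05, 0.05, 0.05, 0.05, 0.03])
        pen = penalized_weighted_median(h, FAST)
        wm = weighted_median(h, FAST)
        consensus = 0.2
        assert abs(pen.beta - consensus) < abs(wm.beta - consensus)

    def test_zero_penalty_factor_is_degenerate(self, make_harmonized):
        h = make_harmonized(np.ones(3), [0.001] * 3, [0.1, 0.5, 0.9],
                            [0.01] * 3)
        with pytest.raises(EstimationError):
            penalized_weighted_median(h, EstimatorConfig(n_boot=10, seed=0,
                                                         penalty_k=0.0))


class TestModes:
    def test_identical_ratios_return_common_value(self, make_harmonized):
        h = make_harmonized(np.ones(3), [1e-8] * 3, np.full(3, 0.4), [1e-8] * 3)
        assert mode_estimate(h, config=FAST).beta == pytest.approx(0.4)

    def test_mode_lands_in_dense_cluster(self, make_harmonized):
        ratios = np.array([0.2, 0.21, 0.19, 0.8])
        h = make_harmonized(np.ones(4), [0.01] * 4, ratios, [0.05] * 4)
        est = mode_estimate(h, config=FAST)
        assert 0.15 < est.beta < 0.25

    def test_grid_argmax_matches_independent_kde(self, make_harmonized):
        ratios = np.array([0.2, 0.21, 0.19, 0.8])
        h = make_harmonized(np.ones(4), [0.01] * 4, ratios, [0.05] * 4)
        est = mode_estimate(h, config=FAST)
        k = len(ratios)
        sd = np.std(ratios, ddof=1)
        mad = np.median(np.abs(ratios - np.median(ratios))) / 0.6745
        bw = 0.9 * min(sd, mad) * k ** -0.2
        grid = np.linspace(ratios.min() - 3 * bw, ratios.max() + 3 * bw, 512)
        dens = np.sum([stats.norm.pdf((grid - r) / bw) for r in ratios], axis=0)
        assert est.beta == pytest.approx(grid[np.argmax(dens)], abs=1e-12)

    def test_weighted_mode_dominant_snp(self, make_harmonized):
        h = make_harmonized(np.ones(4), [0.01] * 4, [0.7, 0.1, 0.2, 0.3],
                            [1e-4, 1.0, 1.0, 1.0])
        est = mode_estimate(h, weighted=True, config=FAST)
        assert est.beta == pytest.approx(0.7, abs=0.01)


class TestMaximumLikelihood:
    def test_single_snp_equals_wald_ratio(self, make_harmonized):
        h = make_harmonized([0.5], [0.02], [0.1], [0.05])
        assert maximum_likelihood(h).beta == pytest.approx(0.2, abs=1e-8)

    def test_no_exposure_error_limit_matches_fixed_effect_ivw(self, make_harmonized):
        rng = np.random.default_rng(21)
        bx = np.abs(rng.normal(0.5, 0.1, 6))
        by = rng.normal(0.3 * bx, 0.02)
        h = make_harmonized(bx, [1e-8] * 6, by, [0.02] * 6)
        ml = maximum_likelihood(h)
        w = 1.0 / (0.02 / bx) ** 2
        fixed_ivw = np.sum(w * by / bx) / np.sum(w)
        assert ml.beta == pytest.approx(fixed_ivw, rel=1e-4)

    def test_matches_profile_grid_search(self, make_harmonized):
        bx, sx = np.array([0.4, 0.6, 0.8]), np.array([0.05, 0.04, 0.06])
        by, sy = np.array([0.1, 0.2, 0.25]), np.array([0.03, 0.05, 0.04])
        h = make_harmonized(bx, sx, by, sy)
        ml = maximum_likelihood(h)
        grid = np.linspace(-1, 2, 30_001)
        ll = [_profile_negloglik(t, bx, sx, by, sy) for t in grid]
        assert ml.beta == pytest.approx(grid[int(np.argmin(ll))], abs=1e-4)


class TestORConversion:
    @pytest.mark.parametrize("beta,expected", [
        (0.32490, 1.38389),
        (0.0, 1.00000),
        (0.00360, 1.00361),
        (0.00208, 1.00208),
        (0.00579, 1.00581),
    ])
    def test_printed_log_effects_round_trip(self, beta, expected):
        assert beta_to_or(beta) == expected


class TestBatteryInvariants:
    def _battery(self, h):
        return run_all_methods(h, FAST)

    def test_all_methods_agree_on_identical_ratios(self, make_harmonized):
        bx = np.array([0.3, 0.5, 0.8, 1.1])
        h = make_harmonized(bx, [0.01] * 4, 0.25 * bx, [0.05] * 4)
        for est in self._battery(h):
            assert est.beta == pytest.approx(0.25, abs=1e-9), est.method

    def test_sign_equivariance_of_point_estimates(self, make_harmonized):
        rng = np.random.default_rng(17)
        bx = np.abs(rng.normal(0.5, 0.1, 6))
        by = rng.normal(0.3 * bx, 0.05)
        sy = rng.uniform(0.03, 0.08, 6)
        h_pos = make_harmonized(bx, [0.02] * 6, by, sy)
        h_neg = make_harmonized(bx, [0.02] * 6, -by, sy)
        for ep, en in zip(self._battery(h_pos), self._battery(h_neg)):
            assert en.beta == pytest.approx(-ep.beta, abs=1e-9), ep.method
        # analytic SEs are exactly sign-invariant
        assert ivw(h_pos).se == pytest.approx(ivw(h_neg).se)
        assert mr_egger(h_pos).se == pytest.approx(mr_egger(h_neg).se)

    def test_reorder_invariance_of_point_estimates(self, make_harmonized):
        rng = np.random.default_rng(19)
        bx = np.abs(rng.normal(0.5, 0.1, 6))
        by = rng.normal(0.3 * bx, 0.05)
        sy = rng.uniform(0.03, 0.08, 6)
        perm = rng.permutation(6)
        h1 = make_harmonized(bx, [0.02] * 6, by, sy)
        h2 = make_harmonized(bx[perm], [0.02] * 6, by[perm], sy[perm])
        for e1, e2 in zip(self._battery(h1), self._battery(h2)):
            assert e2.beta == pytest.approx(e1.beta, abs=1e-9), e1.method

    def test_estimates_tighten_as_noise_shrinks(self):
        # every method's error against the generating slope shrinks when
        # per-SNP standard errors drop by 10x
        rng = np.random.default_rng(23)
        bx_true = np.abs(rng.normal(0.5, 0.15, 30))
        errs = {}
        for level, scale in (("noisy", 1.0), ("quiet", 0.1)):
            sx = np.full(30, 0.02 * scale)
            sy = np.full(30, 0.05 * scale)
            bx = rng.normal(bx_true, sx)
            by = rng.normal(0.4 * bx_true, sy)
            h = build_harmonized(bx, sx, by, sy)
            errs[level] = {e.method: abs(e.beta - 0.4)
                           for e in self._battery(h)}
        for method in errs["noisy"]:
            assert errs["quiet"][method] <= errs["noisy"][method] + 1e-3, method
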