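import math

import numpy as np
import pytest
import statsmodels.api as sm

from reprocausal.estimators import (
    egger,
    ivw,
    run_all,
    wald_ratio,
    weighted_median,
    weighted_median_point,
    weighted_mode,
    weighted_mode_point,
)
from reprocausal.exceptions import (
    DegenerateDesignError,
    InsufficientInstrumentsError,
    UndefinedRatioError,
)
from reprocausal.harmonize import HarmonizedData


def random_data(rng, n=10):
    g = rng.normal(0.1, 0.05, n)
    g[np.abs(g) < 1e-3] = 0.05
    sx = rng.uniform(0.005, 0.02, n)
    sy = rng.uniform(0.005, 0.02, n)
    G = 0.3 * g + rng.normal(0, 0.01, n)
    return HarmonizedData.from_arrays(g, sx, G, sy)


class TestWaldRatio:
    def test_ratio_arithmetic(self, worked3):
        est = wald_ratio(worked3.records[0])
        assert est.beta_hat == pytest.approx(0.2)
        assert est.se == pytest.approx(0.1)

    def test_sign_handled(self):
        d = HarmonizedData.from_arrays([-0.1], [0.01], [0.05], [0.01])
        est = wald_ratio(d.records[0])
        assert est.beta_hat == pytest.approx(-0.5)
        assert est.se == pytest.approx(0.1)

    def test_zero_outcome_effect(self):
        d = HarmonizedData.from_arrays([0.1], [0.01], [0.0], [0.01])
        assert wald_ratio(d.records[0]).beta_hat == 0.0

    def test_zero_gamma_is_error(self):
        d = HarmonizedData.from_arrays([0.0], [0.01], [0.05], [0.01])
        with pytest.raises(UndefinedRatioError):
            wald_ratio(d.records[0])


class TestIVW:
    def test_worked_three_snp_example(self, worked3):
        est = ivw(worked3, model="fixed")
        assert est.beta_hat == pytest.approx(127.5 / 525, rel=1e-12)
        assert est.se == pytest.approx(1 / math.sqrt(525), rel=1e-12)
        assert est.n_snp == 3
        assert est.cochran_q.df == 2

    def test_single_snp_equals_wald(self):
        d = HarmonizedData.from_arrays([0.1], [0.01], [0.05], [0.01])
        fe = ivw(d, model="fixed")
        w = wald_ratio(d.records[0])
        assert fe.beta_hat == pytest.approx(w.beta_hat)
        assert fe.se == pytest.approx(w.se)

    def test_zero_heterogeneity_keeps_fixed_se(self):
        g = np.array([0.1, 0.2, 0.4])
        d = HarmonizedData.from_arrays(g, [0.01] * 3, 0.5 * g, [0.01] * 3)
        fe, re = ivw(d, model="fixed"), ivw(d, model="random")
        assert re.beta_hat == pytest.approx(0.5, abs=1e-12)
        assert re.cochran_q.q == pytest.approx(0.0, abs=1e-16)
        assert re.se == pytest.approx(fe.se)

    def test_equals_weighted_regression_through_origin(self, rng):
        """Ratio-combination formula is WLS of Gamma on gamma through the
        origin with weights 1/sigma_Y^2 (independent statsmodels fit)."""
        for _ in range(200):
            d = random_data(rng, n=int(rng.integers(2, 15)))
            g, _, G, sy = d.arrays()
            est = ivw(d, model="fixed")
            fit = sm.WLS(G, g, weights=1.0 / sy**2).fit()
            assert est.beta_hat == pytest.approx(fit.params[0], abs=1e-10)

    def test_ci_brackets_estimate(self, worked3):
        est = ivw(worked3)
        assert est.ci_low < est.beta_hat < est.ci_high

    def test_too_few_snps(self):
        d = HarmonizedData.from_arrays([0.1], [0.01], [0.05], [0.01])
        with pytest.raises(InsufficientInstrumentsError):
            ivw(d, model="random")


class TestEgger:
    def test_exact_linear_data_recovered(self):
        g = np.array([0.05, 0.1, 0.2, 0.3])
        G = 0.01 + 0.5 * g
        d = HarmonizedData.from_arrays(g, [0.01] * 4, G, [0.01] * 4)
        est = egger(d)
        assert est.beta_hat == pytest.approx(0.5, abs=1e-10)
        assert est.intercept.value == pytest.approx(0.01, abs=1e-10)
        # exact fit: residual scale floored at 1, so se is the unscaled WLS se
        w = 1 / 0.01**2
        sw, swx, swxx = 4 * w, w * g.sum(), w * (g**2).sum()
        det = sw * swxx - swx**2
        assert est.se == pytest.approx(math.sqrt(sw / det), rel=1e-10)

    def test_matches_weighted_normal_equations(self, rng):
        """Slope/intercept equal an independent two-parameter WLS solve."""
        for _ in range(100):
            d = random_data(rng, n=int(rng.integers(3, 15)))
            g, _, G, sy = d.arrays()
            s = np.where(g < 0, -1, 1)
            x, y, w = g * s, G * s, 1 / sy**2
            X = sm.add_constant(x)
            fit = sm.WLS(y, X, weights=w).fit()
            est = egger(d)
            assert est.intercept.value == pytest.approx(fit.params[0], abs=1e-10)
            assert est.beta_hat == pytest.approx(fit.params[1], abs=1e-10)
            # when overdispersion > 1 the SEs agree with statsmodels' scaled WLS
            n = len(x)
            resid = y - fit.params[0] - fit.params[1] * x
            scale = (w * resid**2).sum() / (n - 2)
            if scale > 1:
                assert est.se == pytest.approx(fit.bse[1], rel=1e-8)
                assert est.intercept.se == pytest.approx(fit.bse[0], rel=1e-8)

    def test_degenerate_design_raises(self):
        d = HarmonizedData.from_arrays([0.1] * 4, [0.01] * 4, [0.05] * 4, [0.01] * 4)
        with pytest.raises(DegenerateDesignError):
            egger(d)

    def test_too_few_snps(self, worked3):
        d = worked3.without("s3")
        with pytest.raises(InsufficientInstrumentsError):
            egger(d)


class TestWeightedMedian:
    def test_worked_interpolation_value(self, worked3):
        g, _, G, sy = worked3.arrays()
        est = weighted_median_point(G / g, g**2 / sy**2)
        expected = 0.2 + 0.05 * (0.5 - 0.0952381) / (0.5714286 - 0.0952381)
        assert est == pytest.approx(expected, abs=1e-6)
        assert est == pytest.approx(0.2425, abs=2e-4)

    def test_equal_weights_odd_n_is_plain_median(self):
        ratios = np.array([0.1, 0.9, 0.4, 0.2, 0.6])
        assert weighted_median_point(ratios, np.ones(5)) == pytest.approx(0.4)

    def test_bootstrap_se_is_seed_reproducible(self, worked3):
        a = weighted_median(worked3, n_boot=200, seed=42)
        b = weighted_median(worked3, n_boot=200, seed=42)
        c = weighted_median(worked3, n_boot=200, seed=43)
        assert a.se == b.se
        assert a.se != c.se
        assert a.beta_hat == b.beta_hat

    def test_too_few_snps(self, worked3):
        with pytest.raises(InsufficientInstrumentsError):
            weighted_median(worked3.without("s3"))


class TestWeightedMode:
    def test_identical_ratios_returned_directly(self):
        g = np.array([0.1, 0.2, 0.4])
        d = HarmonizedData.from_arrays(g, [0.01] * 3, 0.4 * g, [0.01] * 3)
        est = weighted_mode(d, n_boot=50, seed=1)
        assert est.beta_hat == pytest.approx(0.4, abs=1e-12)

    def test_mode_ignores_single_outlier(self):
        ratios = np.array([0.2, 0.21, 0.22, 0.9])
        got = weighted_mode_point(ratios, np.ones(4))
        assert 0.18 <= got <= 0.24

    def test_grid_argmax_matches_dense_scan(self, rng):
        """Coarse-grid argmax is within one coarse step of a 10x denser scan."""
        for _ in range(20):
            ratios = rng.normal(0.3, 0.1, 12)
            weights = rng.uniform(0.5, 2.0, 12)
            coarse = weighted_mode_point(ratios, weights, grid_points=128)
            dense = weighted_mode_point(ratios, weights, grid_points=1280)
            span = ratios.max() - ratios.min()
            step = (span + 6 * 0.9 * np.std(ratios, ddof=1) * 12 ** (-0.2)) / 127
            assert abs(coarse - dense) <= step

    def test_too_few_snps(self, worked3):
        with pytest.raises(InsufficientInstrumentsError):
            weighted_mode(worked3.without("s3"))


class TestEquivariance:
    @pytest.mark.parametrize("c", [0.5, 2.0, 10.0])
    def test_outcome_scale_equivariance(self, rng, c):
        d = random_data(rng)
        g, sx, G, sy = d.arrays()
        scaled = HarmonizedData.from_arrays(g, sx, c * G, c * sy)
        for fn in (lambda x: ivw(x), lambda x: egger(x)):
            a, b = fn(d), fn(scaled)
            assert b.beta_hat == pytest.approx(c * a.beta_hat, rel=1e-10)
            assert b.se == pytest.approx(c * a.se, rel=1e-10)
        wm_a = weighted_median_point(G / g, g**2 / sy**2)
        wm_b = weighted_median_point(c * G / g, g**2 / (c * sy) ** 2)
        assert wm_b == pytest.approx(c * wm_a, rel=1e-10)

    def test_outcome_sign_equivariance(self, rng):
        d = random_data(rng)
        g, sx, G, sy = d.arrays()
        neg = HarmonizedData.from_arrays(g, sx, -G, sy)
        assert ivw(neg).beta_hat == pytest.approx(-ivw(d).beta_hat, rel=1e-12)
        ea, eb = egger(d), egger(neg)
        assert eb.beta_hat == pytest.approx(-ea.beta_hat, rel=1e-10)
        assert eb.intercept.pvalue == pytest.approx(ea.intercept.pvalue, rel=1e-10)

    def test_q_invariant_under_reordering(self, rng):
        d = random_data(rng, n=8)
        perm = list(rng.permutation(8))
        shuffled = HarmonizedData(
            exposure_name=d.exposure_name,
            outcome_name=d.outcome_name,
            records=[d.records[i] for i in perm],
        )
        assert ivw(shuffled).cochran_q.q == pytest.approx(ivw(d).cochran_q.q, rel=1e-12)


class TestRunAll:
    def test_single_snp_runs_wald_and_ivw_only(self):
        d = HarmonizedData.from_arrays([0.1], [0.01], [0.05], [0.01])
        ests, skipped = run_all(d)
        assert [e.method for e in ests] == ["wald", "ivw_fe"]
        assert set(skipped) == {"egger", "weighted_median", "weighted_mode"}

    def test_ten_snps_run_four_methods(self, rng):
        d = random_data(rng, n=10)
        ests, skipped = run_all(d, n_boot=50)
        assert [e.method for e in ests] == [
            "ivw_re", "egger", "weighted_median", "weighted_mode",
        ]
        assert skipped == []
        assert ests[0].cochran_q is not None

    def test_consistent_simulation_recovers_truth_across_methods(self, rng):
        """Strong valid instruments: all four estimators land near the true
        effect (joint consistency under no pleiotropy)."""
        n, beta = 30, -0.22
        g = rng.normal(0.15, 0.03, n) * rng.choice([-1, 1], n)
        sx = np.full(n, 0.005)
        sy = np.full(n, 0.005)
        G = beta * g + rng.normal(0, sy)
        d = HarmonizedData.from_arrays(g + rng.normal(0, sx), sx, G, sy)
        ests, _ = run_all(d, seed=3, n_boot=100)
        for est in ests:
            assert est.beta_hat == pytest.approx(beta, abs=0.08), est.method
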