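import numpy as np
import pytest
import statsmodels.api as sm

from mrkit.estimators import (
    egger,
    ivw_fixed,
    ivw_mre,
    ratio_estimates,
    weighted_median,
)
from mrkit.exceptions import CollinearityError, EstimationError
from mrkit.model import MRModel, weighted_median as wm_interp

from .conftest import random_pairs


class TestRatios:
    def test_arithmetic(self):
        m = MRModel([0.1], [0.01], [0.02], [0.01])
        (r,) = ratio_estimates(m)
        assert r.theta == pytest.approx(0.2)
        assert r.sigma == pytest.approx(0.1)
        assert r.weight == pytest.approx(100.0)

    def test_negative_exposure_effect(self):
        m = MRModel([0.2], [0.01], [-0.046], [0.01])
        (r,) = ratio_estimates(m)
        assert r.theta == pytest.approx(-0.23)
        assert r.sigma == pytest.approx(0.05)

    def test_allele_recoding_invariance(self):
        a = ratio_estimates(MRModel([0.1], [0.01], [0.02], [0.01]))[0]
        b = ratio_estimates(MRModel([-0.1], [0.01], [-0.02], [0.01]))[0]
        assert (a.theta, a.sigma) == (b.theta, b.sigma)

    def test_zero_exposure_effect_excluded(self):
        m = MRModel([0.1, 0.0], [0.01, 0.01], [0.02, 0.01], [0.01, 0.01],
                    ["rs1", "rs2"])
        assert m.k == 1 and m.excluded_ids == ["rs2"]


class TestIVW:
    def test_three_snp_fixture_closed_form(self, three_snp_model):
        res = ivw_fixed(three_snp_model)
        assert res.beta == pytest.approx(-0.2193103448, abs=1e-9)
        assert res.se == pytest.approx(0.0371390676, abs=1e-9)
        assert res.or_ == pytest.approx(0.8031, abs=1e-4)
        assert res.k == 3

    def test_single_instrument_equals_wald_ratio(self):
        m = MRModel([0.1], [0.01], [0.02], [0.01])
        res = ivw_fixed(m)
        assert res.beta == pytest.approx(0.2)
        assert res.se == pytest.approx(0.1)

    def test_equal_ratios_conserved(self):
        m = MRModel([0.1, 0.2, 0.4], [0.01] * 3, [0.03, 0.06, 0.12],
                    [0.01, 0.02, 0.05])
        assert ivw_fixed(m).beta == pytest.approx(0.3)

    def test_equals_wls_through_origin(self, rng):
        pairs = random_pairs(rng, k=12)
        m = MRModel.from_pairs(pairs)
        res = ivw_fixed(m)
        wls = sm.WLS(m.beta_y, m.beta_x, weights=1.0 / m.se_y**2).fit()
        assert res.beta == pytest.approx(wls.params[0], abs=1e-10)
        # fe-IVW se is the fixed-effect (unit-scale) WLS se
        se_fixed = float(np.sqrt(np.asarray(wls.cov_params())[0, 0] / wls.scale))
        assert res.se == pytest.approx(se_fixed, abs=1e-10)

    def test_mre_point_estimate_identical_se_scaled(self, three_snp_model):
        fe = ivw_fixed(three_snp_model)
        mre = ivw_mre(three_snp_model)
        assert mre.beta == fe.beta
        # Q = 0.1297 < k-1 so the truncated scale is exactly 1
        assert mre.extras["cochran_q"] == pytest.approx(0.12965517, abs=1e-7)
        assert mre.se == fe.se

    def test_mre_se_doubles_when_q_is_4df(self):
        # two duplicated precise ratios at +-c give Q = 2*w*c^2; choose c so
        # Q/(k-1) = 4 exactly
        w = 100.0  # sigma = 0.1
        k = 4
        c = np.sqrt(4 * (k - 1) / (2 * 2 * w))
        bx = np.array([1.0, 1.0, 1.0, 1.0])
        by = np.array([c, c, -c, -c])
        m = MRModel(bx, [0.01] * 4, by, [0.1] * 4)
        fe, mre = ivw_fixed(m), ivw_mre(m)
        assert mre.se == pytest.approx(2 * fe.se, rel=1e-12)

    def test_underdispersion_truncated_unless_disabled(self):
        m = MRModel([1.0, 1.0, 1.0], [0.01] * 3, [0.2, 0.2, 0.2], [0.1] * 3)
        fe, mre = ivw_fixed(m), ivw_mre(m)
        assert mre.se == fe.se
        free = m.fit("ivw_mre", truncate_scale=False)
        assert free.se < fe.se

    def test_needs_instruments(self):
        empty = MRModel([], [], [], [])
        with pytest.raises(EstimationError):
            ivw_fixed(empty)
        single = MRModel([0.1], [0.01], [0.02], [0.01])
        with pytest.raises(EstimationError):
            ivw_mre(single)


class TestWeightedMedian:
    def test_plain_median_with_equal_weights(self):
        assert wm_interp([0.1, 0.2, 0.3], [1, 1, 1]) == pytest.approx(0.2)

    def test_interpolated_fixture(self):
        assert wm_interp([0.1, 0.2, 0.6], [1, 1, 2]) == pytest.approx(
            1.0 / 3.0, abs=1e-12)

    def test_order_invariance(self):
        assert wm_interp([0.6, 0.1, 0.2], [2, 1, 1]) == pytest.approx(
            wm_interp([0.1, 0.2, 0.6], [1, 1, 2]))

    def test_equal_weights_odd_k_is_sample_median(self, rng):
        theta = rng.normal(size=9)
        assert wm_interp(theta, np.ones(9)) == pytest.approx(
            float(np.median(theta)))

    def test_bootstrap_se_seeded_and_reproducible(self, rng):
        pairs = random_pairs(rng, k=10)
        a = weighted_median(pairs, n_boot=200, seed=5)
        b = weighted_median(pairs, n_boot=200, seed=5)
        assert a.se == b.se and a.beta == b.beta
        assert a.extras == {"n_boot": 200, "seed": 5}

    def test_needs_three_instruments(self):
        m = MRModel([0.1, 0.2], [0.01] * 2, [0.02, 0.04], [0.01] * 2)
        with pytest.raises(EstimationError):
            weighted_median(m, n_boot=10, seed=0)


class TestEgger:
    def test_exact_fit_recovers_slope_and_intercept(self):
        bx = np.array([0.05, 0.1, 0.2, 0.3])
        a, th = 0.01, -0.25
        by = th * bx + a
        m = MRModel(bx, [0.01] * 4, by, [0.01, 0.02, 0.01, 0.03])
        slope, intercept = egger(m)
        assert slope.beta == pytest.approx(th, abs=1e-12)
        assert intercept.beta == pytest.approx(a, abs=1e-12)

    def test_zero_intercept_when_no_pleiotropy(self):
        bx = np.array([0.05, 0.1, 0.2, 0.3])
        m = MRModel(bx, [0.01] * 4, -0.2 * bx, [0.01] * 4)
        _, intercept = egger(m)
        assert intercept.beta == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        pairs = random_pairs(rng, k=4)
        m = MRModel.from_pairs(pairs)
        slope, intercept = egger(m, truncate_scale=False)
        sign = np.where(m.beta_x < 0, -1, 1)
        bx, by = sign * m.beta_x, sign * m.beta_y
        X = sm.add_constant(bx)
        fit = sm.WLS(by, X, weights=1.0 / m.se_y**2).fit()
        assert intercept.beta == pytest.approx(fit.params[0], abs=1e-10)
        assert slope.beta == pytest.approx(fit.params[1], abs=1e-10)
        assert intercept.se == pytest.approx(fit.bse[0], abs=1e-10)
        assert slope.se == pytest.approx(fit.bse[1], abs=1e-10)
        assert slope.pval == pytest.approx(fit.pvalues[1], abs=1e-10)

    def test_collinear_design_rejected(self):
        m = MRModel([0.1] * 4, [0.01] * 4, [0.02] * 4, [0.01] * 4)
        with pytest.raises(CollinearityError):
            egger(m)

    def test_needs_three_instruments(self):
        m = MRModel([0.1, 0.2], [0.01] * 2, [0.02, 0.04], [0.01] * 2)
        with pytest.raises(EstimationError):
            egger(m)


class TestAlleleRecodingInvariance:
    def test_all_methods_invariant_to_recoding_one_snp(self, rng):
        pairs = random_pairs(rng, k=10)
        m1 = MRModel.from_pairs(pairs)
        bx = m1.beta_x.copy()
        by = m1.beta_y.copy()
        bx[3] *= -1
        by[3] *= -1
        m2 = MRModel(bx, m1.se_x, by, m1.se_y)
        for method in ("ivw_fe", "ivw_mre", "egger"):
            r1 = m1.fit(method)
            r2 = m2.fit(method)
            assert r1.beta == pytest.approx(r2.beta, abs=1e-12)
            assert r1.se == pytest.approx(r2.se, abs=1e-12)
        w1 = m1.fit("weighted_median", n_boot=50, seed=1)
        w2 = m2.fit("weighted_median", n_boot=50, seed=1)
        assert w1.beta == pytest.approx(w2.beta, abs=1e-12)


class TestResultContract:
    def test_ci_brackets_or_and_summary_prints(self, three_snp_model):
        res = three_snp_model.fit("ivw_fe")
        assert res.ci_low < res.or_ < res.ci_high
        text = res.summary()
        assert "ivw_fe" in text and "OR" in text
        eg = three_snp_model.fit("egger")
        assert "intercept" in eg.summary()
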