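import numpy as np
import pytest

from bbpcmap.quantify import (
    BBPCMap,
    CBFMap,
    WCMap,
    age_regression,
    compute_bbpc,
    contrast_to_noise,
    correct_cbf,
    method_agreement,
    roi_mean,
)

SHAPE = (6, 6, 4)


class TestComputeBbpc:
    def test_inverse_construction(self):
        wc = WCMap(np.full(SHAPE, 0.83 * 0.8 * 1.04))
        bbpc = compute_bbpc(wc, wc_blood=0.8)
        np.testing.assert_allclose(bbpc.values, 0.83, rtol=1e-12)

    def test_identity_point(self):
        wc = WCMap(np.full(SHAPE, 0.8 * 1.04))
        bbpc = compute_bbpc(wc, wc_blood=0.8)
        np.testing.assert_allclose(bbpc.values, 1.0, rtol=1e-12)

    def test_blood_roi_fixed_point(self):
        # hct-normalized blood mean is wc_blood, so its BBPC is 1/1.04
        wc = WCMap(np.full(SHAPE, 0.79005))
        bbpc = compute_bbpc(wc, wc_blood=0.79005)
        np.testing.assert_allclose(bbpc.values, 1.0 / 1.04, rtol=1e-12)

    def test_invalid_wc_blood(self):
        with pytest.raises(ValueError):
            compute_bbpc(WCMap(np.ones(SHAPE)), wc_blood=0.0)

    def test_metadata_recorded(self):
        bbpc = compute_bbpc(WCMap(np.ones(SHAPE)), wc_blood=0.77)
        assert bbpc.wc_blood_used == pytest.approx(0.77)
        assert bbpc.density_g_per_ml == pytest.approx(1.04)


class TestCorrectCbf:
    def test_bbpc_equal_to_lambda_is_identity(self):
        rng = np.random.default_rng(0)
        cbf = CBFMap(rng.uniform(20, 120, SHAPE))
        out = correct_cbf(cbf, BBPCMap(np.full(SHAPE, 0.9)), assumed_lambda=0.9)
        np.testing.assert_allclose(out.values, cbf.values, rtol=1e-12)

    def test_printed_constants(self):
        cbf = CBFMap(np.full(SHAPE, 81.0))
        out = correct_cbf(cbf, BBPCMap(np.full(SHAPE, 0.83)))
        np.testing.assert_allclose(out.values, 74.7, rtol=1e-12)

    def test_zero_stays_zero(self):
        out = correct_cbf(CBFMap(np.zeros(SHAPE)), BBPCMap(np.full(SHAPE, 0.83)))
        np.testing.assert_array_equal(out.values, 0.0)

    def test_linear_in_both_arguments(self):
        rng = np.random.default_rng(1)
        cbf_vals = rng.uniform(10, 100, SHAPE)
        bbpc_vals = rng.uniform(0.7, 0.9, SHAPE)
        base = correct_cbf(CBFMap(cbf_vals), BBPCMap(bbpc_vals))
        scaled_cbf = correct_cbf(CBFMap(3.0 * cbf_vals), BBPCMap(bbpc_vals))
        scaled_bbpc = correct_cbf(CBFMap(cbf_vals), BBPCMap(3.0 * bbpc_vals))
        np.testing.assert_allclose(scaled_cbf.values, 3.0 * base.values, rtol=1e-12)
        np.testing.assert_allclose(scaled_bbpc.values, 3.0 * base.values, rtol=1e-12)

    def test_grid_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            correct_cbf(CBFMap(np.zeros(SHAPE)), BBPCMap(np.zeros((3, 3, 3))))


class TestContrastToNoise:
    def _masks(self, n_gm=2, n_wm=2):
        gm = np.zeros(SHAPE, dtype=bool)
        wm = np.zeros(SHAPE, dtype=bool)
        gm.flat[:n_gm] = True
        wm.flat[n_gm : n_gm + n_wm] = True
        return gm, wm

    def test_hand_example(self):
        values = np.zeros(SHAPE)
        gm, wm = self._masks()
        values[gm] = [80.0, 82.0]
        values[wm] = [56.0, 58.0]
        cnr = contrast_to_noise(values, gm, wm)
        assert cnr == pytest.approx(16.9706, abs=1e-4)

    def test_identical_distributions_near_zero(self):
        rng = np.random.default_rng(2)
        values = rng.normal(70, 10, SHAPE)
        gm, wm = self._masks(n_gm=60, n_wm=60)
        assert abs(contrast_to_noise(values, gm, wm)) < 1.0

    def test_overlapping_masks_rejected(self):
        gm, _ = self._masks()
        with pytest.raises(ValueError, match="disjoint"):
            contrast_to_noise(np.zeros(SHAPE), gm, gm)

    def test_sign_is_gm_minus_wm(self):
        values = np.zeros(SHAPE)
        gm, wm = self._masks()
        values[gm] = [50.0, 52.0]
        values[wm] = [80.0, 84.0]
        assert contrast_to_noise(values, gm, wm) < 0


class TestMethodAgreement:
    def test_identical_lists(self):
        x = np.array([0.80, 0.83, 0.86, 0.78])
        a = method_agreement(x, x)
        assert a.r_squared == pytest.approx(1.0)
        assert a.bias == pytest.approx(0.0)
        assert a.limits == (pytest.approx(0.0), pytest.approx(0.0))

    def test_constant_offset(self):
        x = np.array([0.80, 0.83, 0.86, 0.78])
        a = method_agreement(x, x + 0.01)
        assert a.r_squared == pytest.approx(1.0)
        assert a.bias == pytest.approx(0.01)

    def test_known_correlation_sampling(self):
        # r = 0.9 bivariate normal: sample R^2 near 0.81 at n = 200
        rng = np.random.default_rng(3)
        n, rho = 200, 0.9
        x = rng.standard_normal(n)
        y = rho * x + np.sqrt(1 - rho**2) * rng.standard_normal(n)
        a = method_agreement(x, y)
        assert a.r_squared == pytest.approx(0.81, abs=0.05)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="equal length"):
            method_agreement([1.0, 2.0, 3.0], [1.0, 2.0])

    def test_limits_bracket_bias(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(50)
        y = x + rng.normal(0.05, 0.1, 50)
        a = method_agreement(x, y)
        lo, hi = a.limits
        assert lo < a.bias < hi
        assert hi - a.bias == pytest.approx(1.96 * np.std(y - x, ddof=1), rel=1e-12)


class TestAgeRegression:
    def test_exact_line(self):
        ages = np.array([5.0, 5.5, 6.0, 6.5, 7.0, 7.5, 8.0])
        values = 128.0 - 7.5 * ages
        slope, intercept, p = age_regression(values, ages)
        assert slope == pytest.approx(-7.5, rel=1e-12)
        assert intercept == pytest.approx(128.0, rel=1e-12)
        assert p < 1e-6

    def test_constant_values(self):
        slope, intercept, p = age_regression(np.full(5, 70.0), np.arange(5.0, 7.5, 0.5))
        assert slope == 0.0
        assert p == 1.0

    def test_constant_ages_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            age_regression([1.0, 2.0, 3.0], [6.0, 6.0, 6.0])

    def test_permutation_null_p_uniform(self):
        # under shuffled pairing the slope p-value should be ~Uniform(0,1)
        rng = np.random.default_rng(5)
        ages = rng.uniform(5, 8, 24)
        values = 128.0 - 7.5 * ages + rng.normal(0, 2, 24)
        pvals = []
        for _ in range(200):
            shuffled = rng.permutation(values)
            _, _, p = age_regression(shuffled, ages)
            pvals.append(p)
        pvals = np.array(pvals)
        # coarse uniformity: mean ~0.5, ~10% below 0.1
        assert 0.40 < pvals.mean() < 0.60
        assert 0.03 < np.mean(pvals < 0.1) < 0.20

    def test_sex_covariate(self):
        rng = np.random.default_rng(6)
        ages = rng.uniform(5, 8, 40)
        sex = rng.integers(0, 2, 40)
        values = 128.0 - 7.5 * ages + 4.0 * sex + rng.normal(0, 0.5, 40)
        slope, _, p = age_regression(values, ages, covariate_sex=sex)
        assert slope == pytest.approx(-7.5, abs=0.2)
        assert p < 1e-6


class TestRoiMean:
    def test_excludes_nan(self):
        values = np.full(SHAPE, np.nan)
        mask = np.ones(SHAPE, dtype=bool)
        values[0, 0, 0] = 3.0
        assert roi_mean(values, mask) == 3.0

    def test_empty_roi(self):
        with pytest.raises(ValueError):
            roi_mean(np.full(SHAPE, np.nan), np.ones(SHAPE, dtype=bool))
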