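import numpy as np
import pytest

from bbpcmap.calibration import (
    BloodSample,
    CalibrationLine,
    PhantomSet,
    WATER_FRACTIONS,
    apply_error_correction,
    fit_phantom_line,
    fit_ratio_regression,
    hct_blood_water,
    normalize_hct,
    normalize_phantom,
    phantom_means,
)
from bbpcmap.recovery import M0Map

SHAPE = (20, 12, 4)


def _m0map(values):
    values = np.asarray(values, dtype=np.float64)
    return M0Map(values, np.isfinite(values), np.zeros_like(values))


def _vials(values=(60.0, 70.0, 80.0, 90.0, 100.0)):
    """Five disjoint 2x12x4 slabs with constant values; returns (map, set)."""
    data = np.full(SHAPE, np.nan)
    masks = []
    for i, v in enumerate(values):
        mask = np.zeros(SHAPE, dtype=bool)
        mask[4 * i : 4 * i + 2] = True
        data[mask] = v
        masks.append(mask)
    return _m0map(data), PhantomSet(masks=masks)


class TestHctFormula:
    # anchors forced by the printed linear formula
    @pytest.mark.parametrize(
        "hct,expected", [(0.0, 0.912), (0.45, 0.79005), (1.0, 0.641)]
    )
    def test_exact_values(self, hct, expected):
        assert hct_blood_water(hct) == pytest.approx(expected, abs=1e-15)

    def test_percent_input_rescaled(self):
        assert hct_blood_water(45.0) == pytest.approx(hct_blood_water(0.45))

    def test_nonsense_input_rejected(self):
        with pytest.raises(ValueError):
            hct_blood_water(1.3)
        with pytest.raises(ValueError):
            hct_blood_water(-0.1)


class TestPhantomMeans:
    def test_constant_vials(self):
        m0, phantoms = _vials()
        np.testing.assert_allclose(phantom_means(m0, phantoms), [60, 70, 80, 90, 100])

    def test_all_nan_vial_named(self):
        m0, phantoms = _vials()
        m0.values[phantoms.masks[2]] = np.nan
        with pytest.raises(ValueError, match="vial 3"):
            phantom_means(m0, phantoms)

    def test_noisy_vials_within_1pc(self):
        rng = np.random.default_rng(0)
        m0, phantoms = _vials()
        noisy = m0.values * (1 + rng.standard_normal(SHAPE) / 50.0)
        means = phantom_means(_m0map(noisy), phantoms)
        np.testing.assert_allclose(means, [60, 70, 80, 90, 100], rtol=0.01)

    def test_overlapping_masks_rejected(self):
        masks = [np.ones(SHAPE, dtype=bool)] * 5
        with pytest.raises(ValueError, match="disjoint"):
            PhantomSet(masks=masks)


class TestPhantomLine:
    def test_exact_line(self):
        line = fit_phantom_line(np.array([60.0, 70, 80, 90, 100]))
        assert line.slope == pytest.approx(0.01, rel=1e-12)
        assert line.intercept == pytest.approx(0.0, abs=1e-12)
        assert line.r_squared == pytest.approx(1.0)

    def test_scale(self):
        line = fit_phantom_line(np.array([120.0, 140, 160, 180, 200]))
        assert line.slope == pytest.approx(0.005, rel=1e-12)
        assert line.intercept == pytest.approx(0.0, abs=1e-12)

    def test_noisy_line_r_squared(self):
        rng = np.random.default_rng(1)
        means = np.array([60.0, 70, 80, 90, 100]) * (1 + rng.uniform(-0.01, 0.01, 5))
        assert fit_phantom_line(means).r_squared > 0.99

    def test_degenerate_means(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_phantom_line(np.full(5, 80.0))

    def test_water_fraction_complement(self):
        assert WATER_FRACTIONS == (0.60, 0.70, 0.80, 0.90, 1.00)


class TestRatioRegression:
    def test_constant_ratio_null(self):
        cohort = [(f"s{i}", 0.7 * p, p) for i, p in enumerate([60.0, 80, 100, 120, 140])]
        reg = fit_ratio_regression(cohort)
        assert reg.beta == pytest.approx(0.0, abs=1e-12)
        assert all(abs(d) < 1e-8 for d in reg.per_subject_error.values())

    def test_injected_gain_nonlinearity_gives_negative_beta(self):
        c = 0.002
        gains = np.linspace(60, 140, 8)
        cohort = []
        for i, g in enumerate(gains):
            p_true, t_true = 0.8 * g, 0.7 * g
            cohort.append((f"s{i}", t_true, p_true * (1 + c * g)))
        assert fit_ratio_regression(cohort).beta < 0

    def test_two_subjects_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            fit_ratio_regression([("a", 1.0, 2.0), ("b", 1.1, 2.1)])


class TestErrorCorrection:
    def _setup(self, blood_value=80.0):
        data = np.full(SHAPE, 70.0)
        brain = np.zeros(SHAPE, dtype=bool)
        brain[:8] = True
        blood_mask = np.zeros(SHAPE, dtype=bool)
        blood_mask[10:12] = True
        data[blood_mask] = blood_value
        m0 = _m0map(data)
        blood = BloodSample.from_map(m0, blood_mask, hct=0.45)
        return m0, brain, blood

    def test_zero_delta_identity(self):
        m0, brain, blood = self._setup()
        out, blood_out = apply_error_correction(m0, brain, blood, 0.0)
        np.testing.assert_array_equal(out.values, m0.values)
        assert blood_out.mean_m0 == blood.mean_m0

    def test_negative_delta_raises_blood_mean(self):
        m0, brain, blood = self._setup(blood_value=80.0)
        _, blood_out = apply_error_correction(m0, brain, blood, -5.0)
        assert blood_out.mean_m0 == pytest.approx(85.0)

    def test_phantom_voxels_untouched(self):
        m0, brain, blood = self._setup()
        vial_region = np.zeros(SHAPE, dtype=bool)
        vial_region[14:16] = True
        out, _ = apply_error_correction(m0, brain, blood, -5.0)
        np.testing.assert_array_equal(out.values[vial_region], m0.values[vial_region])
        np.testing.assert_allclose(out.values[brain], m0.values[brain] + 5.0)

    def test_overcorrection_rejected(self):
        m0, brain, blood = self._setup(blood_value=10.0)
        with pytest.raises(ValueError, match="blood mean"):
            apply_error_correction(m0, brain, blood, 50.0)


class TestNormalization:
    def test_phantom_route_evaluates_line(self):
        m0 = _m0map(np.full(SHAPE, 83.0))
        wc = normalize_phantom(m0, CalibrationLine(0.01, 0.0, 1.0))
        np.testing.assert_allclose(wc.values, 0.83)

    def test_phantom_self_consistency(self):
        rng = np.random.default_rng(4)
        m0, phantoms = _vials()
        noisy = _m0map(m0.values * (1 + rng.standard_normal(SHAPE) / 100.0))
        means = phantom_means(noisy, phantoms)
        line = fit_phantom_line(means)
        wc = normalize_phantom(noisy, line)
        recovered = np.array([np.nanmean(wc.values[m]) for m in phantoms.masks])
        resid = np.abs(np.asarray(WATER_FRACTIONS) - (line.slope * means + line.intercept))
        np.testing.assert_allclose(recovered, WATER_FRACTIONS, atol=max(resid.max(), 1e-6) + 1e-9)

    def test_hct_route_rescales(self):
        data = np.full(SHAPE, 100.0)
        blood_mask = np.zeros(SHAPE, dtype=bool)
        blood_mask[:2] = True
        m0 = _m0map(data)
        blood = BloodSample(mask=blood_mask, mean_m0=100.0, hct=0.45, wc_blood=0.8)
        wc = normalize_hct(m0, blood)
        np.testing.assert_allclose(wc.values, 0.8)

    def test_hct_blood_mean_exact_by_construction(self):
        rng = np.random.default_rng(5)
        data = rng.uniform(50, 120, SHAPE)
        blood_mask = np.zeros(SHAPE, dtype=bool)
        blood_mask[5:8] = True
        m0 = _m0map(data)
        blood = BloodSample.from_map(m0, blood_mask, hct=0.41)
        wc = normalize_hct(m0, blood)
        assert np.nanmean(wc.values[blood_mask]) == pytest.approx(blood.wc_blood, rel=1e-12)

    def test_routes_agree_in_slope_only_world(self):
        # no offset, no nonlinearity: both calibrations are pure rescalings
        rng = np.random.default_rng(6)
        wc_true = rng.uniform(0.6, 1.0, SHAPE)
        gain = 87.3
        m0 = _m0map(gain * wc_true)
        vial_masks = []
        for i, wf in enumerate(WATER_FRACTIONS):
            mask = np.zeros(SHAPE, dtype=bool)
            mask[4 * i : 4 * i + 2, :2] = True
            m0.values[mask] = gain * wf
            vial_masks.append(mask)
        blood_mask = np.zeros(SHAPE, dtype=bool)
        blood_mask[:2, 10:] = True
        hct = 0.45
        wc_blood = hct_blood_water(hct)
        m0.values[blood_mask] = gain * wc_blood
        line = fit_phantom_line(phantom_means(m0, PhantomSet(masks=vial_masks)))
        blood = BloodSample.from_map(m0, blood_mask, hct=hct)
        wc_a = normalize_phantom(m0, line)
        wc_b = normalize_hct(m0, blood)
        np.testing.assert_allclose(wc_a.values, wc_b.values, rtol=1e-9)


class TestBloodSample:
    def test_wc_blood_derived_from_hct(self):
        mask = np.ones((2, 2, 2), dtype=bool)
        blood = BloodSample(mask=mask, mean_m0=90.0, hct=0.45)
        assert blood.wc_blood == pytest.approx(0.79005)

    def test_empty_blood_mask(self):
        m0 = _m0map(np.full(SHAPE, np.nan))
        with pytest.raises(ValueError, match="no fitted voxels"):
            BloodSample.from_map(m0, np.ones(SHAPE, dtype=bool), hct=0.45)
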