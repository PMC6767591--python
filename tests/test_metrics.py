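"""SNR estimation, ventilation thresholding, RMSE and agreement statistics."""

import numpy as np
import pytest

import fluolung as fl
from fluolung.errors import InvalidParameterError
from fluolung.metrics import RoiSpec, default_stats_region, roi_mask


def _flat_image(shape=(32, 32, 8), value=0.0):
    return fl.ImageVolume(values=np.full(shape, value), voxel_size=(1.0, 1.0, 1.0))


class TestMeasureSnr:
    def _rois(self):
        sig = RoiSpec(center=(8.0, 8.0, 4.5), diameter=8.0, plane=4)
        noi = RoiSpec(center=(24.0, 24.0, 4.5), diameter=8.0, plane=4)
        return sig, noi

    def test_direct_formula(self, rng):
        img = _flat_image(value=10.0)
        sig, noi = self._rois()
        values = img.values.copy()
        nmask = roi_mask(values.shape, img.voxel_size, noi)
        noise = rng.standard_normal(nmask.sum())
        noise = (noise - noise.mean()) / noise.std()  # exactly unit std
        values[nmask] = noise
        out = fl.measure_snr(
            fl.ImageVolume(values=values, voxel_size=img.voxel_size), sig, noi
        )
        assert out == pytest.approx(6.6, rel=1e-9)

    def test_scale_invariance(self, rng):
        values = rng.random((32, 32, 8)) + 0.5
        sig, noi = self._rois()
        a = fl.measure_snr(fl.ImageVolume(values=values), sig, noi)
        b = fl.measure_snr(fl.ImageVolume(values=7.3 * values), sig, noi)
        assert a == pytest.approx(b)

    def test_monte_carlo_rayleigh_relation(self):
        # magnitude of complex Gaussian noise: std = 0.655 sigma, so the
        # estimator returns ~ 0.66 S / (0.655 sigma)
        rng = np.random.default_rng(314)
        shape = (256, 256, 4)
        sigma, s_val = 0.7, 12.0
        values = np.abs(
            sigma * (rng.standard_normal(shape) + 1j * rng.standard_normal(shape))
        )
        sig, noi = (
            RoiSpec(center=(64.0, 64.0, 2.5), diameter=80.0, plane=2),
            RoiSpec(center=(192.0, 192.0, 2.5), diameter=80.0, plane=2),
        )
        smask = roi_mask(shape, (1, 1, 1), sig)
        values[smask] = s_val
        out = fl.measure_snr(fl.ImageVolume(values=values), sig, noi)
        assert out == pytest.approx(0.66 * s_val / (0.6551 * sigma), rel=0.05)

    def test_zero_noise_variance_rejected(self):
        sig, noi = self._rois()
        with pytest.raises(InvalidParameterError):
            fl.measure_snr(_flat_image(value=5.0), sig, noi)


class TestRayleighCorrection:
    def test_closed_form_and_rounding(self):
        assert fl.rayleigh_correction() == pytest.approx(np.sqrt(2 - np.pi / 2))
        assert round(fl.rayleigh_correction(), 5) == 0.65514
        assert fl.rayleigh_correction(ndigits=2) == 0.66

    def test_monte_carlo_convergence(self):
        rng = np.random.default_rng(77)
        mags = np.abs(rng.standard_normal(10**6) + 1j * rng.standard_normal(10**6))
        assert np.std(mags) == pytest.approx(fl.rayleigh_correction(), abs=0.003)


class TestVentilatedVolume:
    def test_uniform_image_fully_ventilated(self):
        img = _flat_image(value=3.0)
        region = np.ones(img.values.shape, dtype=bool)
        vv, thr, mask = fl.ventilated_volume(img, stats_region=region)
        assert mask.all()
        assert vv == pytest.approx(np.prod(img.values.shape) * 1e-6)

    def test_noiseless_phantom_recovers_truth_exactly(self, phantom):
        img = fl.ImageVolume(values=np.abs(phantom.values), voxel_size=phantom.voxel_size)
        vv, _, _ = fl.ventilated_volume(img, airway_mask=phantom.airway_mask)
        assert vv == pytest.approx(phantom.true_ventilated_volume, abs=1e-12)

    def test_removing_airway_mask_adds_airway_volume(self, phantom):
        img = fl.ImageVolume(values=np.abs(phantom.values), voxel_size=phantom.voxel_size)
        vv_excl, _, _ = fl.ventilated_volume(img, airway_mask=phantom.airway_mask)
        vv_incl, _, _ = fl.ventilated_volume(img, airway_mask=None)
        airway_l = phantom.airway_mask.sum() * np.prod(phantom.voxel_size) * 1e-6
        assert vv_incl - vv_excl == pytest.approx(airway_l)

    def test_threshold_shifts_with_constant_offset(self, phantom):
        img = np.abs(phantom.values)
        region = default_stats_region(img)
        vv0, thr0, m0 = fl.ventilated_volume(img, stats_region=region)
        vv1, thr1, m1 = fl.ventilated_volume(img + 5.0, stats_region=region)
        assert thr1 - thr0 == pytest.approx(5.0)
        assert np.array_equal(m0, m1)
        assert vv0 == vv1

    def test_empty_stats_region_rejected(self):
        with pytest.raises(InvalidParameterError):
            fl.ventilated_volume(
                _flat_image(), stats_region=np.zeros((32, 32, 8), dtype=bool)
            )


class TestVdp:
    def test_fully_ventilated_is_zero(self):
        assert fl.vdp(5.0, 5.0) == 0.0

    def test_arithmetic(self):
        assert fl.vdp(5.0, 4.5) == pytest.approx(10.0)

    def test_phantom_defect_fraction(self, phantom):
        expected = 100.0 * phantom.defect_mask.sum() / phantom.lung_mask.sum()
        out = fl.vdp(phantom.true_total_volume, phantom.true_ventilated_volume)
        assert out == pytest.approx(expected, abs=1e-9)

    def test_consistency_identity(self, phantom):
        img = fl.ImageVolume(values=np.abs(phantom.values), voxel_size=phantom.voxel_size)
        vv, _, _ = fl.ventilated_volume(img, airway_mask=phantom.airway_mask)
        total = phantom.true_total_volume
        assert fl.vdp(total, vv) + 100.0 * vv / total == pytest.approx(100.0)

    def test_zero_total_rejected(self):
        with pytest.raises(InvalidParameterError):
            fl.vdp(0.0, 0.0)


class TestRmseImages:
    def test_identical_images_zero(self, rng):
        img = rng.random((8, 8, 8))
        assert fl.rmse_images(img, img)[0] == 0.0

    def test_constant_difference(self, rng):
        img = rng.random((8, 8, 8))
        rmse, rel = fl.rmse_images(img, img + 0.25, scale_to=0.5)
        assert rmse == pytest.approx(0.25)
        assert rel == pytest.approx(0.5)

    def test_self_relative_normalization_is_one(self, rng):
        a, b = rng.random((8, 8, 8)), rng.random((8, 8, 8))
        rmse, _ = fl.rmse_images(a, b)
        assert fl.rmse_images(a, b, scale_to=rmse)[1] == pytest.approx(1.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(InvalidParameterError):
            fl.rmse_images(np.zeros((4, 4, 4)), np.zeros((4, 4, 5)))


class TestAgreementStats:
    def test_identical_vectors(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        out = fl.agreement_stats(x, x)
        assert out.bias == 0.0
        assert out.loa_upper - out.loa_lower == 0.0
        assert out.p_value == 1.0

    def test_constant_offset(self):
        x = np.array([1.0, 2.0, 3.0])
        out = fl.agreement_stats(x, x + 0.5)
        assert out.bias == pytest.approx(0.5)
        assert out.loa_halfwidth == pytest.approx(0.0, abs=1e-12)
        assert out.correlation == pytest.approx(1.0)

    def test_matches_brute_force_formulas(self, rng):
        a = rng.random(8) * 5
        b = a + rng.normal(0, 0.3, 8)
        out = fl.agreement_stats(a, b)
        d = b - a
        sd = d.std(ddof=1)
        assert out.bias == pytest.approx(d.mean())
        assert out.loa_lower == pytest.approx(d.mean() - 1.96 * sd)
        assert out.loa_upper == pytest.approx(d.mean() + 1.96 * sd)
        assert out.correlation == pytest.approx(np.corrcoef(a, b)[0, 1])
        assert out.t_statistic == pytest.approx(d.mean() / (sd / np.sqrt(8)))
        from scipy import stats as sps

        assert out.p_value == pytest.approx(
            sps.ttest_rel(b, a).pvalue, rel=1e-9
        )

    def test_pairs_matrix_form(self):
        pairs = np.array([[1.0, 1.1], [2.0, 2.2], [3.0, 2.9]])
        out = fl.agreement_stats(pairs)
        assert out.n == 3
        assert out.bias == pytest.approx((0.1 + 0.2 - 0.1) / 3)

    def test_single_pair_rejected(self):
        with pytest.raises(InvalidParameterError):
            fl.agreement_stats([1.0], [2.0])
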