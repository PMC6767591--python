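"""SPGR signal model, timing/SAR constraints and the grid optimizer."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fluolung as fl
from fluolung.errors import ConstraintViolationError, InvalidParameterError
from fluolung.sequence_model import GAMMA_19F


class TestSpgrSignal:
    def test_zero_flip_gives_zero_signal(self, relax):
        assert fl.spgr_signal(0.0, 10e-3, 0.0, relax) == 0.0

    def test_saturation_limit_at_long_tr(self, relax):
        # 90 degrees, TR >> T1, TE = 0: fully relaxed magnetization
        s = fl.spgr_signal(90.0, 100 * relax.t1, 0.0, relax)
        assert s == pytest.approx(1.0, abs=1e-6)

    def test_te_decay_factorizes(self, relax):
        s0 = fl.spgr_signal(40.0, 7.5e-3, 0.0, relax)
        s1 = fl.spgr_signal(40.0, 7.5e-3, 1.7e-3, relax)
        assert s1 == pytest.approx(s0 * np.exp(-1.7e-3 / relax.t2_star), rel=1e-12)

    def test_grid_maximum_matches_ernst_angle(self, relax):
        # closed form arccos(e^(-TR/T1)) vs a fine flip-angle scan
        tr = 7.5e-3
        flips = np.arange(0.0, 90.001, 0.01)
        sig = fl.spgr_signal(flips, tr, 0.0, relax)
        ernst = fl.ernst_angle_deg(tr, relax.t1)
        assert ernst == pytest.approx(56.9, abs=0.1)
        assert flips[np.argmax(sig)] == pytest.approx(ernst, abs=0.01)

    @settings(max_examples=30, deadline=None)
    @given(tr_ms=st.floats(1.0, 100.0))
    def test_ernst_angle_property_any_tr(self, tr_ms):
        relax = fl.RelaxationParams()
        tr = tr_ms * 1e-3
        flips = np.arange(0.5, 90.0, 0.5)
        sig = fl.spgr_signal(flips, tr, 0.0, relax)
        ernst = fl.ernst_angle_deg(tr, relax.t1)
        assert abs(flips[np.argmax(sig)] - ernst) <= 0.5

    def test_invalid_tr_rejected(self, relax):
        with pytest.raises(InvalidParameterError):
            fl.spgr_signal(40.0, 0.0, 0.0, relax)


class TestTiming:
    def test_pulse_duration_full_rotation_and_linearity(self, hardware):
        f_rabi = hardware.gamma * 4e-6
        assert fl.rf_pulse_duration(360.0, 4e-6, hardware) == pytest.approx(1.0 / f_rabi)
        assert fl.rf_pulse_duration(100.0, 4e-6, hardware) == pytest.approx(
            2 * fl.rf_pulse_duration(50.0, 4e-6, hardware)
        )

    def test_pulse_duration_reference_value(self, hardware):
        # 50 deg at 4 uT, 19F: (50/360)/(40.05e6 * 4e-6) s
        tau = fl.rf_pulse_duration(50.0, 4e-6, hardware)
        assert tau == pytest.approx((50 / 360) / (GAMMA_19F * 4e-6), rel=1e-12)
        assert tau == pytest.approx(0.867e-3, abs=1e-6)

    def test_te_min_readout_contribution(self, hardware):
        geo = fl.AcquisitionGeometry(bw=500.0)
        # readout lasts 1/BW = 2 ms; half contributes 1 ms
        te = fl.te_min(geo, 0.0, hardware)
        assert te == pytest.approx(hardware.encode_overhead + 1e-3)

    def test_te_min_decreases_with_bandwidth(self, hardware):
        tes = [
            fl.te_min(fl.AcquisitionGeometry(bw=bw), 1e-3, hardware)
            for bw in (200.0, 500.0, 1000.0)
        ]
        assert tes[0] > tes[1] > tes[2]

    def test_tr_min_arithmetic_and_spoiler_shift(self):
        hw = fl.HardwareModel(spoiler_duration=0.0)
        geo = fl.AcquisitionGeometry(bw=500.0)
        assert fl.tr_min(2e-3, geo, hw) == pytest.approx(3e-3)
        hw2 = fl.HardwareModel(spoiler_duration=0.7e-3)
        assert fl.tr_min(2e-3, geo, hw2) - fl.tr_min(2e-3, geo, hw) == pytest.approx(0.7e-3)


class TestSar:
    def test_zero_b1_deposits_nothing(self, hardware):
        assert fl.sar_estimate(0.0, 1e-3, 7.5e-3, hardware) == 0.0

    def test_quadratic_in_b1_and_duty_cycle(self, hardware):
        base = fl.sar_estimate(2e-6, 1e-3, 8e-3, hardware)
        assert fl.sar_estimate(4e-6, 1e-3, 8e-3, hardware) == pytest.approx(4 * base)
        assert fl.sar_estimate(2e-6, 1e-3, 4e-3, hardware) == pytest.approx(2 * base)

    def test_default_calibration_puts_protocol_at_local_limit(self, hardware):
        tau = fl.rf_pulse_duration(50.0, 4e-6, hardware)
        assert fl.sar_estimate(4e-6, tau, 7.5e-3, hardware) == pytest.approx(10.0)

    def test_tr_extension_binds_exactly_at_limit(self, hardware):
        tau = fl.rf_pulse_duration(60.0, 8e-6, hardware)
        tr0 = 3e-3
        tr = fl.sar_limited_tr(tr0, 8e-6, tau, 10.0, hardware)
        assert tr > tr0
        assert fl.sar_estimate(8e-6, tau, tr, hardware) == pytest.approx(10.0)

    def test_unbinding_limit_returns_tr_min(self, hardware):
        tau = fl.rf_pulse_duration(10.0, 1e-6, hardware)
        assert fl.sar_limited_tr(8e-3, 1e-6, tau, 10.0, hardware) == 8e-3

    def test_lowering_limit_never_shortens_tr(self, hardware):
        tau = fl.rf_pulse_duration(50.0, 6e-6, hardware)
        trs = [fl.sar_limited_tr(3e-3, 6e-6, tau, lim, hardware) for lim in (10.0, 4.0, 2.0)]
        assert trs[0] <= trs[1] <= trs[2]


class TestSnr:
    def test_sqrt_scan_time_scaling(self, relax, hardware):
        seq = fl.SequenceParams(flip_deg=40.0, b1=4e-6, tr=7.5e-3, te=2e-3,
                                pulse_duration=0.7e-3)
        g1 = fl.AcquisitionGeometry(t_scan=9.0)
        g2 = fl.AcquisitionGeometry(t_scan=18.0)
        assert fl.snr_spgr(g2, seq, relax) == pytest.approx(
            np.sqrt(2) * fl.snr_spgr(g1, seq, relax), rel=1e-12
        )

    def test_te_below_minimum_rejected(self, relax, hardware, geometry):
        seq = fl.SequenceParams(flip_deg=40.0, b1=4e-6, tr=7.5e-3, te=0.1e-3,
                                pulse_duration=0.7e-3)
        with pytest.raises(ConstraintViolationError):
            fl.snr_spgr(geometry, seq, relax, hardware)

    def test_fixed_tr_flip_optimum_is_ernst(self, relax, geometry):
        tr, te = 7.5e-3, 0.0
        flips = np.arange(1.0, 90.1, 0.5)
        snrs = [
            fl.snr_spgr(geometry, fl.SequenceParams(f, 4e-6, tr, te, 0.7e-3), relax)
            for f in flips
        ]
        assert flips[int(np.argmax(snrs))] == pytest.approx(
            fl.ernst_angle_deg(tr, relax.t1), abs=0.5
        )


def _brute_force_optimum(geometry, relax, hardware, sar_limit, flips, bws, b1s):
    """Exhaustive nested-loop re-scan, scalar ops only."""
    best = (-1.0, None)
    for f in flips:
        for bw in bws:
            for b1 in b1s:
                if f <= 0 or bw <= 0 or b1 <= 0:
                    continue
                geo = fl.AcquisitionGeometry(
                    fov=geometry.fov, matrix=geometry.matrix, bw=bw,
                    nsa=geometry.nsa, t_scan=geometry.t_scan,
                )
                tau = fl.rf_pulse_duration(f, b1, hardware)
                te = fl.te_min(geo, tau, hardware)
                tr0 = fl.tr_min(te, geo, hardware)
                tr = fl.sar_limited_tr(tr0, b1, tau, sar_limit, hardware)
                snr = fl.snr_spgr(
                    geo, fl.SequenceParams(f, b1, tr, te, tau), relax, hardware
                )
                if snr > best[0]:
                    best = (snr, (f, bw, b1))
    return best


class TestOptimizer:
    def test_single_point_grid(self, geometry, relax, hardware):
        surf = fl.optimize_parameters(
            geometry, relax, hardware, 10.0, [40.0], [500.0], [4e-6]
        )
        assert surf.optimum["flip_deg"] == 40.0
        assert surf.optimum["bw"] == 500.0

    def test_matches_brute_force_rescan(self, geometry, relax, hardware):
        flips = np.arange(10.0, 90.1, 5.0)
        bws = np.arange(100.0, 1500.1, 100.0)
        b1s = np.array([2e-6, 4e-6, 8e-6])
        surf = fl.optimize_parameters(geometry, relax, hardware, 10.0, flips, bws, b1s)
        snr_bf, (f, bw, b1) = _brute_force_optimum(
            geometry, relax, hardware, 10.0, flips, bws, b1s
        )
        assert surf.optimum["flip_deg"] == f
        assert surf.optimum["bw"] == bw
        assert surf.optimum["b1"] == b1
        assert surf.optimum["snr"] == pytest.approx(snr_bf, rel=1e-10)

    def test_surface_is_sar_compliant_and_nonnegative(self, geometry, relax, hardware):
        surf = fl.optimize_parameters(geometry, relax, hardware, 10.0)
        assert np.all(surf.snr >= 0)
        assert np.all(surf.sar <= 10.0 + 1e-9)

    def test_empty_grid_rejected(self, geometry, relax, hardware):
        with pytest.raises(InvalidParameterError):
            fl.optimize_parameters(geometry, relax, hardware, 10.0, [], [500.0], [4e-6])

    def test_b1_plateau_above_two_microtesla(self, geometry, relax, hardware):
        # SNR gains from raising B1 diminish beyond ~2 uT
        def best(b1):
            return fl.optimize_parameters(
                geometry, relax, hardware, 10.0, b1_grid=[b1]
            ).optimum["snr"]

        gain_low = best(2e-6) - best(0.5e-6)
        gain_high = best(10e-6) - best(2e-6)
        assert 0 < gain_high < gain_low
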