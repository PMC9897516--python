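"""Pulse-wave analysis: derivatives, fiducial detection against analytic
oracles on two-Gaussian pulses, and the morphological features."""

import numpy as np
import pytest

from conftest import dense_alternating_extrema, random_physiologic_params, sample_pulse
from ppgbp import pwa
from ppgbp import synth as sy
from ppgbp.types import EnsemblePulse, PulseParams, Window


def _pulse_from_array(x, fs_pulse, hr=60.0, dc=1000.0):
    return EnsemblePulse(np.asarray(x, float), fs_pulse, hr, Window(0, 20, 0), 1.0, True, dc, 5)


class TestDerivatives:
    def test_sine_first_derivative(self):
        L = 256
        t = np.linspace(0, 1, L, endpoint=False)
        pulse = _pulse_from_array(np.sin(2 * np.pi * t), L)
        d = pwa.derivatives(pulse)
        expected = 2 * np.pi * np.cos(2 * np.pi * t)
        err = np.abs(d.vpg[3:-3] - expected[3:-3]).max()
        assert err < 0.01 * 2 * np.pi

    def test_quadratic_second_and_third(self):
        L = 128
        t = np.linspace(0, 1, L, endpoint=False)
        pulse = _pulse_from_array(t**2, L)
        d = pwa.derivatives(pulse)
        assert np.allclose(d.apg[5:-5], 2.0, atol=0.02)
        assert np.allclose(d.jpg[5:-5], 0.0, atol=0.05)

    def test_two_gaussian_matches_analytic(self):
        params = sy.pulse_from_bp(130.0, 70.0, 60.0)
        pulse = sample_pulse(params)
        d = pwa.derivatives(pulse)
        u = np.linspace(0, params.period, 256, endpoint=False)
        expected = params.derivative(u, 1)
        rmse = np.sqrt(np.mean((d.vpg[3:-3] - expected[3:-3]) ** 2))
        assert rmse < 0.01 * np.abs(expected).max()

    def test_short_pulse_rejected(self):
        with pytest.raises(ValueError):
            pwa.derivatives(_pulse_from_array(np.ones(8), 8))


class TestFiducials:
    def _fiducials(self, params, L=256):
        pulse = sample_pulse(params, L)
        d = pwa.derivatives(pulse)
        return pwa.detect_fiducials(d), d

    def test_two_gaussian_peaks_located(self):
        params = PulseParams(c_sys=0.15, w_sys=0.045, amp_sys=1.0,
                             c_dia=0.40, w_dia=0.07, amp_dia=0.4,
                             baseline=0.0, period=1.0)
        f, _ = self._fiducials(params)
        # analytic extrema of the mixture via dense grid search
        u = np.linspace(0, 1, 1 << 15, endpoint=False)
        vals = params.evaluate(u)
        maxima = dense_alternating_extrema(vals, u, "max", None)
        peaks = [t for t, k in maxima if k == "max"]
        assert abs(f["ppg.sys_peak"][0] - peaks[0]) < 0.010
        assert "ppg.dia_peak" in f
        assert abs(f["ppg.dia_peak"][0] - peaks[1]) < 0.010

    def test_single_gaussian_no_diastolic_peak(self):
        params = PulseParams(c_sys=0.18, w_sys=0.05, amp_sys=1.0,
                             c_dia=0.55, w_dia=0.10, amp_dia=1e-9,
                             baseline=0.0, period=1.0)
        f, _ = self._fiducials(params)
        assert "ppg.dia_peak" not in f
        pulse = sample_pulse(params)
        d = pwa.derivatives(pulse)
        fv = pwa.pulse_features(pulse, d, f)
        assert np.isnan(fv["MSBP"]) and np.isnan(fv["SEVR"])

    @pytest.mark.parametrize("seed", range(50))
    def test_apg_waves_match_analytic_extrema(self, seed):
        """Detected a-e wave times agree with the dense-grid analytic
        second-derivative extrema within one sample at L = 256."""
        rng = np.random.default_rng(1000 + seed)
        params = random_physiologic_params(rng)
        f, d = self._fiducials(params)
        T = params.period
        u = np.linspace(0, T, 1 << 15, endpoint=False)
        analytic = dense_alternating_extrema(params.derivative(u, 2), u, "max", 5)
        names = ["apg.a", "apg.b", "apg.c", "apg.d", "apg.e"]
        n_common = min(len(analytic), sum(nm in f for nm in names))
        assert n_common >= 4  # a-d always present on physiologic pulses
        for nm, (t_true, _) in zip(names[:n_common], analytic[:n_common]):
            assert abs(f[nm][0] - t_true) <= T / 256 + 1e-12, nm

    @pytest.mark.parametrize("seed", range(0, 50, 7))
    def test_vpg_points_match_analytic(self, seed):
        rng = np.random.default_rng(2000 + seed)
        params = random_physiologic_params(rng)
        f, _ = self._fiducials(params)
        T = params.period
        u = np.linspace(0, T, 1 << 15, endpoint=False)
        v = params.derivative(u, 1)
        w_true = u[np.argmax(v)]
        assert abs(f["vpg.w"][0] - w_true) <= T / 256 + 1e-12

    def test_time_shift_moves_all_fiducials(self):
        params = sy.pulse_from_bp(120.0, 65.0, 75.0)
        L = 256
        T = params.period
        u = np.linspace(0, T, L, endpoint=False)
        shift = 10
        dt_shift = shift * (T / L)
        pulse = _pulse_from_array(params.evaluate(u), L / T, 60.0 / T)
        pulse2 = _pulse_from_array(params.evaluate(u - dt_shift), L / T, 60.0 / T)
        f0 = pwa.detect_fiducials(pwa.derivatives(pulse))
        f1 = pwa.detect_fiducials(pwa.derivatives(pulse2))
        for name in ("ppg.sys_peak", "vpg.w", "apg.a", "apg.b", "apg.c"):
            assert f1[name][0] - f0[name][0] == pytest.approx(dt_shift, abs=1.0 / pulse.fs_pulse)
            # amplitudes unchanged by a pure time shift
            assert f1[name][1] == pytest.approx(f0[name][1], rel=1e-3, abs=1e-6)


class TestPulseFeatures:
    def test_rectangular_pulse_areas(self):
        L = 1000
        x = np.ones(L)
        x[0] = 0.0  # foot at baseline
        pulse = _pulse_from_array(x, L / 1.0)  # T = 1 s
        d = pwa.derivatives(pulse)
        f = {"ppg.dicrotic_notch": (0.35, 1.0), "ppg.sys_peak": (0.1, 1.0)}
        fv = pwa.pulse_features(pulse, d, f)
        assert fv["SPTI"] == pytest.approx(0.35, rel=0.02)
        assert fv["DPTI"] == pytest.approx(0.65, rel=0.02)
        assert fv["SEVR"] == pytest.approx(0.65 / 0.35, rel=0.03)
        assert fv["ESP"] == pytest.approx(1.0, rel=1e-6)
        assert fv["MAP"] == pytest.approx(1.0, rel=0.01)

    def test_perfusion_index_ac_over_dc(self):
        L = 256
        t = np.linspace(0, 1, L, endpoint=False)
        pulse = _pulse_from_array(np.sin(2 * np.pi * t), L, dc=10.0)
        d = pwa.derivatives(pulse)
        fv = pwa.pulse_features(pulse, d, {})
        assert fv["PI"] == pytest.approx(10.0, rel=1e-3)

    def test_two_gaussian_quadrature_oracle(self):
        params = sy.pulse_from_bp(140.0, 75.0, 65.0)
        pulse = sample_pulse(params)
        d = pwa.derivatives(pulse)
        f = pwa.detect_fiducials(d)
        fv = pwa.pulse_features(pulse, d, f)
        # high-resolution quadrature of the analytic mixture, foot-anchored
        T = params.period
        u = np.linspace(0, T * (255 / 256), 1 << 16)
        vals = params.evaluate(u) - sample_pulse(params).waveform.min()
        tn = f["ppg.dicrotic_notch"][0]
        assert fv["MAP"] == pytest.approx(np.mean(vals), rel=5e-3)
        spti = np.trapezoid(vals[u <= tn], u[u <= tn])
        dpti = np.trapezoid(vals[u >= tn], u[u >= tn])
        assert fv["SPTI"] == pytest.approx(spti, rel=5e-3)
        assert fv["DPTI"] == pytest.approx(dpti, rel=5e-3)

    @pytest.mark.parametrize("seed", range(0, 50, 5))
    def test_area_conservation_and_invariances(self, seed):
        rng = np.random.default_rng(300 + seed)
        params = random_physiologic_params(rng)
        pulse = sample_pulse(params)
        d = pwa.derivatives(pulse)
        f = pwa.detect_fiducials(d)
        fv = pwa.pulse_features(pulse, d, f)
        if not np.isnan(fv["SPTI"]):
            x = d.ppg - d.ppg.min()
            total = np.trapezoid(x, dx=1.0 / d.fs_pulse)
            assert fv["SPTI"] + fv["DPTI"] == pytest.approx(total, rel=1e-6)
            assert fv["SEVR"] * fv["SPTI"] == pytest.approx(fv["DPTI"], rel=1e-12)
        # scaling by c scales amplitudes/areas, leaves SEVR and AIx75 fixed
        c = 3.7
        pulse2 = _pulse_from_array(c * pulse.waveform, pulse.fs_pulse, pulse.hr,
                                   dc=pulse.dc_mean * c)
        d2 = pwa.derivatives(pulse2)
        fv2 = pwa.pulse_features(pulse2, d2, pwa.detect_fiducials(d2))
        for key in ("MAP", "MSBP", "MDBP", "ESP", "SPTI", "DPTI"):
            if not np.isnan(fv[key]):
                assert fv2[key] == pytest.approx(c * fv[key], rel=1e-9)
        for key in ("SEVR", "AIx75", "PI"):
            if not np.isnan(fv[key]):
                assert fv2[key] == pytest.approx(fv[key], rel=1e-6)


class TestDemographics:
    def test_appends_exactly_four_fields(self):
        fv = {"MAP": 1.0}
        out = pwa.attach_demographics(fv, dict(age=62, weight=72, height=170, gender="male"))
        assert set(out) - set(fv) == {"age", "weight", "height", "gender"}
        assert out["gender"] == 1.0

    def test_collision_rejected(self):
        with pytest.raises(ValueError):
            pwa.attach_demographics({"age": 1.0}, dict(age=62, weight=72, height=170, gender=0))

    def test_empty_or_incomplete_rejected(self):
        with pytest.raises(ValueError):
            pwa.attach_demographics({}, {})
        with pytest.raises(ValueError):
            pwa.attach_demographics({}, dict(age=62, weight=72, height=170))
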