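"""Preprocessing: filtering, alignment, windowing, beat segmentation,
SQI-weighted ensemble averaging and the window exclusion gate."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ppgbp import preprocess as pp
from ppgbp import synth as sy
from ppgbp.types import ReferenceBP, WaveformRecording, Window


def _sine(freq, fs=125.0, dur=60.0, amp=1.0):
    t = np.arange(0, dur, 1 / fs)
    return WaveformRecording(amp * np.sin(2 * np.pi * freq * t), fs)


def butter_cascade_gain(f, lp=15.0, hp=0.5, order=3, fs=125.0):
    """Analytic amplitude oracle for the zero-phase Butterworth cascade.

    Digital Butterworth designed by bilinear transform has
    |H(f)|^2 = 1 / (1 + (tan(pi f/fs) / tan(pi fc/fs))^(2n)); each
    forward-backward pass applies |H|^2, so the cascade's amplitude gain is
    the product of the squared low-pass and high-pass magnitudes."""
    wl = np.tan(np.pi * f / fs) / np.tan(np.pi * lp / fs)
    wh = np.tan(np.pi * hp / fs) / np.tan(np.pi * f / fs)
    return 1.0 / (1.0 + wl ** (2 * order)) / (1.0 + wh ** (2 * order))


class TestBandpass:
    def test_constant_signal_zeroed(self):
        rec = WaveformRecording(np.full(1000, 7.3), 125.0)
        out = pp.bandpass_ppg(rec)
        assert np.allclose(out.samples, 0.0, atol=1e-6)

    @pytest.mark.parametrize("freq,lo,hi", [(2.0, 0.95, 1.0), (0.05, 0.0, 0.01)])
    def test_passband_and_stopband_amplitudes(self, freq, lo, hi):
        rec = _sine(freq, dur=120.0)
        out = pp.bandpass_ppg(rec).samples
        mid = out[out.size // 4 : -out.size // 4]
        amp = np.sqrt(2) * np.sqrt(np.mean(mid**2))
        assert lo <= amp <= hi
        assert amp == pytest.approx(butter_cascade_gain(freq), abs=0.01)

    def test_linearity(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=4000)
        rec = WaveformRecording(x, 125.0)
        rec5 = WaveformRecording(5.0 * x, 125.0)
        a = pp.bandpass_ppg(rec).samples
        b = pp.bandpass_ppg(rec5).samples
        assert np.allclose(b, 5.0 * a, rtol=1e-9, atol=1e-12)

    def test_nyquist_violation_raises(self):
        rec = WaveformRecording(np.zeros(100), 20.0)
        with pytest.raises(ValueError):
            pp.bandpass_ppg(rec, lp_cut=15.0)


class TestAlign:
    def _pulse_train(self, fs=125.0, dur=60.0, shift_s=0.0, noise=0.0, seed=0):
        params = sy.pulse_from_bp(120.0, 70.0, 60.0)
        t = np.arange(0, dur, 1 / fs)
        x = np.zeros_like(t)
        for k in range(int(dur)):
            u = t - k - shift_s
            x += params.evaluate(u) * ((u >= -0.5) & (u < 1.5))
        if noise:
            x = x + np.random.default_rng(seed).normal(0, noise, x.size)
        return WaveformRecording(x, fs)

    def test_identical_signals_zero_lag(self):
        a = self._pulse_train()
        assert pp.align_signals(a, a) == 0.0

    def test_constructed_half_second_delay(self):
        ref = self._pulse_train()
        delayed = self._pulse_train(shift_s=0.5)
        assert pp.align_signals(delayed, ref) == pytest.approx(0.5, abs=1 / 125)

    def test_noisy_offset_recovered_within_one_sample(self):
        # SNR 10 dB: noise sd = signal rms / sqrt(10)
        clean = self._pulse_train()
        rms = np.sqrt(np.mean((clean.samples - clean.samples.mean()) ** 2))
        sd = rms / np.sqrt(10)
        ref = self._pulse_train(noise=sd, seed=1)
        moved = self._pulse_train(shift_s=0.2, noise=sd, seed=2)
        assert pp.align_signals(moved, ref) == pytest.approx(0.2, abs=1 / 125 + 1e-9)


class TestWindows:
    @pytest.mark.parametrize(
        "length,expected_starts",
        [(60.0, [0, 10, 20, 30, 40]), (20.0, [0]), (19.0, [])],
    )
    def test_examples(self, length, expected_starts):
        wins = pp.make_windows(length)
        assert [w.start for w in wins] == expected_starts

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(min_value=0.0, max_value=3600.0))
    def test_count_formula(self, length):
        wins = pp.make_windows(length)
        expected = int(np.floor((length - 20.0) / 10.0 + 1e-9)) + 1 if length >= 20 else 0
        assert len(wins) == expected


class TestBeats:
    def _train(self, fs=125.0, dur=20.0, period=1.0):
        params = sy.pulse_from_bp(120.0, 70.0, 60.0 / period)
        t = np.arange(0, dur, 1 / fs)
        x = np.zeros_like(t)
        for k in range(int(np.ceil(dur / period)) + 1):
            u = t - k * period
            x += params.evaluate(u) * ((u >= -0.5 * period) & (u < 1.5 * period))
        return WaveformRecording(x - x.mean(), fs)

    def test_periodic_train_onsets(self):
        rec = self._train()
        onsets = pp.segment_beats(rec)
        assert 18 <= onsets.size <= 21
        ibi = np.diff(onsets) / rec.fs
        # the first foot sits at the record edge and may land late
        assert np.all(np.abs(ibi[1:] - 1.0) < 0.02)

    def test_flat_signal_no_beats(self):
        rec = WaveformRecording(np.zeros(2500), 125.0)
        assert pp.segment_beats(rec).size == 0

    def test_corrupted_beat_scores_low_sqi(self):
        rec = self._train()
        onsets = pp.segment_beats(rec)
        beats, ibis = pp.resample_beats(rec.samples, onsets, 256)
        rng = np.random.default_rng(3)
        beats[7] = rng.normal(0, np.ptp(beats[0]), 256)
        template = np.median(beats, axis=0)
        sqis = pp.beat_sqis(beats, template)
        assert sqis[7] < 0.75
        assert np.median(sqis) > 0.9


class TestSQI:
    def test_identical_beat_is_perfect(self):
        t = np.linspace(0, 1, 100)
        beat = np.sin(np.pi * t)
        assert pp.beat_sqi(beat, beat, [beat, beat]) == pytest.approx(1.0)

    def test_anticorrelated_beat_is_zero(self):
        t = np.linspace(0, 1, 100)
        template = np.sin(np.pi * t)
        assert pp.beat_sqi(-template, template, [template]) == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_beat_is_zero(self):
        template = np.sin(np.linspace(0, np.pi, 100))
        assert pp.beat_sqi(np.ones(100), template) == 0.0

    def test_monotone_decreasing_in_noise(self):
        rng = np.random.default_rng(11)
        t = np.linspace(0, 1, 256)
        template = np.sin(np.pi * t) ** 2
        noise = rng.normal(size=256)
        sqis = []
        for level in [0.0, 0.05, 0.15, 0.4, 1.0]:
            sqis.append(pp.beat_sqi(template + level * noise, template, [template]))
        assert all(a > b for a, b in zip(sqis, sqis[1:]))

    def test_half_corrupted_window_fails_gate(self):
        """A window whose beats are 50% artifact must fall below the 0.75 gate."""
        rng = np.random.default_rng(5)
        t = np.linspace(0, 1, 256)
        template = np.sin(np.pi * t) ** 2
        beats = np.tile(template, (20, 1))
        beats[::2] = rng.normal(0, 1.0, (10, 256))  # alternate-beat corruption
        sqis = pp.beat_sqis(beats, template)
        pulse = pp.ensemble_average(beats, sqis, np.full(19, 1.0), Window(0, 20, 0))
        ref = ReferenceBP(120, 70, 90, Window(0, 20, 0), 0.01, 0.01)
        assert pulse.sqi < 0.75
        assert pp.gate_window(pulse, ref) is False


class TestEnsembleAverage:
    def _beats(self):
        t = np.linspace(0, 1, 64)
        return np.stack([np.sin(np.pi * t), np.sin(np.pi * t) ** 2, t * (1 - t)])

    def test_identical_beats_reproduced(self):
        beat = self._beats()[0]
        beats = np.tile(beat, (5, 1))
        pulse = pp.ensemble_average(beats, np.full(5, 0.9), np.full(4, 1.0), Window(0, 20, 0))
        assert np.allclose(pulse.waveform, beat)
        assert pulse.hr == pytest.approx(60.0)

    def test_zero_weight_excluded(self):
        beats = self._beats()[:2]
        pulse = pp.ensemble_average(beats, np.array([1.0, 0.0]), np.array([1.0]), Window(0, 20, 0))
        assert np.allclose(pulse.waveform, beats[0])

    def test_hand_computed_weighted_mean(self):
        beats = self._beats()
        w = np.array([0.5, 0.25, 0.25])
        pulse = pp.ensemble_average(beats, w, np.full(2, 1.0), Window(0, 20, 0))
        expected = 0.5 * beats[0] + 0.25 * beats[1] + 0.25 * beats[2]
        assert np.allclose(pulse.waveform, expected)

    def test_order_invariance(self):
        beats = self._beats()
        w = np.array([0.5, 0.25, 0.25])
        a = pp.ensemble_average(beats, w, np.full(2, 1.0), Window(0, 20, 0)).waveform
        perm = [2, 0, 1]
        b = pp.ensemble_average(beats[perm], w[perm], np.full(2, 1.0), Window(0, 20, 0)).waveform
        assert np.allclose(a, b)

    def test_all_zero_weights_invalid(self):
        pulse = pp.ensemble_average(self._beats(), np.zeros(3), np.full(2, 1.0), Window(0, 20, 0))
        assert not pulse.valid


class TestGate:
    def _pulse(self, sqi):
        from ppgbp.types import EnsemblePulse

        wav = np.sin(np.linspace(0, np.pi, 64))
        return EnsemblePulse(wav, 64.0, 60.0, Window(0, 20, 0), sqi, True, 1000.0, 3)

    def _ref(self, var):
        return ReferenceBP(120, 70, 90, Window(0, 20, 0), var, var)

    @pytest.mark.parametrize(
        "sqi,var,expected",
        [(0.80, 0.05, True), (0.74, 0.05, False), (0.90, 0.11, False),
         (0.75, 0.10, True)],
    )
    def test_boundaries(self, sqi, var, expected):
        assert pp.gate_window(self._pulse(sqi), self._ref(var)) is expected

    @settings(derandomize=True, max_examples=60)
    @given(
        st.floats(0, 1), st.floats(0, 1), st.floats(0, 0.5), st.floats(0, 0.5)
    )
    def test_monotonicity(self, s1, s2, v1, v2):
        lo_s, hi_s = sorted((s1, s2))
        lo_v, hi_v = sorted((v1, v2))
        # raising sqi never flips True -> False
        if pp.gate_window(self._pulse(lo_s), self._ref(lo_v)):
            assert pp.gate_window(self._pulse(hi_s), self._ref(lo_v))
        # raising variability never flips False -> True
        if not pp.gate_window(self._pulse(hi_s), self._ref(lo_v)):
            assert not pp.gate_window(self._pulse(hi_s), self._ref(hi_v))


class TestReferenceBP:
    def _abp_train(self, sbps, dbp=70.0, fs=125.0, period=1.0):
        """Pulse train whose k-th beat spans [dbp, sbps[k]] exactly."""
        params = sy.pulse_from_bp(120.0, 70.0, 60.0 / period)
        n = int(len(sbps) * period * fs)
        t = np.arange(n) / fs
        x = np.empty(n)
        onsets = []
        for k, sbp in enumerate(sbps):
            i0, i1 = int(k * period * fs), min(int((k + 1) * period * fs), n)
            seg = params.evaluate(t[i0:i1] - k * period)
            seg = (seg - seg.min()) / np.ptp(seg)
            x[i0:i1] = dbp + (sbp - dbp) * seg
            onsets.append(i0)
        return x, np.asarray(onsets + [n - 1])

    def test_template_train_exact_extrema(self):
        x, onsets = self._abp_train([140.0] * 6)
        ref = pp.reference_bp(x, 125.0, onsets=onsets)
        assert ref.valid
        assert ref.sbp == pytest.approx(140.0, abs=1e-9)
        assert ref.dbp == pytest.approx(70.0, abs=1e-9)

    def test_median_of_beat_series(self):
        x, onsets = self._abp_train([110.0, 120.0, 130.0])
        ref = pp.reference_bp(x, 125.0, onsets=onsets)
        assert ref.sbp == pytest.approx(120.0, abs=1e-9)

    def test_drifting_amplitude_variability(self):
        sbps = np.linspace(110, 150, 8)
        x, onsets = self._abp_train(list(sbps))
        ref = pp.reference_bp(x, 125.0, onsets=onsets)
        assert ref.variability_sbp == pytest.approx(sbps.std() / sbps.mean(), rel=1e-9)

    def test_too_few_beats_invalid(self):
        x, onsets = self._abp_train([120.0, 125.0])
        ref = pp.reference_bp(x, 125.0, onsets=onsets)
        assert not ref.valid

    def test_ordering_invariant_on_synthetic_recording(self, tiny_cohort):
        rec = tiny_cohort.recordings[0]
        res = pp.process_recording(rec.ppg, rec.abp)
        for r in res.refs:
            if r.valid:
                assert r.dbp <= r.mbp <= r.sbp


class TestProcessRecording:
    def test_clean_recording_all_windows_pass(self):
        cfg = sy.CohortConfig(seed=7, n_subjects=1, duration_range=(120.0, 120.0),
                              noise_sd=0.0, corrupt_frac=0.0, abp_noise_sd=0.0)
        rec = sy.synth_recording(cfg, 0)
        res = pp.process_recording(rec.ppg, rec.abp)
        assert len(res.meta) == 11
        assert res.meta["gated"].all()

    def test_nonfinite_window_invalid(self):
        cfg = sy.CohortConfig(seed=7, n_subjects=1, duration_range=(120.0, 120.0),
                              noise_sd=0.0, corrupt_frac=0.0)
        rec = sy.synth_recording(cfg, 0)
        samples = rec.ppg.samples.copy()
        samples[int(35 * rec.ppg.fs)] = np.nan
        ppg = WaveformRecording(samples, rec.ppg.fs, rec.ppg.subject_id, "ppg")
        res = pp.process_recording(ppg, rec.abp)
        bad = res.meta[(res.meta.start <= 35.0) & (res.meta.start + 20 >= 35.0)]
        assert not bad["gated"].any()
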