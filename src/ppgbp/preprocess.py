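"""Raw-waveform preprocessing: filtering, windowing, beat segmentation,
quality-weighted ensemble averaging, and windowed reference BP.

A recording is band-pass filtered (3rd-order Butterworth, 0.5-15 Hz, applied
forward-backward so fiducial timing is not skewed by group delay), split into
20-s windows with 50% overlap, segmented into beats at pulse feet, and each
window's beats are aggregated into one ensemble-average (EA) pulse where each
beat is weighted by its signal quality index (SQI).  The invasive reference is
the median per-beat SBP/DBP/MBP over the same window.  Windows are gated on
EA-pulse SQI (>= 0.75) and reference beat-to-beat variability (std/mean <=
0.10 for both the SBP and DBP series).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .types import EnsemblePulse, ReferenceBP, WaveformRecording, Window

logger = logging.getLogger(__name__)

# Physiologic bounds on the inter-beat interval (seconds): 20-250 bpm.
IBI_MIN_S = 0.24
IBI_MAX_S = 3.0

#: Number of samples each beat is resampled to before averaging and PWA.
PULSE_LENGTH = 256


class AlignmentError(RuntimeError):
    """Raised when PPG/ABP cross-correlation alignment cannot be computed."""


def _butter_sos(fs: float, lp_cut: float, hp_cut: float, order: int):
    if fs <= 2 * lp_cut:
        raise ValueError(
            f"sampling rate {fs} Hz must exceed twice the low-pass cut-off {lp_cut} Hz"
        )
    sos_lp = signal.butter(order, lp_cut, btype="low", fs=fs, output="sos")
    sos_hp = signal.butter(order, hp_cut, btype="high", fs=fs, output="sos")
    return sos_lp, sos_hp


def bandpass_ppg(
    sig: WaveformRecording,
    lp_cut: float = 15.0,
    hp_cut: float = 0.5,
    order: int = 3,
) -> WaveformRecording:
    """Zero-phase band-pass of a raw waveform (low-pass then high-pass).

    Both filters are 3rd-order Butterworth by default and are applied
    forward-backward (``sosfiltfilt``), giving an effective squared magnitude
    response and exactly zero phase.  The high-pass removes the DC baseline,
    so the output is approximately zero-mean.
    """
    sos_lp, sos_hp = _butter_sos(sig.fs, lp_cut, hp_cut, order)
    x = signal.sosfiltfilt(sos_lp, sig.samples)
    x = signal.sosfiltfilt(sos_hp, x)
    return WaveformRecording(x, sig.fs, sig.subject_id, sig.channel, sig.t0)


def align_signals(
    ppg: WaveformRecording,
    abp: WaveformRecording,
    max_lag: float = 5.0,
) -> float:
    """Lag (s) of the PPG relative to the ABP by normalized cross-correlation.

    Both signals are band-passed before correlating.  A positive return value
    means the PPG waveform lags the arterial waveform: shifting the PPG
    earlier by ``lag`` seconds superimposes the two pulse trains.
    """
    if ppg.fs != abp.fs:
        raise ValueError("signals must share a common sampling rate")
    fs = ppg.fs
    x = bandpass_ppg(ppg).samples
    y = bandpass_ppg(abp).samples
    x = x - x.mean()
    y = y - y.mean()
    nx, ny = x.size, y.size
    if min(nx, ny) <= int(max_lag * fs):
        raise AlignmentError("max_lag exceeds the usable record length")
    corr = signal.correlate(x, y, mode="full")
    lags = signal.correlation_lags(nx, ny, mode="full")
    denom = np.linalg.norm(x) * np.linalg.norm(y)
    if denom == 0:
        raise AlignmentError("cannot align signals with zero variance")
    keep = np.abs(lags) <= max_lag * fs
    corr, lags = corr[keep], lags[keep]
    if corr.size == 0:
        raise AlignmentError("empty overlap for the requested lag range")
    return float(lags[np.argmax(corr / denom)] / fs)


def make_windows(
    sig_length: float, win: float = 20.0, overlap: float = 0.5
) -> list[Window]:
    """Fully contained analysis windows over a record of ``sig_length`` s.

    Starts advance by ``win * (1 - overlap)``; a T-second record yields
    ``floor((T - win)/stride) + 1`` windows for T >= win, else none.
    """
    if win <= 0:
        raise ValueError("window duration must be positive")
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    stride = win * (1 - overlap)
    windows: list[Window] = []
    k = 0
    while k * stride + win <= sig_length + 1e-9:
        windows.append(Window(start=k * stride, duration=win, index=k))
        k += 1
    return windows


def segment_beats(sig: WaveformRecording) -> np.ndarray:
    """Beat onset (pulse foot) indices of a filtered pulsatile waveform.

    The steepest systolic upstroke is located as a peak of the first
    derivative (adaptive prominence threshold, refractory distance equal to
    the minimum physiologic inter-beat interval); the foot is the local
    minimum of the waveform immediately preceding each upstroke.  Onsets
    closer than the minimum inter-beat interval are merged.
    """
    x = sig.samples
    fs = sig.fs
    if not np.all(np.isfinite(x)):
        return np.array([], dtype=int)
    vpg = np.gradient(x) * fs
    spread = np.percentile(vpg, 98) - np.percentile(vpg, 2)
    if spread <= 0 or np.ptp(x) == 0:
        return np.array([], dtype=int)
    upstrokes, _ = signal.find_peaks(
        vpg, distance=max(int(IBI_MIN_S * fs), 1), prominence=0.25 * spread
    )
    onsets: list[int] = []
    look_back = max(int(0.30 * fs), 2)
    for u in upstrokes:
        lo = max(u - look_back, 0)
        foot = lo + int(np.argmin(x[lo : u + 1]))
        if onsets and foot - onsets[-1] < IBI_MIN_S * fs:
            continue
        onsets.append(foot)
    return np.asarray(onsets, dtype=int)


def resample_beats(
    x: np.ndarray, onsets: np.ndarray, L: int = PULSE_LENGTH
) -> tuple[np.ndarray, np.ndarray]:
    """Resample each foot-to-foot beat to ``L`` samples.

    Returns ``(beats, ibis)`` where ``beats`` is (n_beats, L) and ``ibis`` the
    inter-onset intervals in samples.  Beats with non-physiologic intervals
    are dropped.
    """
    if onsets.size < 2:
        return np.empty((0, L)), np.empty(0)
    beats, ibis = [], []
    for a, b in zip(onsets[:-1], onsets[1:]):
        n = b - a
        beats.append(np.interp(np.linspace(0, n - 1, L), np.arange(n), x[a:b]))
        ibis.append(n)
    return np.asarray(beats), np.asarray(ibis, dtype=float)


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return -1.0  # zero-variance beat carries no pulse information
    return float(np.dot(a - a.mean(), b - b.mean()) / (a.size * sa * sb))


def beat_sqi(
    beat: np.ndarray, template: np.ndarray, neighbors: list[np.ndarray] | None = None
) -> float:
    """Signal quality of one beat in [0, 1].

    Mean of (a) Pearson correlation with the recording's template beat and
    (b) mean Pearson correlation with the neighbouring beats, each mapped
    from [-1, 1] to [0, 1].  A zero-variance beat scores 0.
    """
    beat = np.asarray(beat, dtype=float)
    if beat.std() == 0 or not np.all(np.isfinite(beat)):
        return 0.0
    parts = [(_safe_corr(beat, template) + 1) / 2]
    if neighbors:
        rs = [(_safe_corr(beat, nb) + 1) / 2 for nb in neighbors]
        parts.append(float(np.mean(rs)))
    return float(np.clip(np.mean(parts), 0.0, 1.0))


def beat_sqis(beats: np.ndarray, template: np.ndarray) -> np.ndarray:
    """Per-beat SQI for a (n_beats, L) matrix, neighbours = adjacent beats."""
    n = beats.shape[0]
    sqis = np.empty(n)
    for i in range(n):
        nb = [beats[j] for j in (i - 1, i + 1) if 0 <= j < n and j != i]
        sqis[i] = beat_sqi(beats[i], template, nb)
    return sqis


def ensemble_average(
    beats: np.ndarray,
    sqis: np.ndarray,
    ibis_s: np.ndarray,
    window: Window,
    dc_mean: float = np.nan,
    fs_pulse: float | None = None,
) -> EnsemblePulse:
    """SQI-weighted ensemble average of onset-aligned, length-L beats.

    ``waveform = sum_i sqi_i * beat_i / sum_i sqi_i``.  Heart rate is 60 over
    the median inter-onset interval; the pulse SQI is the weighted mean of the
    beat SQIs.  All-zero weights (or no beats) yield an invalid pulse.
    """
    beats = np.atleast_2d(np.asarray(beats, dtype=float))
    sqis = np.asarray(sqis, dtype=float)
    L = beats.shape[1] if beats.size else PULSE_LENGTH
    total = sqis.sum() if sqis.size else 0.0
    if beats.size == 0 or total <= 0 or not np.all(np.isfinite(beats)):
        return EnsemblePulse(
            np.full(L, np.nan), np.nan, np.nan, window, 0.0, False, dc_mean, 0
        )
    w = sqis / total
    waveform = w @ beats
    ibi = float(np.median(ibis_s)) if np.asarray(ibis_s).size else np.nan
    hr = 60.0 / ibi if ibi and np.isfinite(ibi) and ibi > 0 else np.nan
    if fs_pulse is None:
        fs_pulse = L / ibi if ibi and np.isfinite(ibi) and ibi > 0 else np.nan
    sqi = float(np.dot(w, sqis))
    valid = bool(np.isfinite(hr) and 20.0 <= hr <= 250.0)
    return EnsemblePulse(waveform, fs_pulse, hr, window, sqi, valid, dc_mean, beats.shape[0])


def reference_bp(
    abp_window: np.ndarray,
    fs: float,
    window: Window | None = None,
    onsets: np.ndarray | None = None,
) -> ReferenceBP:
    """Windowed reference BP from the invasive waveform (mmHg).

    Per detected beat: SBP = maximum, DBP = minimum, MBP = mean.  The window
    values are the medians of the per-beat series; variability is std/mean of
    the SBP and DBP series.  Fewer than three beats invalidates the window.
    """
    window = window or Window(0.0, len(abp_window) / fs, 0)
    x = np.asarray(abp_window, dtype=float)
    if onsets is None:
        filt = bandpass_ppg(WaveformRecording(x, fs, channel="abp"))
        onsets = segment_beats(filt)
    invalid = ReferenceBP(np.nan, np.nan, np.nan, window, np.nan, np.nan, valid=False)
    if onsets.size < 4 or not np.all(np.isfinite(x)):
        return invalid
    sbps, dbps, mbps = [], [], []
    for a, b in zip(onsets[:-1], onsets[1:]):
        beat = x[a:b]
        sbps.append(beat.max())
        dbps.append(beat.min())
        mbps.append(beat.mean())
    sbps, dbps, mbps = map(np.asarray, (sbps, dbps, mbps))
    if sbps.size < 3:
        return invalid
    sbp, dbp, mbp = map(lambda v: float(np.median(v)), (sbps, dbps, mbps))
    if not sbp > dbp > 0:
        return invalid
    var_s = float(sbps.std() / sbps.mean()) if sbps.mean() else np.nan
    var_d = float(dbps.std() / abs(dbps.mean())) if dbps.mean() else np.nan
    return ReferenceBP(sbp, dbp, mbp, window, var_s, var_d, valid=True)


def gate_window(
    pulse: EnsemblePulse,
    ref: ReferenceBP,
    sqi_min: float = 0.75,
    var_max: float = 0.10,
) -> bool:
    """Exclusion gate: keep a window iff the EA-pulse SQI is at least
    ``sqi_min`` and the per-beat reference variability (std/mean) of *both*
    the SBP and DBP series is at most ``var_max``."""
    if not (pulse.valid and ref.valid):
        return False
    if not np.all(np.isfinite(pulse.waveform)):
        return False
    return bool(
        pulse.sqi >= sqi_min
        and ref.variability_sbp <= var_max
        and ref.variability_dbp <= var_max
    )


@dataclass
class PreprocessResult:
    """Per-window EA pulses + references for one recording."""

    subject_id: str
    pulses: list[EnsemblePulse]
    refs: list[ReferenceBP]
    meta: pd.DataFrame  # one row per window: start, sqi, hr, sbp, dbp, ..., gated

    @property
    def gated(self) -> np.ndarray:
        return self.meta["gated"].to_numpy()


def process_recording(
    ppg: WaveformRecording,
    abp: WaveformRecording,
    win: float = 20.0,
    overlap: float = 0.5,
    sqi_min: float = 0.75,
    var_max: float = 0.10,
    lp_cut: float = 15.0,
    hp_cut: float = 0.5,
    order: int = 3,
    align: bool = False,
    max_lag: float = 5.0,
    L: int = PULSE_LENGTH,
) -> PreprocessResult:
    """Full preprocessing of one paired PPG/ABP recording.

    Filters the PPG, segments beats over the whole record, scores each beat's
    SQI against the recording's median-beat template and its neighbours, then
    builds one EA pulse and one reference BP per 20-s window and applies the
    exclusion gate.
    """
    if align:
        lag = align_signals(ppg, abp, max_lag=max_lag)
        shift = int(round(lag * ppg.fs))
        if shift > 0:
            ppg = WaveformRecording(
                ppg.samples[shift:], ppg.fs, ppg.subject_id, ppg.channel, ppg.t0
            )
        elif shift < 0:
            abp = WaveformRecording(
                abp.samples[-shift:], abp.fs, abp.subject_id, abp.channel, abp.t0
            )

    # Non-finite samples would leak through the IIR filter into every window;
    # patch them for filtering and invalidate only the windows touching them.
    bad_ppg = ~np.isfinite(ppg.samples)
    bad_abp = ~np.isfinite(abp.samples)
    if bad_ppg.any():
        patched = ppg.samples.copy()
        patched[bad_ppg] = np.nanmedian(ppg.samples)
        ppg = WaveformRecording(patched, ppg.fs, ppg.subject_id, ppg.channel, ppg.t0)
    if bad_abp.any():
        patched = abp.samples.copy()
        patched[bad_abp] = np.nanmedian(abp.samples)
        abp = WaveformRecording(patched, abp.fs, abp.subject_id, abp.channel, abp.t0)

    filt = bandpass_ppg(ppg, lp_cut=lp_cut, hp_cut=hp_cut, order=order)
    onsets = segment_beats(filt)
    beats, ibis = resample_beats(filt.samples, onsets, L)
    template = np.median(beats, axis=0) if beats.size else np.zeros(L)
    sqis = beat_sqis(beats, template) if beats.size else np.empty(0)
    onset_t = onsets / ppg.fs

    abp_filt = bandpass_ppg(abp, lp_cut=lp_cut, hp_cut=hp_cut, order=order)
    abp_onsets = segment_beats(abp_filt)

    duration = min(ppg.duration, abp.duration)
    windows = make_windows(duration, win=win, overlap=overlap)
    pulses: list[EnsemblePulse] = []
    refs: list[ReferenceBP] = []
    rows = []
    for wdw in windows:
        # beats fully inside the window
        if beats.size:
            sel = (onset_t[:-1] >= wdw.start) & (onset_t[1:] <= wdw.end)
        else:
            sel = np.zeros(0, dtype=bool)
        i0, i1 = int(round(wdw.start * ppg.fs)), int(round(wdw.end * ppg.fs))
        dc = float(np.mean(ppg.samples[i0:i1]))
        pulse = ensemble_average(beats[sel], sqis[sel], ibis[sel] / ppg.fs, wdw, dc)
        j0, j1 = int(round(wdw.start * abp.fs)), int(round(wdw.end * abp.fs))
        w_onsets = abp_onsets[(abp_onsets >= j0) & (abp_onsets < j1)] - j0
        ref = reference_bp(abp.samples[j0:j1], abp.fs, wdw, w_onsets)
        gated = gate_window(pulse, ref, sqi_min=sqi_min, var_max=var_max)
        if bad_ppg[i0:i1].any() or bad_abp[j0:j1].any():
            gated = False
        pulses.append(pulse)
        refs.append(ref)
        rows.append(
            dict(
                index=wdw.index, start=wdw.start, sqi=pulse.sqi, hr=pulse.hr,
                n_beats=pulse.n_beats, dc_mean=dc, sbp=ref.sbp, dbp=ref.dbp,
                mbp=ref.mbp, var_sbp=ref.variability_sbp,
                var_dbp=ref.variability_dbp, gated=gated,
            )
        )
        logger.debug("window %d of %s: gated=%s sqi=%.3f", wdw.index, ppg.subject_id, gated, pulse.sqi)
    meta = pd.DataFrame(rows) if rows else pd.DataFrame(
        columns=["index", "start", "sqi", "hr", "n_beats", "dc_mean", "sbp",
                 "dbp", "mbp", "var_sbp", "var_dbp", "gated"]
    )
    return PreprocessResult(ppg.subject_id, pulses, refs, meta)
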