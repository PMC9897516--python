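"""Pulse-wave analysis of ensemble-average PPG pulses.

Computes the first three time derivatives of the EA pulse -- velocity (VPG),
acceleration (APG) and jerk (JPG) plethysmograms -- locates the field-standard
fiducial points on each (APG a-e waves, VPG w/y/z, the first four alternating
JPG extrema, systolic peak, dicrotic notch and diastolic peak), and derives
the named morphological features: MAP, MSBP, MDBP, ESP, SPTI, DPTI, SEVR,
perfusion index (PI) and the heart-rate-corrected augmentation index (AIx75).

All amplitude features are in PPG signal units (the pipeline never maps the
optical waveform to pressure); the names follow the pressure-pulse analysis
convention from which they are borrowed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .types import EnsemblePulse

logger = logging.getLogger(__name__)

#: HR correction slope for the augmentation index, % per bpm.
AIX_HR_SLOPE = 0.48

#: Fiducial names guaranteed a (t, a) column pair in feature tables.
FIDUCIAL_NAMES = (
    "vpg.w", "vpg.y", "vpg.z",
    "apg.a", "apg.b", "apg.c", "apg.d", "apg.e",
    "jpg.p0", "jpg.p1", "jpg.p2", "jpg.p3",
    "ppg.sys_peak", "ppg.dicrotic_notch", "ppg.dia_peak",
)

#: Scalar pulse-level features.
PULSE_FEATURES = ("MAP", "MSBP", "MDBP", "ESP", "SPTI", "DPTI", "SEVR", "PI", "AIx75", "HR")

DEMOGRAPHIC_FIELDS = ("age", "weight", "height", "gender")


def feature_columns(include_demographics: bool = False) -> list[str]:
    """Canonical ordered column names of a wide feature table."""
    cols = list(PULSE_FEATURES)
    for name in FIDUCIAL_NAMES:
        cols += [f"{name}.t", f"{name}.a"]
    if include_demographics:
        cols += list(DEMOGRAPHIC_FIELDS)
    return cols


@dataclass
class DerivativeSet:
    """EA pulse with its 1st-3rd derivatives, aligned in time."""

    ppg: np.ndarray
    vpg: np.ndarray
    apg: np.ndarray
    jpg: np.ndarray
    fs_pulse: float


def derivatives(pulse: EnsemblePulse, smooth_window: int = 9, polyorder: int = 4) -> DerivativeSet:
    """Numerical 1st-3rd derivatives of the EA pulse.

    Each derivative is a Savitzky-Golay local-polynomial estimate taken
    directly from the pulse (symmetric window, polynomial edge handling), so
    errors do not cascade through repeated differencing and extremum timing
    is unbiased.
    """
    x = np.asarray(pulse.waveform, dtype=float)
    if x.size < 16:
        raise ValueError("pulse too short for differentiation")
    fs = pulse.fs_pulse
    delta = 1.0 / fs
    ds = [
        signal.savgol_filter(x, smooth_window, polyorder, deriv=k, delta=delta, mode="interp")
        for k in (1, 2, 3)
    ]
    return DerivativeSet(x, ds[0], ds[1], ds[2], fs)


def _local_extrema(x: np.ndarray, min_prom_frac: float = 1e-6) -> list[tuple[int, str]]:
    """Sorted (index, 'max'|'min') interior extrema with tiny-prominence guard."""
    prom = min_prom_frac * max(np.ptp(x), np.finfo(float).tiny)
    maxima, _ = signal.find_peaks(x, prominence=prom)
    minima, _ = signal.find_peaks(-x, prominence=prom)
    exts = [(int(i), "max") for i in maxima] + [(int(i), "min") for i in minima]
    return sorted(exts)


def alternating_extrema(
    x: np.ndarray, start_kind: str = "max", count: int | None = None, from_index: int = 0
) -> list[tuple[int, str]]:
    """Greedy alternating extrema walk used for APG a-e and JPG p0-p3.

    Starting at ``from_index`` and expecting ``start_kind`` first, extrema of
    the wrong kind are skipped, which makes the walk robust to small ripples
    that duplicate a kind.
    """
    want = start_kind
    picked: list[tuple[int, str]] = []
    for idx, kind in _local_extrema(x):
        if idx < from_index:
            continue
        if kind == want:
            picked.append((idx, kind))
            want = "min" if want == "max" else "max"
            if count is not None and len(picked) >= count:
                break
    return picked


def detect_fiducials(d: DerivativeSet, fs_pulse: float | None = None) -> dict[str, tuple[float, float]]:
    """Locate the named fiducial points on a single EA pulse.

    Returns a map ``name -> (t, a)`` with ``t`` in seconds from the pulse foot
    and ``a`` the amplitude of the carrying signal at that point.  Points that
    cannot be found on a degenerate pulse are simply absent; downstream
    features that need them become missing.
    """
    fs = fs_pulse or d.fs_pulse
    f: dict[str, tuple[float, float]] = {}

    def put(name: str, sig_arr: np.ndarray, idx: int) -> None:
        f[name] = (idx / fs, float(sig_arr[idx]))

    # systolic peak: global PPG maximum
    sys_idx = int(np.argmax(d.ppg))
    if 0 < sys_idx < d.ppg.size - 1:
        put("ppg.sys_peak", d.ppg, sys_idx)

    # VPG: w global max; y first local min after systolic peak; z next local max
    w_idx = int(np.argmax(d.vpg))
    if 0 < w_idx < d.vpg.size - 1:
        put("vpg.w", d.vpg, w_idx)
    vpg_ext = _local_extrema(d.vpg)
    y_idx = next((i for i, k in vpg_ext if k == "min" and i > sys_idx), None)
    if y_idx is not None:
        put("vpg.y", d.vpg, y_idx)
        z_idx = next((i for i, k in vpg_ext if k == "max" and i > y_idx), None)
        if z_idx is not None:
            put("vpg.z", d.vpg, z_idx)

    # APG a-e: first five alternating extrema after the foot, starting max
    apg_pts = alternating_extrema(d.apg, "max", count=5)
    for name, (idx, _) in zip(("apg.a", "apg.b", "apg.c", "apg.d", "apg.e"), apg_pts):
        put(name, d.apg, idx)

    # JPG p0-p3: first four alternating extrema, starting max
    jpg_pts = alternating_extrema(d.jpg, "max", count=4)
    for name, (idx, _) in zip(("jpg.p0", "jpg.p1", "jpg.p2", "jpg.p3"), jpg_pts):
        put(name, d.jpg, idx)

    # dicrotic notch at the APG e-wave; fallback: VPG z
    notch_idx = None
    if "apg.e" in f:
        notch_idx = int(round(f["apg.e"][0] * fs))
    elif "vpg.z" in f:
        notch_idx = int(round(f["vpg.z"][0] * fs))
    if notch_idx is not None and notch_idx < d.ppg.size:
        put("ppg.dicrotic_notch", d.ppg, notch_idx)
        # diastolic peak: first PPG local max after the notch; on pulses with
        # a pronounced early diastolic wave the e-wave can land past it, so
        # fall back to the first local max after the systolic peak, then to
        # the reflected-wave inflection (VPG local max after the notch)
        ppg_ext = _local_extrema(d.ppg)
        dia_idx = next((i for i, k in ppg_ext if k == "max" and i > notch_idx), None)
        if dia_idx is None:
            dia_idx = next((i for i, k in ppg_ext if k == "max" and i > sys_idx), None)
        if dia_idx is None:
            vmax_after = [i for i, k in _local_extrema(d.vpg) if k == "max" and i > notch_idx]
            dia_idx = vmax_after[0] if vmax_after else None
        if dia_idx is not None:
            put("ppg.dia_peak", d.ppg, dia_idx)
    return f


def pulse_features(
    pulse: EnsemblePulse,
    d: DerivativeSet,
    f: dict[str, tuple[float, float]],
    aix_hr_slope: float = AIX_HR_SLOPE,
    inflection_point: str = "apg.d",
) -> dict[str, float]:
    """Morphological feature vector of one EA pulse.

    With notch time ``T_n`` and pulse duration ``T`` (trapezoidal quadrature
    on the length-L pulse): MAP = mean over [0, T]; MSBP / MDBP = means over
    the systolic / diastolic sub-intervals; ESP = value at ``T_n``;
    SPTI / DPTI = areas of the two sub-intervals; SEVR = DPTI / SPTI;
    PI = 100 * (half peak-to-peak amplitude) / (unfiltered window mean);
    AIx = 100 * (peak - inflection) / amplitude, corrected to 75 bpm with
    ``aix_hr_slope`` % per bpm.  Features whose fiducials are missing are NaN.
    """
    # amplitudes and areas are measured from the diastolic minimum (foot
    # level) so they are nonnegative, as on a pressure pulse
    x = d.ppg - d.ppg.min()
    fs = d.fs_pulse
    dt = 1.0 / fs
    out: dict[str, float] = {k: np.nan for k in PULSE_FEATURES}
    out["MAP"] = float(np.mean(x))
    out["HR"] = float(pulse.hr)

    if "ppg.dicrotic_notch" in f:
        tn = f["ppg.dicrotic_notch"][0]
        n_idx = int(round(tn * fs))
        n_idx = min(max(n_idx, 1), x.size - 2)
        out["MSBP"] = float(np.mean(x[: n_idx + 1]))
        out["MDBP"] = float(np.mean(x[n_idx:]))
        out["ESP"] = float(x[n_idx])
        spti = float(np.trapezoid(x[: n_idx + 1], dx=dt))
        dpti = float(np.trapezoid(x[n_idx:], dx=dt))
        out["SPTI"], out["DPTI"] = spti, dpti
        out["SEVR"] = dpti / spti if spti != 0 else np.nan

    amp = float(np.ptp(x))
    if np.isfinite(pulse.dc_mean) and pulse.dc_mean != 0:
        out["PI"] = 100.0 * (amp / 2.0) / pulse.dc_mean
    if "ppg.sys_peak" in f and inflection_point in f and amp > 0:
        t_inf = f[inflection_point][0]
        i_inf = min(int(round(t_inf * fs)), x.size - 1)
        aix = 100.0 * (float(x.max()) - float(x[i_inf])) / amp
        if np.isfinite(pulse.hr):
            out["AIx75"] = aix + aix_hr_slope * (pulse.hr - 75.0)

    for name in FIDUCIAL_NAMES:
        if name in f:
            out[f"{name}.t"], out[f"{name}.a"] = f[name]
        else:
            out[f"{name}.t"] = out[f"{name}.a"] = np.nan
    return out


def attach_demographics(fv: dict[str, float], demo: dict) -> dict[str, float]:
    """Append age (y), weight (kg), height (cm) and gender (0/1) to a
    feature vector.  Missing fields and key collisions raise; no imputation."""
    if not demo:
        raise ValueError("empty demographics record")
    missing = [k for k in DEMOGRAPHIC_FIELDS if k not in demo or demo[k] is None]
    if missing:
        raise ValueError(f"missing demographic field(s): {missing}")
    collisions = [k for k in DEMOGRAPHIC_FIELDS if k in fv]
    if collisions:
        raise ValueError(f"feature vector already contains: {collisions}")
    out = dict(fv)
    gender = demo["gender"]
    if isinstance(gender, str):
        gender = {"m": 1, "male": 1, "f": 0, "female": 0}[gender.strip().lower()]
    out.update(
        age=float(demo["age"]), weight=float(demo["weight"]),
        height=float(demo["height"]), gender=float(int(gender)),
    )
    return out


def feature_table(
    preproc,  # PreprocessResult
    demographics: dict | None = None,
    gated_only: bool = True,
    aix_hr_slope: float = AIX_HR_SLOPE,
    inflection_point: str = "apg.d",
) -> pd.DataFrame:
    """Wide per-window feature table for one recording.

    One row per (gated) window with the canonical feature columns plus the
    window metadata needed downstream (``start``, reference ``sbp/dbp/mbp``,
    ``subject_id``).  Rows whose required fiducials are missing keep NaN in
    the affected columns; sample builders drop incomplete rows.
    """
    rows = []
    for pulse, ref, (_, m) in zip(preproc.pulses, preproc.refs, preproc.meta.iterrows()):
        if gated_only and not m["gated"]:
            continue
        if not pulse.valid:
            continue
        try:
            d = derivatives(pulse)
        except ValueError:
            continue
        fids = detect_fiducials(d)
        fv = pulse_features(pulse, d, fids, aix_hr_slope, inflection_point)
        if demographics is not None:
            fv = attach_demographics(fv, demographics)
        fv.update(
            start=m["start"], sbp=ref.sbp, dbp=ref.dbp, mbp=ref.mbp,
            subject_id=preproc.subject_id, window_index=int(m["index"]),
        )
        rows.append(fv)
    cols = feature_columns(demographics is not None) + [
        "start", "sbp", "dbp", "mbp", "subject_id", "window_index"
    ]
    return pd.DataFrame(rows, columns=cols)
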