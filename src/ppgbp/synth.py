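"""Seeded synthetic cohorts of paired PPG/ABP recordings.

The generator emulates an anesthesia-induction monitoring session: each
subject has a baseline BP plateau, a rapid induction-related drop of 20-45%
over one to three minutes, partial vasopressor-like recovery bumps, and slow
autoregressive drift.  Beats are rendered from a two-Gaussian pulse model
whose parameters depend on the instantaneous BP through simple closed-form
linear maps (:func:`pulse_from_bp`), so the morphology-BP relationship the
estimation pipeline must recover is known by construction and analytically
differentiable.  Per-subject random offsets on the morphology coefficients
emulate inter-subject pulse-shape variability, which is what makes a
calibration measure informative.

Cohort-level defaults target the demographic and BP summary statistics of a
40-subject adult surgical population: per-subject mean SBP 124.3 +/- 24.8
mmHg (range ~83-200), mean DBP 63.0 +/- 10.4 mmHg, per-subject SBP standard
deviation around 18.7 mmHg, recordings of 9-19 minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .types import PulseParams, WaveformRecording

#: Slopes of the planted linear morphology-BP link (per mmHg).
LINK = dict(
    w_sys_per_sbp=-0.00015,   # steeper upstroke (narrower systolic wave) at high SBP
    c_dia_per_sbp=-0.0009,    # earlier reflected wave at high SBP
    amp_dia_per_sbp=0.004,    # larger diastolic wave at high SBP
    amp_dia_per_dbp=0.003,
    w_dia_per_dbp=0.0006,
    amp_per_sbp=-0.002,       # vasoconstriction shrinks the AC amplitude
)


@dataclass
class CohortConfig:
    """Study conditions of a synthetic cohort.

    All times in seconds, pressures in mmHg, rates in Hz or bpm.
    """

    seed: int
    n_subjects: int = 40
    fs: float = 125.0
    duration_range: tuple[float, float] = (540.0, 1140.0)
    sbp_mean: float = 124.3
    sbp_sd: float = 24.8
    sbp_clip: tuple[float, float] = (85.0, 200.0)
    dbp_mean: float = 63.0
    dbp_sd: float = 10.4
    dbp_clip: tuple[float, float] = (42.0, 86.0)
    hr_range: tuple[float, float] = (55.0, 90.0)
    drop_frac_range: tuple[float, float] = (0.20, 0.45)
    drop_tau_range: tuple[float, float] = (10.0, 30.0)
    n_bumps_range: tuple[int, int] = (1, 3)
    bump_amp_frac_range: tuple[float, float] = (0.10, 0.40)
    ar_sd: float = 3.0
    ar_rho: float = 0.995
    noise_sd: float = 0.02          # PPG white noise, fraction of AC amplitude
    corrupt_frac: float = 0.02      # fraction of beats replaced by artifact
    abp_noise_sd: float = 0.05      # mmHg
    wander_frac: float = 0.05       # baseline wander amplitude, fraction of AC
    # per-subject morphology offsets (sd of the additive offset)
    subject_w_sys_sd: float = 0.003
    subject_c_dia_sd: float = 0.012
    subject_amp_dia_sd: float = 0.05
    subject_w_dia_sd: float = 0.008
    subject_gain_sd: float = 0.15   # lognormal sigma of the PPG gain

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a cohort seed is mandatory")
        if self.n_subjects < 1 or self.fs <= 30:
            raise ValueError("need >= 1 subject and fs > 30 Hz")


@dataclass
class Trajectory:
    """Per-second BP/HR trajectory of one subject."""

    t: np.ndarray
    sbp: np.ndarray
    dbp: np.ndarray
    hr: np.ndarray


@dataclass
class SynthRecording:
    """One subject's paired waveforms plus ground truth."""

    ppg: WaveformRecording
    abp: WaveformRecording
    demographics: dict
    truth: dict


@dataclass
class SynthCohort:
    config: CohortConfig
    recordings: list[SynthRecording] = field(default_factory=list)

    @property
    def subject_ids(self) -> list[str]:
        return [r.ppg.subject_id for r in self.recordings]


def _subject_rng(cfg: CohortConfig, subject_idx: int) -> np.random.Generator:
    return np.random.default_rng([int(cfg.seed), int(subject_idx)])


def bp_trajectory(cfg: CohortConfig, subject_seed: int) -> Trajectory:
    """Piecewise-smooth anesthesia-induction BP trajectory on a 1-s grid.

    Baseline plateau, a logistic induction drop (fraction drawn from
    ``drop_frac_range``, time constant from ``drop_tau_range``), Gaussian
    recovery bumps, and an AR(1) drift of stationary sd ``ar_sd``.  DBP
    follows the SBP dynamics with 80% of the relative drop and correlated
    drift.
    """
    rng = _subject_rng(cfg, subject_seed)
    duration = rng.uniform(*cfg.duration_range)
    t = np.arange(0.0, duration, 1.0)

    # per-subject *time-mean* targets; the pre-induction baseline is derived
    # below so the realized recording mean matches the draw
    sbp_target = float(np.clip(rng.normal(cfg.sbp_mean, cfg.sbp_sd), *cfg.sbp_clip))
    dbp_target = float(np.clip(rng.normal(cfg.dbp_mean, cfg.dbp_sd), *cfg.dbp_clip))
    dbp_target = min(dbp_target, 0.72 * sbp_target)
    hr0 = rng.uniform(*cfg.hr_range)

    # cap the drop so per-subject SBP std stays within the emulated range
    d_lo, d_hi = cfg.drop_frac_range
    d_hi = min(d_hi, 66.0 / (sbp_target + 33.0)) if d_hi > 0 else d_hi
    drop = rng.uniform(d_lo, max(d_lo, d_hi))
    tau = rng.uniform(*cfg.drop_tau_range)
    t_drop = rng.uniform(0.25, 0.45) * duration
    s = 1.0 / (1.0 + np.exp(-(t - t_drop) / max(tau, 1e-6)))

    bumps = np.zeros_like(t)
    lo, hi = cfg.n_bumps_range
    for _ in range(int(rng.integers(lo, hi + 1)) if hi >= lo else 0):
        c = rng.uniform(t_drop + 60.0, max(t_drop + 61.0, duration))
        w = rng.uniform(30.0, 90.0)
        a = rng.uniform(*cfg.bump_amp_frac_range) * drop * sbp_target
        bumps += a * np.exp(-((t - c) ** 2) / (2 * w**2))

    if cfg.ar_sd > 0:
        sigma = cfg.ar_sd * np.sqrt(1 - cfg.ar_rho**2)
        eps = rng.normal(0.0, sigma, size=t.size)
        ar = np.empty_like(t)
        acc = rng.normal(0.0, cfg.ar_sd)
        for k in range(t.size):
            acc = cfg.ar_rho * acc + eps[k]
            ar[k] = acc
    else:
        ar = np.zeros_like(t)

    # baseline solving  mean(B * (1 - drop*s) + bumps + ar) == target
    shape_s = 1.0 - drop * s
    sbp0 = (sbp_target - bumps.mean() - ar.mean()) / shape_s.mean()
    shape_d = 1.0 - 0.8 * drop * s
    dbp0 = (dbp_target - 0.4 * bumps.mean() - 0.5 * ar.mean()) / shape_d.mean()
    sbp = sbp0 * shape_s + bumps + ar
    dbp = dbp0 * shape_d + 0.4 * bumps + 0.5 * ar
    dbp = np.minimum(dbp, sbp - 15.0)
    hr = hr0 + 8.0 * s + 0.3 * ar
    return Trajectory(t, sbp, dbp, hr)


def pulse_from_bp(
    sbp: float, dbp: float, hr: float, offsets: dict | None = None
) -> PulseParams:
    """Deterministic closed-form map from (SBP, DBP, HR) to beat shape.

    With period ``T = 60/hr`` and deviations from the cohort operating point
    (120/63 mmHg), the planted link is::

        w_sys   = T * (0.075 - 0.00015 (SBP-120))    # upstroke steepness
        c_dia   = T * (0.45  - 0.0009  (SBP-120))    # reflected-wave timing
        amp_dia =      0.35  + 0.004   (SBP-120) + 0.003 (DBP-63)
        w_dia   = T * (0.14  + 0.0006  (DBP-63))

    Higher BP therefore gives a steeper upstroke and an earlier, larger
    diastolic (reflected) wave.  ``offsets`` adds per-subject deviations to
    the fractional parameters (keys ``w_sys``, ``c_dia``, ``amp_dia``,
    ``w_dia``); the same call without offsets is bit-identical across calls.
    """
    off = offsets or {}
    T = 60.0 / hr
    ds, dd = sbp - 120.0, dbp - 63.0
    w_sys = T * float(np.clip(0.075 + LINK["w_sys_per_sbp"] * ds + off.get("w_sys", 0.0), 0.045, 0.12))
    c_dia = T * float(np.clip(0.45 + LINK["c_dia_per_sbp"] * ds + off.get("c_dia", 0.0), 0.30, 0.62))
    amp_dia = float(np.clip(0.35 + LINK["amp_dia_per_sbp"] * ds + LINK["amp_dia_per_dbp"] * dd
                            + off.get("amp_dia", 0.0), 0.05, 0.95))
    w_dia = T * float(np.clip(0.14 + LINK["w_dia_per_dbp"] * dd + off.get("w_dia", 0.0), 0.08, 0.22))
    return PulseParams(
        c_sys=0.16 * T, w_sys=w_sys, amp_sys=1.0,
        c_dia=c_dia, w_dia=w_dia, amp_dia=amp_dia,
        baseline=0.0, period=T,
    )


def _draw_demographics(rng: np.random.Generator) -> dict:
    return dict(
        age=float(np.clip(rng.normal(62.4, 12.7), 27, 81)),
        height=float(np.clip(rng.normal(170.1, 9.89), 154, 189)),
        weight=float(np.clip(rng.normal(72.6, 13.4), 46, 102)),
        gender=int(rng.random() < 0.525),
    )


def synth_recording(cfg: CohortConfig, subject_seed: int) -> SynthRecording:
    """Render one subject's paired PPG/ABP waveforms beat by beat.

    The PPG is DC offset + gain * two-Gaussian AC pulses + baseline wander +
    white noise, with a configurable fraction of beats replaced by noise
    bursts (to exercise SQI gating).  The ABP reuses each beat's shape,
    rescaled per beat so the beat maximum/minimum equal the commanded
    SBP/DBP exactly (before the small additive measurement noise).
    """
    rng = _subject_rng(cfg, subject_seed)
    traj = bp_trajectory(cfg, subject_seed)  # same sub-stream: re-derive rng after
    # bp_trajectory consumed from an identically seeded generator; draw the
    # rendering stream from a distinct child so the two stay independent.
    rng = np.random.default_rng([int(cfg.seed), int(subject_seed), 1])

    offsets = dict(
        w_sys=rng.normal(0.0, cfg.subject_w_sys_sd),
        c_dia=rng.normal(0.0, cfg.subject_c_dia_sd),
        amp_dia=rng.normal(0.0, cfg.subject_amp_dia_sd),
        w_dia=rng.normal(0.0, cfg.subject_w_dia_sd),
    )
    gain = float(np.exp(rng.normal(0.0, cfg.subject_gain_sd)))
    dc = float(rng.uniform(800.0, 1200.0))
    demo = _draw_demographics(rng)

    duration = float(traj.t[-1] + 1.0)
    n = int(round(duration * cfg.fs))
    tt = np.arange(n) / cfg.fs
    shape = np.zeros(n)       # unit-amplitude beat shapes (for ABP rescaling)
    ppg_ac = np.zeros(n)

    beat_times: list[float] = []
    beat_sbp: list[float] = []
    beat_dbp: list[float] = []
    corrupt_spans: list[tuple[int, int]] = []
    t_beat = 0.0
    while t_beat < duration - 1.5:
        sbp_b = float(np.interp(t_beat, traj.t, traj.sbp))
        dbp_b = float(np.interp(t_beat, traj.t, traj.dbp))
        hr_b = float(np.interp(t_beat, traj.t, traj.hr)) + rng.normal(0.0, 0.5)
        hr_b = float(np.clip(hr_b, 30.0, 180.0))
        params = pulse_from_bp(sbp_b, dbp_b, hr_b, offsets)
        T = params.period
        i0 = max(int((t_beat - 0.3 * T) * cfg.fs), 0)
        i1 = min(int((t_beat + 1.3 * T) * cfg.fs), n)
        u = tt[i0:i1] - t_beat
        contrib = params.evaluate(u)
        shape[i0:i1] += contrib
        amp_b = gain * (1.0 + LINK["amp_per_sbp"] * (sbp_b - 120.0))
        if rng.random() < cfg.corrupt_frac:
            j0, j1 = int(t_beat * cfg.fs), min(int((t_beat + T) * cfg.fs), n)
            corrupt_spans.append((j0, j1))
        ppg_ac[i0:i1] += amp_b * contrib
        beat_times.append(t_beat)
        beat_sbp.append(sbp_b)
        beat_dbp.append(dbp_b)
        t_beat += T

    # ABP: per-beat min-max rescaling of the shape signal to (DBP, SBP)
    abp = np.empty(n)
    edges = [int(bt * cfg.fs) for bt in beat_times] + [n]
    abp[: edges[0]] = beat_dbp[0] if beat_dbp else 80.0
    for k in range(len(beat_times)):
        seg = shape[edges[k] : edges[k + 1]]
        lo, hi = seg.min(), seg.max()
        span = hi - lo if hi > lo else 1.0
        abp[edges[k] : edges[k + 1]] = beat_dbp[k] + (beat_sbp[k] - beat_dbp[k]) * (seg - lo) / span
    if cfg.abp_noise_sd > 0:
        abp = abp + rng.normal(0.0, cfg.abp_noise_sd, size=n)

    amp_typ = gain  # nominal AC amplitude
    for j0, j1 in corrupt_spans:
        ppg_ac[j0:j1] = rng.normal(0.0, amp_typ, size=j1 - j0)
    wander = cfg.wander_frac * amp_typ * np.sin(2 * np.pi * 0.08 * tt + rng.uniform(0, 2 * np.pi))
    noise = rng.normal(0.0, cfg.noise_sd * amp_typ, size=n) if cfg.noise_sd > 0 else 0.0
    ppg = dc + ppg_ac + wander + noise

    sid = f"S{subject_seed:03d}"
    truth = dict(
        t=traj.t, sbp=traj.sbp, dbp=traj.dbp, hr=traj.hr,
        beat_times=np.asarray(beat_times), beat_sbp=np.asarray(beat_sbp),
        beat_dbp=np.asarray(beat_dbp), offsets=offsets, gain=gain, dc=dc,
        link=dict(LINK),
    )
    return SynthRecording(
        ppg=WaveformRecording(ppg, cfg.fs, sid, "ppg"),
        abp=WaveformRecording(abp, cfg.fs, sid, "abp"),
        demographics=dict(subject_id=sid, **demo),
        truth=truth,
    )


def generate_cohort(cfg: CohortConfig) -> SynthCohort:
    """Generate the full cohort; bit-reproducible given (cfg, seed)."""
    cohort = SynthCohort(config=cfg)
    for idx in range(cfg.n_subjects):
        cohort.recordings.append(synth_recording(cfg, idx))
    return cohort


def cohort_summary(cohort: SynthCohort) -> dict:
    """Cohort-level BP summary statistics (per-subject means and stds)."""
    means_s = [float(r.truth["sbp"].mean()) for r in cohort.recordings]
    stds_s = [float(r.truth["sbp"].std()) for r in cohort.recordings]
    means_d = [float(r.truth["dbp"].mean()) for r in cohort.recordings]
    return dict(
        sbp_mean_of_means=float(np.mean(means_s)),
        sbp_sd_of_means=float(np.std(means_s, ddof=1)) if len(means_s) > 1 else 0.0,
        sbp_mean_of_stds=float(np.mean(stds_s)),
        dbp_mean_of_means=float(np.mean(means_d)),
        per_subject_sbp_means=means_s,
        per_subject_sbp_stds=stds_s,
    )
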