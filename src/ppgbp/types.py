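"""Core domain containers shared across the pipeline.

The pipeline moves data through a fixed sequence of shapes: raw waveforms
(:class:`WaveformRecording`), overlapping analysis windows (:class:`Window`),
one quality-weighted representative beat per window (:class:`EnsemblePulse`)
with its invasive reference (:class:`ReferenceBP`), and finally flat feature
mappings consumed by the regression models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class WaveformRecording:
    """A uniformly sampled physiological signal.

    Parameters
    ----------
    samples:
        Signal values; arbitrary units for PPG, mmHg for arterial pressure.
    fs:
        Sampling rate in Hz (> 0).
    subject_id:
        Identifier of the subject the recording belongs to.
    channel:
        Either ``"ppg"`` or ``"abp"``.
    t0:
        Time of the first sample in seconds.
    """

    samples: np.ndarray
    fs: float
    subject_id: str = ""
    channel: str = "ppg"
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D array")
        if self.channel not in ("ppg", "abp"):
            raise ValueError(f"channel must be 'ppg' or 'abp', got {self.channel!r}")

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fs


@dataclass(frozen=True)
class Window:
    """One 20-s analysis segment; consecutive windows overlap by 50%."""

    start: float
    duration: float
    index: int

    @property
    def end(self) -> float:
        return self.start + self.duration


@dataclass
class EnsemblePulse:
    """Quality-weighted average beat of one window, onset-aligned.

    ``waveform[0]`` is the pulse foot.  ``fs_pulse`` is the effective rate of
    the length-L resampled beat (L / beat period), so fiducial indices convert
    to seconds from the foot.  ``dc_mean`` carries the mean of the *unfiltered*
    window (the DC term of the perfusion index), which the band-pass removed
    from the waveform itself.
    """

    waveform: np.ndarray
    fs_pulse: float
    hr: float
    window: Window
    sqi: float
    valid: bool
    dc_mean: float = np.nan
    n_beats: int = 0


@dataclass
class ReferenceBP:
    """Median invasive BP over one window with per-beat variability.

    ``variability_*`` is std/mean of the per-beat systolic (resp. diastolic)
    series over the window; both series gate the window.
    """

    sbp: float
    dbp: float
    mbp: float
    window: Window
    variability_sbp: float
    variability_dbp: float
    valid: bool = True

    @property
    def variability(self) -> float:
        """Worst-case relative variability over the SBP and DBP beat series."""
        return max(self.variability_sbp, self.variability_dbp)


@dataclass
class SplitSpec:
    """Subject-level train/test partition."""

    train_subjects: list[str]
    test_subjects: list[str]
    train_fraction: float
    seed: int

    def __post_init__(self) -> None:
        overlap = set(self.train_subjects) & set(self.test_subjects)
        if overlap:
            raise ValueError(f"subjects assigned to both sets: {sorted(overlap)}")


@dataclass(frozen=True)
class TrendPair:
    """One (reference change, estimated change) pair for trending analysis."""

    d_inv: float
    d_est: float
    dt: float
    subject_id: str = ""


@dataclass
class ErrorReport:
    """Mean error / error standard deviation of BP estimates (mmHg)."""

    me: float
    stde: float
    n: int
    per_subject: dict[str, tuple[float, float]] = field(default_factory=dict)
    split: str = "test"


@dataclass
class TrendReport:
    """Four-quadrant and polar-plot trending statistics."""

    cr: float
    pearson_r: float
    angular_cr_30: float
    angular_bias: float
    angular_sd: float
    radial_loa_95: tuple[float, float]
    n_pairs: int
    timespan_bin: str = "all"


@dataclass
class SelectionResult:
    """Outcome of L1-penalised feature selection."""

    selected_features: list[str]
    lambda_: float
    coefficients: dict[str, float]
    n_selected: int
    intercept: float = 0.0
    dropped_constant: list[str] = field(default_factory=list)


@dataclass
class PulseParams:
    """Closed-form two-Gaussian beat shape used by the synthetic generator.

    The beat over local time ``u`` in [0, period) is
    ``amp_sys * exp(-(u-c_sys)^2 / (2 w_sys^2)) + amp_dia * exp(-(u-c_dia)^2 / (2 w_dia^2))``.
    """

    c_sys: float
    w_sys: float
    amp_sys: float
    c_dia: float
    w_dia: float
    amp_dia: float
    baseline: float
    period: float

    def __post_init__(self) -> None:
        if not (0 < self.c_sys < self.c_dia < self.period):
            raise ValueError("require 0 < systolic center < diastolic center < period")
        if min(self.amp_sys, self.amp_dia, self.w_sys, self.w_dia) <= 0:
            raise ValueError("amplitudes and widths must be positive")

    def evaluate(self, u: np.ndarray) -> np.ndarray:
        """Evaluate the beat shape at local times ``u`` (seconds)."""
        u = np.asarray(u, dtype=float)
        return (
            self.baseline
            + self.amp_sys * np.exp(-((u - self.c_sys) ** 2) / (2 * self.w_sys**2))
            + self.amp_dia * np.exp(-((u - self.c_dia) ** 2) / (2 * self.w_dia**2))
        )

    def derivative(self, u: np.ndarray, order: int = 1) -> np.ndarray:
        """Analytic derivative of the beat shape (orders 1-3)."""
        u = np.asarray(u, dtype=float)
        out = np.zeros_like(u)
        for c, w, a in ((self.c_sys, self.w_sys, self.amp_sys),
                        (self.c_dia, self.w_dia, self.amp_dia)):
            z = (u - c) / w
            g = a * np.exp(-(z**2) / 2)
            if order == 1:
                out += -z / w * g
            elif order == 2:
                out += (z**2 - 1) / w**2 * g
            elif order == 3:
                out += -z * (z**2 - 3) / w**3 * g
            else:
                raise ValueError("order must be 1, 2 or 3")
        return out
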