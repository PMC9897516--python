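import numpy as np
import pytest

from ppgbp import synth as sy
from ppgbp.types import EnsemblePulse, PulseParams, Window


def sample_pulse(params: PulseParams, L: int = 256, dc_mean: float = 1000.0) -> EnsemblePulse:
    """Sample a closed-form two-Gaussian beat into an ensemble pulse."""
    T = params.period
    u = np.linspace(0.0, T, L, endpoint=False)
    return EnsemblePulse(
        waveform=params.evaluate(u), fs_pulse=L / T, hr=60.0 / T,
        window=Window(0.0, 20.0, 0), sqi=1.0, valid=True, dc_mean=dc_mean,
        n_beats=10,
    )


def random_physiologic_params(rng: np.random.Generator) -> PulseParams:
    """Random beat-shape parameters over the generator's physiologic ranges."""
    sbp = rng.uniform(90.0, 180.0)
    dbp = rng.uniform(45.0, min(85.0, 0.7 * sbp))
    hr = rng.uniform(55.0, 95.0)
    return sy.pulse_from_bp(sbp, dbp, hr)


def dense_alternating_extrema(
    values: np.ndarray, grid: np.ndarray, start_kind: str = "max", count: int | None = None
):
    """Independent extrema oracle: neighbour comparison on a dense grid,
    then a greedy alternation walk starting with ``start_kind``."""
    exts = []
    for i in range(1, values.size - 1):
        if values[i] > values[i - 1] and values[i] > values[i + 1]:
            exts.append((grid[i], "max"))
        elif values[i] < values[i - 1] and values[i] < values[i + 1]:
            exts.append((grid[i], "min"))
    picked = []
    want = start_kind
    for t, kind in exts:
        if kind == want:
            picked.append((t, kind))
            want = "min" if want == "max" else "max"
            if count is not None and len(picked) >= count:
                break
    return picked


@pytest.fixture(scope="session")
def tiny_cohort():
    """Three short synthetic recordings for integration-level unit tests."""
    cfg = sy.CohortConfig(seed=42, n_subjects=3, duration_range=(150.0, 210.0))
    return sy.generate_cohort(cfg)
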