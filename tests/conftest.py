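import numpy as np
import pytest

from ecogprop import CohortConfig, EcogRecording, RunConfig


@pytest.fixture
def run_config() -> RunConfig:
    return RunConfig()


@pytest.fixture
def sine_recording() -> EcogRecording:
    """Three sinusoids (1, 2, 3 Hz) at 250 Hz for I/O round-trip checks."""
    fs = 250.0
    t = np.arange(int(fs * 10)) / fs
    channels = {
        "focus": 100.0 * np.sin(2 * np.pi * 1.0 * t),
        "d1mm": 100.0 * np.sin(2 * np.pi * 2.0 * t),
        "d2mm": 100.0 * np.sin(2 * np.pi * 3.0 * t),
    }
    return EcogRecording(
        animal_id="m01",
        group="epilepsy_control",
        week=3,
        sampling_rate=fs,
        channels=channels,
        rail=500.0,
    ).validate()


@pytest.fixture
def busy_cohort_config() -> CohortConfig:
    """Default-SNR generator with incidence boosted for short sessions.

    Amplitude and noise presets (the SNR) stay at their defaults; only
    the per-day rates are multiplied so a 20-minute desk-scale session
    contains enough events for recall/precision statistics.
    """
    cfg = CohortConfig()
    cfg.rates = {
        g: {etype: 8.0 * rate for etype, rate in r.items()}
        for g, r in cfg.rates.items()
    }
    return cfg
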