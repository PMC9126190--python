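import numpy as np
import pytest

from cbtrhythms import (
    GroupDesign,
    SimulationParams,
    TemperatureSeries,
    WaveletParams,
    clean_series,
    morse_transform,
    simulate_animal,
)

# band-limited wavelet configs: exact restrictions of the default grid used
# where only one band is scored (keeps Monte-Carlo suites fast)
UR_PARAMS = WaveletParams(period_min_h=1.0, period_max_h=3.05)
CR_PARAMS = WaveletParams(period_min_h=20.0, period_max_h=28.0)


def tone_series(period_h: float, n_days: int, amplitude: float = 1.0,
                offset: float = 37.0, animal_id: str = "tone") -> TemperatureSeries:
    t = np.arange(n_days * 1440)
    x = offset + amplitude * np.cos(2 * np.pi * t / (period_h * 60.0))
    return TemperatureSeries(animal_id, t, x)


@pytest.fixture(scope="session")
def intact_animal():
    """One default Intact animal, cleaned, with its ground truth."""
    a = simulate_animal(GroupDesign("Intact"), SimulationParams(), seed=7)
    cleaned, _ = clean_series(a.temperature)
    return a, cleaned


@pytest.fixture(scope="session")
def tone24_spectrum():
    """Morse spectrum of a pure 24 h unit tone over 20 days."""
    return morse_transform(tone_series(24.0, 20), WaveletParams())
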