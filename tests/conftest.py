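import numpy as np
import pytest
from hypothesis import settings

from pftm import ObserverModel, PupilTrace, SessionConfig, Unit

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


def make_trace(values, rate=1000.0, t0=0.0, unit=Unit.MM, gaps=None):
    values = np.asarray(values, dtype=float)
    times = t0 + np.arange(values.size) / rate
    return PupilTrace(times=times, values=values, rate=rate, unit=unit, gaps=gaps)


def cosine_trace(freq, amplitude=1.0, phase_deg=0.0, offset=0.0, rate=1000.0,
                 t0=0.0, duration=4.0):
    n = int(round(duration * rate))
    times = t0 + np.arange(n) / rate
    values = offset + amplitude * np.cos(
        2 * np.pi * freq * (times - t0) + np.radians(phase_deg))
    return PupilTrace(times=times, values=values, rate=rate, unit=Unit.MM)


@pytest.fixture
def human_config():
    """Red fixed at 21.04 cd/m^2 against 15 linearly spaced greens."""
    return SessionConfig("red", 21.04, "green",
                         tuple(np.linspace(4.2, 37.9, 15)), repeats=10)


@pytest.fixture
def same_colour_config():
    """Green-vs-green control: fixed 11.04, 21 levels spanning 1.6-33.05."""
    return SessionConfig("green", 11.04, "green",
                         tuple(np.linspace(1.6, 33.05, 21)), repeats=10)


@pytest.fixture
def quiet_model():
    return ObserverModel(gain=0.85, noise_sd=0.0)


@pytest.fixture
def default_model():
    return ObserverModel(gain=0.85)
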