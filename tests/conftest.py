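import numpy as np
import pandas as pd
import pytest

from pondburst.synthio import (
    DEFAULT_TEMPLATES,
    SimulationConfig,
    generate_amplitude_series,
    generate_weather,
    schedule_events,
)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A reduced two-pond season (55 days, earlier wet spells) for fast tests."""
    return SimulationConfig(
        n_ponds=2,
        season_days=55,
        wet_spell_days=(12.0, 38.0),
        wet_spell_jitter_days=2.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    """Weather, ground-truth events and amplitude series for the small season."""
    weather, events, amplitude = {}, [], {}
    for i, site in enumerate(small_config.site_ids()):
        w = generate_weather(small_config, i)
        evs = schedule_events(w, small_config, i)
        weather[site] = w
        events.extend(evs)
        amplitude[site] = generate_amplitude_series(evs, small_config, i)
    return weather, events, amplitude


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
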