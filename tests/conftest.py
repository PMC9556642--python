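import numpy as np
import pytest

from headbow.core import Passage, PassageSet
from headbow.synth import (
    ConditionProfile,
    GapSpec,
    TempoConfig,
    default_passages,
    generate_beat_grid,
    generate_trial,
)


@pytest.fixture(scope="session")
def default_grid():
    return generate_beat_grid(TempoConfig(), seed=42)


@pytest.fixture(scope="session")
def passages():
    return default_passages()


@pytest.fixture(scope="session")
def short_passages():
    """Two short passages over a 40-step grid, for fast unit tests."""
    return PassageSet([Passage(0, 10, "quarter"), Passage(15, 35, "eighth")])


@pytest.fixture(scope="session")
def short_grid():
    return generate_beat_grid(TempoConfig(n_steps=40), seed=7)


@pytest.fixture(scope="session")
def short_trial(short_grid, short_passages):
    profile = ConditionProfile(
        level_amplitudes={"whole": 12.0, "half": 5.0, "quarter": 3.0, "eighth": 1.5},
        head_bow_lag=-20.0,
        phase_noise_kappa=8.0,
        noise_sd=0.3,
    )
    return generate_trial(profile, short_grid, short_passages,
                          GapSpec(gap_rate=0.1), seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
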