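import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest
from hypothesis import settings

import sleepbouts as sb

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")
from sleepbouts.hypnogram import RAW_STATES


@pytest.fixture
def rng():
    return np.random.default_rng(20190726)


def random_hypnogram(rng, n_epochs, subject="r1", treatment="VEH", states=RAW_STATES):
    return sb.Hypnogram(
        subject_id=subject,
        treatment=treatment,
        states=tuple(rng.choice(states, size=n_epochs)),
    )


@pytest.fixture(scope="session")
def sim_config():
    return sb.default_config(seed=1234)


@pytest.fixture(scope="session")
def study(sim_config):
    """Full simulated study: 6 subjects x 3 treatments x 2700 epochs."""
    return sb.simulate_study(sim_config)


@pytest.fixture(scope="session")
def study_table(study):
    return sb.bout_table(study)
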