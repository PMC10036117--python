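import numpy as np
import pytest

from ymaze.geometry import build_maze
from ymaze.io import specs_for
from ymaze.simulate import default_config, simulate_cohort


@pytest.fixture(scope="session")
def landmark_spec():
    return build_maze("landmark", 1.70)


@pytest.fixture(scope="session")
def geometry_spec():
    return build_maze("geometry", 1.70)


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced full-stream cohort shared across gaze/metrics tests."""
    sim = simulate_cohort(default_config(seed=11, size_scale=0.35))
    return sim, specs_for(sim.trials)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
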