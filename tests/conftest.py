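import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def face_set():
    from cortcol import stimuli

    return stimuli.face_set()


@pytest.fixture(scope="session")
def square_set():
    from cortcol import stimuli

    return stimuli.square_set()


@pytest.fixture(scope="session")
def default_params():
    from cortcol import ModelParams

    return ModelParams()


def _experiment(experiment_id, seed, n_steps=None):
    from cortcol import preset, run_experiment

    return run_experiment(preset(experiment_id, seed=seed, n_steps=n_steps))


@pytest.fixture(scope="session")
def exp1_traces():
    """Experiment 1 (category B, blocked) across three seeds."""
    return {seed: _experiment(1, seed) for seed in (1, 2, 3)}


@pytest.fixture(scope="session")
def exp3_trace():
    """Experiment 3 (feedback gain disabled)."""
    return _experiment(3, 1)


@pytest.fixture(scope="session")
def exp4_trace():
    """Experiment 4 (both categories, twelve cells, 1000 steps)."""
    return _experiment(4, 1)
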