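import numpy as np
import pytest

from aefpipe.geometry import DEFAULT_RADIUS, build_neighbourhoods, project_to_plane
from aefpipe.pipeline import PipelineConfig, preprocess_session
from aefpipe.preprocessing import segment_trials
from aefpipe.synthmeg import SynthScenario, make_sensor_array, simulate_session


@pytest.fixture(scope="session")
def default_array():
    return make_sensor_array(274)


@pytest.fixture(scope="session")
def default_graph(default_array):
    return build_neighbourhoods(default_array, DEFAULT_RADIUS)


@pytest.fixture(scope="session")
def default_coords(default_array):
    return project_to_plane(default_array)


@pytest.fixture(scope="session")
def small_scenario():
    """A 40 s session with 20 stimuli: fast but structurally complete."""
    return SynthScenario(n_stimuli=20, session_length=40.0, noise_session_length=20.0, seed=7)


@pytest.fixture(scope="session")
def small_session(small_scenario):
    return simulate_session(small_scenario)


@pytest.fixture(scope="session")
def small_clean_trials(small_session, small_scenario):
    """Preprocessed + intercepted trials of the small session."""
    cfg = PipelineConfig(scenario=small_scenario)
    cleaned, stim_events, _ = preprocess_session(small_session.recording, cfg)
    return segment_trials(cleaned, stim_events)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
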