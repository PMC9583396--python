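import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from imcoh import CohortConfig, SynthConfig, simulate_session
from imcoh.pipeline import PipelineConfig, analyze_session

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_session():
    """One simulated limb session: 6 extensions, planted 30 % co-contraction,
    unit coupling (theoretical in-band MSC 0.25)."""
    return simulate_session(SynthConfig(n_trials=6, seed=1))


@pytest.fixture(scope="session")
def pipeline_config():
    return PipelineConfig(simulate=CohortConfig())


@pytest.fixture(scope="session")
def analyzed_session(small_session, pipeline_config):
    rows, counts = analyze_session(
        small_session.recording, small_session.mvc_trials, pipeline_config
    )
    return rows, counts


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
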