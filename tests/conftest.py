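import numpy as np
import pytest

from vefkit.config import SimConfig
from vefkit.metrics import compute_metric_table
from vefkit.session_io import segment_trials
from vefkit.synthetic import generate_session


@pytest.fixture(scope="session")
def demo_session():
    """A small deterministic simulated session shared across tests."""
    cfg = SimConfig(n_trials=80, seed=11)
    session, truth = generate_session(cfg)
    return cfg, session, truth


@pytest.fixture(scope="session")
def demo_table(demo_session):
    _, session, _ = demo_session
    return compute_metric_table(session)


@pytest.fixture(scope="session")
def demo_slices(demo_session):
    _, session, _ = demo_session
    return segment_trials(session)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
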