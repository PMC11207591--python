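import numpy as np
import pytest

from semgrip.synth import SynthConfig, generate_feature_dataset, generate_session


@pytest.fixture(scope="session")
def default_session():
    """One default synthetic recording session, shared across tests."""
    return generate_session(SynthConfig(seed=1))


@pytest.fixture(scope="session")
def small_dataset():
    """A one-session labeled feature dataset (200 windows, 12 features)."""
    return generate_feature_dataset(1, SynthConfig(seed=3))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
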