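import numpy as np
import pytest

from gammashift import session as sess
from gammashift import spectral, synth


@pytest.fixture(scope="session")
def small_cfg():
    """A short synthetic session: 12 trials, 8-15 s latencies."""
    return synth.SynthConfig(n_trials=12, trial_duration=(8.0, 15.0), seed=7)


@pytest.fixture(scope="session")
def small_session(small_cfg):
    return synth.generate_lfp_session(small_cfg)


@pytest.fixture(scope="session")
def preprocessed(small_session):
    raw, events = small_session
    return sess.preprocess(raw), events


@pytest.fixture(scope="session")
def trial_table(preprocessed):
    clean, events = preprocessed
    return spectral.build_trial_table(clean, events)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
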