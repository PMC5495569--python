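import numpy as np
import pytest

from fearext import synthcohort as sc


@pytest.fixture(scope="session")
def tone_plan():
    return sc.make_session_plan("recording")


@pytest.fixture(scope="session")
def pip_plan():
    return sc.make_session_plan("recording", {"alignment": "pip"})


@pytest.fixture(scope="session")
def pip_events(pip_plan):
    return sc.make_events(pip_plan, seed=1)


@pytest.fixture(scope="session")
def pip_epoch_events(pip_plan, pip_events):
    return sc.epoch_event_times(pip_events, pip_plan)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
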