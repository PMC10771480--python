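import pytest

from excitep.gating import LuoRudyGating
from excitep.membrane import default_channel_params, resting_state


@pytest.fixture(scope="session")
def gating():
    return LuoRudyGating()


@pytest.fixture(scope="session")
def channels(gating):
    return default_channel_params(gating)


@pytest.fixture(scope="session")
def rest(channels, gating):
    return resting_state(channels, gating)
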