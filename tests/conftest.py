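import numpy as np
import pytest

from meliosim.games import NormalFormGame, build_fixture, list_fixtures


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(params=list_fixtures())
def catalogue_game(request) -> NormalFormGame:
    return build_fixture(request.param)


@pytest.fixture
def pd_game() -> NormalFormGame:
    return build_fixture("pd")


@pytest.fixture
def noiseless_pd() -> NormalFormGame:
    return build_fixture("pd").with_noise_sd(0.0)
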