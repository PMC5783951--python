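import numpy as np
import pytest

from plastevo.synth import gen_toy_model


@pytest.fixture(scope="session")
def linear_toy():
    return gen_toy_model("linear")


@pytest.fixture(scope="session")
def diamond_toy():
    return gen_toy_model("diamond")


@pytest.fixture(scope="session")
def two_source_toy():
    return gen_toy_model("two_source")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
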