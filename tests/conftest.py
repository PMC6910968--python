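import numpy as np
import pytest

from bioassess.synthetic_data import (
    generate_fixture_bundle,
    generate_known_answer_case,
    generate_toy_network,
)


@pytest.fixture(scope="session")
def bundle():
    return generate_fixture_bundle(seed=0, scale="smoke")


@pytest.fixture(scope="session")
def known_case():
    return generate_known_answer_case()


@pytest.fixture(scope="session")
def toy_network():
    return generate_toy_network("putrescine")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
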