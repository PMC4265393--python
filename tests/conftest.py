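import numpy as np
import pytest

from ampliplace.hp_align import AlignParams
from ampliplace.synthetic import ErrorModel, community_fixture, make_reference


@pytest.fixture(scope="session")
def hp_params():
    return AlignParams(hp_model=True)


@pytest.fixture(scope="session")
def plain_params():
    return AlignParams(hp_model=False)


@pytest.fixture(scope="session")
def small_reference():
    """30-leaf synthetic full-gene reference (tree + ungapped MSA)."""
    return make_reference(30, 400, seed=7)


@pytest.fixture(scope="session")
def community():
    """20-template 454-like community with homopolymer-slip-only noise."""
    return community_fixture(seed=42, error=ErrorModel(sub_rate=0.0, hp_slip_base=0.01))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_seq(rng, length, alphabet="ACGT"):
    return "".join(rng.choice(list(alphabet), size=length))
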