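import numpy as np
import pytest
from hypothesis import settings

from reefcarb.lookup import LookupTables
from reefcarb.synthetic import tabletop_fixture

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tables() -> LookupTables:
    return LookupTables.default()


@pytest.fixture()
def tabletop():
    return tabletop_fixture()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20230501)
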