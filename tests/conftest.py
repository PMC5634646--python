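import numpy as np
import pytest
from hypothesis import settings

from ssurna import simdata, taxclass
from ssurna.seqio import PipelineConfig

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def refdb():
    return simdata.build_toy_reference(seed=0)


@pytest.fixture(scope="session")
def ssu_index(refdb):
    return taxclass.build_index(refdb.ssu)


@pytest.fixture(scope="session")
def lsu_index(refdb):
    return taxclass.build_index(refdb.lsu_all)


@pytest.fixture()
def cfg():
    return PipelineConfig()


@pytest.fixture(scope="session")
def small_sim(refdb):
    """2000 mixed SSU/LSU pairs with truth, shared across tests."""
    spec = simdata.mock2_spec(2000, seed=7, lsu_fraction=0.3)
    pairs, truth, stats = simdata.simulate_library(
        spec, simdata.LibraryModel(), refdb
    )
    return pairs, {t.read_id: t for t in truth}, stats


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
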