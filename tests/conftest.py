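import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from antpack import (
    ColonyConfig,
    build_interaction_tables,
    builtin_score_functions,
    load_library,
    make_backbone,
    rotamer_sets_for,
    strip_side_chains,
    toy_library_path,
)
from antpack.fixtures import make_library_instance

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def toy_library():
    return load_library(toy_library_path())


@pytest.fixture(scope="session")
def helix6():
    return make_backbone(6, "helix")


@pytest.fixture(scope="session")
def library_instance():
    """Small physically scored instance (toy library, preset 0)."""
    return make_library_instance(5)


@pytest.fixture(scope="session")
def packing_setup(helix6, toy_library):
    """Stripped backbone, rotamer sets and tables for the 6-residue helix."""
    backbone = strip_side_chains(helix6)
    sets = rotamer_sets_for(backbone, toy_library)
    sf = builtin_score_functions(1)[0]
    tables = build_interaction_tables(backbone, sets, sf)
    return backbone, sets, sf, tables


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def fast_config():
    return ColonyConfig(n_ants=8, max_iters=40, stagnation_iters=10, seed=0)
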