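import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from metapersona import (SimConfig, apply_media, default_media, make_toy1,
                         make_toy1_and, make_toy1_parallel, make_toy_model)


@pytest.fixture
def toy1():
    return make_toy1()


@pytest.fixture
def toy1_parallel():
    return make_toy1_parallel()


@pytest.fixture
def toy1_and():
    return make_toy1_and()


@pytest.fixture(scope="session")
def small_sim_config():
    """Reduced cohort for fast unit tests (full defaults are exercised in
    the acceptance suite)."""
    return SimConfig(seed=11, n_normal=12, n_tumor_per_cluster=6,
                     n_background_genes=200)


@pytest.fixture(scope="session")
def sim_model_with_media(small_sim_config):
    model = make_toy_model(small_sim_config)
    return apply_media(model, default_media(model))
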