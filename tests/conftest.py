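import numpy as np
import pytest

from mirbic.data_io import FoldChangeMatrix
from mirbic.simulate import SimulationConfig, generate_profile


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def small_fc():
    """3 genes x 2 conditions with signal at gene granularity."""
    return FoldChangeMatrix(
        values=np.array([[0.5, -0.5], [0.0, 0.0], [1.0, -1.0]]),
        gene_ids=("g1", "g2", "g3"),
        condition_ids=("c1", "c2"),
    )


@pytest.fixture(scope="session")
def tiny_sim_config():
    """Down-scaled planted-bicluster setting for fast pipeline tests."""
    return SimulationConfig(
        n_rows=150,
        n_cols=90,
        background_density=0.20,
        n_biclusters=2,
        size_min=20,
        size_max=35,
        n_replicates=3,
        rng_seed=7,
    )


@pytest.fixture(scope="session")
def tiny_profile(tiny_sim_config):
    return generate_profile(tiny_sim_config, replicate_seed=7)
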