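import numpy as np
import pytest

from junctionqtl.io_core import GeneModel, add_alternative_donor
from junctionqtl.synthetic_data import SimulationConfig, toy_gene_model


@pytest.fixture(scope="session")
def toy_model() -> GeneModel:
    return toy_gene_model()


@pytest.fixture()
def two_exon_model() -> GeneModel:
    # exons (100,199) and (300,399) 1-based -> single intron (200,299)
    return GeneModel.from_1based("g1", "chr1", "+", [(100, 199), (300, 399)])


@pytest.fixture()
def small_config() -> SimulationConfig:
    return SimulationConfig(n_animals=40, n_markers=30, read_depth=800, seed=7)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20_240_901)
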