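import numpy as np
import pytest

from phagepan import genome_io, homology, mcl
from phagepan.synthetic import SyntheticConfig, generate_pangenome


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """A fast desk-scale collection: 6 genomes, 5 core + 8 accessory families."""
    return SyntheticConfig(
        n_genomes=6, n_clusters=2, n_core=5, n_accessory=8,
        protein_len=(60, 120), divergence=0.1, seed=7, plant_frameshift=True,
    )


@pytest.fixture(scope="session")
def small_collection(small_config):
    return generate_pangenome(small_config)


@pytest.fixture(scope="session")
def small_families(small_collection):
    """MCL families recovered from the small collection, plus the proteome."""
    genomes, _ = small_collection
    proteome = genome_io.extract_proteome(genomes)
    graph = homology.all_vs_all_graph(proteome)
    partition = mcl.run_mcl(graph)
    return mcl.extract_families(partition, proteome), proteome


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
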