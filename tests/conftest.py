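import numpy as np
import pandas as pd
import pytest

from metasense.core_io import GeneRecord, GenomeMeta
from metasense.simulate import SimConfig, simulate_community


@pytest.fixture(scope="session")
def small_community():
    """A small but fully structured synthetic community shared across tests."""
    config = SimConfig(n_genomes=4, genes_per_genome=40, n_hyper_asrna_genes=2)
    return simulate_community(config, n_samples=4, seed=42)


@pytest.fixture
def toy_records():
    return [
        GeneRecord("g1", "G1", "c1", 0, 100, "+"),
        GeneRecord("g2", "G1", "c1", 150, 350, "-"),
        GeneRecord("g3", "G2", "c2", 0, 300, "+"),
    ]


@pytest.fixture
def toy_counts():
    return pd.DataFrame(
        {
            "gene_id": ["g1", "g2", "g3", "g1", "g2", "g3"],
            "sample_id": ["s1", "s1", "s1", "s2", "s2", "s2"],
            "sense": [10, 0, 50, 20, 5, 40],
            "antisense": [2, 30, 0, 1, 25, 10],
        }
    )
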