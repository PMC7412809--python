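import numpy as np
import pytest

from scregpot.synthetic_fixtures import (
    SimulationConfig,
    simulate_cells,
    simulate_genome,
)


@pytest.fixture(scope="session")
def default_sim():
    """One default-condition synthetic dataset shared across tests."""
    config = SimulationConfig(seed=1)
    genome = simulate_genome(config)
    rna, atac, rna_types, atac_types, signatures = simulate_cells(config, genome)
    return {
        "config": config,
        "genome": genome,
        "rna": rna,
        "atac": atac,
        "rna_types": rna_types,
        "atac_types": atac_types,
        "signatures": signatures,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(2020)
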