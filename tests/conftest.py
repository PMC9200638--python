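import numpy as np
import pytest

from pansvherit.synthpop import SimConfig, simulate_population


SMALL_CFG = SimConfig(seed=11, n_chrom=3,
                      variants_per_chrom={"SNP": 300, "INDEL": 30, "SV": 20},
                      n_genes_per_chrom=15, n_allelic_het_genes=3)


@pytest.fixture(scope="session")
def small_pop():
    """A small simulated inbred panel shared across tests (read-only)."""
    cat, g, genes, het = simulate_population(SMALL_CFG)
    return cat, g, genes, het


@pytest.fixture(scope="session")
def default_pop():
    """The default study-condition panel (332 accessions, 6 chromosomes)."""
    cat, g, genes, het = simulate_population(SimConfig(seed=7))
    return cat, g, genes, het


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
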