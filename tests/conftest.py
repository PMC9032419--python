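import numpy as np
import pytest

import allodosage as ad


@pytest.fixture(scope="session")
def small_config():
    """A small but non-trivial hybrid: 4+4 chromosomes, 1 hybrid pair."""
    return ad.SimConfig(
        n_chromosomes_per_subgenome=4,
        genes_per_chromosome=12,
        chrom_length=100_000,
        n_hybrid_chromosomes=1,
        depth_per_copy=80.0,
        seed=101,
    )


@pytest.fixture(scope="session")
def small_strain(small_config):
    return ad.simulate.simulate_strain(small_config)


@pytest.fixture(scope="session")
def called_strain(small_strain):
    """Karyotype called from coverage and genes annotated with CN."""
    k = ad.karyotype.call_karyotype(small_strain.coverage)
    genes = ad.karyotype.assign_gene_cn(small_strain.genes, k)
    return k, genes


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
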