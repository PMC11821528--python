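import numpy as np
import pandas as pd
import pytest

from scmr.genotype_io import GenotypeMatrix
from scmr.synthetic import (default_config, simulate_cells, simulate_cohort,
                            simulate_genotypes)


@pytest.fixture(scope="session")
def small_config():
    return default_config(seed=7, n_donors=150, n_genes=10,
                          cell_types=("astrocytes", "microglia"),
                          cells_per_donor=60.0)


@pytest.fixture(scope="session")
def small_genotypes(small_config):
    return simulate_genotypes(small_config)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def small_cells(small_config, small_genotypes, small_cohort):
    return simulate_cells(small_genotypes, small_cohort, small_config)


@pytest.fixture()
def toy_genotypes():
    """Hand-built 6-donor x 4-SNP matrix with a known SNP map."""
    donors = pd.Index([f"d{i}" for i in range(6)])
    snps = pd.Index(["s1", "s2", "s3", "s4"])
    dosage = np.array([
        [0, 0, 1, 2],
        [1, 1, 0, 2],
        [2, 2, 1, 2],
        [0, 0, 2, 2],
        [1, 1, 0, 2],
        [2, 2, 1, 2],
    ], dtype=float)
    snp_map = pd.DataFrame({
        "chrom": [1, 1, 1, 2],
        "pos": [100, 200, 100_000, 500],
        "a1": ["A", "C", "G", "T"],
        "a2": ["G", "T", "A", "C"],
        "maf": [0.5, 0.5, 0.4, 0.0],
        "info": [1.0, 1.0, 1.0, 1.0],
    }, index=snps)
    return GenotypeMatrix(donors, snps, dosage, snp_map)
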