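import numpy as np
import pandas as pd
import pytest

from genevec.cohort import CohortConfig, generate_cohort
from genevec.vectors import GenotypeTable, GeneDefinition, build_gene_vector_matrix


@pytest.fixture(scope="session")
def small_cohort():
    """A small but fully structured synthetic cohort shared across tests."""
    cfg = CohortConfig(
        n_f2=40, n_f3=110, n_genes=12, seed=42,
        response_genes=[(f"g{i:03d}", 0.30, 0.05) for i in range(3)],
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_matrix(small_cohort):
    return small_cohort.gene_vectors()


@pytest.fixture()
def toy_table():
    """Three subjects x two genes (3 + 2 SNPs) with one missing genotype."""
    snps = pd.DataFrame(
        {
            "snp_id": ["a1", "a2", "a3", "b1", "b2"],
            "gene": ["gA", "gA", "gA", "gB", "gB"],
            "chrom": ["1", "1", "1", "2", "2"],
            "pos": [100, 200, 300, 50, 60],
        }
    )
    geno = np.array(
        [
            [1, 2, 0, 0, 0],
            [1, 2, 0, 2, 1],
            [0, -1, 0, 1, 1],
        ],
        dtype=np.int8,
    )
    return GenotypeTable(["s1", "s2", "s3"], snps, geno)


@pytest.fixture()
def toy_genes():
    return [
        GeneDefinition("gA", "1", 1, 1000, ["a1", "a2", "a3"]),
        GeneDefinition("gB", "2", 1, 1000, ["b1", "b2"]),
    ]
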