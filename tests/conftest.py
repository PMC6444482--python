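import numpy as np
import pytest

from sirekit.data import align_phenotypes
from sirekit.qc import dedupe_records
from sirekit.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """Shared desk-scale dataset: 400 bulls x 800 SNPs, 5 dominance QTLs."""
    cfg = SimulationConfig(n_individuals=400, n_snps=800, seed=42)
    genotypes, gene_models, pheno, truth = simulate_dataset(cfg)
    return cfg, genotypes, gene_models, pheno, truth


@pytest.fixture(scope="session")
def small_aligned(small_dataset):
    _, genotypes, _, pheno, _ = small_dataset
    y, X, names = align_phenotypes(genotypes, dedupe_records(pheno))
    return y, X, names


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
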