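import numpy as np
import pytest

import permlmm as pl


@pytest.fixture(scope="session")
def panel():
    """Small synthetic genotype panel shared across tests."""
    return pl.simulate_genotypes(n=60, m=120, seed=11)


@pytest.fixture(scope="session")
def panel_kinship(panel):
    return pl.stabilize(pl.realized_relationship(panel))


def make_dataset(genotype, kinship, y, covariates=None):
    pheno = pl.PhenotypeVector(genotype.sample_ids, y)
    return pl.AlignedDataset(genotype, pheno, kinship.values, covariates)


def draw_null_phenotype(rng, K, sigma_g2=0.7, sigma_e2=0.3):
    """y ~ N(0, sigma_g2 K + sigma_e2 I): the mixed model with no marker effect."""
    n = len(K)
    V = sigma_g2 * K + sigma_e2 * np.eye(n)
    C = np.linalg.cholesky(V + 1e-10 * np.eye(n))
    return C @ rng.standard_normal(n)
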