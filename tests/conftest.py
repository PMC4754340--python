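import numpy as np
import pytest

from tagfun import sim_haplotype_panel
from tagfun.qc_assoc import GenotypeMatrix, PhenotypeTable, VariantInfo


@pytest.fixture(scope="session")
def ld06_panel():
    """Large two-locus panel at r2 ~ 0.6, shared across tests."""
    return sim_haplotype_panel(0.3, 0.3, 0.6, 20000, seed=1)


@pytest.fixture(scope="session")
def perfect_ld_panel():
    return sim_haplotype_panel(0.5, 0.5, 1.0, 1000, seed=2)


@pytest.fixture()
def toy_geno_pheno():
    """Deterministic 200-sample, 5-SNP genotype matrix with balanced phenotypes."""
    rng = np.random.default_rng(42)
    n = 200
    freqs = [0.3, 0.4, 0.2, 0.25, 0.35]
    dos = np.column_stack([rng.binomial(2, f, size=n) for f in freqs]).astype(float)
    variants = [VariantInfo(f"snp{i}", "9", 1000 + i) for i in range(5)]
    samples = [f"s{i}" for i in range(n)]
    status = np.zeros(n)
    status[: n // 2] = 1
    return GenotypeMatrix(dos, variants, samples), PhenotypeTable(status, None, samples)
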