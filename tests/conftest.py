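import numpy as np
import pytest

from polygxe.genotype_io import GenotypeMatrix


def make_genotypes(dosages, chrom=None, pos=None, snp_ids=None):
    """GenotypeMatrix from a raw dosage array with default metadata."""
    dosages = np.asarray(dosages, dtype=float)
    L = dosages.shape[1]
    return GenotypeMatrix(
        dosages=dosages,
        snp_ids=np.array(snp_ids if snp_ids is not None else [f"snp{j+1}" for j in range(L)]),
        chrom=np.array(chrom if chrom is not None else [1] * L),
        pos=np.array(pos if pos is not None else np.arange(1, L + 1) * 100),
        alleles=np.tile(np.array([["A", "G"]]), (L, 1)),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def hwe_genotypes(rng):
    """500 x 20 independent Hardy-Weinberg genotypes, MAF 0.1-0.5."""
    maf = rng.uniform(0.1, 0.5, size=20)
    return make_genotypes(rng.binomial(2, maf, size=(500, 20)))
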