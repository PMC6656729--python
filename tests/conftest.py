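import numpy as np
import pandas as pd
import pytest

from slowfast.io_core import GenotypeMatrix


def make_genotypes(dosage, positions=None, chrom="chr1", intergenic=None):
    """Build a GenotypeMatrix from a plain dosage array (helper, not a fixture)."""
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    if positions is None:
        positions = np.arange(1, m + 1) * 1000
    if intergenic is None:
        intergenic = [True] * m
    snps = pd.DataFrame(
        {
            "chrom": [chrom] * m if isinstance(chrom, str) else chrom,
            "pos": positions,
            "id": [f"snp{j}" for j in range(m)],
            "intergenic": intergenic,
        }
    )
    return GenotypeMatrix(
        samples=[f"s{i}" for i in range(n)], snps=snps, dosage=dosage
    )


def labels_from_sizes(sizes, prefix="group_"):
    """Population assignment Series for consecutive blocks of samples."""
    names = np.repeat([f"{prefix}{i + 1}" for i in range(len(sizes))], sizes)
    return pd.Series(names, index=[f"s{i}" for i in range(int(np.sum(sizes)))])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def counts_to_genotypes(alt_counts, sizes):
    """One-SNP genotype matrix realizing exact per-population allele counts."""
    cols = []
    for c, n in zip(alt_counts, sizes):
        cols.append(np.r_[np.ones(c), np.zeros(n - c)])
    return make_genotypes(np.concatenate(cols)[:, None])
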