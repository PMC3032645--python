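import numpy as np
import pytest

from crequtl.data_io import ExpressionMatrix, GenotypeMatrix, SnpLocus
from crequtl.preprocess import rank_normalize
from crequtl.simulate import ModuleSpec, SimulationSpec, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def small_expression(rng):
    """30 genes x 20 samples of pure noise."""
    values = rng.normal(size=(30, 20))
    return ExpressionMatrix(
        [f"G{i:02d}" for i in range(30)],
        [f"S{j:02d}" for j in range(20)],
        values,
    )


@pytest.fixture
def planted_dataset():
    """52 samples, one 6-gene module whose tightness is driven by SNP 0."""
    spec = SimulationSpec(
        n_samples=52,
        n_genes=120,
        n_snps=40,
        maf_range=(0.3, 0.3),
        modules=[ModuleSpec(size=6, driver_snp=0,
                            tightness_by_genotype=(0.5, 1.5, 3.0))],
        rng_seed=7,
    )
    return simulate_dataset(spec)


@pytest.fixture
def planted_norm(planted_dataset):
    X, G, annotations, truth = planted_dataset
    return rank_normalize(X), G, annotations, truth


def make_genotypes(codes, sample_prefix="S", chrom="chr1", spacing=1000):
    """Small GenotypeMatrix from a code array (SNPs x samples)."""
    codes = np.asarray(codes, dtype=np.int8)
    n_snps, n_samples = codes.shape
    return GenotypeMatrix(
        snp_ids=[f"rs{i + 1}" for i in range(n_snps)],
        sample_ids=[f"{sample_prefix}{j + 1}" for j in range(n_samples)],
        codes=codes,
        loci=[SnpLocus(chrom, spacing * (i + 1)) for i in range(n_snps)],
    )
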