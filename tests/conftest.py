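import numpy as np
import pytest

from haplogen import HaplotypeMatrix, PopStructureConfig, structured_mosaic_dataset


@pytest.fixture
def toy_matrix() -> HaplotypeMatrix:
    """2x3 matrix with known frequencies [0.5, 1.0, 0.5]."""
    return HaplotypeMatrix(
        values=np.array([[0, 1, 1], [1, 1, 0]]),
        labels=("POP1", "POP1"),
    )


@pytest.fixture(scope="session")
def structured_data() -> HaplotypeMatrix:
    """Two populations, 500 haplotypes, 100 SNPs, with mosaic LD."""
    return structured_mosaic_dataset(
        PopStructureConfig(
            n_pops=2, haplotypes_per_pop=250, n_snps=100,
            differentiation=0.2, seed=42,
        )
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
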