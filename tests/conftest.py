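import numpy as np
import pytest

from episcan import (
    GenotypeMatrix,
    sample_architecture,
    sample_genotypes,
    simulate_phenotype,
)


@pytest.fixture(scope="session")
def small_inbred():
    """500 x 40 inbred genotypes used across solver/pipeline tests."""
    return sample_genotypes(500, 40, seed=11)


@pytest.fixture(scope="session")
def small_outbred():
    return sample_genotypes(400, 30, mode="outbred", seed=12)


@pytest.fixture()
def planted_instance():
    """Easy planted instance: 1 simple + 2 pairs at h2 = 0.6, n = 800."""
    X = sample_genotypes(800, 30, seed=21)
    arch = sample_architecture(30, 1, 2, target_h2=0.6, seed=22)
    Y = simulate_phenotype(X, arch, seed=23)
    return X, Y, arch


def tiny_genotypes(values, ploidy=1):
    """GenotypeMatrix from a literal matrix, with auto metadata."""
    values = np.asarray(values, dtype=np.int8)
    n, p = values.shape
    from episcan.simdata import Marker

    return GenotypeMatrix(
        values,
        [Marker("1", i + 1, f"s{i}") for i in range(p)],
        [f"i{i}" for i in range(n)],
        ploidy=ploidy,
    )


@pytest.fixture(scope="session")
def tiny():
    return tiny_genotypes
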