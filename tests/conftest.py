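import numpy as np
import pytest

from fusim.demography import (
    DatasetComposition,
    canonical_compositions,
    canonical_fusion_scenarios,
    canonical_nonfusion_models,
)
from fusim.hky import MutationModel


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def scenarios():
    return canonical_fusion_scenarios()


@pytest.fixture(scope="session")
def nonfusion_models():
    return canonical_nonfusion_models()


@pytest.fixture(scope="session")
def compositions():
    return canonical_compositions()


@pytest.fixture(scope="session")
def mm():
    return MutationModel()


@pytest.fixture(scope="session")
def tiny_comp():
    """A small composition for fast end-to-end runs."""
    return DatasetComposition(n_alleles=10, locus_length=500, n_loci=10)


def random_toy_alignment(rng, n_max=10, L_max=40):
    """A random small nucleotide alignment, occasionally with repeated rows."""
    n = int(rng.integers(4, n_max + 1))
    L = int(rng.integers(5, L_max + 1))
    mat = rng.integers(0, 4, size=(n, L))
    if rng.random() < 0.4:
        mat[int(rng.integers(n))] = mat[int(rng.integers(n))]
    return ["".join("ACGT"[b] for b in row) for row in mat]
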