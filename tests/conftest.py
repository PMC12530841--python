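import numpy as np
import pandas as pd
import pytest

import germdiv as gd
from germdiv.ssr import GenotypeMatrix


@pytest.fixture
def t22_table():
    """Binary bulbil-presence trait: 110 accessions coded 1, 3 coded 0."""
    codes = pd.DataFrame({"T22": [1.0] * 110 + [0.0] * 3},
                         index=[f"CY{i + 1:03d}" for i in range(113)])
    desc = {"T22": gd.TraitDescriptor("T22", "Bulbil", "qualitative", (0, 1))}
    return gd.TraitTable(codes=codes, descriptors=desc)


@pytest.fixture
def small_genotypes():
    """Five diploid accessions at two loci with a clone pair (a, b)."""
    a1 = np.array([[100, 200], [100, 200], [100, 202], [102, 204], [104, 206]])
    a2 = np.array([[100, 202], [100, 202], [102, 202], [102, 206], [106, 208]])
    return GenotypeMatrix([f"acc{i}" for i in range(5)], ["L1", "L2"],
                          np.minimum(a1, a2), np.maximum(a1, a2))


@pytest.fixture(scope="session")
def fixture_bundle():
    """Study-scale synthetic dataset with planted truth (session-cached)."""
    return gd.paper_scale_fixture(seed=1)


def random_frequency_vectors(n_vectors: int, seed: int):
    """Random allele-frequency vectors of mixed lengths (2..15 alleles)."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_vectors):
        k = int(rng.integers(2, 16))
        out.append(rng.dirichlet(np.ones(k)))
    return out
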