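import numpy as np
import pandas as pd
import pytest

from coevoprof import ProfileMatrix
from coevoprof.tree import SpeciesTree


@pytest.fixture
def quartet_tree():
    return SpeciesTree.from_newick("((A,B)n1,(C,D)n2)root;")


@pytest.fixture
def small_profiles():
    data = pd.DataFrame(
        [[1, 1, 0, 0], [1, 1, 0, 0], [1, 0, 1, 0], [0, 0, 1, 1], [1, 1, 1, 1]],
        index=["g1", "g2", "g3", "g4", "g5"],
        columns=["A", "B", "C", "D"],
    )
    return ProfileMatrix(data)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_binary_pairs(n_pairs=200, length=20, seed=99):
    """Seeded random binary profile pairs for oracle comparisons."""
    gen = np.random.default_rng(seed)
    return [
        (gen.integers(0, 2, size=length), gen.integers(0, 2, size=length))
        for _ in range(n_pairs)
    ]


def all_binary_vectors(length):
    """All binary vectors of a given length, lexicographic order."""
    return [
        np.array([(i >> k) & 1 for k in range(length - 1, -1, -1)], dtype=np.int8)
        for i in range(2 ** length)
    ]
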