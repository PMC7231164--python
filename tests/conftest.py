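import numpy as np
import pytest

import sgskit as sk


@pytest.fixture(scope="session")
def small_cohort():
    """A modest antagonistic cohort shared by read-mostly tests."""
    return sk.generate_cohort(n_loci=300, n_selected=10, seed=42)


@pytest.fixture(scope="session")
def tiny_matrix():
    """A hand-built 6-individual, 4-locus matrix with two groups."""
    calls = np.array([
        [2, 1, 0, 2],
        [1, 1, 1, 2],
        [0, 1, 2, 2],
        [2, 2, 0, 1],
        [1, 0, 1, -1],
        [0, 2, 2, 2],
    ], dtype=np.int8)
    return sk.GenotypeMatrix(
        calls=calls,
        individuals=np.array([f"i{k}" for k in range(6)], dtype=object),
        loci=np.array(["L1", "L2", "L3", "L4"], dtype=object),
        groups=np.array(["g1", "g1", "g1", "g2", "g2", "g2"], dtype=object),
    )
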