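import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def haplotype_matrix_pi(H: np.ndarray) -> float:
    """Brute-force mean pairwise Hamming distance over all haplotype pairs
    (independent oracle for the SFS-based pi formula)."""
    n = H.shape[0]
    total = 0.0
    pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += np.sum(H[i] != H[j])
            pairs += 1
    return total / pairs
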