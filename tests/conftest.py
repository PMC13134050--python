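import numpy as np
import pytest

from haplodrift.alignment import alignment_from_strings


@pytest.fixture
def toy_alignment():
    """Four 12-column sequences with hand-placed variants."""
    return alignment_from_strings(
        [
            "ACGTACGTACGT",
            "ACGTACGTACGT",
            "ACGAACGTACGT",
            "ACGAACGTTCGT",
        ]
    )


def random_alignment(rng: np.random.Generator, n=None, L=None):
    """Uniform-random ACGT alignment for oracle-equivalence tests."""
    n = n if n is not None else int(rng.integers(4, 9))
    L = L if L is not None else int(rng.integers(10, 51))
    bases = np.array([b"A", b"C", b"G", b"T"], dtype="S1")
    matrix = bases[rng.integers(0, 4, size=(n, L))]
    return alignment_from_strings(
        [b"".join(row).decode() for row in matrix]
    )
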