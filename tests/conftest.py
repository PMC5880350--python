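import numpy as np
import pytest

from bibit.preprocess import BinaryMatrix

# 5x4 worked example: rows A..E, every qualifying pair pattern known by hand
TOY_BITS = np.array(
    [
        [1, 1, 0, 1],  # A
        [1, 1, 1, 0],  # B
        [0, 1, 1, 1],  # C
        [1, 1, 1, 1],  # D
        [1, 0, 0, 0],  # E
    ],
    dtype=np.uint8,
)

TOY_ROW_NAMES = ["A", "B", "C", "D", "E"]
TOY_COL_NAMES = ["s0", "s1", "s2", "s3"]

# (rows, columns) of all six biclusters at mnr=2, mnc=2
TOY_EXPECTED_MNR2 = {
    ((0, 1, 3), (0, 1)),
    ((0, 2, 3), (1, 3)),
    ((0, 3), (0, 1, 3)),
    ((1, 2, 3), (1, 2)),
    ((1, 3), (0, 1, 2)),
    ((2, 3), (1, 2, 3)),
}
TOY_EXPECTED_MNR3 = {
    ((0, 1, 3), (0, 1)),
    ((0, 2, 3), (1, 3)),
    ((1, 2, 3), (1, 2)),
}


@pytest.fixture
def toy_matrix() -> BinaryMatrix:
    return BinaryMatrix(TOY_BITS.copy(), list(TOY_ROW_NAMES), list(TOY_COL_NAMES))


def as_sets(biclusters):
    """Comparable representation: list of (row tuple, column tuple)."""
    return [b.row_col_sets() for b in biclusters]


def random_binary(rng, m, n, p):
    return BinaryMatrix((rng.random((m, n)) < p).astype(np.uint8))
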