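"""Seeded synthetic binary matrices with optional implanted biclusters.

The generator reproduces the kind of benchmark input the algorithm is
evaluated on: matrices of independent Bernoulli(p) cells (rows are
attributes, columns are samples) at the benchmark dimensions — thousands
to tens of thousands of attributes, 100–200 samples, one-probabilities
around 0.10–0.15 — optionally with all-ones submatrices forced in for
recovery tests.  Randomness comes from numpy's default PCG64 generator,
so a given seed yields a bit-identical matrix on every platform.

``exact_density=True`` switches from i.i.d. cells to placing an exact
global count of ``round(p * m * n)`` ones uniformly at random, for
sensitivity checks of the density definition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .core import Bicluster, Pattern
from .errors import ValidationError
from .preprocess import BinaryMatrix

__all__ = [
    "GenSpec",
    "random_binary_matrix",
    "implant_recovery_case",
    "write_fixture_arff",
]


@dataclass(frozen=True)
class GenSpec:
    """Recipe for one synthetic matrix: dimensions, density, seed, implants."""

    m: int
    n: int
    p: float
    seed: int
    implants: tuple[tuple[tuple[int, ...], tuple[int, ...]], ...] = field(
        default_factory=tuple
    )
    exact_density: bool = False

    def __post_init__(self) -> None:
        if self.m < 2 or self.n < 1:
            raise ValidationError(f"need m >= 2 and n >= 1, got {self.m}x{self.n}")
        if not 0.0 <= self.p <= 1.0:
            raise ValidationError(f"one-probability must be in [0, 1], got {self.p}")
        for rows, cols in self.implants:
            if any(not 0 <= i < self.m for i in rows) or any(
                not 0 <= j < self.n for j in cols
            ):
                raise ValidationError("implant indices out of matrix bounds")


def random_binary_matrix(spec: GenSpec) -> BinaryMatrix:
    """Bernoulli(p) background with implanted all-ones submatrices."""
    rng = np.random.default_rng(spec.seed)
    if spec.exact_density:
        k = round(spec.p * spec.m * spec.n)
        flat = np.zeros(spec.m * spec.n, dtype=np.uint8)
        flat[rng.choice(spec.m * spec.n, size=k, replace=False)] = 1
        bits = flat.reshape(spec.m, spec.n)
    else:
        bits = (rng.random((spec.m, spec.n)) < spec.p).astype(np.uint8)
    for rows, cols in spec.implants:
        bits[np.ix_(list(rows), list(cols))] = 1
    return BinaryMatrix(bits)


def implant_recovery_case(
    rows: int, cols: int, m: int, n: int
) -> tuple[BinaryMatrix, Bicluster]:
    """Zero background with one all-ones block; returns matrix and truth.

    The implant occupies the first ``rows`` x ``cols`` block, so the only
    nonempty pair pattern is the implant's column set and the expected
    recovery is exactly that bicluster.
    """
    if not (2 <= rows <= m) or not (1 <= cols <= n):
        raise ValidationError(
            f"need 2 <= rows <= m and 1 <= cols <= n, got ({rows},{cols}) in {m}x{n}"
        )
    spec = GenSpec(
        m=m,
        n=n,
        p=0.0,
        seed=0,
        implants=((tuple(range(rows)), tuple(range(cols))),),
    )
    matrix = random_binary_matrix(spec)
    expected = Bicluster(
        pattern=Pattern.from_columns(range(cols), n), rows=tuple(range(rows))
    )
    return matrix, expected


def write_fixture_arff(matrix: BinaryMatrix, path: str | Path) -> None:
    """Serialize a BinaryMatrix as dense ARFF (one attribute per sample).

    Round-trips exactly through :func:`bibit.io_formats.read_arff` up to
    the synthesized row names.
    """
    path = Path(path)
    lines = ["@relation bibit_fixture", ""]
    lines += [f"@attribute {name} numeric" for name in matrix.col_names]
    lines += ["", "@data"]
    lines += [",".join(str(int(v)) for v in row) for row in matrix.bits]
    path.write_text("\n".join(lines) + "\n")
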