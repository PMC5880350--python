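"""Binarization, multi-level discretization and word-packed encoding.

Real-valued expression matrices are turned into binary ones either with a
single strict threshold (``binarize``) or with the multi-level scheme used
for expression data: standardize each gene (row) to mean 0 / variance 1,
discretize the whole matrix into ``L`` equal-width levels (default 12),
and emit the ``L - 1`` nested binary matrices obtained by cutting at each
level.

Binary rows are packed into arrays of unsigned machine words
(``encode``), least-significant bit first, so that the pattern operations
of the biclustering core become word-wise AND plus popcount.  Results are
identical for 32- and 64-bit words; the width is a performance knob only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .io_formats import RawMatrix

__all__ = [
    "BinaryMatrix",
    "EncodedMatrix",
    "LevelMatrix",
    "binarize",
    "standardize",
    "discretize_levels",
    "level_threshold_matrices",
    "encode",
    "decode",
    "popcount",
]

_WORD_DTYPES = {32: np.uint32, 64: np.uint64}


@dataclass
class BinaryMatrix:
    """An m x n 0/1 matrix with row (attribute) and column (sample) names."""

    bits: np.ndarray
    row_names: list[str] = field(default_factory=list)
    col_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits)
        if self.bits.ndim != 2:
            raise ValidationError("binary matrix must be two-dimensional")
        if not np.isin(self.bits, (0, 1)).all():
            raise ValidationError("binary matrix entries must be exactly 0 or 1")
        self.bits = self.bits.astype(np.uint8)
        m, n = self.bits.shape
        if not self.row_names:
            self.row_names = [f"row{i}" for i in range(m)]
        if not self.col_names:
            self.col_names = [f"col{j}" for j in range(n)]
        if len(self.row_names) != m or len(self.col_names) != n:
            raise ValidationError("name lists do not match matrix dimensions")

    @property
    def shape(self) -> tuple[int, int]:
        return self.bits.shape

    def density(self) -> float:
        return float(self.bits.mean())


@dataclass
class LevelMatrix:
    """Integer discretization of a real matrix into levels ``0 .. L-1``."""

    levels: np.ndarray
    L: int
    row_names: list[str] = field(default_factory=list)
    col_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=np.int64)
        if self.levels.min() < 0 or self.levels.max() > self.L - 1:
            raise ValidationError(f"levels must lie in 0..{self.L - 1}")


@dataclass
class EncodedMatrix:
    """Rows packed into unsigned ``width``-bit words, LSB-first.

    Column ``j`` lives at bit ``j mod width`` of word ``j // width``;
    padding bits beyond column ``n - 1`` are zero.
    """

    words: np.ndarray
    n: int
    width: int

    def __post_init__(self) -> None:
        if self.width not in _WORD_DTYPES:
            raise ValidationError(f"word width must be 32 or 64, got {self.width}")
        self.words = np.ascontiguousarray(self.words, dtype=_WORD_DTYPES[self.width])
        if self.words.shape[1] != self.nwords:
            raise ValidationError(
                f"expected {self.nwords} words per row for n={self.n}, "
                f"got {self.words.shape[1]}"
            )

    @property
    def m(self) -> int:
        return self.words.shape[0]

    @property
    def nwords(self) -> int:
        return -(-self.n // self.width)


def binarize(raw: RawMatrix, threshold: float) -> BinaryMatrix:
    """Set to one every value strictly greater than ``threshold``."""
    bits = (raw.values > threshold).astype(np.uint8)
    return BinaryMatrix(bits, list(raw.row_names), list(raw.col_names))


def standardize(raw: RawMatrix) -> RawMatrix:
    """Scale each row to mean 0 and variance 1 (population denominator)."""
    mean = raw.values.mean(axis=1, keepdims=True)
    sd = raw.values.std(axis=1, keepdims=True)  # ddof=0
    flat = np.flatnonzero(sd.ravel() == 0)
    if flat.size:
        names = [raw.row_names[i] for i in flat]
        raise ValidationError(f"constant rows cannot be standardized: {names}")
    return RawMatrix((raw.values - mean) / sd, list(raw.row_names), list(raw.col_names))


def discretize_levels(raw: RawMatrix, L: int = 12) -> LevelMatrix:
    """Equal-width binning of the global value range into ``L`` levels."""
    if L < 2:
        raise ValidationError(f"need at least 2 levels, got {L}")
    lo, hi = raw.values.min(), raw.values.max()
    if lo == hi:
        raise ValidationError("matrix is constant; level range is degenerate")
    levels = np.floor(L * (raw.values - lo) / (hi - lo)).astype(np.int64)
    np.clip(levels, 0, L - 1, out=levels)
    return LevelMatrix(levels, L, list(raw.row_names), list(raw.col_names))


def level_threshold_matrices(levels: LevelMatrix) -> list[BinaryMatrix]:
    """One binary matrix per level cut: bit set iff level >= cut, cut in 1..L-1.

    The matrices are nested: each cut's ones are a subset of the previous
    cut's ones.  With the default 12 levels this yields 11 matrices.
    """
    return [
        BinaryMatrix(
            (levels.levels >= cut).astype(np.uint8),
            list(levels.row_names),
            list(levels.col_names),
        )
        for cut in range(1, levels.L)
    ]


def encode(bin_matrix: BinaryMatrix, width: int = 64) -> EncodedMatrix:
    """Pack each row's n bits into ``ceil(n / width)`` unsigned words."""
    if width not in _WORD_DTYPES:
        raise ValidationError(f"word width must be 32 or 64, got {width}")
    m, n = bin_matrix.shape
    nwords = -(-n // width)
    padded = np.zeros((m, nwords * width), dtype=np.uint8)
    padded[:, :n] = bin_matrix.bits
    packed = np.packbits(padded, axis=1, bitorder="little")
    words = packed.view(_WORD_DTYPES[width]).reshape(m, nwords)
    return EncodedMatrix(words, n=n, width=width)


def decode(enc: EncodedMatrix) -> np.ndarray:
    """Unpack an :class:`EncodedMatrix` back to an m x n uint8 bit matrix."""
    as_bytes = np.ascontiguousarray(enc.words).view(np.uint8).reshape(enc.m, -1)
    bits = np.unpackbits(as_bytes, axis=1, bitorder="little")
    return bits[:, : enc.n]


def unpack_words(words: np.ndarray, n: int) -> np.ndarray:
    """Unpack a single word array to its first ``n`` bits (uint8)."""
    as_bytes = np.ascontiguousarray(words).view(np.uint8)
    return np.unpackbits(as_bytes, bitorder="little")[:n]


def pack_bits(bits: Sequence[int] | np.ndarray, width: int = 64) -> np.ndarray:
    """Pack a flat bit sequence into a word array (LSB-first, zero padding)."""
    bits = np.asarray(bits, dtype=np.uint8)
    n = bits.size
    nwords = max(1, -(-n // width))
    padded = np.zeros(nwords * width, dtype=np.uint8)
    padded[:n] = bits
    return np.packbits(padded, bitorder="little").view(_WORD_DTYPES[width])


def popcount(word):
    """Number of set bits of an unsigned word or array of words."""
    arr = np.asarray(word, dtype=np.uint64)
    counts = np.bitwise_count(arr)
    return int(counts) if np.isscalar(word) or arr.ndim == 0 else counts
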