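"""The BiBit bit-pattern biclustering algorithm.

A bicluster of a binary matrix is a pair (R, C) of row and column subsets
such that every cell in R x C equals one.  BiBit finds them in two phases:

1. *Seeding*: for every unordered pair of rows, the bitwise AND of the two
   packed rows gives a candidate column pattern.  Patterns with fewer than
   ``mnc`` set bits are dropped; duplicate patterns are inserted only once.
2. *Completion*: each surviving pattern p is extended with every row r
   satisfying ``p AND r == p``; biclusters with fewer than ``mnr`` rows are
   discarded.

Because completion recomputes the full containing-row set from the pattern
alone, the output depends only on the *set* of distinct qualifying
patterns — never on which pair seeded a pattern or in which order pairs
were enumerated.  This invariance licenses the second, algebraically
equivalent execution strategy implemented here (``strategy="support"``):
enumerate all column sets whose containing-row support reaches ``mnr``
(levelwise, support being anti-monotone under set inclusion), keep those
of size >= ``mnc``, and keep a set iff some pair of its containing rows
has it as their exact AND.  On sparse random matrices this avoids touching
all ~m^2/2 pairs and scales to tens of thousands of rows; on matrices
where the levelwise enumeration would blow up it falls back to the direct
pairwise route.  Both strategies produce identical results (tested), as
does :func:`reference_oracle`, a deliberately naive set-based
restatement used for verification.

Patterns that are strict subsets of other reported patterns are *not*
filtered: deduplication is by identical pattern only, so the output is
not restricted to maximal biclusters.
"""

from __future__ import annotations

import threading
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

from .errors import ValidationError
from .preprocess import BinaryMatrix, EncodedMatrix, encode, pack_bits, unpack_words

__all__ = [
    "Pattern",
    "Bicluster",
    "BiclusterSet",
    "Params",
    "pair_pattern",
    "initialize_biclusters",
    "complete_bicluster",
    "run_bibit",
    "reference_oracle",
    "sort_canonical",
]


@dataclass(frozen=True)
class Pattern:
    """A column subset as a packed word array; the bicluster's identity key."""

    words: np.ndarray
    n: int
    width: int
    ones: int

    @classmethod
    def from_words(cls, words: np.ndarray, n: int, width: int) -> "Pattern":
        words = np.ascontiguousarray(words)
        words.setflags(write=False)
        ones = int(np.bitwise_count(words.astype(np.uint64, copy=False)).sum())
        return cls(words=words, n=n, width=width, ones=ones)

    @classmethod
    def from_columns(cls, cols: Sequence[int], n: int, width: int = 64) -> "Pattern":
        bits = np.zeros(n, dtype=np.uint8)
        bits[list(cols)] = 1
        return cls.from_words(pack_bits(bits, width), n, width)

    def key(self) -> bytes:
        return self.words.tobytes()

    def bits(self) -> np.ndarray:
        return unpack_words(self.words, self.n)

    def columns(self) -> np.ndarray:
        return np.flatnonzero(self.bits())

    def sort_key(self) -> bytes:
        # lexicographic on the unpacked bit sequence, column 0 first
        return np.packbits(self.bits()).tobytes()


@dataclass(frozen=True)
class Bicluster:
    """A pattern plus the ordered row indices whose rows contain it."""

    pattern: Pattern
    rows: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValidationError("a bicluster needs at least 2 rows")
        if any(b <= a for a, b in zip(self.rows, self.rows[1:])):
            raise ValidationError("row indices must be strictly increasing")

    @property
    def nr(self) -> int:
        return len(self.rows)

    @property
    def nc(self) -> int:
        return self.pattern.ones

    def row_col_sets(self) -> tuple[tuple[int, ...], tuple[int, ...]]:
        return self.rows, tuple(int(c) for c in self.pattern.columns())


class BiclusterSet:
    """Pattern-keyed collection enforcing pattern uniqueness.

    ``add`` performs the membership test and insertion as one atomic step
    under an internal lock, so concurrent seeding workers can share one
    instance (the pattern AND and popcount happen outside the lock).
    """

    def __init__(self) -> None:
        self._entries: dict[bytes, Bicluster] = {}
        self._lock = threading.Lock()

    def add(self, bicluster: Bicluster) -> bool:
        """Insert unless a bicluster with the same pattern exists; report success."""
        key = bicluster.pattern.key()
        with self._lock:
            if key in self._entries:
                return False
            self._entries[key] = bicluster
            return True

    def __contains__(self, pattern: Pattern) -> bool:
        return pattern.key() in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self) -> Iterator[Bicluster]:
        return iter(list(self._entries.values()))


@dataclass
class Params:
    """User parameters: minimum rows/columns, word width, worker count."""

    mnr: int
    mnc: int
    threshold: Optional[float] = None
    word_width: int = 64
    workers: int = 1
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.mnr < 2:
            raise ValidationError(f"mnr must be >= 2, got {self.mnr}")
        if self.mnc < 1:
            raise ValidationError(f"mnc must be >= 1, got {self.mnc}")
        if self.word_width not in (32, 64):
            raise ValidationError(f"word width must be 32 or 64, got {self.word_width}")
        if self.workers < 1:
            raise ValidationError(f"workers must be >= 1, got {self.workers}")


def pair_pattern(D: EncodedMatrix, i: int, k: int) -> Pattern:
    """Word-wise AND of rows ``i`` and ``k`` (the pair's joint pattern)."""
    if not (0 <= i < k < D.m):
        raise ValidationError(f"need 0 <= i < k < {D.m}, got i={i}, k={k}")
    return Pattern.from_words(D.words[i] & D.words[k], D.n, D.width)


def initialize_biclusters(
    D: EncodedMatrix,
    mnc: int,
    pairs: Optional[Iterable[tuple[int, int]]] = None,
    into: Optional[BiclusterSet] = None,
    row_range: Optional[tuple[int, int]] = None,
) -> BiclusterSet:
    """Seed one bicluster per distinct qualifying row-pair pattern.

    Every unordered row pair's AND pattern with at least ``mnc`` set bits
    is inserted into the shared set; duplicate patterns keep the
    first-seen seeding pair (irrelevant downstream, since completion
    depends only on the pattern).

    ``pairs`` overrides the enumeration order (used to verify order
    independence); ``row_range`` restricts the outer row index to
    ``[start, stop)`` so parallel workers can split the pair space;
    ``into`` supplies the shared set those workers insert into.
    """
    S = into if into is not None else BiclusterSet()
    if pairs is not None:
        for i, k in pairs:
            p = pair_pattern(D, i, k)
            if p.ones >= mnc:
                S.add(Bicluster(pattern=p, rows=(i, k)))
        return S

    start, stop = row_range if row_range is not None else (0, D.m - 1)
    words = D.words
    for i in range(start, stop):
        block = words[i] & words[i + 1 :]
        ones = np.bitwise_count(block.astype(np.uint64, copy=False)).sum(
            axis=1, dtype=np.int64
        )
        for off in np.flatnonzero(ones >= mnc):
            p = Pattern.from_words(block[off], D.n, D.width)
            S.add(Bicluster(pattern=p, rows=(i, i + 1 + int(off))))
    return S


def complete_bicluster(D: EncodedMatrix, seed: Bicluster, mnr: int) -> Optional[Bicluster]:
    """Extend a seed to all rows containing its pattern; drop if below ``mnr``.

    A row r belongs iff ``pattern AND r == pattern``.  The result depends
    only on the pattern, never on the seeding pair.
    """
    p = seed.pattern.words
    mask = ((D.words & p) == p).all(axis=1)
    rows = np.flatnonzero(mask)
    if rows.size < mnr:
        return None
    return Bicluster(pattern=seed.pattern, rows=tuple(int(r) for r in rows))


def sort_canonical(biclusters: Iterable[Bicluster]) -> list[Bicluster]:
    """Deterministic output order: lexicographic on the unpacked pattern bits."""
    return sorted(biclusters, key=lambda b: b.pattern.sort_key())


def run_bibit(
    bin_matrix: BinaryMatrix,
    params: Params,
    strategy: str = "auto",
) -> list[Bicluster]:
    """Run the full seeding + completion pipeline on a binary matrix.

    ``strategy`` selects the execution route: ``"pairwise"`` (the direct
    two-phase algorithm), ``"support"`` (levelwise frequent-column-set
    enumeration with seed-pair witnesses; efficient for large sparse
    matrices), or ``"auto"`` which picks by problem size.  All routes
    return the same canonically ordered list, for any word width.
    """
    if strategy not in ("auto", "pairwise", "support"):
        raise ValidationError(f"unknown strategy {strategy!r}")
    D = encode(bin_matrix, params.word_width)
    if strategy == "auto":
        npairs = D.m * (D.m - 1) // 2
        strategy = "pairwise" if npairs <= 4_000_000 else "support"
    if strategy == "support":
        try:
            result = _run_support(bin_matrix, D, params.mnr, params.mnc)
        except _SupportInfeasible:
            result = _run_pairwise(D, params.mnr, params.mnc)
    else:
        result = _run_pairwise(D, params.mnr, params.mnc)
    return sort_canonical(result)


def _run_pairwise(D: EncodedMatrix, mnr: int, mnc: int) -> list[Bicluster]:
    seeds = initialize_biclusters(D, mnc)
    completed = (complete_bicluster(D, s, mnr) for s in seeds)
    return [b for b in completed if b is not None]


def reference_oracle(bin_matrix: BinaryMatrix, mnr: int, mnc: int) -> list[Bicluster]:
    """Naive set-based restatement of the algorithm, used as a test oracle.

    Works directly on Python column-index sets with no packing, no
    popcount and no shortcuts; intended for small instances only.
    """
    Params(mnr=mnr, mnc=mnc)  # validate thresholds
    bits = bin_matrix.bits
    m, n = bits.shape
    row_sets = [frozenset(int(j) for j in np.flatnonzero(bits[i])) for i in range(m)]
    patterns: dict[frozenset, None] = {}
    for i in range(m - 1):
        for k in range(i + 1, m):
            p = row_sets[i] & row_sets[k]
            if len(p) >= mnc:
                patterns.setdefault(p)
    out = []
    for p in patterns:
        rows = tuple(i for i in range(m) if p <= row_sets[i])
        if len(rows) >= mnr:
            out.append(Bicluster(pattern=Pattern.from_columns(sorted(p), n), rows=rows))
    return sort_canonical(out)


# ---------------------------------------------------------------------------
# Support-based execution route
# ---------------------------------------------------------------------------


class _SupportInfeasible(Exception):
    """Levelwise enumeration would exceed its size guards; use pairwise."""


# guards against combinatorial blow-up of the levelwise enumeration
_MAX_CANDIDATES = 8_000_000
_MAX_FREQUENT = 2_000_000


def _pack_columns(bits: np.ndarray) -> np.ndarray:
    """Pack each *column* over its m row-bits into uint64 words (LSB-first)."""
    m, n = bits.shape
    mwords = -(-m // 64)
    padded = np.zeros((n, mwords * 64), dtype=np.uint8)
    padded[:, :m] = bits.T
    return np.packbits(padded, axis=1, bitorder="little").view(np.uint64)


def _subset_supports(colbits: np.ndarray, cands: np.ndarray) -> np.ndarray:
    """Row support of each candidate column set (rows containing all columns)."""
    ncand, k = cands.shape
    out = np.empty(ncand, dtype=np.int64)
    chunk = max(1, 40_000_000 // (k * colbits.shape[1]))
    for s in range(0, ncand, chunk):
        sl = cands[s : s + chunk]
        acc = colbits[sl[:, 0]].copy()
        for t in range(1, k):
            acc &= colbits[sl[:, t]]
        out[s : s + chunk] = np.bitwise_count(acc).sum(axis=1, dtype=np.int64)
    return out


def _apriori_candidates(frequent: list[tuple[int, ...]]) -> np.ndarray:
    """Join frequent k-sets sharing a (k-1)-prefix; prune by subset frequency."""
    if not frequent:
        return np.empty((0, 1), dtype=np.int64)
    k = len(frequent[0])
    fset = set(frequent)
    by_prefix: dict[tuple[int, ...], list[int]] = {}
    for t in sorted(frequent):
        by_prefix.setdefault(t[:-1], []).append(t[-1])
    cands = []
    for prefix, tails in by_prefix.items():
        for a_idx in range(len(tails) - 1):
            for b in tails[a_idx + 1 :]:
                cand = prefix + (tails[a_idx], b)
                # all k-subsets must be frequent (support is anti-monotone)
                if all(
                    cand[:d] + cand[d + 1 :] in fset for d in range(k - 1)
                ):
                    cands.append(cand)
                    if len(cands) > _MAX_CANDIDATES:
                        raise _SupportInfeasible
    return np.asarray(cands, dtype=np.int64).reshape(len(cands), k + 1)


def _frequent_column_sets(
    bits: np.ndarray, colbits: np.ndarray, mnr: int
) -> dict[tuple[int, ...], int]:
    """All column sets contained in at least ``mnr`` rows, by levelwise search."""
    m, n = bits.shape
    support1 = bits.sum(axis=0, dtype=np.int64)
    frequent: dict[tuple[int, ...], int] = {
        (int(j),): int(support1[j]) for j in np.flatnonzero(support1 >= mnr)
    }
    f1 = sorted(j for (j,) in frequent)
    if len(f1) < 2:
        return frequent
    # level 2 via co-occurrence counts (dense matmul; m x |f1| is small)
    sub = bits[:, f1].astype(np.float32)
    co = (sub.T @ sub).astype(np.int64)
    level: list[tuple[int, ...]] = []
    for ai in range(len(f1) - 1):
        for bi in range(ai + 1, len(f1)):
            if co[ai, bi] >= mnr:
                pair = (f1[ai], f1[bi])
                frequent[pair] = int(co[ai, bi])
                level.append(pair)
    while level:
        if len(frequent) > _MAX_FREQUENT:
            raise _SupportInfeasible
        cands = _apriori_candidates(level)
        if cands.size == 0:
            break
        sup = _subset_supports(colbits, cands)
        keep = np.flatnonzero(sup >= mnr)
        level = [tuple(int(c) for c in cands[idx]) for idx in keep]
        for idx, t in zip(keep, level):
            frequent[t] = int(sup[idx])
    return frequent


def _has_seed_pair(D: EncodedMatrix, rows_idx: np.ndarray, pwords: np.ndarray) -> bool:
    """True iff two containing rows have exactly this pattern as their AND.

    Equivalent to: two rows of the restriction to the pattern's *complement*
    columns are disjoint.  Scans row against later rows with early exit;
    on sparse data the first scan almost always finds a witness.
    """
    sub = D.words[rows_idx] & ~pwords  # row padding is zero, so ~p is safe
    for t in range(len(sub) - 1):
        rest = sub[t] & sub[t + 1 :]
        if not rest.any(axis=1).all():
            return True
    return False


def _run_support(
    bin_matrix: BinaryMatrix, D: EncodedMatrix, mnr: int, mnc: int
) -> list[Bicluster]:
    bits = bin_matrix.bits
    colbits = _pack_columns(bits)
    frequent = _frequent_column_sets(bits, colbits, mnr)
    out = []
    for cols, support in frequent.items():
        if len(cols) < mnc:
            continue
        mask = bits[:, list(cols)].all(axis=1)
        rows_idx = np.flatnonzero(mask)
        assert rows_idx.size == support
        pattern = Pattern.from_columns(cols, D.n, D.width)
        if _has_seed_pair(D, rows_idx, pattern.words):
            out.append(
                Bicluster(pattern=pattern, rows=tuple(int(r) for r in rows_idx))
            )
    return out
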