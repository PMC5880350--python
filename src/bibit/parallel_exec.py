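"""Parallel execution of seeding and completion with an equivalence contract.

Workers are threads sharing the read-only encoded matrix.  Seeding
partitions the pair space by outer row index; all workers insert into one
shared :class:`~bibit.core.BiclusterSet` whose membership-test-plus-insert
is atomic per pattern.  Completion partitions the seed list into
near-equal contiguous blocks with no cross-worker coordination, since
completing one bicluster is independent of all others.  The canonical
output ordering makes the result byte-identical to the serial run for any
worker count.
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass

from .core import (
    Bicluster,
    BiclusterSet,
    Params,
    complete_bicluster,
    initialize_biclusters,
    sort_canonical,
)
from .errors import ValidationError
from .preprocess import BinaryMatrix, encode

__all__ = ["WorkPartition", "partition_range", "run_parallel"]


@dataclass(frozen=True)
class WorkPartition:
    """Disjoint ascending half-open intervals covering ``[0, total)`` exactly."""

    ranges: tuple[tuple[int, int], ...]
    total: int

    def __post_init__(self) -> None:
        pos = 0
        for start, end in self.ranges:
            if start != pos or end < start:
                raise ValidationError("intervals must be ascending, disjoint, covering")
            pos = end
        if pos != self.total:
            raise ValidationError(f"intervals cover [0, {pos}), expected [0, {self.total})")


def partition_range(total: int, workers: int) -> WorkPartition:
    """Static block partition: first ``total % workers`` blocks one item larger."""
    if total < 0 or workers < 1:
        raise ValidationError(f"need total >= 0 and workers >= 1, got {total}, {workers}")
    base, rem = divmod(total, workers)
    ranges = []
    pos = 0
    for w in range(workers):
        size = base + (1 if w < rem else 0)
        ranges.append((pos, pos + size))
        pos += size
    return WorkPartition(ranges=tuple(ranges), total=total)


def run_parallel(bin_matrix: BinaryMatrix, params: Params) -> list[Bicluster]:
    """Multi-worker run producing output identical to the serial pipeline.

    Any worker failure propagates as an error; no silent partial results.
    """
    D = encode(bin_matrix, params.word_width)
    workers = params.workers
    S = BiclusterSet()
    # seeding: split outer row indices; pattern AND + popcount run outside
    # the set's per-pattern atomic insert
    seed_part = partition_range(max(D.m - 1, 0), workers)
    with ThreadPoolExecutor(max_workers=workers) as pool:
        futures = [
            pool.submit(initialize_biclusters, D, params.mnc, None, S, rng)
            for rng in seed_part.ranges
        ]
        for fut in futures:
            fut.result()  # re-raise worker exceptions

    seeds = list(S)
    comp_part = partition_range(len(seeds), workers)

    def complete_block(block: tuple[int, int]) -> list[Bicluster]:
        start, end = block
        done = (complete_bicluster(D, s, params.mnr) for s in seeds[start:end])
        return [b for b in done if b is not None]

    with ThreadPoolExecutor(max_workers=workers) as pool:
        results = list(pool.map(complete_block, comp_part.ranges))
    return sort_canonical(b for block in results for b in block)
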