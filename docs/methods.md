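# Methods

## The model

The object of interest is an *all-ones bicluster* of a binary matrix
M ∈ {0,1}^{m×n}: a pair (R, C) of row and column subsets with M[i, j] = 1
for every i ∈ R, j ∈ C. Rows are attributes (genes, words, products),
columns are samples. The algorithm implemented here is the bit-pattern
(BiBit) approach:

1. **Seeding.** For every unordered row pair (r₁, r₂) form the joint
   pattern p = r₁ ∧ r₂ (bitwise AND over the n column bits). Keep p if it
   has at least `mnc` ones and no earlier pair produced the same pattern.
2. **Completion.** For each surviving pattern p, the bicluster's rows are
   *all* rows r with p ∧ r = p; discard biclusters with fewer than `mnr`
   rows. The columns are the set bits of p.

Deduplication is by identical pattern only: a pattern strictly contained
in another reported pattern is still reported, so the output is not
restricted to maximal biclusters. Every reported bicluster is an exact
all-ones submatrix — the method has no noise tolerance by design.

A key algebraic fact drives the implementation: completion depends only
on the pattern, never on which pair seeded it or in which order pairs
were enumerated. The output is therefore a function of the *set* of
distinct qualifying pair patterns, which licenses both the parallel mode
and the alternative execution strategy below.

## Parameters

| parameter | meaning | default |
|---|---|---|
| `mnr` | minimum rows per bicluster (≥ 2) | — (user-set; benchmarks use 1% of m) |
| `mnc` | minimum columns per bicluster (≥ 1) | — (benchmarks use 2) |
| `threshold` | binarization cut for real input; strictly `value > threshold` maps to 1 | none (input must be binary) |
| `word_width` | packing width, 32 or 64 bits | 64 |
| `workers` | worker threads | 1 (CLI: number of processors) |
| `L` | discretization levels for the multi-level scheme | 12 |

`mnc = 0` is rejected: an all-zero pattern is contained in every row and
carries no information. Word width is a performance knob only — outputs
are identical for 32 and 64 bits (tested at the byte level).

## Encoding and numerical conventions

Each row's n bits are packed into ⌈n/W⌉ unsigned W-bit words,
least-significant bit first: column j is bit `j mod W` of word `j // W`;
padding bits beyond column n−1 are zero. Pattern operations are word-wise
AND plus popcount (`numpy.bitwise_count`). Output lines are ordered by the
unpacked pattern bit sequence compared lexicographically from column 0,
which makes output files byte-deterministic across repeated runs, worker
counts, word widths and pair enumeration orders.

Binarization of real matrices uses a strict inequality (ties map to 0).
The multi-level scheme for expression data standardizes each row (gene)
to mean 0 / variance 1 with the population denominator, bins the global
value range into L = 12 equal-width levels (top value clamped to level
L−1), and emits the 11 nested binary matrices with bit 1 iff
level ≥ ℓ for ℓ = 1..11. Standardization is per row because that is the
convention for expression matrices; discretization statistics are global
so that the 11 matrices share one level scale. Constant rows (zero
variance) and constant matrices (degenerate range) are rejected with the
offending row names.

## Execution strategies

`run_bibit(..., strategy=...)` selects one of two routes that provably
and testably return identical results:

- **pairwise** — the direct two-phase algorithm, vectorized one outer row
  at a time (AND of row i against all later rows, popcount filter,
  pattern-keyed dedup, then per-pattern completion against all rows).
  Default for matrices with up to ~4·10⁶ row pairs.
- **support** — for large sparse matrices, where the pair loop and the
  completion of millions of distinct patterns are prohibitive. It
  enumerates every column set contained in at least `mnr` rows by
  levelwise (Apriori-style) search — support is anti-monotone under set
  inclusion, and level 2 comes from one dense co-occurrence matmul — and
  then keeps a set p iff some pair of its containing rows has p as their
  *exact* AND (equivalently: the two rows, restricted to the complement
  of p, are disjoint). That witness test scans containing-row pairs with
  early exit; on sparse data the first scan almost always succeeds. The
  route bounds its own combinatorics (candidate and frequent-set caps)
  and falls back to pairwise when a dense or highly structured matrix
  would make the levelwise enumeration blow up.

Equivalence of the two strategies, and of both against a deliberately
naive set-based oracle (`reference_oracle`, no packing, no dedup
shortcuts), is enforced on hundreds of randomized small instances plus
the hand-checked 5×4 worked example.

The parallel mode (`run_parallel`) targets one machine: threads share the
read-only packed matrix; seeding splits the pair space by outer row index
into near-equal blocks while all workers insert into one shared
pattern-keyed set whose membership-test-plus-insert is atomic under a
lock (pattern AND and popcount happen outside the lock); completion
splits the seed list into contiguous near-equal blocks with no
coordination, since biclusters complete independently. The canonical
ordering makes serial and parallel output files byte-identical for any
worker count.

## Synthetic data

`datagen` emulates the benchmark inputs: matrices of i.i.d. Bernoulli(p)
cells at the benchmark dimensions (12,800–51,200 attributes, 100–200
samples, p = 0.10–0.15), with optional all-ones implants forced in for
recovery tests and an `exact_density` variant that places exactly
round(p·m·n) ones. "Percentage of ones" is interpreted as the per-cell
i.i.d. probability; at 15% density this reproduces the published
bicluster counts (C(n,2), see below). Randomness is numpy's PCG64; a
given seed yields a bit-identical matrix on any platform.

What the generator does *not* emulate: correlated genes, sample batch
structure, noisy or overlapping implants, realistic expression marginals.
Passing the recovery and count tests therefore demonstrates algorithmic
correctness and scale, not biological performance on real data.

## Why the benchmark counts are sharp

At m = 12,800, n = 100, p = 0.15, mnr = 128, mnc = 2: a fixed column
pair is jointly one in a row with probability p² = 0.0225, so its
completed support is ≈ Binomial(12800, 0.0225), mean 288 ≫ 128 (a 9.5 σ
margin), while any 3-column set's support has mean 12800·p³ ≈ 43 ≪ 128.
With overwhelming probability every one of the C(100,2) = 4950 column
pairs is reported and nothing larger is, so the count is exactly 4950;
likewise 19,900 = C(200,2) at n = 200 and 4950 at m = 25,600,
mnr = 256 (mean 576). At p = 0.10 the pair-support mean is exactly the
threshold 128, so roughly half the pairs pass and the count lands near
2475 — the count then depends on the RNG stream, so only the band
[2000, 3000] is asserted. These sizes run in seconds to tens of seconds
with the support strategy; they are the scales used by
`scripts/acceptance.py` and the end-to-end tests.

## Known limitations

- Exact patterns only: a single zero cell excludes a row; no noise model.
- The support strategy's worst case (dense or block-structured matrices)
  degrades to the pairwise route, which is quadratic in m.
- ARFF support covers dense numeric / {0,1}-nominal attributes only;
  orientation (data lines = attributes) is a convention, flippable with
  `--transpose`.
- Parallelism is thread-based on one machine; no multi-node execution.
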