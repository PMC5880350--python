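# bibit

Exhaustive bit-pattern biclustering of binary matrices.

Given an m × n 0/1 matrix — genes × samples with 1 meaning "differentially
expressed", words × documents, products × customers — `bibit` finds
**all-ones biclusters**: pairs (R, C) of row and column subsets with
M[i, j] = 1 for every i ∈ R, j ∈ C. It is aimed at analysts working with
binary (or thresholdable real-valued) expression-style matrices who need
an exact, exhaustive and reproducible enumeration rather than a heuristic
one.

## The algorithm

Every unordered row pair (r₁, r₂) contributes its *joint pattern*
p = r₁ ∧ r₂ (bitwise AND over the n column bits). Distinct patterns with
at least `mnc` ones seed candidate biclusters; each is then *completed*
with every row r satisfying p ∧ r = p and kept if it reaches `mnr` rows.
The columns of the bicluster are the set bits of p. Patterns are
deduplicated by identity only, so subsumed (non-maximal) patterns are
still reported; every reported submatrix is exactly all ones.

Rows are packed into 32- or 64-bit words, so pattern operations are
word-wise AND plus popcount. Because completion depends only on the
pattern, the output is invariant to pair enumeration order, worker count
and word width — output files are byte-identical across all of these. For
large sparse matrices an equivalent support-based strategy (levelwise
enumeration of column sets contained in ≥ `mnr` rows, plus an exact
seed-pair witness test) avoids touching all ~m²/2 pairs; see
`docs/methods.md`.

Also included: binarization front-ends (single strict threshold, and the
standardize → 12-level discretize → 11 nested binary matrices scheme used
for real expression data), ARFF/TSV/CSV readers, a seeded synthetic
benchmark generator, a naive reference oracle, and a thread-parallel mode
contractually equivalent to the serial run.

## Worked example

A 5×4 matrix with rows A–E:

```
A: 1 1 0 1
B: 1 1 1 0
C: 0 1 1 1
D: 1 1 1 1
E: 1 0 0 0
```

saved as `toy.arff` (ARFF, TSV and CSV are accepted; `bibit generate`
emits seeded random fixtures in either format). Then

```sh
bibit run --input toy.arff --output out.txt --mnr 2 --mnc 2
```

logs the phase boundaries

```
INFO read: toy.arff, m=5 attributes, n=4 samples (0.00s)
INFO binarize: density=0.7000 (0.00s)
INFO encode: word width 64, 1 words per row
INFO init+complete: strategy=pairwise, 6 biclusters (0.00s)
INFO write: 6 lines to out.txt (0.00s)
```

and writes one line per bicluster — `nr;nc;` then the `nr` row names,
then the `nc` column names:

```
3;2;row0;row2;row3;s1;s3
3;2;row1;row2;row3;s1;s2
2;3;row2;row3;s1;s2;s3
3;2;row0;row1;row3;s0;s1
2;3;row0;row3;s0;s1;s3
2;3;row1;row3;s0;s1;s2
```

The ten row pairs yield six distinct patterns with ≥ 2 ones; completion
finds, e.g., that pattern {s0, s1} (seeded by rows A and B) is also
contained in row D, giving the 3×2 bicluster {A, B, D} × {s0, s1}. With
`--mnr 3` only the three 3-row biclusters remain. Raising `--mnr`/`--mnc`
prunes harder; real-valued input needs `--threshold` (strictly greater
maps to 1). `bibit oracle` runs the naive reference implementation on the
same inputs and produces an identical file.

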