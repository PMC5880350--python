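import numpy as np
import pytest

from bibit.core import (
    Bicluster,
    Params,
    Pattern,
    complete_bicluster,
    initialize_biclusters,
    pair_pattern,
    reference_oracle,
    run_bibit,
)
from bibit.errors import ValidationError
from bibit.preprocess import BinaryMatrix, encode

from conftest import TOY_EXPECTED_MNR2, TOY_EXPECTED_MNR3, as_sets, random_binary


class TestParams:
    @pytest.mark.parametrize("kw", [{"mnr": 1, "mnc": 2}, {"mnr": 2, "mnc": 0},
                                    {"mnr": 2, "mnc": 1, "workers": 0},
                                    {"mnr": 2, "mnc": 1, "word_width": 16}])
    def test_invalid_rejected(self, kw):
        with pytest.raises(ValidationError):
            Params(**kw)


class TestPairPattern:
    def test_and_of_two_rows(self, toy_matrix):
        D = encode(toy_matrix)
        p = pair_pattern(D, 0, 1)  # A & B
        assert list(p.columns()) == [0, 1]
        assert p.ones == 2

    def test_identical_rows_give_row_pattern(self):
        bits = np.array([[1, 0, 1, 1], [1, 0, 1, 1]], dtype=np.uint8)
        p = pair_pattern(encode(BinaryMatrix(bits)), 0, 1)
        assert list(p.columns()) == [0, 2, 3]

    def test_disjoint_rows_give_empty_pattern(self):
        bits = np.array([[1, 1, 0, 0], [0, 0, 1, 1]], dtype=np.uint8)
        assert pair_pattern(encode(BinaryMatrix(bits)), 0, 1).ones == 0

    @pytest.mark.parametrize("i,k", [(1, 1), (2, 1), (0, 9)])
    def test_bad_indices_rejected(self, toy_matrix, i, k):
        with pytest.raises(ValidationError):
            pair_pattern(encode(toy_matrix), i, k)


class TestInitializeBiclusters:
    def test_toy_seeds_exactly_six_patterns(self, toy_matrix):
        S = initialize_biclusters(encode(toy_matrix), mnc=2)
        patterns = {tuple(b.pattern.bits()) for b in S}
        assert patterns == {
            (1, 1, 0, 0), (0, 1, 0, 1), (1, 1, 0, 1),
            (0, 1, 1, 0), (1, 1, 1, 0), (0, 1, 1, 1),
        }

    def test_mnc_above_n_gives_empty_set(self, toy_matrix):
        assert len(initialize_biclusters(encode(toy_matrix), mnc=5)) == 0

    def test_all_ones_matrix_dedups_to_single_seed(self):
        bits = np.ones((3, 4), dtype=np.uint8)
        S = initialize_biclusters(encode(BinaryMatrix(bits)), mnc=2)
        assert len(S) == 1
        (seed,) = list(S)
        assert seed.pattern.ones == 4


class TestCompleteBicluster:
    def test_toy_pattern_collects_all_containing_rows(self, toy_matrix):
        D = encode(toy_matrix)
        seed = Bicluster(pattern=pair_pattern(D, 0, 1), rows=(0, 1))
        done = complete_bicluster(D, seed, mnr=2)
        assert done.rows == (0, 1, 3)
        assert done.nr == 3

    def test_mnr_above_support_discards(self, toy_matrix):
        D = encode(toy_matrix)
        seed = Bicluster(pattern=pair_pattern(D, 0, 1), rows=(0, 1))
        assert complete_bicluster(D, seed, mnr=4) is None

    def test_all_ones_matrix_collects_every_row(self):
        D = encode(BinaryMatrix(np.ones((3, 4), dtype=np.uint8)))
        seed = Bicluster(pattern=pair_pattern(D, 0, 1), rows=(0, 1))
        assert complete_bicluster(D, seed, mnr=2).rows == (0, 1, 2)

    def test_result_depends_only_on_pattern(self, toy_matrix):
        D = encode(toy_matrix)
        p = pair_pattern(D, 0, 3)  # pattern {0,1,3} also seedable by (A,D)
        for rows in [(0, 3)]:
            done = complete_bicluster(D, Bicluster(pattern=p, rows=rows), mnr=2)
            assert done.rows == (0, 3)


class TestRunBibit:
    def test_toy_mnr2_worked_example(self, toy_matrix):
        result = run_bibit(toy_matrix, Params(mnr=2, mnc=2))
        assert set(as_sets(result)) == TOY_EXPECTED_MNR2

    def test_toy_mnr3_worked_example(self, toy_matrix):
        result = run_bibit(toy_matrix, Params(mnr=3, mnc=2))
        assert set(as_sets(result)) == TOY_EXPECTED_MNR3

    @pytest.mark.parametrize("strategy", ["pairwise", "support"])
    def test_strategies_agree_on_toy(self, toy_matrix, strategy):
        result = run_bibit(toy_matrix, Params(mnr=2, mnc=2), strategy=strategy)
        assert set(as_sets(result)) == TOY_EXPECTED_MNR2

    def test_output_canonically_ordered(self, toy_matrix):
        result = run_bibit(toy_matrix, Params(mnr=2, mnc=2))
        keys = [b.pattern.sort_key() for b in result]
        assert keys == sorted(keys)


class TestReferenceOracle:
    def test_toy_equals_run_bibit(self, toy_matrix):
        assert as_sets(reference_oracle(toy_matrix, 2, 2)) == as_sets(
            run_bibit(toy_matrix, Params(mnr=2, mnc=2))
        )

    def test_single_column_matrix_empty_under_mnc2(self):
        bits = np.ones((4, 1), dtype=np.uint8)
        assert reference_oracle(BinaryMatrix(bits), 2, 2) == []

    def test_identity_matrix_has_no_biclusters(self):
        bits = np.eye(5, dtype=np.uint8)
        assert reference_oracle(BinaryMatrix(bits), 2, 1) == []


class TestOracleEquivalence:
    """run_bibit (both strategies) vs the naive oracle on random instances."""

    @pytest.mark.parametrize("seed", range(8))
    def test_random_matrices_all_strategies_agree(self, seed):
        rng = np.random.default_rng(1000 + seed)
        for _ in range(6):
            m = int(rng.integers(4, 41))
            n = int(rng.integers(2, 17))
            p = float(rng.choice([0.1, 0.3, 0.5, 0.7, 0.9]))
            mnr = int(rng.integers(2, 5))
            mnc = int(rng.integers(1, 4))
            mat = random_binary(rng, m, n, p)
            expected = as_sets(reference_oracle(mat, mnr, mnc))
            for strategy in ("pairwise", "support"):
                got = as_sets(run_bibit(mat, Params(mnr=mnr, mnc=mnc), strategy=strategy))
                assert got == expected, (m, n, p, mnr, mnc, strategy)


class TestInvariants:
    def _random_case(self, seed):
        rng = np.random.default_rng(seed)
        mat = random_binary(rng, 30, 12, 0.4)
        return mat, run_bibit(mat, Params(mnr=2, mnc=2))

    @pytest.mark.parametrize("seed", [21, 22, 23])
    def test_validity_and_completeness(self, seed):
        mat, result = self._random_case(seed)
        seen_patterns = set()
        for b in result:
            rows, cols = b.row_col_sets()
            # all-ones submatrix
            assert mat.bits[np.ix_(rows, cols)].all()
            # no row outside contains the pattern
            outside = [i for i in range(mat.shape[0]) if i not in rows]
            for i in outside:
                assert not mat.bits[i, list(cols)].all()
            # pattern uniqueness and thresholds
            assert cols not in seen_patterns
            seen_patterns.add(cols)
            assert b.nr >= 2 and b.pattern.ones >= 2

    def test_seed_order_independence(self, toy_matrix):
        D = encode(toy_matrix)
        m = D.m
        pairs = [(i, k) for i in range(m - 1) for k in range(i + 1, m)]
        rng = np.random.default_rng(3)
        baseline = None
        for _ in range(5):
            rng.shuffle(pairs)
            S = initialize_biclusters(D, mnc=2, pairs=list(pairs))
            done = sorted(
                b.row_col_sets()
                for s in S
                if (b := complete_bicluster(D, s, mnr=2)) is not None
            )
            if baseline is None:
                baseline = done
            assert done == baseline
        assert set(map(tuple, baseline)) == TOY_EXPECTED_MNR2

    @pytest.mark.parametrize("seed", [31, 32])
    def test_row_permutation_equivariance(self, seed):
        rng = np.random.default_rng(seed)
        mat = random_binary(rng, 20, 10, 0.4)
        perm = rng.permutation(20)
        permuted = BinaryMatrix(mat.bits[perm])
        base = set(as_sets(run_bibit(mat, Params(mnr=2, mnc=2))))
        # permuted row i is original row perm[i]
        mapped = {
            (tuple(sorted(int(perm[i]) for i in rows)), cols)
            for rows, cols in as_sets(run_bibit(permuted, Params(mnr=2, mnc=2)))
        }
        assert mapped == base

    @pytest.mark.parametrize("seed", [41, 42])
    def test_column_permutation_equivariance(self, seed):
        rng = np.random.default_rng(seed)
        mat = random_binary(rng, 20, 10, 0.4)
        perm = rng.permutation(10)
        permuted = BinaryMatrix(mat.bits[:, perm])
        base = set(as_sets(run_bibit(mat, Params(mnr=2, mnc=2))))
        # permuted column j is original column perm[j]
        mapped = {
            (rows, tuple(sorted(int(perm[j]) for j in cols)))
            for rows, cols in as_sets(run_bibit(permuted, Params(mnr=2, mnc=2)))
        }
        assert mapped == base

    @pytest.mark.parametrize("seed", [51, 52])
    def test_word_width_invariance(self, seed):
        rng = np.random.default_rng(seed)
        mat = random_binary(rng, 25, 70, 0.3)
        r32 = run_bibit(mat, Params(mnr=2, mnc=2, word_width=32))
        r64 = run_bibit(mat, Params(mnr=2, mnc=2, word_width=64))
        assert as_sets(r32) == as_sets(r64)

    @pytest.mark.parametrize("seed", [61, 62])
    def test_safe_prefilter_of_sparse_rows(self, seed):
        """Dropping rows with fewer than mnc ones leaves the output unchanged."""
        rng = np.random.default_rng(seed)
        mat = random_binary(rng, 30, 8, 0.25)
        mnc = 3
        keep = np.flatnonzero(mat.bits.sum(axis=1) >= mnc)
        filtered = BinaryMatrix(mat.bits[keep])
        base = set(as_sets(run_bibit(mat, Params(mnr=2, mnc=mnc))))
        mapped = {
            (tuple(int(keep[i]) for i in rows), cols)
            for rows, cols in as_sets(run_bibit(filtered, Params(mnr=2, mnc=mnc)))
        }
        assert mapped == base
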