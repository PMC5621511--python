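"""Packing, NODF, matrix temperature, discrepancy, and the null-model test."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.optimize import brentq

import macrorich as mr
from macrorich.errors import InvalidArgumentError, UndefinedStatisticError
from conftest import random_binary_matrix

TRI = np.array([[1, 1, 1],
                [1, 1, 0],
                [1, 0, 0]])


class TestPack:
    def test_packed_matrix_is_identity_permutation(self):
        p = mr.pack(TRI)
        np.testing.assert_array_equal(p.row_order, [0, 1, 2])
        np.testing.assert_array_equal(p.col_order, [0, 1, 2])

    def test_packing_a_reversed_matrix_recovers_packed_form(self):
        rev = TRI[::-1, ::-1]
        p = mr.pack(rev)
        np.testing.assert_array_equal(p.matrix, TRI)

    def test_ties_are_stable(self):
        M = np.array([[1, 0, 1],
                      [0, 1, 1]])  # equal row totals, tied column totals
        p = mr.pack(M)
        np.testing.assert_array_equal(p.row_order, [0, 1])
        # column 2 (total 2) first, then 0 and 1 in original order
        np.testing.assert_array_equal(p.col_order, [2, 0, 1])

    def test_external_scores_order_columns(self):
        p = mr.pack(TRI, external_site_scores=[1.0, 5.0, 3.0])
        np.testing.assert_array_equal(p.col_order, [1, 2, 0])
        with pytest.raises(InvalidArgumentError):
            mr.pack(TRI, external_site_scores=[1.0, 2.0])


def _nodf_brute(M):
    """All-pairs loop implementation of NODF."""
    M = np.asarray(M)

    def line_pairs(lines):
        tot = [l.sum() for l in lines]
        s, npairs = 0.0, 0
        for i in range(len(lines)):
            for j in range(i + 1, len(lines)):
                npairs += 1
                if tot[i] == tot[j] or min(tot[i], tot[j]) == 0:
                    continue
                full, sparse = (i, j) if tot[i] > tot[j] else (j, i)
                shared = int((lines[full] & lines[sparse]).sum())
                s += shared / tot[sparse] * 100.0
        return s, npairs

    rs, rn = line_pairs([M[i] for i in range(M.shape[0])])
    cs, cn = line_pairs([M[:, j] for j in range(M.shape[1])])
    return (rs + cs) / (rn + cn), cs / cn, rs / rn


class TestNODF:
    def test_perfectly_nested_is_100(self):
        assert mr.nodf(TRI) == (100.0, 100.0, 100.0)

    def test_equal_totals_contribute_zero(self):
        assert mr.nodf(np.eye(2, dtype=int)) == (0.0, 0.0, 0.0)

    def test_matches_brute_force_on_random_matrices(self, rng):
        for _ in range(100):
            M = random_binary_matrix(rng, (8, 8))
            got = mr.nodf(M)
            want = _nodf_brute(M)
            np.testing.assert_allclose(got, want, atol=1e-10)

    def test_invariant_to_row_and_column_permutations(self, rng):
        M = random_binary_matrix(rng, (10, 12))
        base = mr.nodf(M)
        for _ in range(5):
            P = M[rng.permutation(10)][:, rng.permutation(12)]
            np.testing.assert_allclose(mr.nodf(P), base, atol=1e-12)

    def test_all_zero_row_rejected(self):
        M = TRI.copy()
        M[2] = 0
        with pytest.raises(InvalidArgumentError):
            mr.nodf(M)


def _temperature_brute(M):
    """Independent cell-enumeration implementation of matrix temperature.

    Solves the isocline exponent by numerical quadrature and every cell's
    diagonal crossing with scalar root finding, then sums squared distances
    of unexpected cells.
    """
    M = np.asarray(M)
    m, n = M.shape
    P = M[np.argsort(-M.sum(axis=1), kind="stable")][
        :, np.argsort(-M.sum(axis=0), kind="stable")]
    fill = M.mean()

    def f(x, p):
        return 1.0 - (1.0 - (1.0 - x) ** p) ** (1.0 / p)

    p = brentq(lambda q: quad(f, 0, 1, args=(q,), epsabs=1e-13,
                              epsrel=1e-13)[0] - fill, 1e-4, 1e4, xtol=1e-14)
    total = 0.0
    for i in range(m):
        for j in range(n):
            r = (i + 0.5) / m
            c = (j + 0.5) / n
            a = c - r
            x = brentq(lambda t: f(t, p) - t - a, 0.0, 1.0, xtol=1e-14)
            u = (r - x) / (1.0 - abs(a))
            if (u > 0 and P[i, j] == 1) or (u < 0 and P[i, j] == 0):
                total += u * u
    return 100.0 * total / (m * n) / 0.04145


class TestTemperature:
    def test_perfectly_nested_fixture_is_zero(self):
        assert mr.temperature(TRI) == 0.0

    def test_checkerboard_is_near_scale_maximum(self):
        # a checkerboard stays maximally disordered under any packing
        # (the complement of a nested matrix repacks into a nested one,
        # so it cannot serve as the anti-nested fixture)
        cb = (np.indices((6, 6)).sum(axis=0) % 2).astype(int)
        assert mr.temperature(cb) > 80.0
        assert mr.temperature(TRI) == 0.0

    def test_degenerate_fill_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            mr.temperature(np.ones((3, 3), int))
        with pytest.raises(UndefinedStatisticError):
            mr.temperature(np.zeros((3, 3), int))

    def test_one_displaced_presence_matches_enumeration_oracle(self):
        M = np.array([[1, 1, 0],
                      [1, 0, 1],
                      [1, 0, 0]])
        assert mr.temperature(M) == pytest.approx(_temperature_brute(M),
                                                  abs=1e-10)

    def test_matches_enumeration_oracle_on_random_matrices(self, rng):
        for _ in range(30):
            M = random_binary_matrix(rng, (6, 7))
            assert mr.temperature(M) == pytest.approx(_temperature_brute(M),
                                                      abs=1e-10)

    def test_invariant_to_permutations_with_tie_free_marginals(self, rng):
        # packing breaks marginal-total ties by original position, so exact
        # invariance is guaranteed only when all totals are distinct; build
        # such a matrix as a triangle plus marginal-preserving 2x2 swaps
        M = np.tril(np.ones((7, 7), int))
        for _ in range(10):
            i1, i2 = sorted(rng.choice(7, size=2, replace=False))
            j1, j2 = sorted(rng.choice(7, size=2, replace=False))
            if M[i1, j1] == M[i2, j2] == 1 and M[i1, j2] == M[i2, j1] == 0:
                M[[i1, i2], [j1, j2]] = 0
                M[[i1, i2], [j2, j1]] = 1
        assert len(set(M.sum(axis=1))) == 7 and len(set(M.sum(axis=0))) == 7
        base = mr.temperature(M)
        for _ in range(5):
            P = M[rng.permutation(7)][:, rng.permutation(7)]
            assert mr.temperature(P) == pytest.approx(base, abs=1e-12)


class TestDiscrepancy:
    def test_perfectly_packed_is_zero(self):
        assert mr.discrepancy(TRI) == 0

    def test_identity_two_by_two(self):
        # both shift options move exactly one presence
        assert mr.discrepancy(np.eye(2, dtype=int)) == 1

    def test_bounded_by_total_presences(self, rng):
        for _ in range(20):
            M = random_binary_matrix(rng, (6, 6))
            assert 0 <= mr.discrepancy(M) <= M.sum()

    def test_matches_loop_oracle(self, rng):
        def brute(M):
            # presences outside each row's leftmost block, column-packed
            order = sorted(range(M.shape[1]),
                           key=lambda j: (-M[:, j].sum(), j))
            total = 0
            for i in range(M.shape[0]):
                row = [M[i, j] for j in order]
                r = sum(row)
                total += sum(row[r:])
            return total

        for _ in range(100):
            M = random_binary_matrix(rng, (7, 8))
            assert mr.discrepancy(M) == brute(M)

    def test_more_packed_is_cooler(self, rng):
        """Moving a presence into packed position never raises T or BR."""
        M = np.array([[1, 1, 1, 0],
                      [1, 0, 0, 1],
                      [1, 1, 0, 0]])
        packed = np.array([[1, 1, 1, 0],
                           [1, 1, 0, 0],
                           [1, 1, 0, 0]])  # same row sums, fully packed
        assert mr.discrepancy(packed) <= mr.discrepancy(M)
        assert mr.temperature(packed) <= mr.temperature(M)


class TestNullModel:
    def test_row_sums_preserved_in_every_replicate(self, rng):
        M = random_binary_matrix(rng, (10, 20))
        ens = mr.null_fixed_rows_equiprob_cols(M, 200, seed=1)
        r = M.sum(axis=1)
        assert (ens.replicates.sum(axis=2) == r).all()

    def test_expected_column_totals_uniform(self, rng):
        M = random_binary_matrix(rng, (10, 20))
        n_iter = 10000
        ens = mr.null_fixed_rows_equiprob_cols(M, n_iter, seed=2)
        col_means = ens.replicates.sum(axis=1).mean(axis=0)
        expect = M.sum() / 20
        # per-column binomial-ish SE over the ensemble
        se = ens.replicates.sum(axis=1).std(ddof=1, axis=0) / np.sqrt(n_iter)
        assert (np.abs(col_means - expect) < 3 * se + 1e-9).all()

    def test_same_seed_identical(self, rng):
        M = random_binary_matrix(rng, (6, 9))
        a = mr.null_fixed_rows_equiprob_cols(M, 50, seed=3)
        b = mr.null_fixed_rows_equiprob_cols(M, 50, seed=3)
        np.testing.assert_array_equal(a.replicates, b.replicates)

    def test_full_rows_allowed_and_preserved(self):
        # a 0/1 matrix can never have a row total above its column count;
        # ubiquitous species (full rows) must still randomize validly
        ens = mr.null_fixed_rows_equiprob_cols(np.ones((2, 3), int), 10,
                                               seed=0)
        assert (ens.replicates == 1).all()


class TestNestednessTest:
    def test_ci_brackets_null_mean_and_p_valid(self, rng):
        M = random_binary_matrix(rng, (10, 15))
        for index in ("T", "BR", "NODF", "NODFc", "NODFr"):
            res = mr.nestedness_test(M, index, n_iter=300, seed=5)
            assert res.null_ci[0] <= res.null_mean <= res.null_ci[1]
            assert 0 < res.p <= 1
            assert res.p + res.p_opposite >= 1.0  # overlapping tails

    def test_source_sink_world_is_strongly_nested(self):
        env = mr.make_environment((12, 12), seed=31)
        rs = mr.make_ranges(25, env, seed=32)
        M = mr.build_matrix(rs).matrix
        for index in ("T", "BR", "NODF"):
            res = mr.nestedness_test(M, index, n_iter=999, seed=33)
            assert res.p <= 0.005, (index, res.p)

    def test_unknown_index_rejected(self, rng):
        with pytest.raises(InvalidArgumentError):
            mr.nestedness_test(random_binary_matrix(rng, (4, 4)), "Q",
                               n_iter=10, seed=0)
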