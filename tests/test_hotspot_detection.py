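"""Spatial weights, Moran's I, Gi*, and hotspot delineation."""

import numpy as np
import pytest
from scipy import stats

import macrorich as mr
from macrorich.errors import (
    DegenerateWeightsError,
    InvalidArgumentError,
    UndefinedStatisticError,
)


def _full_mask(shape):
    return np.ones(shape, bool)


class TestWeights:
    def test_neighbor_counts(self):
        w_queen = mr.build_weights(_full_mask((5, 5)), scheme="queen")
        w_rook = mr.build_weights(_full_mask((5, 5)), scheme="rook")
        counts_q = np.asarray(w_queen.W.sum(axis=1)).ravel()
        counts_r = np.asarray(w_rook.W.sum(axis=1)).ravel()
        center = 2 * 5 + 2
        corner = 0
        assert counts_q[center] == 8
        assert counts_r[corner] == 2

    def test_row_standardized_rows_sum_to_one(self):
        w = mr.build_weights(_full_mask((6, 4)), row_standardize=True)
        np.testing.assert_allclose(np.asarray(w.W.sum(axis=1)).ravel(),
                                   1.0, atol=1e-12)

    def test_single_cell_degenerate(self):
        mask = np.zeros((3, 3), bool)
        mask[1, 1] = True
        with pytest.raises(DegenerateWeightsError):
            mr.build_weights(mask)


class TestMoransI:
    def test_checkerboard_is_minus_one(self):
        rr, cc = np.meshgrid(np.arange(8), np.arange(8), indexing="ij")
        vals = np.where((rr + cc) % 2 == 0, 1.0, -1.0)
        w = mr.build_weights(_full_mask((8, 8)), scheme="rook")
        res = mr.morans_i(vals, w)
        assert res.I == pytest.approx(-1.0, abs=1e-12)

    def test_expected_value_closed_form(self):
        w = mr.build_weights(_full_mask((10, 10)))
        res = mr.morans_i(np.random.default_rng(1).random((10, 10)), w)
        assert res.expected == pytest.approx(-1.0 / 99)

    def test_permuted_surface_is_near_expectation(self):
        rng = np.random.default_rng(2)
        shape = (30, 30)
        surface = rng.permutation(np.linspace(0, 1, 900)).reshape(shape)
        w = mr.build_weights(_full_mask(shape))
        res = mr.morans_i(surface, w, inference="normal")
        assert abs(res.z) < 3  # within 3 SE of -1/(n-1) under the null

    def test_permutation_inference_matches_normal_direction(self, world):
        grid = world["grid"]
        w = mr.build_weights(grid)
        perm = mr.morans_i(grid.richness.astype(float), w,
                           inference="permutation", n_perm=199, seed=0)
        norm = mr.morans_i(grid.richness.astype(float), w)
        assert perm.I == pytest.approx(norm.I)
        assert perm.p < 0.05 and norm.p < 0.05

    def test_affine_invariance(self, world):
        grid = world["grid"]
        w = mr.build_weights(grid)
        x = grid.richness.astype(float)
        a = mr.morans_i(x, w).I
        b = mr.morans_i(3.5 * x + 11.0, w).I
        assert a == pytest.approx(b, abs=1e-12)

    def test_constant_surface_undefined(self):
        w = mr.build_weights(_full_mask((4, 4)))
        with pytest.raises(UndefinedStatisticError):
            mr.morans_i(np.ones((4, 4)), w)


def _gstar_brute(values, mask, scheme="queen"):
    """Independent loop implementation of the Gi* formula."""
    rows, cols = values.shape
    cells = [(r, c) for r in range(rows) for c in range(cols) if mask[r, c]]
    x = np.array([values[r, c] for r, c in cells], float)
    n = len(x)
    xbar = x.mean()
    s = np.sqrt(np.mean(x ** 2) - xbar ** 2)
    offs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 0), (0, 1),
            (1, -1), (1, 0), (1, 1)]
    if scheme == "rook":
        offs = [(-1, 0), (1, 0), (0, -1), (0, 1), (0, 0)]
    out = []
    index = {rc: i for i, rc in enumerate(cells)}
    for r, c in cells:
        wsum = w2sum = local = 0.0
        for dr, dc in offs:
            j = index.get((r + dr, c + dc))
            if j is not None:
                wsum += 1.0
                w2sum += 1.0
                local += x[j]
        denom = s * np.sqrt((n * w2sum - wsum ** 2) / (n - 1))
        out.append((local - xbar * wsum) / denom)
    return np.array(out)


class TestGiStar:
    def test_constant_surface_errors(self):
        w = mr.build_weights(_full_mask((4, 4)), include_self=True)
        with pytest.raises(UndefinedStatisticError):
            mr.getis_ord_gstar(np.full((4, 4), 2.0), w)

    def test_requires_self_inclusion(self):
        w = mr.build_weights(_full_mask((4, 4)))
        with pytest.raises(InvalidArgumentError):
            mr.getis_ord_gstar(np.zeros((4, 4)) + np.eye(4), w)

    def test_center_spike_hand_expansion(self):
        """Spike of 9 at the centre of a 5x5 grid: expand the formula by hand.

        The centre's queen+self neighbourhood is the inner 3x3 window, so its
        local sum is the spike itself and every term of the Z formula has a
        closed form.
        """
        vals = np.zeros((5, 5))
        vals[2, 2] = 9.0
        w = mr.build_weights(_full_mask((5, 5)), include_self=True)
        z = mr.getis_ord_gstar(vals, w)
        n = 25
        xbar = 9.0 / 25
        s = np.sqrt(81.0 / 25 - xbar ** 2)
        wsum = 9.0   # inner 3x3 window, binary weights
        local = 9.0  # only the spike contributes
        expected = (local - xbar * wsum) / (
            s * np.sqrt((n * wsum - wsum ** 2) / (n - 1)))
        center = 2 * 5 + 2
        assert z[center] == pytest.approx(expected, abs=1e-10)

    def test_matches_brute_force_on_random_grids(self):
        rng = np.random.default_rng(7)
        for trial in range(30):
            shape = (rng.integers(4, 8), rng.integers(4, 8))
            vals = rng.random(shape) * 10
            mask = rng.random(shape) < 0.85
            mask.flat[rng.integers(0, mask.size, 4)] = True
            if mask.sum() < 3:
                continue
            vals = np.where(mask, vals, 0.0)
            w = mr.build_weights(mask, include_self=True)
            got = mr.getis_ord_gstar(vals, w)
            want = _gstar_brute(vals, mask)
            np.testing.assert_allclose(got, want, atol=1e-10)

    def test_spike_maximizes_z(self):
        for scheme in ("queen", "rook"):
            vals = np.ones((7, 7))
            vals[3, 3] = 50.0
            w = mr.build_weights(_full_mask((7, 7)), scheme=scheme,
                                 include_self=True)
            z = w.to_grid(mr.getis_ord_gstar(vals, w))
            # the spike's whole neighbourhood shares the top local sum, so
            # the maximum is attained (not necessarily uniquely) at the spike
            assert z[3, 3] == pytest.approx(np.nanmax(z), abs=1e-12)
            assert z[3, 3] > 0 > z[0, 0]


class TestDelineation:
    def test_no_significance_no_clusters(self):
        rng = np.random.default_rng(3)
        z = rng.normal(0, 0.1, 100)  # nothing near significance
        w = mr.build_weights(_full_mask((10, 10)), include_self=True)
        res = mr.delineate_hotspots(z, w)
        assert res.clusters.empty
        assert res.hot_labels.max() == 0

    def test_clustered_cells_are_significant_cells(self, world):
        grid = world["grid"]
        w = mr.build_weights(grid, include_self=True)
        z = mr.getis_ord_gstar(grid.richness.astype(float), w)
        res = mr.delineate_hotspots(z, w)
        in_cluster = (res.hot_labels > 0) | (res.cold_labels > 0)
        assert not (in_cluster & ~res.significant).any()
        # every flagged cell belongs to exactly one cluster
        flagged_hot = res.significant & (res.z_grid > 0)
        assert res.clusters.query("kind == 'hot'")["n_cells"].sum() == \
            flagged_hot.sum()

    def test_deterministic(self, world):
        grid = world["grid"]
        w = mr.build_weights(grid, include_self=True)
        z = mr.getis_ord_gstar(grid.richness.astype(float), w)
        a = mr.delineate_hotspots(z, w)
        b = mr.delineate_hotspots(z, w)
        np.testing.assert_array_equal(a.hot_labels, b.hot_labels)
        assert a.clusters.equals(b.clusters)

    def test_raw_threshold_flags_more_than_fdr(self, world):
        grid = world["grid"]
        w = mr.build_weights(grid, include_self=True)
        z = mr.getis_ord_gstar(grid.richness.astype(float), w)
        fdr = mr.delineate_hotspots(z, w, correction="fdr")
        raw = mr.delineate_hotspots(z, w, correction="none")
        assert raw.significant.sum() >= 0 and fdr.significant.sum() >= 0
        assert stats.norm.sf(0) == 0.5  # sanity anchor for the p transform
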