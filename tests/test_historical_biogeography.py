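"""DEC likelihood, ML fitting, AIC comparison, stochastic mapping."""

import dendropy
import numpy as np
import pytest
from scipy.linalg import expm

import macrorich as mr
from macrorich.errors import InvalidArgumentError


def _cherry(t1=1.0, t2=1.0):
    return dendropy.Tree.get(data=f"(a:{t1},b:{t2});", schema="newick")


def _oracle_loglik(tree, coding, d, e, j=0.0):
    """Enumeration + matrix-exponential oracle for small trees.

    Recursively sums over every ancestral state with explicit loops and
    scipy's expm; no scaling, no shared code with the implementation.
    """
    areas = coding.areas
    n = len(areas)
    masks = list(range(1 << n))

    def gain_rate(mask, k):
        if mask >> k & 1:
            return 0.0
        return d * bin(mask).count("1")

    Q = np.zeros((1 << n, 1 << n))
    for m in masks:
        if m == 0:
            continue
        for k in range(n):
            if not m >> k & 1:
                Q[m, m | 1 << k] += gain_rate(m, k)
            elif e > 0:
                Q[m, m & ~(1 << k)] += e
        Q[m, m] = -Q[m].sum()

    def events(mask):
        size = bin(mask).count("1")
        singles_in = [1 << a for a in range(n) if mask >> a & 1]
        singles_out = [1 << a for a in range(n) if not mask >> a & 1]
        nj = []
        if size == 1:
            nj = [(mask, mask)]
        else:
            for s in singles_in:
                nj += [(s, mask), (mask, s)]
                rest = mask & ~s
                if (s, rest) not in nj:
                    nj += [(s, rest), (rest, s)]
        out = []
        jumps = [(mask, s) for s in singles_out] + \
                [(s, mask) for s in singles_out] if j > 0 else []
        wn = (1.0 - j) if jumps else 1.0
        out += [(l, r, wn / len(nj)) for l, r in nj]
        out += [(l, r, j / len(jumps)) for l, r in jumps]
        return out

    def partial(node):
        if node.is_leaf():
            vec = np.zeros(1 << n)
            vec[coding.mask(node.taxon.label)] = 1.0
            return vec
        left, right = node.child_nodes()
        pl = expm(Q * left.edge.length) @ partial(left)
        pr = expm(Q * right.edge.length) @ partial(right)
        vec = np.zeros(1 << n)
        for m in masks:
            if m == 0:
                continue
            vec[m] = sum(w * pl[l] * pr[r] for l, r, w in events(m))
        return vec

    root = partial(tree.seed_node)
    return float(np.log(np.mean([root[m] for m in masks if m != 0])))


class TestLikelihood:
    def test_frozen_cherry_equals_root_prior_mass(self):
        coding = mr.RangeCoding(areas=("A", "B"), ranges={"a": "A", "b": "A"})
        ll = mr.dec_loglik(_cherry(), coding, 0.0, 0.0)
        assert ll == pytest.approx(np.log(1.0 / 3.0), abs=1e-12)

    @pytest.mark.parametrize("d,e,j", [
        (0.05, 0.0, 0.0),
        (0.1, 0.03, 0.0),
        (0.5, 0.2, 0.0),
        (0.1, 0.02, 0.15),
    ])
    def test_matches_enumeration_oracle_on_two_area_trees(self, d, e, j):
        coding = mr.RangeCoding(areas=("A", "B"),
                                ranges={"a": "A", "b": "B", "c": "AB",
                                        "d": "B"})
        tree = dendropy.Tree.get(
            data="((a:1.0,b:2.0):1.5,(c:0.7,d:0.7):2.8);", schema="newick")
        got = mr.dec_loglik(tree, coding, d, e, j)
        want = _oracle_loglik(tree, coding, d, e, j)
        assert got == pytest.approx(want, abs=1e-8)

    def test_decj_at_zero_jump_equals_dec(self):
        tree = mr.simulate_tree(10, seed=2)
        h = mr.simulate_dec(tree, 0.2, 0.05, 0.0, ("A", "B", "C"), "B", seed=3)
        a = mr.dec_loglik(tree, h.coding, 0.1, 0.02, 0.0)
        b = mr.dec_loglik(tree, h.coding, 0.1, 0.02)
        assert a == pytest.approx(b, abs=1e-10)

    def test_invariant_to_consistent_area_relabeling(self):
        tree = _cherry(1.0, 2.0)
        c1 = mr.RangeCoding(areas=("A", "B"), ranges={"a": "A", "b": "AB"})
        c2 = mr.RangeCoding(areas=("B", "A"), ranges={"a": "B", "b": "BA"})
        assert mr.dec_loglik(tree, c1, 0.1, 0.02) == pytest.approx(
            mr.dec_loglik(tree, c2, 0.1, 0.02), abs=1e-12)

    def test_small_rate_expected_gain_limit(self):
        # P(single -> both areas) ~ d*t in the small d*t limit (e = 0)
        proc = mr.DECProcess(("A", "B"), d=0.002, e=0.0)
        Q = proc.rate_matrix()
        P = expm(Q * 5.0)  # d*t = 0.01
        i, k = proc.index[1], proc.index[3]
        assert P[i, k] == pytest.approx(0.01, rel=0.01)

    def test_oversized_tip_range_rejected(self):
        with pytest.raises(InvalidArgumentError):
            mr.RangeCoding(areas=("A", "B", "C"),
                           ranges={"a": "ABC"}, max_range_size=2)


class TestFitAndCompare:
    def test_aic_identity(self):
        fit = mr.DECFit(model="DEC", d=0.1, e=0.01, j=0.0,
                        lnL=-150.2872457, df=2)
        assert fit.aic == pytest.approx(2 * 2 - 2 * (-150.2872457), abs=1e-12)

    def test_compare_models_flags_near_ties(self):
        a = mr.DECFit("DEC", 0.1, 0.01, 0.0, lnL=-150.2872457, df=2,
                      data_key=("x",))
        b = mr.DECFit("DEC+j", 0.1, 0.01, 0.01, lnL=-149.2852047, df=3,
                      data_key=("x",))
        table = mr.compare_models([a, b])
        assert table["model"].iloc[0] == "DEC+j"
        assert table["dAIC"].iloc[1] == pytest.approx(0.0040819, abs=1e-6)
        assert table["indistinguishable"].all()
        # ranking invariant to a constant shift of both log-likelihoods
        a2 = mr.DECFit("DEC", 0.1, 0.01, 0.0, lnL=a.lnL + 7, df=2,
                       data_key=("x",))
        b2 = mr.DECFit("DEC+j", 0.1, 0.01, 0.01, lnL=b.lnL + 7, df=3,
                       data_key=("x",))
        assert list(mr.compare_models([a2, b2])["model"]) == \
            list(table["model"])

    def test_compare_requires_identical_data(self):
        a = mr.DECFit("DEC", 0.1, 0.01, 0.0, -10.0, 2, data_key=("x",))
        b = mr.DECFit("DEC+j", 0.1, 0.01, 0.0, -9.0, 3, data_key=("y",))
        with pytest.raises(InvalidArgumentError):
            mr.compare_models([a, b])

    def test_fit_recovers_rates_roughly(self):
        tree = mr.simulate_tree(40, seed=77)
        h = mr.simulate_dec(tree, 0.05, 0.0, 0.0, ("A", "B", "C", "D"), "B",
                            seed=78)
        fit = mr.fit_dec(tree, h.coding, "DEC")
        assert fit.converged
        assert 0.0 < fit.d < 0.5
        assert fit.aic == pytest.approx(2 * fit.df - 2 * fit.lnL)


class TestBSM:
    def test_no_movement_means_zero_dispersal(self):
        tree = mr.simulate_tree(6, seed=5)
        coding = mr.RangeCoding(
            areas=("A", "B"),
            ranges={l.taxon.label: "A" for l in tree.leaf_node_iter()})
        fit = mr.DECFit("DEC", d=0.0, e=0.0, j=0.0, lnL=0.0, df=2)
        s = mr.bsm(tree, coding, fit, n_maps=20, seed=1)
        assert (s.dispersal.to_numpy() == 0).all()
        assert (np.diag(s.dispersal.to_numpy()) == 0).all()

    def test_same_seed_identical_summary(self):
        tree = mr.simulate_tree(8, seed=6)
        h = mr.simulate_dec(tree, 0.15, 0.02, 0.0, ("A", "B", "C"), "B",
                            seed=7)
        fit = mr.DECFit("DEC", d=0.15, e=0.02, j=0.0, lnL=0.0, df=2)
        a = mr.bsm(tree, h.coding, fit, n_maps=25, seed=11)
        b = mr.bsm(tree, h.coding, fit, n_maps=25, seed=11)
        assert a.dispersal.equals(b.dispersal)
        assert a.event_totals == b.event_totals

    def test_conditional_counts_match_forward_truth(self):
        """Forward-simulated mean dispersal totals vs BSM conditional means.

        E[counts] over the forward process equals E over tip patterns of the
        conditional expectation BSM estimates; compare the total dispersal
        count (all area pairs pooled) within combined Monte-Carlo error.
        """
        areas = ("A", "B", "C")
        d, e = 0.12, 0.0
        tree = mr.simulate_tree(10, seed=8)
        fwd_counts, patterns = [], []
        for rep in range(150):
            h = mr.simulate_dec(tree, d, e, 0.0, areas, "B", seed=2000 + rep)
            fwd_counts.append(
                sum(1 for ev in h.events if ev["type"] == "dispersal"))
            patterns.append(h.coding)
        fwd = np.asarray(fwd_counts, float)
        fit = mr.DECFit("DEC", d=d, e=e, j=0.0, lnL=0.0, df=2, root_prior="B")
        bsm_means = []
        for i in range(0, 60):
            s = mr.bsm(tree, patterns[i], fit, n_maps=10, seed=3000 + i)
            bsm_means.append(s.dispersal.to_numpy().sum())
        bsm_arr = np.asarray(bsm_means)
        se = np.sqrt(fwd.var(ddof=1) / len(fwd)
                     + bsm_arr.var(ddof=1) / len(bsm_arr))
        assert abs(fwd.mean() - bsm_arr.mean()) < 2.5 * se
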