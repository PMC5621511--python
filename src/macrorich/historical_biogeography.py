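"""Dispersal–extinction–cladogenesis (DEC) range evolution on a dated tree.

The model follows the classic Lagrange parameterisation: a species range is a
non-empty subset of discrete areas; along branches areas are gained at rate
``d`` (per source area, optionally scaled by a dispersal multiplier matrix)
and lost at rate ``e``; at speciation the range is partitioned by one of the
allowed cladogenetic events (sympatric range copying for single-area ranges,
subset sympatry and single-area vicariance for widespread ranges).  The "+j"
extension adds founder-event jump speciation, in which one daughter starts in
a single area outside the ancestral range; ``j`` is the total probability
weight assigned to jump events at a node, split equally among destinations.

The module provides the likelihood (:func:`dec_loglik`), maximum-likelihood
fitting with AIC comparison (:func:`fit_dec`, :func:`compare_models`), and
biogeographic stochastic mapping (:func:`bsm`): sampling complete event
histories conditional on the tip ranges and fitted rates, summarised as a
source-area x destination-area matrix of mean dispersal-event counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import minimize

from .errors import (
    InvalidArgumentError,
    OptimizationError,
    SamplingError,
)

__all__ = [
    "RangeCoding",
    "DECProcess",
    "DECFit",
    "BSMSummary",
    "dec_loglik",
    "fit_dec",
    "bsm",
    "compare_models",
    "validate_tree",
]


# ---------------------------------------------------------------------------
# Range coding
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RangeCoding:
    """Tip-to-range assignment over an ordered area set.

    Parameters
    ----------
    areas:
        Ordered area labels, e.g. ``["A", "B", "C", "D"]``.  The order fixes
        the bitmask encoding of ranges.
    ranges:
        Mapping from tip label to its range, written as a string of area
        labels (``"B"``, ``"BC"`` ...).  Every range must be a non-empty
        subset of ``areas``.
    max_range_size:
        Largest allowed range; defaults to the number of areas
        (unconstrained).
    """

    areas: tuple
    ranges: Mapping[str, str]
    max_range_size: int | None = None

    def __post_init__(self):
        areas = tuple(self.areas)
        object.__setattr__(self, "areas", areas)
        if len(set(areas)) != len(areas) or not areas:
            raise InvalidArgumentError("areas must be a non-empty set of unique labels")
        mx = self.max_range_size if self.max_range_size is not None else len(areas)
        if not 1 <= mx <= len(areas):
            raise InvalidArgumentError("max_range_size out of range")
        object.__setattr__(self, "max_range_size", mx)
        for tip, rng in self.ranges.items():
            if not rng:
                raise InvalidArgumentError(f"tip {tip!r} has an empty range")
            extra = set(rng) - set(areas)
            if extra:
                raise InvalidArgumentError(f"tip {tip!r} uses unknown areas {sorted(extra)}")
            if len(set(rng)) > mx:
                raise InvalidArgumentError(
                    f"tip {tip!r} range {rng!r} exceeds max range size {mx}"
                )

    def mask(self, tip: str) -> int:
        """Bitmask of a tip's range (bit i set = occupies ``areas[i]``)."""
        return self.str_to_mask(self.ranges[tip])

    def str_to_mask(self, rng: str) -> int:
        m = 0
        for a in rng:
            m |= 1 << self.areas.index(a)
        return m

    def mask_to_str(self, mask: int) -> str:
        return "".join(a for i, a in enumerate(self.areas) if mask >> i & 1)


# ---------------------------------------------------------------------------
# The DEC process: state space, rate matrix, cladogenetic event set
# ---------------------------------------------------------------------------

class DECProcess:
    """State space and transition structure of a DEC(+j) process.

    States are ranges encoded as bitmasks over ``areas``; the absorbing empty
    range is kept internally (index 0) so that extinction of single-area
    ranges leaks probability correctly through the matrix exponential.
    """

    def __init__(self, areas: Sequence[str], d: float, e: float, j: float = 0.0,
                 max_range_size: int | None = None,
                 dispersal_matrix: np.ndarray | None = None):
        if d < 0 or e < 0 or j < 0:
            raise InvalidArgumentError("rates must be non-negative")
        if j >= 1:
            raise InvalidArgumentError("jump weight j must lie in [0, 1)")
        self.areas = tuple(areas)
        n = len(self.areas)
        self.n_areas = n
        self.d, self.e, self.j = float(d), float(e), float(j)
        self.max_range_size = max_range_size if max_range_size is not None else n
        if dispersal_matrix is None:
            dispersal_matrix = np.ones((n, n))
        self.dispersal = np.asarray(dispersal_matrix, dtype=float)
        if self.dispersal.shape != (n, n):
            raise InvalidArgumentError("dispersal matrix must be n_areas x n_areas")
        # states ordered: empty, then by (range size, bitmask)
        nonempty = [m for m in range(1, 1 << n) if bin(m).count("1") <= self.max_range_size]
        nonempty.sort(key=lambda m: (bin(m).count("1"), m))
        self.states = [0] + nonempty
        self.index = {m: i for i, m in enumerate(self.states)}
        self.n_states = len(self.states)
        self._clado_cache: dict[int, list] = {}

    # -- anagenesis ---------------------------------------------------------

    def gain_rates(self, mask: int) -> list[tuple[int, float]]:
        """(area index, rate) pairs for areas that can be added to ``mask``."""
        out = []
        if mask == 0:
            return out
        size = bin(mask).count("1")
        if size >= self.max_range_size:
            return out
        occupied = [i for i in range(self.n_areas) if mask >> i & 1]
        for k in range(self.n_areas):
            if mask >> k & 1:
                continue
            rate = self.d * sum(self.dispersal[l, k] for l in occupied)
            if rate > 0:
                out.append((k, rate))
        return out

    def loss_rates(self, mask: int) -> list[tuple[int, float]]:
        if self.e == 0 or mask == 0:
            return []
        return [(a, self.e) for a in range(self.n_areas) if mask >> a & 1]

    def rate_matrix(self) -> np.ndarray:
        """Dense generator over the full state space (empty state absorbing)."""
        Q = np.zeros((self.n_states, self.n_states))
        for i, mask in enumerate(self.states):
            for k, r in self.gain_rates(mask):
                Q[i, self.index[mask | (1 << k)]] += r
            for a, r in self.loss_rates(mask):
                Q[i, self.index[mask & ~(1 << a)]] += r
            Q[i, i] = -Q[i].sum()
        return Q

    # -- cladogenesis -------------------------------------------------------

    def clado_events(self, mask: int) -> list[tuple[int, int, str, float]]:
        """Allowed cladogenetic events for an ancestral range.

        Returns ``(left_mask, right_mask, kind, weight)`` tuples over ordered
        daughter pairs; weights sum to 1.  Non-jump events share weight
        ``1 - j`` equally; jump events share ``j`` equally (pure DEC when
        ``j == 0``).
        """
        if mask in self._clado_cache:
            return self._clado_cache[mask]
        if mask == 0:
            return []
        size = bin(mask).count("1")
        singles_in = [1 << a for a in range(self.n_areas) if mask >> a & 1]
        singles_out = [1 << a for a in range(self.n_areas) if not mask >> a & 1]
        nonjump: list[tuple[int, int, str]] = []
        if size == 1:
            nonjump.append((mask, mask, "sympatry"))
        else:
            for s in singles_in:
                nonjump.append((s, mask, "subset"))
                nonjump.append((mask, s, "subset"))
                rest = mask & ~s
                nonjump.append((s, rest, "vicariance"))
                nonjump.append((rest, s, "vicariance"))
            # for 2-area ranges each ordered vicariance split arises twice
            nonjump = list(dict.fromkeys(nonjump))
        jumps: list[tuple[int, int, str]] = []
        if self.j > 0:
            for s in singles_out:
                jumps.append((mask, s, "jump"))
                jumps.append((s, mask, "jump"))
        events: list[tuple[int, int, str, float]] = []
        w_nonjump = (1.0 - self.j) if jumps else 1.0
        for l, r, kind in nonjump:
            events.append((l, r, kind, w_nonjump / len(nonjump)))
        for l, r, kind in jumps:
            events.append((l, r, kind, self.j / len(jumps)))
        self._clado_cache[mask] = events
        return events


# ---------------------------------------------------------------------------
# Tree utilities
# ---------------------------------------------------------------------------

def validate_tree(tree: dendropy.Tree, ultrametric_tol: float = 1e-4) -> None:
    """Check a dated tree: bifurcating, positive branch lengths.

    Warns (does not fail) if tip depths differ by more than ``ultrametric_tol``
    relative to the maximum depth, since DEC is usually run on dated trees.
    """
    leaves = tree.leaf_nodes()
    if len(leaves) < 2:
        raise InvalidArgumentError("tree must have at least two tips")
    for node in tree.preorder_node_iter():
        children = node.child_nodes()
        if children and len(children) != 2:
            raise InvalidArgumentError("tree must be strictly bifurcating")
        if node.parent_node is not None:
            if node.edge.length is None or node.edge.length <= 0:
                raise InvalidArgumentError("all branch lengths must be positive")
    depths = [leaf.distance_from_root() for leaf in leaves]
    span = max(depths)
    if span <= 0:
        raise InvalidArgumentError("zero-length tree")
    if (max(depths) - min(depths)) / span > ultrametric_tol:
        warnings.warn("tree is not ultrametric; treating branch lengths as given",
                      stacklevel=2)


def _tip_label(leaf: dendropy.Node) -> str:
    return leaf.taxon.label if leaf.taxon is not None else str(leaf.label)


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

def _branch_propagators(Q: np.ndarray, lengths: Sequence[float]) -> dict[float, np.ndarray]:
    """exp(Q t) for each distinct branch length.

    Uses one eigendecomposition of ``Q`` reused across branches, falling back
    to scipy's expm when the eigenbasis is ill-conditioned.
    """
    uniq = sorted(set(float(t) for t in lengths))
    out: dict[float, np.ndarray] = {}
    try:
        w, V = np.linalg.eig(Q)
        Vinv = np.linalg.inv(V)
        cond = np.linalg.cond(V)
    except np.linalg.LinAlgError:
        cond = np.inf
    if np.isfinite(cond) and cond < 1e8:
        for t in uniq:
            P = (V * np.exp(w * t)) @ Vinv
            P = np.real(P)
            np.clip(P, 0.0, None, out=P)
            out[t] = P
    else:
        for t in uniq:
            P = expm(Q * t)
            np.clip(P, 0.0, None, out=P)
            out[t] = P
    return out


def _root_prior_vector(proc: DECProcess, coding: RangeCoding, root_prior) -> np.ndarray:
    pi = np.zeros(proc.n_states)
    if root_prior == "uniform":
        pi[1:] = 1.0 / (proc.n_states - 1)
    else:
        mask = coding.str_to_mask(str(root_prior))
        if mask == 0 or mask not in proc.index:
            raise InvalidArgumentError(f"invalid root range {root_prior!r}")
        pi[proc.index[mask]] = 1.0
    return pi


def _postorder_partials(tree, proc: DECProcess, coding: RangeCoding,
                        props: dict[float, np.ndarray]):
    """Conditional likelihood vectors D_v(s) at every node, log-scaled.

    Returns (partials dict node->vector, total log scaling factor).
    """
    partials: dict = {}
    log_scale = 0.0
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            vec = np.zeros(proc.n_states)
            vec[proc.index[coding.mask(_tip_label(node))]] = 1.0
            partials[node] = vec
            continue
        left, right = node.child_nodes()
        ml = props[float(left.edge.length)] @ partials[left]
        mr = props[float(right.edge.length)] @ partials[right]
        vec = np.zeros(proc.n_states)
        for i, mask in enumerate(proc.states):
            if mask == 0:
                continue
            acc = 0.0
            for lm, rm, _kind, w in proc.clado_events(mask):
                acc += w * ml[proc.index[lm]] * mr[proc.index[rm]]
            vec[i] = acc
        top = vec.max()
        if top <= 0:
            return None, -np.inf
        vec /= top
        log_scale += np.log(top)
        partials[node] = vec
    return partials, log_scale


def dec_loglik(tree: dendropy.Tree, coding: RangeCoding, d: float, e: float,
               j: float = 0.0, dispersal_matrix: np.ndarray | None = None,
               root_prior="uniform") -> float:
    """Log-likelihood of tip ranges under DEC (``j = 0``) or DEC+j.

    Felsenstein pruning over the range state space: anagenetic transitions
    through exp(Qt) per branch, cladogenetic mixing at each internal node over
    the allowed event set, and a root prior that is uniform over allowed
    non-empty ranges by default (pass an area string to condition on a fixed
    root range).
    """
    validate_tree(tree)
    proc = DECProcess(coding.areas, d, e, j, coding.max_range_size, dispersal_matrix)
    for leaf in tree.leaf_node_iter():
        label = _tip_label(leaf)
        if label not in coding.ranges:
            raise InvalidArgumentError(f"tip {label!r} missing from the range coding")
    Q = proc.rate_matrix()
    lengths = [nd.edge.length for nd in tree.preorder_node_iter() if nd.parent_node]
    props = _branch_propagators(Q, lengths)
    partials, log_scale = _postorder_partials(tree, proc, coding, props)
    if partials is None:
        return -np.inf
    pi = _root_prior_vector(proc, coding, root_prior)
    root_mass = float(pi @ partials[tree.seed_node])
    if root_mass <= 0:
        return -np.inf
    return float(np.log(root_mass) + log_scale)


# ---------------------------------------------------------------------------
# Fitting and model comparison
# ---------------------------------------------------------------------------

@dataclass
class DECFit:
    """Maximum-likelihood DEC fit. ``aic`` always equals ``2*df - 2*lnL``."""

    model: str
    d: float
    e: float
    j: float
    lnL: float
    df: int
    converged: bool = True
    root_prior: object = "uniform"
    data_key: tuple = field(default=(), repr=False)

    @property
    def aic(self) -> float:
        return 2.0 * self.df - 2.0 * self.lnL


def _data_key(tree: dendropy.Tree, coding: RangeCoding) -> tuple:
    tips = tuple(sorted((_tip_label(l), coding.ranges[_tip_label(l)])
                        for l in tree.leaf_node_iter()))
    lengths = tuple(round(float(nd.edge.length), 12)
                    for nd in tree.preorder_node_iter() if nd.parent_node)
    return tips, lengths, coding.areas


def fit_dec(tree: dendropy.Tree, coding: RangeCoding, model: str = "DEC",
            dispersal_matrix: np.ndarray | None = None, root_prior="uniform",
            rate_bound: float = 10.0, x0: Sequence[float] | None = None) -> DECFit:
    """Fit DEC or DEC+j by bounded maximum likelihood.

    ``df`` is 2 for DEC (d, e) and 3 for DEC+j; ``aic = 2*df - 2*lnL``.
    """
    model = model.upper().replace(" ", "")
    if model not in {"DEC", "DEC+J", "DECJ"}:
        raise InvalidArgumentError(f"unknown model {model!r}")
    with_j = model != "DEC"
    tag = "DEC+j" if with_j else "DEC"

    def nll(x):
        d, e = x[0], x[1]
        j = x[2] if with_j else 0.0
        ll = dec_loglik(tree, coding, d, e, j,
                        dispersal_matrix=dispersal_matrix, root_prior=root_prior)
        return -ll if np.isfinite(ll) else 1e10

    lo = 1e-12
    bounds = [(lo, rate_bound), (lo, rate_bound)] + ([(0.0, 0.999)] if with_j else [])
    starts = [x0] if x0 is not None else [
        [0.01, 0.01] + ([0.01] if with_j else []),
        [0.1, 0.001] + ([0.1] if with_j else []),
    ]
    best = None
    for s in starts:
        res = minimize(nll, np.asarray(s, dtype=float), method="L-BFGS-B",
                       bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e9:
        raise OptimizationError("DEC likelihood optimization failed")
    d, e = float(best.x[0]), float(best.x[1])
    j = float(best.x[2]) if with_j else 0.0
    return DECFit(model=tag, d=d, e=e, j=j, lnL=-float(best.fun),
                  df=3 if with_j else 2, converged=bool(best.success),
                  root_prior=root_prior, data_key=_data_key(tree, coding))


def compare_models(fits: Sequence[DECFit], tie_threshold: float = 2.0) -> pd.DataFrame:
    """AIC model-comparison table; ΔAIC < ``tie_threshold`` flagged as ties."""
    if not fits:
        raise InvalidArgumentError("no fits to compare")
    keys = {f.data_key for f in fits}
    if len(keys) > 1:
        raise InvalidArgumentError("fits were computed on different data")
    rows = [{"model": f.model, "lnL": f.lnL, "df": f.df, "d": f.d, "e": f.e,
             "j": f.j, "AIC": f.aic} for f in fits]
    table = pd.DataFrame(rows).sort_values("AIC", kind="stable").reset_index(drop=True)
    table["dAIC"] = table["AIC"] - table["AIC"].iloc[0]
    table["indistinguishable"] = table["dAIC"] < tie_threshold
    return table


# ---------------------------------------------------------------------------
# Biogeographic stochastic mapping
# ---------------------------------------------------------------------------

@dataclass
class BSMSummary:
    """Mean event counts over stochastic maps.

    ``dispersal`` holds anagenetic range-expansion counts (source area x
    destination area; a gain from a multi-area range is split equally among
    its source areas).  ``jump`` holds cladogenetic founder-event counts in
    the same shape.  ``event_totals`` gives the mean count per event type.
    """

    areas: tuple
    dispersal: pd.DataFrame
    jump: pd.DataFrame
    event_totals: dict
    n_maps: int
    seed: int | None


def _sample_endpoint_path(Q, R, mu, Rpows, x, y, t, p_xy, rng,
                          max_jumps=2048, retries=100):
    """Endpoint-conditioned CTMC path via uniformization.

    Returns the list of (time, from_state, to_state) real transitions on
    (0, t) for a chain starting in state index ``x`` and ending in ``y``.
    """
    if mu == 0.0:
        if x != y:
            raise SamplingError("no transitions possible but endpoints differ")
        return []
    for _ in range(retries):
        # number of virtual jumps
        u = rng.random()
        log_pois = -mu * t
        pois = np.exp(log_pois)
        cum = 0.0
        n = None
        k = 0
        while k < max_jumps:
            while len(Rpows) <= k:
                Rpows.append(Rpows[-1] @ R)
            prob = pois * Rpows[k][x, y] / p_xy
            cum += prob
            if cum >= u:
                n = k
                break
            k += 1
            pois *= mu * t / k
        if n is None:
            continue
        # jump chain states
        states = [x]
        ok = True
        for i in range(1, n):
            a = states[-1]
            w = R[a, :] * Rpows[n - i][:, y]
            tot = w.sum()
            if tot <= 0:
                ok = False
                break
            states.append(int(rng.choice(len(w), p=w / tot)))
        if not ok:
            continue
        if n >= 1:
            if R[states[-1], y] <= 0:
                continue
            states.append(y)
        times = np.sort(rng.random(n)) * t
        path = [(float(times[i]), states[i], states[i + 1])
                for i in range(n) if states[i] != states[i + 1]]
        return path
    raise SamplingError("endpoint-conditioned path sampling exceeded the retry cap")


def bsm(tree: dendropy.Tree, coding: RangeCoding, fit: DECFit, n_maps: int = 1000,
        seed: int | None = None, dispersal_matrix: np.ndarray | None = None) -> BSMSummary:
    """Biogeographic stochastic mapping under a fitted DEC(+j) model.

    Samples ``n_maps`` complete histories conditional on the tip ranges:
    joint node states drawn from conditional-likelihood-weighted
    distributions, branch histories by uniformization between endpoints.
    Anagenetic dispersal and cladogenetic jump events are counted separately
    by (source area, destination area).
    """
    if n_maps < 1:
        raise InvalidArgumentError("n_maps must be >= 1")
    validate_tree(tree)
    proc = DECProcess(coding.areas, fit.d, fit.e, fit.j,
                      coding.max_range_size, dispersal_matrix)
    Q = proc.rate_matrix()
    lengths = [nd.edge.length for nd in tree.preorder_node_iter() if nd.parent_node]
    props = _branch_propagators(Q, lengths)
    partials, _ = _postorder_partials(tree, proc, coding, props)
    if partials is None:
        raise SamplingError("data have zero likelihood under the fitted model")
    pi = _root_prior_vector(proc, coding, fit.root_prior)
    rng = np.random.default_rng(seed)

    mu = float(np.max(-np.diag(Q)))
    R = np.eye(proc.n_states) + (Q / mu if mu > 0 else 0.0)
    Rpows = [np.eye(proc.n_states)]

    n_areas = proc.n_areas
    size = np.array([bin(m).count("1") for m in proc.states])
    disp_sum = np.zeros((n_areas, n_areas))
    jump_sum = np.zeros((n_areas, n_areas))
    totals: dict[str, float] = {}

    def count_gain(src_mask, gained_area, mat):
        srcs = [i for i in range(n_areas) if src_mask >> i & 1]
        for s in srcs:
            mat[s, gained_area] += 1.0 / len(srcs)

    for _ in range(n_maps):
        disp = np.zeros((n_areas, n_areas))
        jmp = np.zeros((n_areas, n_areas))
        counts: dict[str, float] = {}

        def draw(weights):
            w = np.asarray(weights, dtype=float)
            tot = w.sum()
            if tot <= 0:
                raise SamplingError("degenerate conditional distribution in BSM")
            return int(rng.choice(len(w), p=w / tot))

        # root state
        root = tree.seed_node
        root_state = draw(pi * partials[root])
        stack = [(root, root_state)]
        while stack:
            node, s_idx = stack.pop()
            mask = proc.states[s_idx]
            events = proc.clado_events(mask)
            left, right = node.child_nodes()
            ml = props[float(left.edge.length)] @ partials[left]
            mr = props[float(right.edge.length)] @ partials[right]
            w = [wt * ml[proc.index[lm]] * mr[proc.index[rm]]
                 for lm, rm, _k, wt in events]
            lm, rm, kind, _wt = events[draw(w)]
            counts[kind] = counts.get(kind, 0.0) + 1.0
            if kind == "jump":
                single = lm if size[proc.index[lm]] == 1 and lm & ~mask else rm
                area = int(np.log2(single))
                count_gain(mask, area, jmp)
            for child, start_mask in ((left, lm), (right, rm)):
                x = proc.index[start_mask]
                t = float(child.edge.length)
                P = props[t]
                if child.is_leaf():
                    y = proc.index[coding.mask(_tip_label(child))]
                else:
                    y = draw(P[x] * partials[child])
                path = _sample_endpoint_path(Q, R, mu, Rpows, x, y, t,
                                             P[x, y], rng)
                for _tm, a, b in path:
                    ma, mb = proc.states[a], proc.states[b]
                    if size[b] > size[a]:
                        gained = int(np.log2(mb & ~ma))
                        count_gain(ma, gained, disp)
                        counts["dispersal"] = counts.get("dispersal", 0.0) + 1.0
                    else:
                        counts["local_extinction"] = counts.get("local_extinction", 0.0) + 1.0
                if not child.is_leaf():
                    stack.append((child, y))
        disp_sum += disp
        jump_sum += jmp
        for k, v in counts.items():
            totals[k] = totals.get(k, 0.0) + v

    labels = list(proc.areas)
    return BSMSummary(
        areas=proc.areas,
        dispersal=pd.DataFrame(disp_sum / n_maps, index=labels, columns=labels),
        jump=pd.DataFrame(jump_sum / n_maps, index=labels, columns=labels),
        event_totals={k: v / n_maps for k, v in sorted(totals.items())},
        n_maps=n_maps,
        seed=seed,
    )
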