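"""Probabilistic hotspot delineation on gridded species richness.

The protocol: (1) test for global spatial autocorrelation with Moran's I;
(2) score every cell with the self-inclusive Getis-Ord Gi* statistic, which
compares the value sum in a cell-plus-neighbourhood against the global mean;
(3) flag cells whose Gi* Z score stays significantly positive after multiple
-testing correction and label queen-connected components of flagged cells as
hotspots (significant negative cells are coldspots, reported separately).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, sparse, stats

from .errors import (
    DegenerateWeightsError,
    InvalidArgumentError,
    UndefinedStatisticError,
)
from .grid_assembly import RichnessGrid

__all__ = [
    "SpatialWeights",
    "MoranResult",
    "HotspotResult",
    "build_weights",
    "morans_i",
    "getis_ord_gstar",
    "delineate_hotspots",
]

_QUEEN = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
_ROOK = [(-1, 0), (1, 0), (0, -1), (0, 1)]


@dataclass
class SpatialWeights:
    """Sparse contiguity weights over the valid cells of a grid.

    ``cell_ids`` are flat row-major indices into the source grid, in
    deterministic ascending order; ``W[i, j]`` is the weight from
    ``cell_ids[i]`` to ``cell_ids[j]``.
    """

    W: sparse.csr_matrix
    cell_ids: np.ndarray
    shape: tuple
    scheme: str
    row_standardized: bool
    include_self: bool
    islands: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def n(self) -> int:
        return len(self.cell_ids)

    def to_grid(self, values: np.ndarray, fill=np.nan) -> np.ndarray:
        """Scatter a vector over valid cells back onto the 2-D grid."""
        out = np.full(self.shape, fill, dtype=float)
        out.flat[self.cell_ids] = values
        return out


def build_weights(grid, scheme: str = "queen", row_standardize: bool = False,
                  include_self: bool = False) -> SpatialWeights:
    """Queen or rook contiguity weights on the valid cells of a grid.

    ``grid`` may be a :class:`RichnessGrid` or a boolean mask.  Weights are
    binary before optional row standardization; ``include_self`` adds a unit
    self-weight (required for Gi*).  Valid cells without any valid neighbour
    are kept but recorded in ``islands``.
    """
    mask = grid.valid if isinstance(grid, RichnessGrid) else np.asarray(grid, bool)
    if mask.ndim != 2:
        raise InvalidArgumentError("grid mask must be 2-D")
    if scheme not in {"queen", "rook"}:
        raise InvalidArgumentError(f"unknown contiguity scheme {scheme!r}")
    cell_ids = np.flatnonzero(mask.ravel())
    n = len(cell_ids)
    if n == 0:
        raise InvalidArgumentError("valid mask is empty")
    if n == 1:
        raise DegenerateWeightsError("cannot build weights for a single valid cell")
    rows_, cols_ = mask.shape
    pos = {int(c): i for i, c in enumerate(cell_ids)}
    offsets = _QUEEN if scheme == "queen" else _ROOK
    ii, jj = [], []
    for i, c in enumerate(cell_ids):
        r, q = divmod(int(c), cols_)
        for dr, dc in offsets:
            nr, nc = r + dr, q + dc
            if 0 <= nr < rows_ and 0 <= nc < cols_:
                k = pos.get(nr * cols_ + nc)
                if k is not None:
                    ii.append(i)
                    jj.append(k)
    W = sparse.csr_matrix((np.ones(len(ii)), (ii, jj)), shape=(n, n))
    islands = np.flatnonzero(np.asarray(W.sum(axis=1)).ravel() == 0)
    if include_self:
        W = W + sparse.eye(n, format="csr")
    if row_standardize:
        rs = np.asarray(W.sum(axis=1)).ravel()
        rs[rs == 0] = 1.0
        W = sparse.diags(1.0 / rs) @ W
    return SpatialWeights(W=W.tocsr(), cell_ids=cell_ids, shape=mask.shape,
                          scheme=scheme, row_standardized=row_standardize,
                          include_self=include_self, islands=islands)


def _aligned_values(values, weights: SpatialWeights) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    if v.ndim == 2:
        if v.shape != weights.shape:
            raise InvalidArgumentError("value grid shape does not match weights")
        v = v.ravel()[weights.cell_ids]
    elif v.shape != (weights.n,):
        raise InvalidArgumentError("values must align with the weights' cells")
    if not np.isfinite(v).all():
        raise InvalidArgumentError("values must be finite")
    return v


@dataclass
class MoranResult:
    I: float
    expected: float
    z: float
    p: float
    inference: str
    n_perm: int | None = None


def morans_i(values, weights: SpatialWeights, inference: str = "normal",
             n_perm: int = 999, seed: int | None = None) -> MoranResult:
    """Global Moran's I with normality-based or permutation inference.

    I = (n / S0) * sum_ij w_ij z_i z_j / sum_i z_i^2 with centred values;
    E[I] = -1/(n-1).  Under ``inference="normal"`` the Z score uses the
    classic normality variance; ``"permutation"`` compares I against values
    shuffled over cells (one-tailed in the observed direction, +1 corrected).
    """
    x = _aligned_values(values, weights)
    n = len(x)
    z = x - x.mean()
    denom = float(z @ z)
    if denom == 0.0:
        raise UndefinedStatisticError("Moran's I undefined for constant values")
    W = weights.W
    s0 = float(W.sum())
    if s0 == 0:
        raise DegenerateWeightsError("weights sum to zero")
    num = float(z @ (W @ z))
    I = n / s0 * num / denom
    eI = -1.0 / (n - 1)
    if inference == "normal":
        Wd = W + W.T
        s1 = 0.5 * float(Wd.multiply(Wd).sum())
        rt = np.asarray(W.sum(axis=1)).ravel() + np.asarray(W.sum(axis=0)).ravel()
        s2 = float((rt ** 2).sum())
        var = (n * n * s1 - n * s2 + 3 * s0 * s0) / (s0 * s0 * (n * n - 1)) - eI ** 2
        zscore = (I - eI) / np.sqrt(var)
        p = float(2 * stats.norm.sf(abs(zscore)))
        return MoranResult(I=I, expected=eI, z=zscore, p=p, inference="normal")
    if inference == "permutation":
        rng = np.random.default_rng(seed)
        sims = np.empty(n_perm)
        for b in range(n_perm):
            zp = rng.permutation(z)
            sims[b] = n / s0 * float(zp @ (W @ zp)) / denom
        if I >= eI:
            extreme = int((sims >= I).sum())
        else:
            extreme = int((sims <= I).sum())
        p = (extreme + 1) / (n_perm + 1)
        sd = sims.std()
        zscore = (I - sims.mean()) / sd if sd > 0 else np.nan
        return MoranResult(I=I, expected=eI, z=float(zscore), p=float(p),
                           inference="permutation", n_perm=n_perm)
    raise InvalidArgumentError(f"unknown inference {inference!r}")


def getis_ord_gstar(values, weights: SpatialWeights) -> np.ndarray:
    """Per-cell Gi* Z scores (self-inclusive Getis-Ord local statistic).

    Z_i = (sum_j w_ij x_j - Xbar W_i) /
          (S * sqrt((n * sum_j w_ij^2 - W_i^2) / (n - 1)))
    with Xbar and S the global (population) mean and standard deviation and
    W_i = sum_j w_ij.  Requires self-inclusive weights and n >= 3.
    """
    if not weights.include_self:
        raise InvalidArgumentError("Gi* requires self-inclusive weights")
    x = _aligned_values(values, weights)
    n = len(x)
    if n < 3:
        raise InvalidArgumentError("Gi* requires at least 3 cells")
    xbar = x.mean()
    s = np.sqrt((x ** 2).mean() - xbar ** 2)
    if s == 0.0:
        raise UndefinedStatisticError("Gi* undefined for constant values")
    W = weights.W
    wi = np.asarray(W.sum(axis=1)).ravel()
    wi2 = np.asarray(W.multiply(W).sum(axis=1)).ravel()
    local = W @ x
    denom = s * np.sqrt((n * wi2 - wi ** 2) / (n - 1))
    with np.errstate(invalid="ignore", divide="ignore"):
        zi = (local - xbar * wi) / denom
    return zi


@dataclass
class HotspotResult:
    """Delineated hot/cold clusters of Gi* scores.

    ``z_grid``/``p_grid`` are 2-D surfaces (NaN outside valid cells);
    ``hot_labels``/``cold_labels`` hold positive integer cluster ids (0 =
    unflagged); ``clusters`` is a per-cluster table with cell counts and
    max/mean Z.  ``excluded`` lists valid cells excluded from inference
    (no-neighbour islands).
    """

    z_grid: np.ndarray
    p_grid: np.ndarray
    significant: np.ndarray
    hot_labels: np.ndarray
    cold_labels: np.ndarray
    clusters: pd.DataFrame
    alpha: float
    correction: str
    excluded: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


def _bh_reject(p: np.ndarray, alpha: float) -> np.ndarray:
    m = len(p)
    order = np.argsort(p, kind="stable")
    thresh = alpha * (np.arange(1, m + 1)) / m
    passed = p[order] <= thresh
    reject = np.zeros(m, dtype=bool)
    if passed.any():
        kmax = np.max(np.flatnonzero(passed))
        reject[order[: kmax + 1]] = True
    return reject


def delineate_hotspots(z, weights: SpatialWeights, alpha: float = 0.05,
                       correction: str = "fdr") -> HotspotResult:
    """Flag significant Gi* cells and label queen-connected clusters.

    ``z`` is the Gi* vector over the weights' cells (or a 2-D grid).
    Two-sided normal p-values are corrected with Benjamini-Hochberg FDR
    (``correction="fdr"``) or used raw (``"none"``); cells with corrected-
    significant Z > 0 form hotspots, Z < 0 coldspots.  No-neighbour islands
    are excluded from inference and reported.
    """
    if correction not in {"fdr", "none"}:
        raise InvalidArgumentError(f"unknown correction {correction!r}")
    zv = np.asarray(z, dtype=float)
    if zv.ndim == 2:
        zv = zv.ravel()[weights.cell_ids]
    if not np.isfinite(zv).all():
        raise InvalidArgumentError("Z scores must be finite")
    keep = np.ones(weights.n, dtype=bool)
    keep[weights.islands] = False
    p = 2 * stats.norm.sf(np.abs(zv))
    sig = np.zeros(weights.n, dtype=bool)
    if keep.any():
        if correction == "fdr":
            sig[keep] = _bh_reject(p[keep], alpha)
        else:
            sig[keep] = p[keep] <= alpha
    struct = np.ones((3, 3), dtype=int)  # queen connectivity

    def label(mask_vec):
        grid = np.zeros(weights.shape, dtype=bool)
        grid.flat[weights.cell_ids[mask_vec]] = True
        labels, _ = ndimage.label(grid, structure=struct)
        return labels

    hot = label(sig & (zv > 0))
    cold = label(sig & (zv < 0))
    zgrid = weights.to_grid(zv)
    rows = []
    for kind, lab in (("hot", hot), ("cold", cold)):
        for cid in range(1, lab.max() + 1):
            cz = zgrid[lab == cid]
            rows.append({"kind": kind, "cluster": cid, "n_cells": int(cz.size),
                         "max_z": float(np.nanmax(cz)) if kind == "hot"
                         else float(np.nanmin(cz)),
                         "mean_z": float(np.nanmean(cz))})
    clusters = pd.DataFrame(rows, columns=["kind", "cluster", "n_cells",
                                           "max_z", "mean_z"])
    return HotspotResult(z_grid=zgrid, p_grid=weights.to_grid(p),
                         significant=weights.to_grid(sig.astype(float)) == 1.0,
                         hot_labels=hot, cold_labels=cold, clusters=clusters,
                         alpha=alpha, correction=correction,
                         excluded=weights.cell_ids[weights.islands])
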