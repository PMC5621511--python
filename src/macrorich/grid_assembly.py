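"""Richness grids and presence–absence matrices from rasterized ranges.

Species richness is the per-cell count of overlapping ranges; the
presence–absence matrix keeps one column per cell with at least one record
(sites without records are excluded, matching how community matrices are
assembled from range maps).  ``regrid`` aggregates occupancy to coarser
resolutions by any-presence per species before recounting richness, and
``kappa_compare`` scores the agreement between two richness maps with
Cohen's kappa over binned richness classes.

Grid convention: origin at the north-west corner, row-major, 0-based cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import cohen_kappa_score

from .errors import EmptyResultError, InvalidArgumentError
from .synthetic_data import RangeSet

__all__ = [
    "RichnessGrid",
    "PresenceAbsenceMatrix",
    "stack_richness",
    "build_matrix",
    "regrid",
    "kappa_compare",
]


@dataclass
class RichnessGrid:
    """Per-cell species counts with a valid mask (cells holding >= 1 record)."""

    richness: np.ndarray
    cell_size: float = 1.0
    valid: np.ndarray | None = None

    def __post_init__(self):
        self.richness = np.asarray(self.richness, dtype=int)
        if self.richness.ndim != 2:
            raise InvalidArgumentError("richness must be a 2-D grid")
        if (self.richness < 0).any():
            raise InvalidArgumentError("richness must be non-negative")
        if self.valid is None:
            self.valid = self.richness > 0
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.shape != self.richness.shape:
            raise InvalidArgumentError("valid mask shape mismatch")

    @property
    def shape(self) -> tuple:
        return self.richness.shape


@dataclass
class PresenceAbsenceMatrix:
    """Species x sites 0/1 matrix; columns are occupied grid cells.

    ``site_labels`` are ``"r{row}c{col}"`` cell identifiers on the source
    grid; ``provenance`` records the grid shape and resolution.
    """

    matrix: np.ndarray
    species: list
    site_labels: list
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix)
        if not np.isin(self.matrix, (0, 1)).all():
            raise InvalidArgumentError("matrix entries must be 0/1")
        self.matrix = self.matrix.astype(int)
        if self.matrix.shape != (len(self.species), len(self.site_labels)):
            raise InvalidArgumentError("matrix shape does not match labels")
        if self.matrix.shape[1] and (self.matrix.sum(axis=0) == 0).any():
            raise InvalidArgumentError("all-zero site columns are not allowed")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.species, columns=self.site_labels)


def stack_richness(ranges: RangeSet, cell_size: float | None = None) -> RichnessGrid:
    """Overlap ranges into a richness grid (per-cell count of species)."""
    if ranges.occupancy.shape[0] == 0:
        raise InvalidArgumentError("RangeSet is empty")
    richness = ranges.occupancy.sum(axis=0).astype(int)
    return RichnessGrid(richness=richness,
                        cell_size=cell_size or ranges.cell_size)


def build_matrix(ranges: RangeSet, cell_size: float | None = None,
                 drop_empty: bool = True) -> PresenceAbsenceMatrix:
    """Species x sites matrix over grid cells, keeping occupied cells only."""
    occ = ranges.occupancy
    rows, cols = occ.shape[1:]
    flat = occ.reshape(occ.shape[0], -1)
    occupied = flat.any(axis=0)
    if drop_empty:
        keep = np.flatnonzero(occupied)
    else:
        keep = np.arange(flat.shape[1])
    if occupied.sum() == 0:
        raise EmptyResultError("no occupied cells")
    labels = [f"r{i // cols}c{i % cols}" for i in keep]
    return PresenceAbsenceMatrix(
        matrix=flat[:, keep].astype(int),
        species=list(ranges.species_ids),
        site_labels=labels,
        provenance={"shape": (rows, cols),
                    "cell_size": cell_size or ranges.cell_size,
                    "drop_empty": drop_empty},
    )


def regrid(ranges: RangeSet, new_cell_size: float) -> RichnessGrid:
    """Aggregate to a coarser grid and recount richness.

    Each species is first aggregated by any-presence within every coarse
    cell (a coarse cell is occupied if any of its fine cells is), then
    richness is recomputed — never by summing fine-cell richness.  The new
    cell size must be an integer multiple of the base resolution; trailing
    partial blocks at the south/east edges form their own (smaller) cells.
    """
    ratio = new_cell_size / ranges.cell_size
    factor = int(round(ratio))
    if factor < 1 or abs(ratio - factor) > 1e-9:
        raise InvalidArgumentError(
            f"new cell size {new_cell_size} is not an integer multiple of "
            f"the base resolution {ranges.cell_size}")
    if factor == 1:
        return stack_richness(ranges)
    occ = ranges.occupancy
    s, rows, cols = occ.shape
    cr = -(-rows // factor)
    cc = -(-cols // factor)
    coarse = np.zeros((s, cr, cc), dtype=bool)
    for bi in range(cr):
        for bj in range(cc):
            block = occ[:, bi * factor:(bi + 1) * factor,
                        bj * factor:(bj + 1) * factor]
            coarse[:, bi, bj] = block.any(axis=(1, 2))
    richness = coarse.sum(axis=0).astype(int)
    return RichnessGrid(richness=richness, cell_size=new_cell_size)


def kappa_compare(map_a: RichnessGrid, map_b: RichnessGrid,
                  n_classes: int = 10) -> float:
    """Cohen's kappa between two richness maps over binned richness classes.

    Both maps are binned into ``n_classes`` equal-width classes spanning the
    joint richness range of their shared valid cells; kappa is computed over
    per-cell class labels.  1 means total agreement, values near 0 chance
    agreement, negative values systematic disagreement.
    """
    if map_a.shape != map_b.shape:
        raise InvalidArgumentError("maps must share a common grid")
    if n_classes < 2:
        raise InvalidArgumentError("n_classes must be >= 2")
    both = map_a.valid & map_b.valid
    if not both.any():
        raise InvalidArgumentError("maps have disjoint valid masks")
    a = map_a.richness[both].astype(float)
    b = map_b.richness[both].astype(float)
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    if hi == lo:
        # single joint class: agreement is total by construction
        return 1.0
    edges = np.linspace(lo, hi, n_classes + 1)
    la = np.clip(np.digitize(a, edges[1:-1], right=True), 0, n_classes - 1)
    lb = np.clip(np.digitize(b, edges[1:-1], right=True), 0, n_classes - 1)
    if (la == lb).all():
        return 1.0  # cohen_kappa_score is 0/0 when a single shared class remains
    return float(cohen_kappa_score(la, lb))
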