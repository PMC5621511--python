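"""Nestedness indices (matrix temperature T, discrepancy BR, NODF) and their
Monte-Carlo significance under the fixed-rows / equiprobable-columns null.

A community is nested when species-poor sites hold subsets of the species
found at species-rich sites.  Polarity differs by index: T and BR shrink as
nestedness increases (0 = perfectly nested), NODF grows (100 = perfectly
nested).  Significance contrasts the observed index against matrices in
which each species keeps its occurrence count but occurrences are placed
uniformly at random across sites (row sums fixed, column sums free).

Matrix temperature follows the isocline formulation of the
Rodríguez-Gironés & Santamaría algorithm: the packed matrix is mapped onto
the unit square, an isocline ``y = 1 - (1 - (1-x)^p)^(1/p)`` is solved so
the area above it equals the matrix fill, and each unexpected presence or
absence contributes its squared normalized diagonal distance to the
isocline; the sum is scaled by 100/0.04145 so the expected maximum is near
100.  Packing here is the deterministic sort by marginal totals (stable in
the original order on ties).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import gammaln

from .errors import InvalidArgumentError, UndefinedStatisticError

__all__ = [
    "PackedMatrix",
    "NullEnsemble",
    "NestednessResult",
    "pack",
    "nodf",
    "temperature",
    "discrepancy",
    "null_fixed_rows_equiprob_cols",
    "test",
]

_TEMP_SCALE = 100.0 / 0.04145

_INDICES = ("T", "BR", "NODF", "NODFc", "NODFr")
# nested direction per index: -1 = smaller is more nested, +1 = larger
_POLARITY = {"T": -1, "BR": -1, "NODF": 1, "NODFc": 1, "NODFr": 1}


def _validate01(M, min_rows=1, min_cols=1) -> np.ndarray:
    A = np.asarray(M)
    if A.ndim != 2:
        raise InvalidArgumentError("matrix must be 2-D")
    if not np.isin(A, (0, 1)).all():
        raise InvalidArgumentError("matrix entries must be 0/1")
    if A.shape[0] < min_rows or A.shape[1] < min_cols:
        raise InvalidArgumentError(
            f"matrix must be at least {min_rows}x{min_cols}")
    return A.astype(int)


# ---------------------------------------------------------------------------
# Packing
# ---------------------------------------------------------------------------

@dataclass
class PackedMatrix:
    matrix: np.ndarray
    row_order: np.ndarray
    col_order: np.ndarray
    criterion: str


def pack(M, criterion: str = "totals", external_site_scores=None) -> PackedMatrix:
    """Sort rows and columns into packed form.

    Rows always sort by decreasing row total.  Columns sort by decreasing
    column total (``criterion="totals"``) or by decreasing external site
    score (e.g. AET productivity) when ``external_site_scores`` is given.
    Ties keep the original order (stable sort), so packing is deterministic.
    """
    A = _validate01(M)
    if (A.sum(axis=0) == 0).any():
        raise InvalidArgumentError("matrix has an all-zero column")
    row_order = np.argsort(-A.sum(axis=1), kind="stable")
    if external_site_scores is not None:
        scores = np.asarray(external_site_scores, dtype=float)
        if scores.shape != (A.shape[1],):
            raise InvalidArgumentError(
                "external_site_scores length must equal the number of sites")
        col_order = np.argsort(-scores, kind="stable")
        criterion = "external"
    else:
        col_order = np.argsort(-A.sum(axis=0), kind="stable")
    return PackedMatrix(matrix=A[np.ix_(row_order, col_order)],
                        row_order=row_order, col_order=col_order,
                        criterion=criterion)


# ---------------------------------------------------------------------------
# NODF
# ---------------------------------------------------------------------------

def _nodf_pair_terms(S: np.ndarray, totals: np.ndarray) -> tuple[float, int]:
    """Sum of paired-overlap percentages over pairs with unequal totals."""
    t_i = totals[:, None]
    t_j = totals[None, :]
    smaller = np.minimum(t_i, t_j).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        po = np.where((t_i != t_j) & (smaller > 0), S / smaller * 100.0, 0.0)
    iu = np.triu_indices(len(totals), k=1)
    return float(po[iu].sum()), len(iu[0])


def nodf(M) -> tuple[float, float, float]:
    """NODF and its column/row components, each in [0, 100].

    For every ordered pair of lines with strictly decreasing marginal
    totals, the paired overlap is the percentage of the sparser line's
    presences also present in the fuller line; equal-total pairs contribute
    zero.  ``NODFr`` averages row pairs, ``NODFc`` column pairs, ``NODF``
    all pairs.  Invariant to row/column permutations.
    """
    A = _validate01(M, min_rows=2, min_cols=2)
    if (A.sum(axis=1) == 0).any():
        raise InvalidArgumentError("matrix has an all-zero row")
    rows_sum, rows_n = _nodf_pair_terms(A @ A.T, A.sum(axis=1))
    cols_sum, cols_n = _nodf_pair_terms(A.T @ A, A.sum(axis=0))
    nodf_r = rows_sum / rows_n
    nodf_c = cols_sum / cols_n
    total = (rows_sum + cols_sum) / (rows_n + cols_n)
    return float(total), float(nodf_c), float(nodf_r)


# ---------------------------------------------------------------------------
# Matrix temperature
# ---------------------------------------------------------------------------

def _fill_integral(p: float) -> float:
    # area above the isocline: integral_0^1 [1 - (1-(1-x)^p)^(1/p)] dx
    logb = gammaln(1.0 / p) + gammaln(1.0 + 1.0 / p) - gammaln(1.0 + 2.0 / p)
    return 1.0 - np.exp(logb - np.log(p))


def _isocline_shape(fill: float) -> float:
    """Solve the isocline exponent p so the area above the curve equals fill."""
    return float(np.exp(brentq(lambda lp: _fill_integral(np.exp(lp)) - fill,
                               np.log(1e-4), np.log(1e4), xtol=1e-13)))


def _isocline(x: np.ndarray, p: float) -> np.ndarray:
    return 1.0 - (1.0 - (1.0 - x) ** p) ** (1.0 / p)


def _signed_distances(m: int, n: int, p: float) -> np.ndarray:
    """Signed normalized diagonal distance of every cell to the isocline.

    Cell (i, j) maps to (x, y) = ((j+0.5)/n, (i+0.5)/m) in the unit square
    (y down from the top).  The distance runs along the cell's diagonal of
    slope 1 and is normalized by the diagonal's length inside the square;
    positive values lie below/right of the isocline.  The crossing point is
    found by vectorized bisection (the isocline is symmetric about y = x, so
    the root of f(x) - x = a gives the crossing's y-coordinate directly).
    """
    r = (np.arange(m) + 0.5) / m
    c = (np.arange(n) + 0.5) / n
    a = c[None, :] - r[:, None]
    lo = np.zeros_like(a)
    hi = np.ones_like(a)
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        h = _isocline(mid, p) - mid - a
        above = h > 0
        lo = np.where(above, mid, lo)
        hi = np.where(above, hi, mid)
    ystar = 0.5 * (lo + hi)
    return (r[:, None] - ystar) / (1.0 - np.abs(a))


def _temperature_from_packed(packed: np.ndarray, u0: np.ndarray) -> float:
    unexpected = ((u0 > 0) & (packed == 1)) | ((u0 < 0) & (packed == 0))
    u = np.where(unexpected, u0, 0.0)
    return float(_TEMP_SCALE * np.mean(u ** 2))


def temperature(M) -> float:
    """Matrix temperature T in [0, ~100]; 0 = perfectly nested."""
    A = _validate01(M, min_rows=2, min_cols=2)
    fill = A.mean()
    if fill == 0.0 or fill == 1.0:
        raise UndefinedStatisticError("temperature undefined at 0% or 100% fill")
    packed = pack(A).matrix if (A.sum(axis=0) > 0).all() else _pack_loose(A)
    p = _isocline_shape(fill)
    u0 = _signed_distances(*A.shape, p)
    return _temperature_from_packed(packed, u0)


def _pack_loose(A: np.ndarray) -> np.ndarray:
    # packing that tolerates all-zero lines (T and BR accept them; pack() not)
    ro = np.argsort(-A.sum(axis=1), kind="stable")
    co = np.argsort(-A.sum(axis=0), kind="stable")
    return A[np.ix_(ro, co)]


# ---------------------------------------------------------------------------
# Discrepancy
# ---------------------------------------------------------------------------

def discrepancy(M) -> int:
    """Brualdi–Sanderson discrepancy BR.

    After sorting columns by decreasing totals, BR counts the presences
    lying outside each row's leftmost r_i positions — the minimum number of
    shifts needed to reach the maximally packed matrix with the same row
    sums.  0 = perfectly packed.
    """
    A = _validate01(M)
    co = np.argsort(-A.sum(axis=0), kind="stable")
    P = A[:, co]
    r = P.sum(axis=1)
    inside = np.arange(P.shape[1])[None, :] < r[:, None]
    return int((P & ~inside).sum())


# ---------------------------------------------------------------------------
# Null model and Monte-Carlo test
# ---------------------------------------------------------------------------

@dataclass
class NullEnsemble:
    """Randomized matrices under fixed rows / equiprobable columns."""

    replicates: np.ndarray      # (n_iter, rows, cols) uint8
    row_sums: np.ndarray
    seed: int | None


def _null_stack(row_sums: np.ndarray, n_cols: int, n_iter: int, rng) -> np.ndarray:
    ranks = np.argsort(rng.random((n_iter, len(row_sums), n_cols)),
                       axis=2, kind="stable").argsort(axis=2, kind="stable")
    return (ranks < row_sums[None, :, None]).astype(np.uint8)


def null_fixed_rows_equiprob_cols(M, n_iter: int, seed: int | None = None) -> NullEnsemble:
    """Draw matrices with each species' presences placed uniformly at random.

    Every replicate keeps the observed row sums exactly; each row's r_i
    presences land on a uniform random subset of the columns, so expected
    column totals are uniform across sites.
    """
    A = _validate01(M)
    if n_iter < 1:
        raise InvalidArgumentError("n_iter must be >= 1")
    r = A.sum(axis=1)
    if (r > A.shape[1]).any():
        raise InvalidArgumentError("row total exceeds the number of columns")
    rng = np.random.default_rng(seed)
    return NullEnsemble(replicates=_null_stack(r, A.shape[1], n_iter, rng),
                        row_sums=r, seed=seed)


# -- vectorized index evaluators over stacks of replicates ------------------

def _nodf_stack(reps: np.ndarray, which: str) -> np.ndarray:
    R = reps.astype(np.float32)
    b, m, n = R.shape

    def part(S, totals):
        t_i = totals[:, :, None]
        t_j = totals[:, None, :]
        smaller = np.minimum(t_i, t_j)
        with np.errstate(divide="ignore", invalid="ignore"):
            po = np.where((t_i != t_j) & (smaller > 0), S / smaller * 100.0, 0.0)
        iu = np.triu_indices(totals.shape[1], k=1)
        return po[:, iu[0], iu[1]].sum(axis=1), len(iu[0])

    rs, rn = part(np.einsum("bij,bkj->bik", R, R), R.sum(axis=2))
    cs, cn = part(np.einsum("bij,bik->bjk", R, R), R.sum(axis=1))
    if which == "NODFr":
        return rs / rn
    if which == "NODFc":
        return cs / cn
    return (rs + cs) / (rn + cn)


def _temperature_stack(reps: np.ndarray, u0: np.ndarray,
                       row_order: np.ndarray) -> np.ndarray:
    b, m, n = reps.shape
    colsums = reps.sum(axis=1)
    col_order = np.argsort(-colsums, axis=1, kind="stable")
    packed = np.take_along_axis(reps[:, row_order, :], col_order[:, None, :], axis=2)
    unexpected = ((u0[None] > 0) & (packed == 1)) | ((u0[None] < 0) & (packed == 0))
    u2 = np.where(unexpected, u0[None] ** 2, 0.0)
    return _TEMP_SCALE * u2.mean(axis=(1, 2))


def _discrepancy_stack(reps: np.ndarray) -> np.ndarray:
    b, m, n = reps.shape
    colsums = reps.sum(axis=1)
    col_order = np.argsort(-colsums, axis=1, kind="stable")
    packed = np.take_along_axis(reps, col_order[:, None, :], axis=2)
    r = packed.sum(axis=2)
    inside = np.arange(n)[None, None, :] < r[:, :, None]
    return (packed.astype(bool) & ~inside).sum(axis=(1, 2))


def _null_values(M, index: str, n_iter: int, rng, chunk: int = 2000) -> np.ndarray:
    A = _validate01(M)
    r = A.sum(axis=1)
    out = []
    if index == "T":
        fill = A.mean()
        p = _isocline_shape(fill)
        u0 = _signed_distances(*A.shape, p)
        row_order = np.argsort(-r, kind="stable")
    done = 0
    while done < n_iter:
        k = min(chunk, n_iter - done)
        reps = _null_stack(r, A.shape[1], k, rng)
        if index == "T":
            out.append(_temperature_stack(reps, u0, row_order))
        elif index == "BR":
            out.append(_discrepancy_stack(reps))
        else:
            out.append(_nodf_stack(reps, index))
        done += k
    return np.concatenate(out)


@dataclass
class NestednessResult:
    """Observed index vs its fixed-rows/equiprobable-columns null.

    ``p`` is the one-tailed Monte-Carlo p-value in the nested direction
    (with the +1 correction); ``p_opposite`` is the other tail.
    ``direction_conflict`` flags matrices whose observed value deviates from
    the null mean in the anti-nested direction while that tail is
    significant at 0.05.
    """

    index: str
    observed: float
    null_mean: float
    null_ci: tuple
    p: float
    p_opposite: float
    tail: str
    n_iter: int
    seed: int | None
    direction_conflict: bool = False


def _observed(M, index: str) -> float:
    if index == "T":
        return temperature(M)
    if index == "BR":
        return float(discrepancy(M))
    total, c, rr = nodf(M)
    return {"NODF": total, "NODFc": c, "NODFr": rr}[index]


def test(M, index: str, n_iter: int = 10000, seed: int | None = None) -> NestednessResult:
    """Monte-Carlo nestedness test for one index.

    Reports the observed index, the null mean and percentile 95% CI, and a
    one-tailed p in the nested direction: ((number of null values at least
    as nested as observed) + 1) / (n_iter + 1).
    """
    if index not in _INDICES:
        raise InvalidArgumentError(f"index must be one of {_INDICES}")
    obs = _observed(M, index)
    rng = np.random.default_rng(seed)
    nulls = _null_values(M, index, n_iter, rng)
    pol = _POLARITY[index]
    if pol < 0:
        as_nested = int((nulls <= obs).sum())
        opposite = int((nulls >= obs).sum())
        tail = "nested_smaller"
    else:
        as_nested = int((nulls >= obs).sum())
        opposite = int((nulls <= obs).sum())
        tail = "nested_larger"
    p = (as_nested + 1) / (n_iter + 1)
    p_opp = (opposite + 1) / (n_iter + 1)
    lo, hi = np.percentile(nulls, [2.5, 97.5])
    return NestednessResult(
        index=index, observed=float(obs), null_mean=float(nulls.mean()),
        null_ci=(float(lo), float(hi)), p=float(p), p_opposite=float(p_opp),
        tail=tail, n_iter=n_iter, seed=seed,
        direction_conflict=bool(p > 0.5 and p_opp <= 0.05),
    )
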