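"""Checkerboard C-score co-occurrence analysis with a null-model SES.

For each unordered species pair the number of checkerboard units is
CU = (r_i - S)(r_j - S), with r the row totals and S the number of shared
sites; the C-score is the mean CU over all pairs.  Larger scores mean more
segregation.  Significance uses the same fixed-rows / equiprobable-columns
randomization as the nestedness tests; the standardized effect size is
SES = (observed - null mean) / null sd, negative when species co-occur more
than expected (aggregation), positive when they segregate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidArgumentError, UndefinedStatisticError
from .nestedness import _null_stack, _validate01

__all__ = ["CScoreResult", "c_score", "ses", "cooccurrence_test"]


def c_score(M) -> float:
    """Mean checkerboard units over all unordered species pairs."""
    A = _validate01(M, min_rows=2)
    S = A @ A.T
    r = A.sum(axis=1)
    cu = (r[:, None] - S) * (r[None, :] - S)
    iu = np.triu_indices(A.shape[0], k=1)
    return float(cu[iu].mean())


def ses(observed: float, null_mean: float, null_sd: float) -> float:
    """Standardized effect size (observed - null mean) / null sd.

    Negative values indicate more co-occurrence (aggregation) than expected,
    positive values less (segregation); |SES| > 2 is roughly significant at
    alpha = 0.05 under normality.
    """
    if null_sd <= 0:
        raise UndefinedStatisticError("null standard deviation must be positive")
    return (observed - null_mean) / null_sd


def _c_score_stack(reps: np.ndarray) -> np.ndarray:
    R = reps.astype(np.float32)
    S = np.einsum("bij,bkj->bik", R, R)
    r = R.sum(axis=2)
    cu = (r[:, :, None] - S) * (r[:, None, :] - S)
    iu = np.triu_indices(reps.shape[1], k=1)
    return cu[:, iu[0], iu[1]].mean(axis=1)


@dataclass
class CScoreResult:
    """C-score vs its null distribution.

    ``null_var`` is the population variance of the null replicates;
    ``ses = (observed - null_mean) / sqrt(null_var)`` exactly.  ``p_upper``
    is the Monte-Carlo tail toward segregation, ``p_lower`` toward
    aggregation (both +1 corrected).
    """

    observed: float
    null_mean: float
    null_var: float
    ses: float
    p_upper: float
    p_lower: float
    n_null: int
    seed: int | None


def cooccurrence_test(M, n_null: int = 50000, seed: int | None = None,
                      chunk: int = 5000) -> CScoreResult:
    """C-score test under the fixed-rows / equiprobable-columns null."""
    A = _validate01(M, min_rows=2)
    if n_null < 2:
        raise InvalidArgumentError("n_null must be >= 2")
    obs = c_score(A)
    r = A.sum(axis=1)
    if (r > A.shape[1]).any():
        raise InvalidArgumentError("row total exceeds the number of columns")
    rng = np.random.default_rng(seed)
    vals = []
    done = 0
    while done < n_null:
        k = min(chunk, n_null - done)
        vals.append(_c_score_stack(_null_stack(r, A.shape[1], k, rng)))
        done += k
    nulls = np.concatenate(vals).astype(float)
    mean = float(nulls.mean())
    var = float(nulls.var())  # population form
    if var == 0.0:
        raise UndefinedStatisticError("degenerate null distribution")
    return CScoreResult(
        observed=obs, null_mean=mean, null_var=var,
        ses=ses(obs, mean, np.sqrt(var)),
        p_upper=float(((nulls >= obs).sum() + 1) / (n_null + 1)),
        p_lower=float(((nulls <= obs).sum() + 1) / (n_null + 1)),
        n_null=n_null, seed=seed,
    )
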