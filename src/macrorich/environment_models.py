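"""Richness–environment association models and constraint envelopes.

Four tools operating on a per-site table (one row per valid grid cell with
longitude, latitude, richness and named covariates):

* Pearson correlation between richness and a covariate;
* forward-stepwise multiple OLS selected by AICc (small-sample corrected
  AIC), reporting coefficients ordered by absolute standardized effect;
* a maximum-likelihood spatial autoregressive model — the spatial-error
  form y = Xb + u, u = lambda*W*u + eps — which absorbs residual spatial
  autocorrelation that inflates OLS significance on gridded richness;
* linear quantile regressions at extreme quantiles (1st/99th by default),
  whose fitted lines trace the lower and upper constraint envelope of the
  richness–covariate scatter, with a rank-score permutation test for
  slope = 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.optimize import minimize_scalar

from .errors import (
    CollinearityError,
    InvalidArgumentError,
    OptimizationError,
    UndefinedStatisticError,
)
from .grid_assembly import RichnessGrid
from .hotspot_detection import SpatialWeights
from .synthetic_data import EnvStack

__all__ = [
    "ModelFit",
    "QuantileEnvelope",
    "assemble_sites",
    "pearson",
    "forward_stepwise",
    "sar_fit",
    "quantile_envelope",
]


def assemble_sites(richness: RichnessGrid, env: EnvStack,
                   origin: tuple = (0.0, 0.0)) -> pd.DataFrame:
    """One row per valid cell: longitude, latitude, richness, covariates.

    Coordinates are cell centres; ``origin`` is the (lon, lat) of the
    north-west grid corner, latitude decreasing with row index.
    """
    if env.shape != richness.shape:
        raise InvalidArgumentError("environment and richness grids differ in shape")
    rr, cc = np.nonzero(richness.valid)
    cs = richness.cell_size
    table = {
        "longitude": origin[0] + (cc + 0.5) * cs,
        "latitude": origin[1] - (rr + 0.5) * cs,
        "richness": richness.richness[rr, cc],
    }
    for name, layer in env.layers.items():
        table[name] = layer[rr, cc]
    df = pd.DataFrame(table)
    if df.isna().any().any():
        raise InvalidArgumentError("site table contains missing values")
    return df


def pearson(x, y) -> tuple[float, float]:
    """Product-moment correlation and its two-tailed t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise InvalidArgumentError("need n >= 3 paired observations")
    if np.var(x) == 0 or np.var(y) == 0:
        raise UndefinedStatisticError("correlation undefined for constant input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# OLS with AICc and forward-stepwise selection
# ---------------------------------------------------------------------------

def _aicc(llf: float, k: int, n: int) -> float:
    # k counts the intercept, slopes, and the error variance
    if n - k - 1 <= 0:
        return np.inf
    return -2.0 * llf + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def _check_rank(X: pd.DataFrame) -> None:
    arr = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
    if np.linalg.matrix_rank(arr) < arr.shape[1]:
        bad = []
        cols = list(X.columns)
        base = np.ones((len(X), 1))
        rank = 1
        for i, c in enumerate(cols):
            cand = np.column_stack([base, X[c].to_numpy(dtype=float)])
            r = np.linalg.matrix_rank(cand)
            if r == rank:
                bad.append(c)
            else:
                base, rank = cand, r
        raise CollinearityError(
            f"design matrix is rank deficient (offending columns: {bad})", bad)


@dataclass
class ModelFit:
    """A fitted richness model (OLS or SAR-error).

    ``covariates`` are ordered by decreasing absolute standardized
    coefficient.  For SAR fits, ``r2`` is the pseudo-R² (squared Pearson
    correlation of the trend Xb with the observed response) and ``lambda_``
    the spatial-error coefficient with its profile-likelihood SE.
    """

    family: str
    response: str
    covariates: list
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    std_coef: pd.Series
    r2: float
    aicc: float
    llf: float
    n: int
    lambda_: float | None = None
    lambda_se: float | None = None
    history: list = field(default_factory=list)


def _standardized_coefs(params: pd.Series, X: pd.DataFrame, y: np.ndarray) -> pd.Series:
    sy = y.std()
    out = {}
    for c in X.columns:
        out[c] = params[c] * X[c].std() / sy if sy > 0 else np.nan
    return pd.Series(out)


def forward_stepwise(sites: pd.DataFrame, candidates: list,
                     response: str = "richness") -> ModelFit:
    """Greedy forward selection of an OLS model by AICc.

    Starting from the intercept-only model, each step adds the candidate
    giving the largest AICc decrease and stops when no addition improves
    AICc (ties broken by candidate order).  The selected model's AICc is
    therefore never above the intercept-only model's.
    """
    if not candidates:
        raise InvalidArgumentError("at least one candidate covariate required")
    missing = [c for c in list(candidates) + [response] if c not in sites.columns]
    if missing:
        raise InvalidArgumentError(f"columns missing from site table: {missing}")
    y = sites[response].to_numpy(dtype=float)
    n = len(y)
    selected: list[str] = []
    current = _aicc(sm.OLS(y, np.ones((n, 1))).fit().llf, 2, n)
    history = [("<intercept>", current)]
    remaining = list(candidates)
    while remaining:
        best_c, best_aicc = None, current
        for c in remaining:
            cols = selected + [c]
            if n <= len(cols) + 3:
                continue
            X = sm.add_constant(sites[cols].to_numpy(dtype=float))
            if np.linalg.matrix_rank(X) < X.shape[1]:
                continue
            fit = sm.OLS(y, X).fit()
            a = _aicc(fit.llf, len(cols) + 2, n)
            if a < best_aicc - 1e-12:
                best_c, best_aicc = c, a
        if best_c is None:
            break
        selected.append(best_c)
        remaining.remove(best_c)
        current = best_aicc
        history.append((best_c, current))
    Xdf = sites[selected]
    _check_rank(Xdf)
    X = sm.add_constant(Xdf.to_numpy(dtype=float)) if selected else np.ones((n, 1))
    fit = sm.OLS(y, X).fit()
    names = ["const"] + selected
    params = pd.Series(fit.params, index=names)
    std = _standardized_coefs(params, Xdf, y) if selected else pd.Series(dtype=float)
    order = list(std.abs().sort_values(ascending=False).index)
    return ModelFit(
        family="OLS", response=response, covariates=order,
        params=params, bse=pd.Series(fit.bse, index=names),
        pvalues=pd.Series(fit.pvalues, index=names), std_coef=std,
        r2=float(fit.rsquared), aicc=current, llf=float(fit.llf), n=n,
        history=history,
    )


# ---------------------------------------------------------------------------
# Spatial autoregressive (error) model
# ---------------------------------------------------------------------------

def sar_fit(sites: pd.DataFrame, covariates: list, weights: SpatialWeights,
            response: str = "richness", variant: str = "error") -> ModelFit:
    """Maximum-likelihood spatial-error SAR: y = Xb + u, u = lambda*W*u + eps.

    ``weights`` must be row-standardized and aligned with the site table
    (both enumerate the valid cells of the same grid in row-major order).
    The likelihood is concentrated over lambda; log|I - lambda*W| uses the
    eigenvalues of W.  ``variant="lag"`` fits the spatial-lag form
    y = rho*W*y + Xb + eps instead.
    """
    if variant not in {"error", "lag"}:
        raise InvalidArgumentError(f"unknown SAR variant {variant!r}")
    if not weights.row_standardized:
        raise InvalidArgumentError("SAR requires row-standardized weights")
    y = sites[response].to_numpy(dtype=float)
    n = len(y)
    if n != weights.n:
        raise InvalidArgumentError("weights do not align with the site table")
    Xdf = sites[list(covariates)]
    _check_rank(Xdf)
    X = np.column_stack([np.ones(n), Xdf.to_numpy(dtype=float)])
    W = weights.W.toarray()
    eigs = np.linalg.eigvals(W)
    lo = 1.0 / eigs.real.min() + 1e-6 if eigs.real.min() < 0 else -0.999
    hi = 1.0 / eigs.real.max() - 1e-6

    Wy = W @ y
    WX = W @ X

    def concentrated(lam):
        if variant == "error":
            ys = y - lam * Wy
            Xs = X - lam * WX
            beta, *_ = np.linalg.lstsq(Xs, ys, rcond=None)
            e = ys - Xs @ beta
        else:
            ys = y - lam * Wy
            beta, *_ = np.linalg.lstsq(X, ys, rcond=None)
            e = ys - X @ beta
        sigma2 = float(e @ e) / n
        logdet = float(np.sum(np.log(np.abs(1.0 - lam * eigs))))
        ll = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0) + logdet
        return ll, beta, sigma2

    res = minimize_scalar(lambda lam: -concentrated(lam)[0],
                          bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-8})
    if not res.success:
        raise OptimizationError(f"SAR likelihood optimization failed: {res}")
    lam = float(res.x)
    ll, beta, sigma2 = concentrated(lam)

    # profile-likelihood SE for lambda via the numeric second derivative
    h = max(1e-5, 1e-4 * (hi - lo))
    l_plus = concentrated(min(lam + h, hi))[0]
    l_minus = concentrated(max(lam - h, lo))[0]
    d2 = (l_plus - 2 * ll + l_minus) / h ** 2
    lam_se = float(np.sqrt(-1.0 / d2)) if d2 < 0 else np.nan

    if variant == "error":
        Xs = X - lam * WX
        cov = sigma2 * np.linalg.inv(Xs.T @ Xs)
    else:
        cov = sigma2 * np.linalg.inv(X.T @ X)
    bse = np.sqrt(np.diag(cov))
    zvals = beta / bse
    pvals = 2 * stats.norm.sf(np.abs(zvals))

    names = ["const"] + list(covariates)
    params = pd.Series(beta, index=names)
    trend = X @ beta
    if variant == "lag":
        trend = np.linalg.solve(np.eye(n) - lam * W, trend)
    r = np.corrcoef(trend, y)[0, 1] if np.std(trend) > 0 else 0.0
    std = _standardized_coefs(params, Xdf, y)
    order = list(std.abs().sort_values(ascending=False).index)
    k = len(names) + 2  # + sigma2 + lambda
    return ModelFit(
        family=f"SAR-{variant}", response=response, covariates=order,
        params=params, bse=pd.Series(bse, index=names),
        pvalues=pd.Series(pvals, index=names), std_coef=std,
        r2=float(r ** 2), aicc=_aicc(ll, k, n), llf=float(ll), n=n,
        lambda_=lam, lambda_se=lam_se,
    )


# ---------------------------------------------------------------------------
# Quantile-regression constraint envelopes
# ---------------------------------------------------------------------------

@dataclass
class QuantileEnvelope:
    """Linear quantile fits at extreme taus plus slope tests.

    ``slopes``/``intercepts``/``p_values`` are keyed by tau; p-values come
    from the rank-score permutation test of slope = 0 (``n_boot``
    randomizations, +1 corrected).  The Pearson correlation of the same
    variable pair is included for reference.
    """

    taus: tuple
    slopes: dict
    intercepts: dict
    p_values: dict
    n_boot: int
    seed: int | None
    pearson_rho: float
    pearson_p: float


def _rank_score_p(x: np.ndarray, y: np.ndarray, tau: float, n_boot: int,
                  rng) -> float:
    """Permutation rank-score test of zero slope at quantile tau.

    Scores are tau - 1{y_i < q_tau(y)} from the intercept-only fit; the
    statistic sum((x - xbar) * s) is recomputed under random permutations of
    x, giving an exact-style two-sided p.
    """
    q = np.quantile(y, tau)
    s = tau - (y < q).astype(float)
    xc = x - x.mean()
    obs = abs(float(xc @ s))
    hits = 0
    for _ in range(n_boot):
        hits += abs(float(rng.permutation(xc) @ s)) >= obs - 1e-12
    return (hits + 1) / (n_boot + 1)


def quantile_envelope(x, y, taus: tuple = (0.01, 0.99), n_boot: int = 10000,
                      seed: int | None = None) -> QuantileEnvelope:
    """Constraint envelope of y on x at extreme quantiles.

    Fits linear quantile regressions (check-loss minimization) at each tau
    and tests slope = 0 with the rank-score permutation test.  Warns below
    n = 30, where extreme-quantile fits are unstable.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise InvalidArgumentError("need matched x, y with n >= 3")
    if np.var(x) == 0:
        raise InvalidArgumentError("x is degenerate (zero variance)")
    if len(x) < 30:
        warnings.warn("fewer than 30 points: extreme-quantile fits are unstable",
                      stacklevel=2)
    for tau in taus:
        if not 0 < tau < 1:
            raise InvalidArgumentError("taus must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    X = sm.add_constant(x)
    slopes, intercepts, pvals = {}, {}, {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # statsmodels IterationLimit on flat fits
        for tau in taus:
            fit = sm.QuantReg(y, X).fit(q=tau)
            intercepts[tau] = float(fit.params[0])
            slopes[tau] = float(fit.params[1])
            pvals[tau] = _rank_score_p(x, y, tau, n_boot, rng)
    rho, rho_p = pearson(x, y)
    return QuantileEnvelope(taus=tuple(taus), slopes=slopes,
                            intercepts=intercepts, p_values=pvals,
                            n_boot=n_boot, seed=seed,
                            pearson_rho=rho, pearson_p=rho_p)
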