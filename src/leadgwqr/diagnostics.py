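"""Spatial diagnostics: nonstationarity assessment and Moran's I.

Nonstationarity rule: at a given quantile, a coefficient whose local
estimates (from the geographically weighted fit) have an interquartile
range strictly greater than twice the standard error of the corresponding
global coefficient is declared "Nonstationary"; boundary ties go to
"Stationary".

Moran's I for values z with spatial weights w_ij:

    I = (n / S0) * sum_ij w_ij (z_i - zbar)(z_j - zbar) / sum_i (z_i - zbar)^2

with expectation E[I] = -1/(n-1) under no autocorrelation and the
closed-form variance under the normality assumption; the z-score and a
two-sided normal p-value follow.  Weights default to row-standardized
k-nearest-neighbour (k = 8) on block centroids.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.spatial import cKDTree
from scipy.stats import norm

__all__ = [
    "SpatialWeights",
    "MoranResult",
    "NONSTATIONARY",
    "STATIONARY",
    "nonstationarity_status",
    "assess_nonstationarity",
    "build_weights",
    "morans_i",
    "residual_autocorrelation_report",
]

NONSTATIONARY = "Nonstationary"
STATIONARY = "Stationary"


# -- spatial weights ---------------------------------------------------------

@dataclass
class SpatialWeights:
    """Sparse spatial weight matrix with its construction metadata."""

    scheme: str
    parameter: float
    row_standardized: bool
    matrix: sparse.csr_matrix

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


def build_weights(coords, scheme: str = "knn", parameter=8,
                  row_standardized: bool = True) -> SpatialWeights:
    """k-nearest-neighbour or fixed-radius spatial weights.

    ``scheme="knn"``: each unit's k nearest distinct units get weight 1
    (ties broken by index via the KD-tree ordering); the resulting matrix
    is generally asymmetric.  ``scheme="distance_band"``: all pairs within
    the radius get weight 1 (symmetric); isolated units trigger a warning.
    Row standardization divides each row by its sum.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n < 3:
        raise ValueError("need at least 3 units")
    tree = cKDTree(coords)
    if scheme == "knn":
        k = int(parameter)
        if k >= n:
            raise ValueError(f"k={k} must be smaller than n={n}")
        # brute-force distances with a stable sort so exact distance ties
        # break toward the smaller index, deterministically
        diff = coords[:, None, :] - coords[None, :, :]
        d2 = np.einsum("ijk,ijk->ij", diff, diff)
        np.fill_diagonal(d2, np.inf)
        idx = np.argsort(d2, axis=1, kind="stable")[:, :k]
        rows = np.repeat(np.arange(n), k)
        W = sparse.csr_matrix((np.ones(n * k), (rows, idx.ravel())),
                              shape=(n, n))
    elif scheme == "distance_band":
        radius = float(parameter)
        pairs = tree.query_pairs(radius, output_type="ndarray")
        if pairs.size == 0:
            raise ValueError("no neighbour pairs within the radius")
        rows = np.concatenate([pairs[:, 0], pairs[:, 1]])
        cols = np.concatenate([pairs[:, 1], pairs[:, 0]])
        W = sparse.csr_matrix((np.ones(rows.size), (rows, cols)),
                              shape=(n, n))
        isolated = np.asarray(W.sum(axis=1)).ravel() == 0
        if isolated.any():
            warnings.warn(f"{int(isolated.sum())} unit(s) have no "
                          "neighbours within the radius")
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    W.setdiag(0)
    W.eliminate_zeros()
    if row_standardized:
        rs = np.asarray(W.sum(axis=1)).ravel()
        rs[rs == 0] = 1.0
        W = sparse.diags(1.0 / rs) @ W
    return SpatialWeights(scheme=scheme, parameter=parameter,
                          row_standardized=row_standardized,
                          matrix=W.tocsr())


# -- Moran's I ---------------------------------------------------------------

@dataclass
class MoranResult:
    """Moran's I with its null moments under the normality assumption."""

    I: float
    expected_I: float
    variance_I: float
    z_score: float
    p_value: float
    n: int


def morans_i(values, weights: SpatialWeights) -> MoranResult:
    """Moran's I with z-score and two-sided p-value (normality variance)."""
    z = np.asarray(values, dtype=float).ravel()
    W = weights.matrix
    n = z.size
    if n != W.shape[0]:
        raise ValueError("values and weights have inconsistent sizes")
    if n < 3:
        raise ValueError("need at least 3 units")
    zc = z - z.mean()
    denom = float(zc @ zc)
    scale = max(float(np.abs(z).max()), 1.0)
    if denom <= n * (1e-12 * scale) ** 2:
        raise ValueError("values are (numerically) constant; Moran's I "
                         "is undefined")
    S0 = float(W.sum())
    num = float(zc @ (W @ zc))
    I = (n / S0) * num / denom

    Wd = W + W.T
    S1 = 0.5 * float(Wd.multiply(Wd).sum())
    row = np.asarray(W.sum(axis=1)).ravel()
    col = np.asarray(W.sum(axis=0)).ravel()
    S2 = float(((row + col) ** 2).sum())
    EI = -1.0 / (n - 1)
    var = ((n**2 * S1 - n * S2 + 3 * S0**2)
           / (S0**2 * (n**2 - 1))) - EI**2
    if var <= 0:
        raise ValueError("non-positive Moran variance; degenerate weights")
    zscore = (I - EI) / np.sqrt(var)
    p = 2.0 * norm.sf(abs(zscore))
    return MoranResult(I=I, expected_I=EI, variance_I=var, z_score=zscore,
                       p_value=p, n=n)


# -- nonstationarity ---------------------------------------------------------

def nonstationarity_status(iqr: float, global_se: float) -> str:
    """Strict rule: Nonstationary iff IQR > 2 * SE (ties -> Stationary)."""
    return NONSTATIONARY if iqr > 2.0 * global_se else STATIONARY


def assess_nonstationarity(local_estimates, global_fit,
                           names=None, local_tau=None) -> pd.DataFrame:
    """Summarise local coefficient surfaces against global standard errors.

    Parameters
    ----------
    local_estimates : fitted GWQuantileRegressor, DataFrame, or ndarray
        Local coefficient estimates, one column per coefficient (intercept
        first when taken from a fitted surface).  NaN rows (failed local
        fits) are excluded.
    global_fit : fitted LinearQuantileRegressor
        Must carry bootstrap ``se_`` (intercept first) at the same tau.
    names : sequence of str, optional
        Coefficient names; defaults to intercept/x1..xp.
    local_tau : float, optional
        Tau of the local surface when ``local_estimates`` is a bare array.

    Returns a DataFrame with columns coefficient, mean, median, min, max,
    iqr, global_se, status.
    """
    if hasattr(local_estimates, "local_beta_"):
        local_tau = local_estimates.tau
        local = np.asarray(local_estimates.local_beta_, dtype=float)
    elif isinstance(local_estimates, pd.DataFrame):
        names = names or list(local_estimates.columns)
        local = local_estimates.to_numpy(dtype=float)
    else:
        local = np.asarray(local_estimates, dtype=float)
    if not hasattr(global_fit, "se_"):
        raise ValueError("global_fit needs bootstrap inference (se_) first")
    if local_tau is not None and not np.isclose(local_tau, global_fit.tau):
        raise ValueError(
            f"tau mismatch: local surface at {local_tau}, global fit at "
            f"{global_fit.tau}")
    se = np.asarray(global_fit.se_, dtype=float)
    if local.shape[1] != se.size:
        raise ValueError("coefficient count mismatch between local and "
                         "global fits")
    if names is None:
        names = ["intercept"] + [f"x{k}" for k in range(1, se.size)]
    rows = []
    for j, name in enumerate(names):
        col = local[:, j]
        col = col[np.isfinite(col)]
        if col.size < 4:
            raise ValueError(f"need at least 4 local estimates for {name!r}")
        q1, q3 = np.percentile(col, [25, 75])
        rows.append({
            "coefficient": name,
            "mean": col.mean(),
            "median": float(np.median(col)),
            "min": col.min(),
            "max": col.max(),
            "iqr": q3 - q1,
            "global_se": se[j],
            "status": nonstationarity_status(q3 - q1, se[j]),
        })
    return pd.DataFrame(rows)


# -- residual autocorrelation report ----------------------------------------

def residual_autocorrelation_report(data, fits, weights: SpatialWeights,
                                    response: str = "rate") -> pd.DataFrame:
    """Moran's I table for the observed rate and per-tau QR residuals.

    ``fits`` maps tau -> fitted LinearQuantileRegressor with stored
    ``residuals_``.  Vectors that are constant (e.g. residuals of an exact
    fit) produce an NA row instead of aborting the report.
    """
    rows = []

    def add_row(label, values):
        try:
            r = morans_i(values, weights)
            rows.append({"series": label, "morans_i": r.I,
                         "z_score": r.z_score, "p_value": r.p_value})
        except ValueError:
            rows.append({"series": label, "morans_i": np.nan,
                         "z_score": np.nan, "p_value": np.nan})

    add_row("observed", np.asarray(data[response], dtype=float))
    for tau in sorted(fits):
        add_row(f"residuals_tau_{tau:g}", np.asarray(fits[tau].residuals_))
    return pd.DataFrame(rows)
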