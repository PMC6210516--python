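"""Linear quantile regression fitted by linear programming.

The conditional tau-quantile of a response y given covariates X is modelled
as Q_tau(y | x) = x' beta(tau).  The coefficient vector minimises the total
check (pinball) loss

    sum_i rho_tau(y_i - x_i' beta),
    rho_tau(r) = tau * r        for r >= 0
               = (tau - 1) * r  for r <  0,

a piecewise-linear convex problem solved exactly as a linear program in the
split-residual primal form (residual r = u - v with u, v >= 0).  At
tau = 0.5 this is L1 (median) regression.

Inference is by paired (x, y) bootstrap: the standard error of each
coefficient is the standard deviation over bootstrap refits, the confidence
interval is the percentile interval, and the p-value uses a two-sided
normal approximation on beta / SE.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import sparse
from scipy.optimize import linprog
from scipy.stats import norm
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "check_loss",
    "sample_quantile",
    "LinearQuantileRegressor",
    "fit_qr",
    "qr_inference",
    "standardized_fit",
]


def _validate_tau(tau: float) -> float:
    tau = float(tau)
    if not 0.0 < tau < 1.0:
        raise ValueError(f"tau must lie strictly between 0 and 1, got {tau}")
    return tau


def check_loss(residual, tau):
    """Check (pinball) loss: tau * r for r >= 0, (1 - tau) * |r| for r < 0.

    Vectorised over ``residual``; returns a scalar for scalar input.
    """
    tau = _validate_tau(tau)
    r = np.asarray(residual, dtype=float)
    out = np.where(r >= 0, tau * r, (tau - 1.0) * r)
    return float(out) if np.isscalar(residual) or out.ndim == 0 else out


def sample_quantile(y, tau):
    """Sample tau-quantile as the minimiser of the total check loss.

    When the minimising set is an interval (n * tau integer) the lower
    endpoint is returned, matching the left-continuous inverse CDF
    Q(tau) = inf{y : F(y) >= tau}.
    """
    tau = _validate_tau(tau)
    y = np.asarray(y, dtype=float).ravel()
    if y.size == 0:
        raise ValueError("sample_quantile requires a nonempty sample")
    ys = np.sort(y)
    n = ys.size
    m = n * tau
    # order statistic index (1-based): ceil(m), or m itself when integral
    k = int(np.ceil(m - 1e-9))
    k = max(k, 1)
    return float(ys[k - 1])


def _rank_check(X: np.ndarray, columns=None):
    """Raise if X is column rank deficient, naming an offending column."""
    n, p = X.shape
    if n < p:
        raise ValueError(f"need more observations ({n}) than parameters ({p})")
    _, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    scale = diag.max() if diag.max() > 0 else 1.0
    bad = np.where(diag < 1e-10 * scale)[0]
    if bad.size:
        j = int(bad[0])
        name = columns[j] if columns is not None else f"column {j}"
        raise ValueError(
            f"design matrix is rank deficient: {name!r} is linearly "
            "dependent on the preceding columns"
        )


def _solve_qr_lp_primal(X: np.ndarray, y: np.ndarray, tau: float) -> np.ndarray:
    """Split-residual primal LP: min tau 1'u + (1-tau) 1'v s.t. X b + u - v = y."""
    n, p = X.shape
    c = np.concatenate([np.zeros(p), np.full(n, tau), np.full(n, 1.0 - tau)])
    eye = sparse.eye(n, format="csc")
    A_eq = sparse.hstack([sparse.csc_matrix(X), eye, -eye], format="csc")
    bounds = [(None, None)] * p + [(0, None)] * (2 * n)
    res = linprog(c, A_eq=A_eq, b_eq=y, bounds=bounds, method="highs")
    if not res.success:
        raise RuntimeError(
            f"quantile-regression LP did not converge: status={res.status} "
            f"({res.message})"
        )
    return res.x[:p]


def _solve_qr_lp(X: np.ndarray, y: np.ndarray, tau: float) -> np.ndarray:
    """Minimise sum rho_tau(y - X beta) exactly via the LP dual.

    The dual of the split-residual primal is max y'a subject to X'a = 0
    with box constraints a_i in [tau - 1, tau]; the coefficient vector is
    the (negated) vector of equality-constraint marginals.  The dual has
    only p equality rows, which is much faster than the primal's n rows
    for the bootstrap-heavy workloads here; both paths give the same
    vertex solutions (see the primal cross-check in the test suite).
    """
    n, p = X.shape
    res = linprog(-y, A_eq=X.T, b_eq=np.zeros(p),
                  bounds=[(tau - 1.0, tau)] * n, method="highs")
    if not res.success:
        raise RuntimeError(
            f"quantile-regression LP did not converge: status={res.status} "
            f"({res.message})"
        )
    return -res.eqlin.marginals


class LinearQuantileRegressor(RegressorMixin, BaseEstimator):
    """Linear quantile regression solved exactly by linear programming.

    Parameters
    ----------
    tau : float, default 0.5
        Quantile level in (0, 1).  0.5 gives median (L1) regression.
    fit_intercept : bool, default True
        Whether to prepend an intercept column.

    Attributes
    ----------
    coef_ : ndarray of shape (p,)
        Slope coefficients.
    intercept_ : float
        Intercept (0.0 when ``fit_intercept=False``).
    residuals_ : ndarray of shape (n,)
        In-sample residuals y - X beta.
    objective_ : float
        Minimised total check loss (weighted when sample weights given).
    se_, ci_lower_, ci_upper_, p_values_ : ndarray of shape (p + 1,)
        Set by :meth:`bootstrap_inference`; ordered intercept first, then
        slopes (intercept entries are NaN when ``fit_intercept=False``).
    """

    def __init__(self, tau: float = 0.5, fit_intercept: bool = True):
        self.tau = tau
        self.fit_intercept = fit_intercept

    # -- helpers -----------------------------------------------------------
    def _design(self, X: np.ndarray) -> np.ndarray:
        if self.fit_intercept:
            return np.column_stack([np.ones(X.shape[0]), X])
        return X

    def _column_names(self, X):
        names = None
        if hasattr(X, "columns"):
            names = list(X.columns)
        if names is not None and self.fit_intercept:
            names = ["intercept"] + names
        return names

    # -- estimator API -----------------------------------------------------
    def fit(self, X, y, sample_weight=None):
        tau = _validate_tau(self.tau)
        names = self._column_names(X)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        y = np.asarray(y, dtype=float).ravel()
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y have inconsistent lengths")
        if not (np.isfinite(X).all() and np.isfinite(y).all()):
            raise ValueError("X and y must be finite")
        D = self._design(X)
        _rank_check(D, names)
        if sample_weight is not None:
            w = np.asarray(sample_weight, dtype=float).ravel()
            if w.shape[0] != y.shape[0]:
                raise ValueError("sample_weight has wrong length")
            if (w < 0).any():
                raise ValueError("sample_weight must be nonnegative")
            # rho_tau(c r) = c rho_tau(r) for c > 0, so weighting rows of the
            # loss equals scaling both X and y rows by the weights
            beta = _solve_qr_lp(D * w[:, None], y * w, tau)
        else:
            w = None
            beta = _solve_qr_lp(D, y, tau)
        if self.fit_intercept:
            self.intercept_ = float(beta[0])
            self.coef_ = beta[1:].copy()
        else:
            self.intercept_ = 0.0
            self.coef_ = beta.copy()
        self.n_features_in_ = X.shape[1]
        self.residuals_ = y - D @ beta
        loss = check_loss(self.residuals_, tau)
        self.objective_ = float(np.sum(loss if w is None else w * loss))
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return X @ self.coef_ + self.intercept_

    @property
    def beta_(self) -> np.ndarray:
        """Full coefficient vector, intercept first."""
        check_is_fitted(self, "coef_")
        return np.concatenate([[self.intercept_], self.coef_])

    # -- inference ---------------------------------------------------------
    def bootstrap_inference(self, X, y, n_boot: int = 1000, random_state=None,
                            max_dropped_frac: float = 0.2):
        """Paired bootstrap SE, 95% percentile CI and normal-approx p-value.

        Resamples (x_i, y_i) rows with replacement ``n_boot`` times and
        refits; replicates whose resampled design is rank deficient are
        dropped (an error is raised if more than ``max_dropped_frac`` are).
        """
        check_is_fitted(self, "coef_")
        if n_boot < 50:
            raise ValueError("n_boot must be at least 50")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        y = np.asarray(y, dtype=float).ravel()
        n = y.shape[0]
        rng = np.random.default_rng(random_state)
        tau = _validate_tau(self.tau)
        D = self._design(X)
        boot = np.empty((n_boot, X.shape[1] + 1))
        dropped = 0
        kept = 0
        for b in range(n_boot):
            idx = rng.integers(0, n, size=n)
            Db = D[idx]
            # cheap rank guard: a column constant at zero or a singular
            # normal matrix marks a degenerate resample
            try:
                beta = _solve_qr_lp(Db, y[idx], tau)
            except RuntimeError:
                dropped += 1
                continue
            if not np.isfinite(beta).all():
                dropped += 1
                continue
            if self.fit_intercept:
                boot[kept] = beta
            else:
                boot[kept, 0] = 0.0
                boot[kept, 1:] = beta
            kept += 1
        if dropped > max_dropped_frac * n_boot:
            raise RuntimeError(
                f"{dropped}/{n_boot} bootstrap replicates failed "
                "(rank-deficient or non-convergent resamples)"
            )
        if dropped:
            warnings.warn(f"dropped {dropped} degenerate bootstrap replicates")
        boot = boot[:kept]
        if not self.fit_intercept:
            boot[:, 0] = np.nan
        self.se_ = boot.std(axis=0, ddof=1)
        self.ci_lower_ = np.percentile(boot, 2.5, axis=0)
        self.ci_upper_ = np.percentile(boot, 97.5, axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(self.se_ > 0, self.beta_ / self.se_, np.inf)
        self.p_values_ = 2.0 * norm.sf(np.abs(z))
        self.n_boot_used_ = kept
        return self

    def standardized_coefficients(self, X, y):
        """Standardised slopes (STB): refit after z-scoring X and y.

        The intercept of the refit is excluded; STB ranks predictors on a
        common scale.  Raises on constant columns.
        """
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        y = np.asarray(y, dtype=float).ravel()
        sx = X.std(axis=0, ddof=1)
        sy = y.std(ddof=1)
        if (sx <= 0).any() or sy <= 0:
            bad = np.where(sx <= 0)[0]
            what = f"X column(s) {bad.tolist()}" if bad.size else "y"
            raise ValueError(f"cannot standardize constant {what}")
        Z = (X - X.mean(axis=0)) / sx
        zy = (y - y.mean()) / sy
        est = LinearQuantileRegressor(self.tau, fit_intercept=True).fit(Z, zy)
        return est.coef_


# -- thin functional wrappers ---------------------------------------------

def fit_qr(X, y, tau: float) -> LinearQuantileRegressor:
    """Fit a global linear quantile regression (intercept included)."""
    return LinearQuantileRegressor(tau=tau).fit(X, y)


def qr_inference(fit: LinearQuantileRegressor, X, y, n_boot: int = 1000,
                 seed=None) -> LinearQuantileRegressor:
    """Attach bootstrap se_/ci_/p_values_ to a fitted model."""
    return fit.bootstrap_inference(X, y, n_boot=n_boot, random_state=seed)


def standardized_fit(X, y, tau: float) -> np.ndarray:
    """Standardised slope coefficients (STB) at quantile tau."""
    return LinearQuantileRegressor(tau=tau).standardized_coefficients(X, y)
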