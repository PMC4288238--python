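"""Closed-form ordinary least squares used by the model-fitting layers.

Design matrices here are tiny (tens of samples, at most six columns), so the
fits are computed directly from the normal equations rather than through a
statistics framework; the test suite cross-checks coefficients, F statistics
and AIC ordering against statsmodels.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

# Relative RSS floor: fits whose residual sum of squares falls below this
# fraction of the total sum of squares are treated as numerically exact, so
# that AIC comparisons between an exact fit and its supersets are decided by
# the parameter-count penalty rather than by float noise in a ~1e-25 RSS.
_EXACT_FIT_RTOL = 1e-12


class RankDeficientError(np.linalg.LinAlgError):
    """Design matrix is rank deficient; the model cannot be identified."""


@dataclass
class OlsFit:
    """Result of a least-squares fit of y on an intercept plus regressors."""

    intercept: float
    coefficients: np.ndarray        # per regressor, excluding the intercept
    stderr: np.ndarray              # standard errors, intercept first
    residuals: np.ndarray
    rss: float
    tss: float
    aic: float
    f_pvalue: float
    r2: float
    adj_r2: float
    nobs: int

    @property
    def t_pvalues(self) -> np.ndarray:
        """Two-sided t-test p-values, intercept first."""
        params = np.concatenate([[self.intercept], self.coefficients])
        df = self.nobs - params.size
        with np.errstate(divide="ignore", invalid="ignore"):
            t = params / self.stderr
        return 2.0 * stats.t.sf(np.abs(t), df)


def gaussian_aic(rss: float, tss: float, n: int, n_regressors: int) -> float:
    """AIC under a Gaussian likelihood, ``n*log(RSS/n) + 2*(k+1)``.

    The parameter count includes the intercept; the variance term contributes
    a constant shared by all candidates on the same response and is dropped.
    Only AIC differences between candidate regressor subsets are meaningful.
    """
    floor = _EXACT_FIT_RTOL * max(tss, 1.0)
    rss_eff = max(rss, floor)
    return n * np.log(rss_eff / n) + 2.0 * (n_regressors + 1)


def fit_ols(y: np.ndarray, X: np.ndarray) -> OlsFit:
    """Fit ``y = b0 + X @ b`` by ordinary least squares.

    Parameters
    ----------
    y : (n,) response vector.
    X : (n, k) regressor matrix, without an intercept column; ``k`` may be 0
        for the intercept-only model (used only as the F-test baseline).

    Raises
    ------
    RankDeficientError
        If the design matrix (including intercept) is not full column rank.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = y.size
    k = X.shape[1]
    D = np.column_stack([np.ones(n), X])
    if n <= k + 1:
        raise RankDeficientError(
            f"need more than {k + 1} samples to fit {k} regressors, got {n}"
        )
    q, r = np.linalg.qr(D)
    diag = np.abs(np.diag(r))
    if diag.min() <= max(n, k + 1) * np.finfo(float).eps * max(diag.max(), 1.0):
        raise RankDeficientError("design matrix is rank deficient")
    params = np.linalg.solve(r, q.T @ y)
    fitted = D @ params
    resid = y - fitted
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())

    dof = n - k - 1
    sigma2 = rss / dof
    # (D'D)^-1 from the QR factor; diagonal gives the coefficient variances.
    rinv = np.linalg.solve(r, np.eye(k + 1))
    stderr = np.sqrt(sigma2 * (rinv * rinv).sum(axis=1))

    if tss > 0:
        r2 = 1.0 - rss / tss
    else:
        r2 = 0.0
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / dof if dof > 0 else np.nan

    if k > 0 and tss > 0:
        with np.errstate(divide="ignore", invalid="ignore"):
            f_stat = ((tss - rss) / k) / (rss / dof) if rss > 0 else np.inf
        f_pvalue = float(stats.f.sf(f_stat, k, dof)) if np.isfinite(f_stat) else 0.0
    else:
        f_pvalue = 1.0

    return OlsFit(
        intercept=float(params[0]),
        coefficients=params[1:].copy(),
        stderr=stderr,
        residuals=resid,
        rss=rss,
        tss=tss,
        aic=gaussian_aic(rss, tss, n, k),
        f_pvalue=f_pvalue,
        r2=r2,
        adj_r2=adj_r2,
        nobs=n,
    )
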