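"""Ordinary least squares with textbook t / F inference.

Multiple regression of a stance-phase outcome on femoral anteversion and
neck-shaft angle (both in degrees, entered untransformed, with intercept).
The fit uses a numerically stable orthogonal (QR) decomposition; reference
distributions come from scipy.stats.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import DataError, ParameterError


@dataclass
class RegressionResult:
    outcome: str
    predictor_names: tuple[str, ...]
    coefficients: np.ndarray      # intercept first
    std_errors: np.ndarray
    t_values: np.ndarray
    p_values: np.ndarray
    r_squared: float
    f_statistic: float
    f_pvalue: float
    n: int
    alpha: float = 0.05
    residual_df: int = 0

    @property
    def significant(self) -> dict[str, bool]:
        """Per-coefficient two-sided significance at the configured alpha."""
        return {name: bool(p < self.alpha)
                for name, p in zip(("intercept",) + self.predictor_names,
                                   self.p_values)}

    def conf_int(self, level: float = 0.95) -> np.ndarray:
        """(k, 2) coefficient confidence intervals at the given level."""
        tcrit = stats.t.ppf(0.5 + level / 2, self.residual_df)
        half = tcrit * self.std_errors
        return np.column_stack([self.coefficients - half,
                                self.coefficients + half])


def fit_ols(y: np.ndarray, X: np.ndarray, outcome: str,
            predictor_names: tuple[str, ...], alpha: float = 0.05
            ) -> RegressionResult:
    """OLS of y on predictors (an intercept column is prepended).

    Raises on rank deficiency, naming the degenerate predictor.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, k = X.shape
    if len(y) != n:
        raise ParameterError("y and X have different numbers of rows")
    if n < k + 2:
        raise ParameterError(f"need at least {k + 2} rows, got {n}")
    for j, name in enumerate(predictor_names):
        if np.ptp(X[:, j]) < 1e-12:
            raise DataError(f"predictor {name!r} is constant (rank-deficient "
                            "design)")
    D = np.column_stack([np.ones(n), X])
    Q, R = np.linalg.qr(D)
    if np.min(np.abs(np.diag(R))) < 1e-10 * np.max(np.abs(np.diag(R))):
        raise DataError("rank-deficient design matrix (collinear predictors)")
    beta = np.linalg.solve(R, Q.T @ y)
    resid = y - D @ beta
    df_resid = n - (k + 1)
    sse = float(resid @ resid)
    sigma2 = sse / df_resid
    Rinv = np.linalg.inv(R)
    cov = sigma2 * (Rinv @ Rinv.T)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta / se
    pvals = 2 * stats.t.sf(np.abs(tvals), df_resid)
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst < 1e-30:
        raise DataError(f"outcome {outcome!r} is constant")
    r2 = 1.0 - sse / sst
    if sse < 1e-25 * max(sst, 1.0):
        # numerically perfect fit: F explodes; report infinity cleanly
        fstat, fp = np.inf, 0.0
    else:
        fstat = ((sst - sse) / k) / sigma2
        fp = float(stats.f.sf(fstat, k, df_resid))
    return RegressionResult(outcome=outcome,
                            predictor_names=tuple(predictor_names),
                            coefficients=beta, std_errors=se, t_values=tvals,
                            p_values=pvals, r_squared=float(r2),
                            f_statistic=float(fstat), f_pvalue=fp, n=n,
                            alpha=alpha, residual_df=df_resid)
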