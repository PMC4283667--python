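"""Small ridge-stabilised Newton (IRLS) logistic solver.

The bootstrap inclusion-frequency stage fits tens of thousands of small
logistic regressions (stepwise elimination inside every bootstrap resample of
every database), and the chained-equations imputer fits hundreds more.  This
module provides a minimal Newton solver tuned for that workload: dense
numpy, warm starts, optional L2 penalty on the non-intercept coefficients as
a fallback under (quasi-)separation.  It is cross-checked against
statsmodels' Logit in the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

logger = logging.getLogger(__name__)

__all__ = ["LogitFit", "SeparationError", "fit_logit", "fit_logit_safe"]


class SeparationError(RuntimeError):
    """The likelihood is unbounded (perfect or quasi separation)."""


@dataclass
class LogitFit:
    """Fitted logistic regression (first column of X is the intercept)."""

    beta: np.ndarray
    loglik: float  # unpenalised log-likelihood at beta
    hessian: np.ndarray  # penalised observed information X'WX + ridge*I
    converged: bool
    penalised: bool

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * len(self.beta)


def _loglik(X: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    eta = X @ beta
    # y'eta - sum log(1+exp(eta)), computed stably
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def fit_logit(
    X: np.ndarray,
    y: np.ndarray,
    ridge: float = 0.0,
    max_iter: int = 40,
    tol: float = 1e-6,
    beta0: np.ndarray | None = None,
) -> LogitFit:
    """Newton–Raphson logistic fit of y on X (X must include an intercept column).

    ``ridge`` penalises all coefficients except the first (intercept);
    ``beta0`` warm-starts the iteration.  Raises :class:`SeparationError`
    when the unpenalised likelihood appears unbounded, and
    ``numpy.linalg.LinAlgError`` on a singular information matrix.
    """
    X = np.ascontiguousarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    pen = np.full(p, ridge)
    pen[0] = 0.0
    if beta0 is not None and len(beta0) == p:
        beta = np.array(beta0, dtype=float)
    else:
        beta = np.zeros(p)
        ybar = min(max(y.mean(), 1e-9), 1 - 1e-9)
        beta[0] = np.log(ybar / (1.0 - ybar))
    Xt = X.T
    didx = np.arange(p)
    converged = False
    H = np.eye(p)
    for _ in range(max_iter):
        mu = expit(X @ beta)
        w = mu * (1.0 - mu)
        grad = Xt @ (y - mu) - pen * beta
        H = (X * w[:, None]).T @ X
        H[didx, didx] += pen
        step = np.linalg.solve(H, grad)
        smax = np.abs(step).max()
        if smax > 10.0:  # dampen absurd steps far from the optimum
            step *= 10.0 / smax
        beta = beta + step
        if smax < tol:
            converged = True
            break
        if ridge == 0.0 and np.abs(beta).max() > 20.0:
            raise SeparationError("slope diverging; likely separation")
    if ridge == 0.0 and not converged:
        raise SeparationError("logistic fit did not converge; likely separation")
    if not converged and np.abs(beta[1:]).max() > 50.0:
        raise SeparationError("penalised logistic fit diverged")
    return LogitFit(
        beta=beta,
        loglik=_loglik(X, y, beta),
        hessian=H,
        converged=converged,
        penalised=ridge > 0.0,
    )


def fit_logit_safe(
    X: np.ndarray,
    y: np.ndarray,
    fallback_ridge: float = 1.0,
    beta0: np.ndarray | None = None,
) -> LogitFit:
    """Maximum-likelihood fit with a logged penalised fallback.

    Tries the plain MLE first; on separation or a singular information
    matrix, refits with an L2 penalty of ``fallback_ridge`` on the slopes.
    """
    try:
        return fit_logit(X, y, ridge=0.0, beta0=beta0)
    except (SeparationError, np.linalg.LinAlgError):
        logger.debug(
            "logistic MLE failed (separation or singular design); "
            "refitting with ridge=%.3g", fallback_ridge,
        )
        return fit_logit(X, y, ridge=fallback_ridge, max_iter=60)
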