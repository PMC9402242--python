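"""Logistic regression machinery: ordinary IRLS maximum likelihood and the
Firth (Jeffreys-prior) penalized fit.

The penalized fit maximizes ``l(beta) + 1/2 * log det I(beta)``. The penalty
removes the first-order small-sample bias of the MLE and guarantees finite
estimates under complete or quasi-complete separation, which is why it is the
validation method of choice for low-frequency variants, where a cell of the
genotype x outcome table is often empty.

Both fitters share one Newton/IRLS loop: convergence when the largest
(modified) score component falls below ``score_tol`` or the step below
``step_tol``, with step-halving on any decrease of the (penalized)
log-likelihood. Estimates wandering past |beta| = 30 during the ordinary fit
are treated as separation: no plausible log-odds-ratio lives out there.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

__all__ = [
    "LogisticFit",
    "FirthLogit",
    "FirthLogitResults",
    "SeparationError",
    "ConvergenceError",
    "fit_logistic",
    "firth_logistic",
]

#: IRLS estimates beyond this magnitude are declared separated (ordinary fit).
SEPARATION_BETA = 30.0


class SeparationError(RuntimeError):
    """Ordinary ML estimates diverged (complete/quasi-complete separation)."""


class ConvergenceError(RuntimeError):
    """The iteration limit was reached without meeting the tolerance."""


@dataclass
class LogisticFit:
    """Result of a logistic fit.

    Attributes
    ----------
    params : ndarray
        Coefficient estimates, one per design column.
    cov : ndarray
        Estimated covariance (inverse observed / penalized information).
    loglike : float
        Log-likelihood at the estimate (penalized value for Firth fits).
    method : str
        ``"mle"`` or ``"firth"``.
    """

    params: np.ndarray
    cov: np.ndarray
    loglike: float
    n_iter: int
    converged: bool
    method: str

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))


def _validate(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != y.shape[0]:
        raise ValueError(
            f"design has {X.shape[0]} rows but outcome has {y.shape[0]}"
        )
    if not np.isfinite(X).all():
        raise ValueError("design contains non-finite values")
    uniq = np.unique(y)
    if not np.isin(uniq, (0.0, 1.0)).all():
        raise ValueError("outcome must be coded 0/1")
    if uniq.size < 2:
        raise ValueError("outcome has a single class; cannot fit")
    return X, y


def _loglike(X, y, beta):
    eta = X @ beta
    # log(1+e^eta) via logaddexp for stability
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def fit_logistic(
    X,
    y,
    *,
    max_iter: int = 50,
    score_tol: float = 1e-6,
    step_tol: float = 1e-8,
) -> LogisticFit:
    """Maximum-likelihood logistic regression by Newton iteration.

    Parameters
    ----------
    X : array_like, (n, p)
        Design matrix, caller-supplied intercept column included.
    y : array_like, (n,)
        Binary outcome (0/1) with both classes present.

    Raises
    ------
    SeparationError
        When estimates diverge (|beta| > 30); the message advises the
        Firth fit, which remains finite in this regime.
    ValueError
        Single-class outcome or rank-deficient design.
    """
    X, y = _validate(X, y)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient")
    beta = np.zeros(p)
    ll = _loglike(X, y, beta)
    for it in range(1, max_iter + 1):
        pr = special.expit(X @ beta)
        w = pr * (1.0 - pr)
        score = X.T @ (y - pr)
        info = (X * w[:, None]).T @ X
        if np.max(np.abs(score)) < score_tol:
            return LogisticFit(beta, np.linalg.inv(info), ll, it, True, "mle")
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - rank checked
            raise SeparationError(
                "information matrix singular during IRLS; data may be "
                "separated - consider the Firth fit"
            ) from exc
        # step-halving: never accept a likelihood decrease
        for _ in range(25):
            cand = beta + step
            ll_new = _loglike(X, y, cand)
            if ll_new >= ll - 1e-12:
                break
            step = step / 2.0
        if np.max(np.abs(cand)) > SEPARATION_BETA:
            raise SeparationError(
                "estimates diverged (|beta| > 30): the data are (quasi-)"
                "separated; use firth_logistic for a finite estimate"
            )
        done = np.max(np.abs(step)) < step_tol
        beta, ll = cand, ll_new
        if done:
            pr = special.expit(X @ beta)
            w = pr * (1.0 - pr)
            info = (X * w[:, None]).T @ X
            return LogisticFit(beta, np.linalg.inv(info), ll, it, True, "mle")
    raise ConvergenceError(f"IRLS did not converge in {max_iter} iterations")


def _penalized_parts(X, y, beta):
    """Return (penalized loglike, modified score, information) at beta."""
    pr = special.expit(X @ beta)
    w = pr * (1.0 - pr)
    Xw = X * w[:, None]
    info = Xw.T @ X
    sign, logdet = np.linalg.slogdet(info)
    if sign <= 0:
        return -np.inf, None, info
    pll = _loglike(X, y, beta) + 0.5 * logdet
    # hat diagonal of sqrt(W) X (X'WX)^-1 X' sqrt(W)
    h = np.einsum("ij,ij->i", X @ np.linalg.inv(info), Xw)
    score = X.T @ (y - pr + h * (0.5 - pr))
    return pll, score, info


def firth_logistic(
    X,
    y,
    *,
    max_iter: int = 50,
    score_tol: float = 1e-6,
    step_tol: float = 1e-8,
) -> LogisticFit:
    """Firth penalized logistic regression (Jeffreys-prior penalty).

    Solves the modified score equations ``sum_i (y_i - p_i + h_i(1/2 - p_i))
    x_ij = 0`` where ``h_i`` is the i-th leverage; Wald standard errors come
    from the inverse penalized information. Estimates are finite even under
    complete separation. Raises rather than returning a silently diverged fit.
    """
    X, y = _validate(X, y)
    n, p = X.shape
    # name any constant covariate up front (all-ones intercept excepted):
    # the penalty cannot save a column that carries no information
    for j in range(p):
        col = X[:, j]
        if np.ptp(col) == 0.0 and not np.all(col == 1.0):
            raise ValueError(f"design column {j} is constant")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient")
    beta = np.zeros(p)
    pll, score, info = _penalized_parts(X, y, beta)
    for it in range(1, max_iter + 1):
        if np.max(np.abs(score)) < score_tol:
            return LogisticFit(beta, np.linalg.inv(info), pll, it, True, "firth")
        step = np.linalg.solve(info, score)
        for _ in range(30):
            cand = beta + step
            pll_new, score_new, info_new = _penalized_parts(X, y, cand)
            if pll_new >= pll - 1e-12:
                break
            step = step / 2.0
        done = np.max(np.abs(step)) < step_tol
        beta, pll, score, info = cand, pll_new, score_new, info_new
        if done:
            return LogisticFit(beta, np.linalg.inv(info), pll, it, True, "firth")
    raise ConvergenceError(
        f"Firth iteration did not converge in {max_iter} iterations"
    )


class FirthLogit:
    """Firth-penalized logistic model, statsmodels-style.

    Parameters
    ----------
    endog : array_like
        Binary outcome.
    exog : array_like or DataFrame
        Design matrix including intercept.

    Examples
    --------
    >>> res = FirthLogit(y, X).fit()
    >>> res.params, res.bse, res.pvalues
    """

    def __init__(self, endog, exog, exog_names=None):
        names = exog_names
        if names is None and hasattr(exog, "columns"):
            names = list(exog.columns)
        self.exog = np.asarray(exog, dtype=float)
        if self.exog.ndim == 1:
            self.exog = self.exog[:, None]
        self.endog = np.asarray(endog, dtype=float).ravel()
        if names is None:
            names = [f"x{j}" for j in range(self.exog.shape[1])]
        self.exog_names = list(names)

    def fit(self, **kwargs) -> "FirthLogitResults":
        return FirthLogitResults(self, firth_logistic(self.exog, self.endog, **kwargs))


@dataclass
class FirthLogitResults:
    model: FirthLogit
    _fit: LogisticFit

    @property
    def params(self) -> np.ndarray:
        return self._fit.params

    @property
    def bse(self) -> np.ndarray:
        return self._fit.se

    @property
    def zvalues(self) -> np.ndarray:
        return self.params / self.bse

    # statsmodels calls the Wald z stats "tvalues" on every results class
    tvalues = zvalues

    @property
    def pvalues(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.zvalues))

    @property
    def converged(self) -> bool:
        return self._fit.converged

    def cov_params(self) -> np.ndarray:
        return self._fit.cov

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        z = stats.norm.ppf(1.0 - alpha / 2.0)
        return np.column_stack(
            [self.params - z * self.bse, self.params + z * self.bse]
        )

    def summary(self) -> str:
        lines = [
            "Firth penalized logistic regression",
            f"n = {self.model.endog.size}, events = {int(self.model.endog.sum())}, "
            f"iterations = {self._fit.n_iter}",
            f"{'term':<16}{'coef':>10}{'se':>10}{'z':>8}{'P>|z|':>12}{'OR':>8}",
        ]
        for name, b, s, z, p in zip(
            self.model.exog_names, self.params, self.bse, self.zvalues, self.pvalues
        ):
            lines.append(
                f"{name:<16}{b:>10.4f}{s:>10.4f}{z:>8.2f}{p:>12.3e}{np.exp(b):>8.3f}"
            )
        return "\n".join(lines)
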