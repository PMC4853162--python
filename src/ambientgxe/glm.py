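"""Maximum-likelihood logistic regression via iteratively reweighted least
squares, with Wald odds-ratio machinery.

The fitter is deliberately self-contained: it returns the coefficient
vector, the inverse observed information as the covariance, the final
log-likelihood and convergence metadata, and it detects the two failure
modes that matter for sparse case-control tables — a singular design
(collinearity) and complete/quasi-complete separation (coefficients
diverging without bound).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

from .errors import CollinearityError, ModelError, SeparationError

#: Convergence defaults: relative log-likelihood change and gradient norm.
DEFAULT_TOL_LL = 1e-10
DEFAULT_TOL_GRAD = 1e-8
DEFAULT_MAX_ITER = 100
#: |beta| beyond this is treated as divergence toward separation.
SEPARATION_BOUND = 15.0

Z_95 = 1.959963984540054  # standard-normal 97.5% quantile


@dataclass
class LogisticFit:
    """A fitted logistic model."""

    coefficients: np.ndarray
    covariance: np.ndarray
    loglik: float
    n_iterations: int
    converged: bool
    terms: list = field(default_factory=list)
    n_obs: int = 0

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.covariance))

    def __getitem__(self, term: str) -> float:
        return float(self.coefficients[self.terms.index(term)])


@dataclass(frozen=True)
class EffectEstimate:
    """An odds ratio with its 95% Wald interval and two-sided p-value."""

    OR: float
    ci_low: float
    ci_high: float
    p: float
    contrast: tuple = ()
    log_or: float = 0.0
    se: float = 0.0


def _loglik(X, y, beta):
    eta = X @ beta
    # log(1 + e^eta) computed stably
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def fit_logistic(
    X,
    y,
    tol=DEFAULT_TOL_LL,
    grad_tol=DEFAULT_TOL_GRAD,
    max_iterations=DEFAULT_MAX_ITER,
    terms=None,
) -> LogisticFit:
    """Fit logit P(y=1) = X beta by IRLS (Newton-Raphson).

    Parameters
    ----------
    X : (n, p) design matrix including any intercept column.
    y : (n,) 0/1 outcome vector.
    tol, grad_tol : convergence thresholds on the relative log-likelihood
        change and the max absolute score component.
    terms : optional coefficient labels, used in error messages and results.

    Raises
    ------
    CollinearityError
        if the design (or the weighted information) is numerically singular.
    SeparationError
        if any coefficient diverges past ``SEPARATION_BOUND``, the signature
        of complete or quasi-complete separation.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if terms is None:
        terms = [f"x{j}" for j in range(p)]
    if n <= p:
        raise ModelError(f"need more observations ({n}) than terms ({p})")
    if np.any(np.all(X == 0.0, axis=0)):
        raise CollinearityError("design contains a constant-zero column")
    if np.linalg.matrix_rank(X) < p:
        raise CollinearityError("design matrix is rank deficient")

    beta = np.zeros(p)
    ll = _loglik(X, y, beta)
    converged = False
    for iteration in range(1, max_iterations + 1):
        mu = special.expit(X @ beta)
        w = mu * (1.0 - mu)
        grad = X.T @ (y - mu)
        info = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            raise CollinearityError(
                "singular information matrix during IRLS"
            ) from None
        beta_new = beta + step
        ll_new = _loglik(X, y, beta_new)
        # step-halving keeps Newton monotone on badly scaled designs
        halvings = 0
        while ll_new < ll - 1e-12 and halvings < 30:
            step *= 0.5
            beta_new = beta + step
            ll_new = _loglik(X, y, beta_new)
            halvings += 1
        beta = beta_new
        if np.any(np.abs(beta) > SEPARATION_BOUND):
            worst = terms[int(np.argmax(np.abs(beta)))]
            raise SeparationError(
                "complete or quasi-complete separation detected "
                f"(coefficient for {worst!r} diverging)",
                term=worst,
            )
        rel_change = abs(ll_new - ll) / (abs(ll) + 1e-300)
        ll = ll_new
        mu = special.expit(X @ beta)
        grad = X.T @ (y - mu)
        if rel_change < tol and np.max(np.abs(grad)) < grad_tol:
            converged = True
            break
    w = mu * (1.0 - mu)
    info = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        raise CollinearityError("singular information at the optimum") from None
    return LogisticFit(
        coefficients=beta,
        covariance=cov,
        loglik=ll,
        n_iterations=iteration,
        converged=converged,
        terms=list(terms),
        n_obs=n,
    )


def wald_or(fit: LogisticFit, contrast) -> EffectEstimate:
    """Odds ratio exp(c . beta) with 95% Wald CI and two-sided p.

    ``contrast`` is a coefficient-combination vector of the same length as
    the coefficient vector; e.g. selecting bg + be + bge yields the joint
    effect of carrying the risk factors together.
    """
    c = np.asarray(contrast, dtype=float)
    if c.shape != fit.coefficients.shape:
        raise ModelError(
            f"contrast length {c.size} != number of coefficients "
            f"{fit.coefficients.size}"
        )
    est = float(c @ fit.coefficients)
    var = float(c @ fit.covariance @ c)
    if np.allclose(c, 0.0):
        return EffectEstimate(
            OR=1.0, ci_low=1.0, ci_high=1.0, p=1.0, contrast=tuple(c)
        )
    if var <= 0.0:
        raise ModelError("zero-variance contrast")
    se = np.sqrt(var)
    z = est / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return EffectEstimate(
        OR=float(np.exp(est)),
        ci_low=float(np.exp(est - Z_95 * se)),
        ci_high=float(np.exp(est + Z_95 * se)),
        p=p,
        contrast=tuple(c),
        log_or=est,
        se=float(se),
    )


def likelihood_ratio_p(fit_full: LogisticFit, fit_reduced: LogisticFit, df=1):
    """Likelihood-ratio p comparing nested fits (full vs reduced)."""
    lr = 2.0 * (fit_full.loglik - fit_reduced.loglik)
    lr = max(lr, 0.0)
    return float(stats.chi2.sf(lr, df=df))
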