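"""Maximum-likelihood logistic regression by iteratively reweighted least squares.

A compact, fully controlled IRLS fitter used for propensity scores, the
restricted-cubic-spline linearity tests, the AIC cutoff scan and the
diagnostic model.  Convergence is declared when the relative change in
log-likelihood drops below 1e-10 (at most 100 iterations).  Complete or
quasi-complete separation is detected (diverging coefficients / vanishing
working weights) and handled by refitting with a small ridge penalty, which
is flagged on the result.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

MAX_ITER = 100
LL_RTOL = 1e-10
SEPARATION_RIDGE = 1e-6


class CollinearityError(ValueError):
    """Raised when the design matrix is rank-deficient, naming the columns."""


@dataclass
class LogisticFit:
    """Fitted logistic model: coefficients, Wald inference, likelihood, AIC.

    ``aic = 2k - 2*log_likelihood`` with k the number of free coefficients.
    """

    terms: list[str]
    params: np.ndarray
    bse: np.ndarray
    log_likelihood: float
    converged: bool
    separation: bool = False
    ridge: float = 0.0
    n_obs: int = 0

    @property
    def k(self) -> int:
        return len(self.params)

    @property
    def aic(self) -> float:
        return 2.0 * self.k - 2.0 * self.log_likelihood

    @property
    def zvalues(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.params / self.bse

    @property
    def p_values(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.zvalues))

    def coef(self, term: str) -> float:
        return float(self.params[self.terms.index(term)])

    def predict(self, X) -> np.ndarray:
        """Predicted probabilities for a design matrix (columns = terms)."""
        X = np.asarray(X, float)
        return _expit(X @ self.params)

    def linear_predictor(self, X) -> np.ndarray:
        return np.asarray(X, float) @ self.params

    def summary(self) -> pd.DataFrame:
        """Coefficient table: estimate, SE, z, p, 95% Wald CI."""
        lo = self.params - 1.959963984540054 * self.bse
        hi = self.params + 1.959963984540054 * self.bse
        return pd.DataFrame(
            {
                "coef": self.params,
                "std_err": self.bse,
                "z": self.zvalues,
                "p_value": self.p_values,
                "ci_low": lo,
                "ci_high": hi,
            },
            index=pd.Index(self.terms, name="term"),
        )


def _expit(eta: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * eta))


def _log_likelihood(y, eta, weights) -> float:
    # numerically stable sum w*(y*eta - log(1+exp(eta)))
    return float(np.sum(weights * (y * eta - np.logaddexp(0.0, eta))))


def fit_logistic(
    design,
    outcome,
    terms: list[str] | None = None,
    ridge: float | None = None,
    freq_weights=None,
) -> LogisticFit:
    """Fit a binary logistic model by IRLS.

    Parameters
    ----------
    design : (n, k) array or DataFrame — must include its own intercept
        column if one is wanted; DataFrames supply term names.
    outcome : binary 0/1 vector.
    ridge : optional L2 penalty on all coefficients; applied automatically
        at :data:`SEPARATION_RIDGE` when separation is detected.
    freq_weights : optional per-row frequency weights (aggregated data).

    Raises :class:`CollinearityError` naming the collinear columns when the
    design is rank-deficient.
    """
    if isinstance(design, pd.DataFrame):
        terms = terms or list(design.columns)
        X = design.to_numpy(float)
    else:
        X = np.asarray(design, float)
        terms = terms or [f"x{i}" for i in range(X.shape[1])]
    y = np.asarray(outcome, float)
    w = np.ones(X.shape[0]) if freq_weights is None else np.asarray(freq_weights, float)
    if X.shape[0] != y.size:
        raise ValueError("design and outcome lengths differ")
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise ValueError("outcome must be binary 0/1")
    _check_rank(X, terms)

    fit = _irls(X, y, w, ridge or 0.0)
    if ridge is None and (not fit.converged or fit.separation):
        log.warning("separation detected; refitting with ridge penalty %.1e", SEPARATION_RIDGE)
        fit = _irls(X, y, w, SEPARATION_RIDGE)
        fit.separation = True
    fit.terms = terms
    fit.n_obs = int(w.sum())
    return fit


def _check_rank(X: np.ndarray, terms) -> None:
    if X.shape[1] == 0:
        raise ValueError("empty design")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name a minimal set of offending columns by greedy QR inspection
        bad = []
        cols: list[int] = []
        for j in range(X.shape[1]):
            trial = X[:, cols + [j]]
            if np.linalg.matrix_rank(trial) == len(cols) + 1:
                cols.append(j)
            else:
                bad.append(terms[j])
        raise CollinearityError(f"design is rank-deficient; collinear column(s): {bad}")


def _irls(X, y, w, ridge: float) -> LogisticFit:
    n, k = X.shape
    beta = np.zeros(k)
    eta = X @ beta
    ll = _log_likelihood(y, eta, w) - 0.5 * ridge * beta @ beta
    converged = False
    separation = False
    for _ in range(MAX_ITER):
        mu = _expit(eta)
        W = w * mu * (1.0 - mu)
        grad = X.T @ (w * (y - mu)) - ridge * beta
        H = (X * W[:, None]).T @ X + ridge * np.eye(k)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            separation = True
            break
        # step-halving so the penalised likelihood never (materially) decreases;
        # a float-noise tolerance lets the full Newton step land at the optimum
        new_ll = ll
        noise = 1e-10 * (abs(ll) + 1.0) if np.isfinite(ll) else np.inf
        for half in range(30):
            cand = beta + step / (2.0**half)
            eta_c = X @ cand
            cand_ll = _log_likelihood(y, eta_c, w) - 0.5 * ridge * cand @ cand
            if cand_ll >= ll - noise:
                beta, eta, new_ll = cand, eta_c, cand_ll
                break
        if np.isfinite(ll) and abs(new_ll - ll) <= LL_RTOL * (abs(ll) + LL_RTOL):
            ll = new_ll
            converged = True
            break
        ll = new_ll
    if np.max(np.abs(beta)) > 30.0:
        separation = True
    mu = _expit(X @ beta)
    W = w * mu * (1.0 - mu)
    H = (X * W[:, None]).T @ X + ridge * np.eye(k)
    try:
        cov = np.linalg.inv(H)
        bse = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        bse = np.full(k, np.nan)
        separation = True
    return LogisticFit(
        terms=[f"x{i}" for i in range(k)],
        params=beta,
        bse=bse,
        log_likelihood=_log_likelihood(y, X @ beta, w),
        converged=converged,
        separation=separation,
        ridge=ridge,
    )
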