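"""Proportional-odds (cumulative-logit) regression fitted by Newton's method.

This is the statistical engine behind the gene burden test.  The outcome is an
ordered categorical variable (here control < late-onset case < early-onset
case) and the model for K ordered levels with K-1 cutpoints ``theta`` is

    P(Y >= k | x) = logistic(x' beta - theta_k),   k = 1..K-1

so a positive ``beta`` on the burden score means the score shifts probability
mass toward the more severe end of the outcome — i.e. beta > 0 is
risk-increasing.  A single slope vector is shared across all cutpoints
(the proportional-odds assumption).

The fitter is a dense Newton iteration with analytic gradient and Hessian and
step-halving, supporting frequency weights so that data sets with few distinct
(outcome, covariate) rows — e.g. covariate-free power simulations — collapse
to a handful of weighted rows and fit in microseconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from scipy.stats import chi2

__all__ = ["OrdinalModelFit", "fit_proportional_odds", "lrt_p"]

_PROB_FLOOR = 1e-300


@dataclass
class OrdinalModelFit:
    """Result of a proportional-odds fit.

    ``cutpoints`` are strictly increasing; ``beta`` holds the slopes for the
    columns of the design matrix (empty for an intercept-only/null model).
    ``cov`` is the observed-information covariance of (cutpoints, beta).
    """

    cutpoints: np.ndarray
    beta: np.ndarray
    log_likelihood: float
    converged: bool
    n_iter: int
    n_obs: float
    cov: np.ndarray | None = None
    message: str = ""
    levels: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def beta_se(self) -> np.ndarray:
        if self.cov is None:
            return np.full_like(self.beta, np.nan)
        k = len(self.cutpoints)
        return np.sqrt(np.diag(self.cov)[k:])


def _eta_probs(codes, X, weights, theta, beta, K):
    """Per-sample boundary logits and category probabilities.

    Returns (pi, s_lo, s_hi) where pi is P(Y = observed category) and s_lo,
    s_hi are the survivor probabilities at the category's lower/upper boundary
    (1 for the lowest boundary, 0 for the highest).
    """
    lin = X @ beta if X is not None and X.shape[1] else np.zeros(len(codes))
    eta = lin[:, None] - theta[None, :]  # (n, K-1)
    s = expit(eta)
    # survivor at boundaries 0..K: s_full[:, 0] = 1, s_full[:, K] = 0
    s_full = np.concatenate(
        [np.ones((len(codes), 1)), s, np.zeros((len(codes), 1))], axis=1
    )
    idx = np.arange(len(codes))
    s_lo = s_full[idx, codes]
    s_hi = s_full[idx, codes + 1]
    pi = s_lo - s_hi
    return pi, s_lo, s_hi


def _loglik(codes, X, weights, theta, beta, K):
    if np.any(np.diff(theta) <= 0):
        return -np.inf
    pi, _, _ = _eta_probs(codes, X, weights, theta, beta, K)
    if np.any(pi <= 0):
        return -np.inf
    return float(np.sum(weights * np.log(np.maximum(pi, _PROB_FLOOR))))


def _grad_hess(codes, X, weights, theta, beta, K):
    n = len(codes)
    p = X.shape[1] if X is not None else 0
    pi, s_lo, s_hi = _eta_probs(codes, X, weights, theta, beta, K)
    pi = np.maximum(pi, _PROB_FLOOR)
    u_lo = s_lo * (1.0 - s_lo)
    u_hi = s_hi * (1.0 - s_hi)
    g_lo = u_lo / pi  # zero automatically for lowest category (u_lo = 0)
    g_hi = -u_hi / pi
    h_ll = u_lo * (1.0 - 2.0 * s_lo) / pi - (u_lo / pi) ** 2
    h_uu = -u_hi * (1.0 - 2.0 * s_hi) / pi - (u_hi / pi) ** 2
    h_lu = u_lo * u_hi / pi**2

    w = weights
    k_lo = codes - 1  # theta index at lower boundary, valid when codes >= 1
    k_hi = codes  # theta index at upper boundary, valid when codes <= K-2
    m_lo = codes >= 1
    m_hi = codes <= K - 2

    nth = K - 1
    grad = np.zeros(nth + p)
    np.add.at(grad, k_lo[m_lo], -(w * g_lo)[m_lo])
    np.add.at(grad, k_hi[m_hi], -(w * g_hi)[m_hi])
    if p:
        grad[nth:] = X.T @ (w * (g_lo + g_hi))

    H = np.zeros((nth + p, nth + p))
    np.add.at(H, (k_lo[m_lo], k_lo[m_lo]), (w * h_ll)[m_lo])
    np.add.at(H, (k_hi[m_hi], k_hi[m_hi]), (w * h_uu)[m_hi])
    both = m_lo & m_hi
    np.add.at(H, (k_lo[both], k_hi[both]), (w * h_lu)[both])
    np.add.at(H, (k_hi[both], k_lo[both]), (w * h_lu)[both])
    if p:
        for m in range(nth):
            wrow = np.zeros(n)
            sel = m_lo & (k_lo == m)
            wrow[sel] += (h_ll + h_lu)[sel]
            sel = m_hi & (k_hi == m)
            wrow[sel] += (h_uu + h_lu)[sel]
            block = -(X.T @ (w * wrow))
            H[m, nth:] = block
            H[nth:, m] = block
        wbb = w * (h_ll + 2.0 * h_lu + h_uu)
        H[nth:, nth:] = X.T @ (wbb[:, None] * X)
    return grad, H


def fit_proportional_odds(
    y,
    X=None,
    weights=None,
    max_iter: int = 100,
    tol: float = 1e-8,
    start: np.ndarray | None = None,
) -> OrdinalModelFit:
    """Maximum-likelihood proportional-odds fit.

    Parameters
    ----------
    y : array-like of ordered integer codes (any set of >= 2 distinct values;
        they are ranked and recoded internally).
    X : optional (n, p) design matrix of slopes; no intercept column (the
        cutpoints absorb it).  ``None`` or zero columns fits the null model.
    weights : optional frequency weights.
    """
    y = np.asarray(y)
    levels, codes = np.unique(y, return_inverse=True)
    K = len(levels)
    if K < 2:
        raise ValueError("outcome must have at least two observed levels")
    n = len(codes)
    weights = np.ones(n) if weights is None else np.asarray(weights, float)
    if X is not None:
        X = np.atleast_2d(np.asarray(X, float))
        if X.shape[0] != n:
            X = X.T
        if X.shape[0] != n:
            raise ValueError("design matrix and outcome lengths differ")
    p = X.shape[1] if X is not None else 0

    wtot = weights.sum()
    if start is not None:
        phi = np.asarray(start, float).copy()
    else:
        # empirical cumulative logits at beta = 0
        cum = np.array(
            [weights[codes >= k].sum() / wtot for k in range(1, K)]
        )
        cum = np.clip(cum, 1e-6, 1 - 1e-6)
        theta0 = -np.log(cum / (1 - cum))
        phi = np.concatenate([theta0, np.zeros(p)])

    nth = K - 1
    ll = _loglik(codes, X, weights, phi[:nth], phi[nth:], K)
    converged = False
    message = "max iterations reached"
    it = 0
    for it in range(1, max_iter + 1):
        grad, H = _grad_hess(codes, X, weights, phi[:nth], phi[nth:], K)
        if np.max(np.abs(grad)) < tol:
            converged = True
            message = "gradient norm below tolerance"
            break
        try:
            step = np.linalg.solve(H, -grad)
        except np.linalg.LinAlgError:
            message = "singular Hessian"
            break
        # step-halving: H is negative definite near the optimum, so the
        # Newton direction ascends; back off until the likelihood improves
        # (acceptance is relative — near the optimum the likelihood sits at
        # its floating-point plateau)
        scale = 1.0
        for _ in range(40):
            cand = phi + scale * step
            ll_new = _loglik(codes, X, weights, cand[:nth], cand[nth:], K)
            if ll_new > ll - 1e-10 * max(1.0, abs(ll)):
                break
            scale *= 0.5
        else:
            # per-observation gradient already negligible: accept as solved
            if np.max(np.abs(grad)) < 1e-6 * max(1.0, wtot):
                converged = True
                message = "likelihood at floating-point plateau"
            else:
                message = "step-halving failed to improve likelihood"
            break
        if np.max(np.abs(scale * step)) < 1e-14:
            converged = True
            message = "step size below tolerance"
            phi = cand
            ll = ll_new
            break
        phi = cand
        ll = ll_new

    theta, beta = phi[:nth], phi[nth:]
    cov = None
    try:
        _, H = _grad_hess(codes, X, weights, theta, beta, K)
        cov = np.linalg.inv(-H)
    except np.linalg.LinAlgError:
        pass
    if p and np.any(np.abs(beta) > 30):
        converged = False
        message = "estimate diverged (possible separation)"
    return OrdinalModelFit(
        cutpoints=theta,
        beta=beta,
        log_likelihood=ll,
        converged=converged,
        n_iter=it,
        n_obs=float(wtot),
        cov=cov,
        message=message,
        levels=levels,
    )


def lrt_p(full: OrdinalModelFit, null: OrdinalModelFit, df: int = 1) -> float:
    """Likelihood-ratio P: upper chi^2_df tail of 2*(ll_full - ll_null).

    The statistic is floored at zero; a full-model likelihood materially
    below the null indicates an optimizer failure and raises.
    """
    delta = full.log_likelihood - null.log_likelihood
    if delta < -1e-6 * max(1.0, abs(null.log_likelihood)):
        raise RuntimeError(
            "full-model likelihood below null-model likelihood: "
            f"{full.log_likelihood} < {null.log_likelihood}"
        )
    stat = max(0.0, 2.0 * delta)
    return float(chi2.sf(stat, df))
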