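"""Maximum-likelihood fitting of the cumulative-logit proportional-odds model.

The model for an ordinal outcome Y in {1, ..., J} with covariate row x is

    logit P(Y <= k | x) = alpha_k + x' beta,      k = 1, ..., J-1,

with strictly increasing cut-points alpha_1 < ... < alpha_{J-1} and a
single slope vector shared across cuts (the proportional-odds
assumption).  Under this coding a covariate that moves subjects toward
higher categories gets a negative slope.

The fitter is a damped Newton ascent on the exact multinomial
log-likelihood with analytic gradient and Hessian, step-halving to
guarantee monotone ascent, and a ridge fallback when the Hessian is not
negative definite.  The returned ``loglik`` is the maximized multinomial
log-likelihood consumed directly by the likelihood-ratio tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.special import expit


class DegenerateDataError(ValueError):
    """Raised when the outcome has fewer than two observed categories."""


@dataclass(frozen=True)
class OLRFit:
    """Result of a proportional-odds fit.

    ``intercepts`` are the cut-points alpha_k for the categories actually
    observed in the data (unobserved categories contribute no cut);
    ``slopes`` are the covariate coefficients; ``loglik`` is the maximized
    log-likelihood (always <= 0).
    """

    intercepts: np.ndarray
    slopes: np.ndarray
    loglik: float
    converged: bool
    n_iterations: int
    grad_norm: float


def _loglik_terms(alpha, beta, X, yi, K):
    """Log-likelihood and per-subject logistic quantities.

    yi holds 0-based category indices; cut k sits between categories k and
    k+1.  Subjects in the top category have no upper cut (z1 = +inf) and
    subjects in the bottom category no lower cut (z0 = -inf).
    """
    xb = X @ beta if X.shape[1] else np.zeros(len(yi))
    hi = yi < K  # has an upper cut
    lo = yi > 0  # has a lower cut
    k1 = np.minimum(yi, K - 1)  # index of upper cut (masked by hi)
    k0 = np.maximum(yi - 1, 0)  # index of lower cut (masked by lo)
    F1 = np.where(hi, expit(alpha[k1] + xb), 1.0)
    F0 = np.where(lo, expit(alpha[k0] + xb), 0.0)
    pr = F1 - F0
    return xb, hi, lo, k1, k0, F1, F0, pr


def fit_proportional_odds(
    y: np.ndarray,
    covariates: Optional[np.ndarray] = None,
    start: Optional[np.ndarray] = None,
    grad_tol: float = 1e-8,
    loglik_tol: float = 1e-10,
    max_iter: int = 200,
) -> OLRFit:
    """Fit logit P(Y <= k) = alpha_k + x' beta by damped Newton ascent.

    Parameters
    ----------
    y
        Ordinal outcome codes (any integers; only the observed ordering
        matters, and intercepts are returned for observed cuts only).
    covariates
        Optional ``(n, p)`` design matrix (no intercept column); ``None``
        or a zero-column matrix fits the intercept-only model, whose MLE
        reproduces the empirical cumulative category frequencies.
    start
        Optional warm start ``[alpha_1..alpha_K, beta_1..beta_p]``, e.g.
        the solution of a nested model padded with zeros.

    Raises
    ------
    DegenerateDataError
        If fewer than two categories are observed.
    """
    y = np.asarray(y)
    cats, yi = np.unique(y, return_inverse=True)
    K = len(cats) - 1
    if K < 1:
        raise DegenerateDataError("outcome has a single observed category")
    n = len(y)
    X = (
        np.zeros((n, 0))
        if covariates is None
        else np.asarray(covariates, dtype=float).reshape(n, -1)
    )
    p = X.shape[1]

    if start is not None and len(start) == K + p:
        alpha = np.asarray(start[:K], dtype=float).copy()
        beta = np.asarray(start[K:], dtype=float).copy()
        if not np.all(np.diff(alpha) > 0):
            start = None
    if start is None or len(start) != K + p:
        # empirical cumulative logits; clip away 0/1 frequencies
        cum = np.cumsum(np.bincount(yi, minlength=K + 1))[:K] / n
        cum = np.clip(cum, 1.0 / (2 * n), 1 - 1.0 / (2 * n))
        alpha = np.log(cum / (1 - cum))
        alpha = np.maximum.accumulate(alpha + np.arange(K) * 1e-9)
        beta = np.zeros(p)

    xb, hi, lo, k1, k0, F1, F0, pr = _loglik_terms(alpha, beta, X, yi, K)
    ll = float(np.log(pr).sum())
    grad_norm = np.inf
    converged = False
    it = 0

    for it in range(1, max_iter + 1):
        f1 = F1 * (1 - F1)
        f0 = F0 * (1 - F0)
        g1 = np.where(hi, f1 / pr, 0.0)
        g0 = np.where(lo, f0 / pr, 0.0)
        # second derivatives of log pr in (z1, z0)
        h11 = np.where(hi, f1 * (1 - 2 * F1) / pr, 0.0) - g1 * g1
        h00 = np.where(lo, -f0 * (1 - 2 * F0) / pr, 0.0) - g0 * g0
        h10 = g1 * g0

        grad = np.empty(K + p)
        grad[:K] = np.bincount(k1, weights=g1, minlength=K) - np.bincount(
            k0, weights=g0, minlength=K
        )
        if p:
            grad[K:] = X.T @ (g1 - g0)
        grad_norm = float(np.max(np.abs(grad)))
        if grad_norm < grad_tol:
            converged = True
            break

        H = np.zeros((K + p, K + p))
        # alpha-alpha block: diagonal plus adjacent-cut couplings
        np.add.at(H, (k1, k1), np.where(hi, h11, 0.0))
        np.add.at(H, (k0, k0), np.where(lo, h00, 0.0))
        both = hi & lo
        if both.any():
            np.add.at(H, (k1[both], k0[both]), h10[both])
            np.add.at(H, (k0[both], k1[both]), h10[both])
        if p:
            w1 = h11 + h10  # weight on row k1
            w0 = h00 + h10  # weight on row k0
            for c in range(p):
                xc = X[:, c]
                ab = np.bincount(k1, weights=w1 * xc, minlength=K) + np.bincount(
                    k0, weights=w0 * xc, minlength=K
                )
                H[:K, K + c] = ab
                H[K + c, :K] = ab
            wbb = h11 + h00 + 2 * h10
            H[K:, K:] = X.T @ (wbb[:, None] * X)

        # Newton direction from -H, with a ridge if not positive definite
        A = -H
        ridge = 0.0
        scale = max(1.0, float(np.max(np.abs(np.diag(A)))))
        for _ in range(40):
            try:
                cf = cho_factor(A + ridge * np.eye(K + p), lower=True)
                break
            except np.linalg.LinAlgError:
                ridge = 1e-8 * scale if ridge == 0.0 else ridge * 10
        else:  # pragma: no cover - ridge always succeeds eventually
            break
        delta = cho_solve(cf, grad)

        # step-halving: require finite ascent and ordered cut-points
        step = 1.0
        accepted = False
        for _ in range(40):
            a_new = alpha + step * delta[:K]
            b_new = beta + step * delta[K:]
            if K == 1 or np.all(np.diff(a_new) > 0):
                terms = _loglik_terms(a_new, b_new, X, yi, K)
                pr_new = terms[-1]
                if np.all(pr_new > 0):
                    ll_new = float(np.log(pr_new).sum())
                    if ll_new > ll - 1e-13:
                        accepted = True
                        break
            step *= 0.5
        if not accepted:
            break
        alpha, beta = a_new, b_new
        xb, hi, lo, k1, k0, F1, F0, pr = terms
        dll = ll_new - ll
        ll = ll_new
        if abs(dll) < loglik_tol:
            # confirm with the gradient at the new point on the next pass,
            # but treat a stalled likelihood as converged
            converged = True
            break

    # report the score at the returned point, not at the previous iterate
    f1 = F1 * (1 - F1)
    f0 = F0 * (1 - F0)
    g1 = np.where(hi, f1 / pr, 0.0)
    g0 = np.where(lo, f0 / pr, 0.0)
    grad = np.empty(K + p)
    grad[:K] = np.bincount(k1, weights=g1, minlength=K) - np.bincount(
        k0, weights=g0, minlength=K
    )
    if p:
        grad[K:] = X.T @ (g1 - g0)
    grad_norm = float(np.max(np.abs(grad)))
    if not converged and grad_norm < 1e-5:
        # gradient essentially flat; accept as converged
        converged = True
    return OLRFit(
        intercepts=alpha,
        slopes=beta,
        loglik=ll,
        converged=converged,
        n_iterations=it,
        grad_norm=grad_norm,
    )
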