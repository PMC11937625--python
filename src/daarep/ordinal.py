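"""Maximum-likelihood fitting of the proportional-odds (cumulative logit) model.

The model for an ordered response with categories ``0 .. J-1`` and covariate
row ``x`` is ``P(Y <= j | x) = expit(alpha_j - x @ beta)`` with increasing
thresholds ``alpha_0 < ... < alpha_{J-2}``.  A positive slope shifts
probability mass toward higher categories.

Used here per taxon with the distinct TSS proportions of the taxon as the
ordered categories (ties share a category), which makes the two-group test a
covariate-capable generalization of the Wilcoxon rank-sum test.

The fit is a dedicated Newton solver with analytic gradient and Hessian:
the evaluation protocols need tens of thousands of per-taxon fits, so the
solver is written for that scale and verified against a generic ordinal
regression implementation in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

#: |slope| beyond which the likelihood is treated as unbounded (separation)
SEPARATION_BOUND = 20.0


@dataclass
class OrdinalFit:
    beta: np.ndarray  # slopes, shape (k,)
    se: np.ndarray  # Wald standard errors of the slopes
    alpha: np.ndarray  # thresholds, shape (J-1,)
    loglike: float
    converged: bool
    separated: bool
    n_iter: int


def _loglike_parts(alpha: np.ndarray, eta: np.ndarray, codes: np.ndarray, J: int):
    """Per-observation F, f, f' at the two active thresholds and cell prob."""
    has_b = codes < J - 1
    has_a = codes > 0
    u_b = np.where(has_b, alpha[np.minimum(codes, J - 2)] - eta, np.inf)
    u_a = np.where(has_a, alpha[np.maximum(codes - 1, 0)] - eta, -np.inf)
    F_b = np.where(has_b, expit(u_b), 1.0)
    F_a = np.where(has_a, expit(u_a), 0.0)
    f_b = np.where(has_b, F_b * (1.0 - F_b), 0.0)
    f_a = np.where(has_a, F_a * (1.0 - F_a), 0.0)
    fp_b = f_b * (1.0 - 2.0 * F_b)
    fp_a = f_a * (1.0 - 2.0 * F_a)
    p = np.clip(F_b - F_a, 1e-300, None)
    return has_a, has_b, f_a, f_b, fp_a, fp_b, p


def _grad_hess(theta: np.ndarray, X: np.ndarray, codes: np.ndarray, J: int):
    """Log-likelihood, gradient and Hessian at ``theta = [alpha, beta]``."""
    n, k = X.shape
    m_a = J - 1
    alpha, beta = theta[:m_a], theta[m_a:]
    eta = X @ beta
    has_a, has_b, f_a, f_b, fp_a, fp_b, p = _loglike_parts(alpha, eta, codes, J)
    ll = float(np.log(p).sum())

    r_b = f_b / p
    r_a = f_a / p
    s = (f_a - f_b) / p  # d log p / d eta

    g = np.zeros(m_a + k)
    b_idx = np.minimum(codes, J - 2)
    a_idx = np.maximum(codes - 1, 0)
    np.add.at(g, b_idx[has_b], r_b[has_b])
    np.add.at(g, a_idx[has_a], -r_a[has_a])
    g[m_a:] = X.T @ s

    H = np.zeros((m_a + k, m_a + k))
    # threshold block
    np.add.at(H, (b_idx[has_b], b_idx[has_b]), (fp_b / p - r_b**2)[has_b])
    np.add.at(H, (a_idx[has_a], a_idx[has_a]), (-fp_a / p - r_a**2)[has_a])
    both = has_a & has_b
    cross = (r_a * r_b)[both]
    np.add.at(H, (a_idx[both], b_idx[both]), cross)
    np.add.at(H, (b_idx[both], a_idx[both]), cross)
    # threshold x slope block
    coef_b = -(fp_b / p) - r_b * s
    coef_a = (fp_a / p) + r_a * s
    for l in range(k):
        np.add.at(H, (b_idx[has_b], m_a + l), (coef_b * X[:, l])[has_b])
        np.add.at(H, (a_idx[has_a], m_a + l), (coef_a * X[:, l])[has_a])
        np.add.at(H, (m_a + l, b_idx[has_b]), (coef_b * X[:, l])[has_b])
        np.add.at(H, (m_a + l, a_idx[has_a]), (coef_a * X[:, l])[has_a])
    # slope block
    w = (fp_b - fp_a) / p - s**2
    H[m_a:, m_a:] = (X * w[:, None]).T @ X
    return ll, g, H


def _loglike(theta: np.ndarray, X: np.ndarray, codes: np.ndarray, J: int) -> float:
    m_a = J - 1
    eta = X @ theta[m_a:]
    *_, p = _loglike_parts(theta[:m_a], eta, codes, J)
    return float(np.log(p).sum())


def fit_proportional_odds(
    y: np.ndarray,
    X: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> OrdinalFit:
    """Fit the cumulative logit model by Newton's method.

    ``y`` may be any 1-D array; its distinct values define the ordered
    categories (ties share a category).  ``X`` is the covariate matrix
    without an intercept (the thresholds absorb it).  Requires at least two
    distinct response values.
    """
    y = np.asarray(y)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, k = X.shape
    _, codes = np.unique(y, return_inverse=True)
    J = int(codes.max()) + 1
    if J < 2:
        raise ValueError("response has a single distinct value; model is degenerate")

    # start at the empirical cumulative logits, slope zero
    counts = np.bincount(codes, minlength=J)
    cum = np.cumsum(counts)[:-1] / n
    cum = np.clip(cum, 1.0 / (2 * n), 1 - 1.0 / (2 * n))
    theta = np.concatenate([np.log(cum / (1 - cum)), np.zeros(k)])

    ll = -np.inf
    converged = False
    separated = False
    it = 0
    for it in range(1, max_iter + 1):
        ll, g, H = _grad_hess(theta, X, codes, J)
        if np.max(np.abs(g)) < tol:
            converged = True
            break
        # Newton direction on the negative Hessian; ridge fallback if singular
        try:
            step = np.linalg.solve(-H, g)
        except np.linalg.LinAlgError:
            step = np.linalg.solve(-H + 1e-8 * np.eye(H.shape[0]), g)
        # step halving: keep thresholds ordered and the likelihood increasing
        scale = 1.0
        for _ in range(40):
            cand = theta + scale * step
            if (J == 2 or np.all(np.diff(cand[: J - 1]) > 0)) and _loglike(
                cand, X, codes, J
            ) >= ll - 1e-10:
                break
            scale *= 0.5
        theta = theta + scale * step
        if np.max(np.abs(theta[J - 1 :])) > SEPARATION_BOUND:
            separated = True
            theta[J - 1 :] = np.clip(theta[J - 1 :], -SEPARATION_BOUND, SEPARATION_BOUND)
            break

    ll, g, H = _grad_hess(theta, X, codes, J)
    try:
        cov = np.linalg.inv(-H)
        se = np.sqrt(np.clip(np.diag(cov)[J - 1 :], 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(k, np.nan)
    return OrdinalFit(
        beta=theta[J - 1 :].copy(),
        se=se,
        alpha=theta[: J - 1].copy(),
        loglike=ll,
        converged=converged or separated,
        separated=separated,
        n_iter=it,
    )
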