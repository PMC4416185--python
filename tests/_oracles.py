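"""Independent reference computations for cross-checking the solver.

Everything here deliberately avoids the package's IRLS-CD code path: the
convex oracle minimizes the penalized objective through scipy's L-BFGS-B on
the exact split-variable reformulation (beta = b+ - b-, b+/- >= 0, which
turns the L1 term into a smooth linear one), and the likelihood references
work from the raw per-subject covariates rather than the difference matrix.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize


def penalized_objective_reference(X, starts, sizes, penalty_mask, beta, lam):
    """Direct evaluation of sum_n log(1 + sum_l e^{-x_ln beta}) + lam ||beta_pen||_1."""
    eta = X @ beta
    m = np.maximum(np.maximum.reduceat(-eta, starts), 0.0)
    S = np.add.reduceat(np.exp(-eta - np.repeat(m, sizes)), starts)
    nll = float(np.sum(m + np.log(np.exp(-m) + S)))
    return nll + lam * float(np.abs(beta[penalty_mask]).sum())


def convex_oracle(dm, lam):
    """Minimize the penalized conditional likelihood with a generic convex solver.

    Returns ``(beta_opt, f_opt)``.  Uses the split beta = b+ - b- with
    nonnegativity bounds, so the problem is smooth and L-BFGS-B applies; the
    optimum coincides with the L1 problem's.
    """
    X = np.asarray(dm.X.todense()) if dm.is_sparse else np.asarray(dm.X)
    starts, sizes, mask = dm.starts, dm.stratum_sizes, dm.penalty_mask
    p = X.shape[1]
    lam_vec = np.where(mask, lam, 0.0)

    def fg(z):
        beta = z[:p] - z[p:]
        eta = X @ beta
        m = np.maximum(np.maximum.reduceat(-eta, starts), 0.0)
        expterms = np.exp(-eta - np.repeat(m, sizes))
        S = np.add.reduceat(expterms, starts)
        nll = float(np.sum(m + np.log(np.exp(-m) + S)))
        r = expterms / np.repeat(np.exp(-m) + S, sizes)
        g = -(X.T @ r)
        val = nll + float(lam_vec @ (z[:p] + z[p:]))
        return val, np.concatenate([g + lam_vec, -g + lam_vec])

    res = minimize(
        fg,
        np.zeros(2 * p),
        jac=True,
        method="L-BFGS-B",
        bounds=[(0, None)] * (2 * p),
        options=dict(maxiter=20000, maxfun=100000, ftol=1e-16, gtol=1e-10),
    )
    return res.x[:p] - res.x[p:], float(res.fun)


def undifferenced_log_likelihood(U, stratum_codes, case_indicator, beta):
    """Conditional log-likelihood from raw covariates: per stratum,
    u_case beta - log sum_l exp(u_l beta).  Never forms differences."""
    U = np.asarray(U, dtype=float)
    eta = U @ np.asarray(beta, dtype=float)
    codes = np.asarray(stratum_codes)
    ll = 0.0
    for s in np.unique(codes):
        rows = np.flatnonzero(codes == s)
        e = eta[rows]
        m = e.max()
        lse = m + np.log(np.sum(np.exp(e - m)))
        case = rows[np.asarray(case_indicator)[rows] == 1][0]
        ll += eta[case] - lse
    return float(ll)


def lasso_quadratic_oracle(A, b, lambda_vec):
    """Minimize (1/2) g^t A g - b^t g + sum lambda_j |g_j| by split L-BFGS-B."""
    A = np.asarray(A, dtype=float)
    b = np.asarray(b, dtype=float)
    lv = np.asarray(lambda_vec, dtype=float)
    p = len(b)

    def f(z):
        g = z[:p] - z[p:]
        return 0.5 * g @ A @ g - b @ g + lv @ (z[:p] + z[p:])

    res = minimize(f, np.zeros(2 * p), method="L-BFGS-B", bounds=[(0, None)] * (2 * p),
                   options=dict(maxiter=5000, ftol=1e-16, gtol=1e-12))
    return res.x[:p] - res.x[p:], float(res.fun)


def mle_exists(dm, bound: float = 10.0) -> bool:
    """Heuristic existence check for the unpenalized conditional MLE:
    the oracle solution stays bounded (no separation)."""
    beta, _ = convex_oracle(dm, 0.0)
    return bool(np.max(np.abs(beta)) < bound)


def full_rank(dm, tol: float = 1e-8) -> bool:
    X = np.asarray(dm.X.todense()) if dm.is_sparse else np.asarray(dm.X)
    if X.shape[0] < X.shape[1]:
        return False
    sv = np.linalg.svd(X, compute_uv=False)
    return bool(sv.min() > tol)
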