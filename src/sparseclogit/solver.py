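"""Penalized fit at a fixed lambda: IRLS outer loop, coordinate-descent inner loop.

Each outer iteration builds the diagonal-weight quadratic model of the
conditional log-likelihood at the current beta, reduces it to the p x p Gram
system (A = X^t W X, b = X^t W z), solves the resulting weighted Lasso
problem by cyclic coordinate descent with soft-thresholding, and applies an
Armijo backtracking line search on the true penalized objective.  The solver
only ever touches A and b — never W^(1/2) X — so memory stays O(p^2)
regardless of the number of matched sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from . import likelihood
from .data import DifferenceMatrix

logger = logging.getLogger(__name__)


@dataclass
class SolverConfig:
    """Knobs of the IRLS-CD solver.

    tau : relative decrease of the penalized objective declaring outer
        convergence.
    alpha1, alpha2 : Armijo slope fraction (<= 0.5) and backtracking shrink
        factor (< 1).
    inner_tol : max absolute coordinate change per CD sweep declaring the
        inner problem solved.
    weight_floor : lower clamp on IRLS weights (near-separation guard).
    """

    tau: float = 1e-8
    alpha1: float = 0.25
    alpha2: float = 0.5
    max_outer: int = 100
    inner_tol: float = 1e-9
    max_inner_sweeps: int | None = None  # default 10 p + 100
    weight_floor: float = likelihood.WEIGHT_FLOOR
    t_min: float = 1e-12
    step_tol: float = 1e-10  # max |gamma - beta| declaring the fixed point reached
    kkt_tol: float = 1e-5    # subgradient residual required on top of the tau test
    kkt_flat_tol: float = 1e-4  # residual accepted once the objective is fp-flat
    snap_tol: float = 1e-10  # penalized |beta_j| below this collapse to exact zero
    verbose: bool = False

    def __post_init__(self):
        if not (self.tau > 0 and self.inner_tol > 0 and self.weight_floor > 0):
            raise ValueError("tolerances must be positive")
        if not (0 <= self.alpha1 <= 0.5):
            raise ValueError("alpha1 must lie in [0, 0.5]")
        if not (0 < self.alpha2 < 1):
            raise ValueError("alpha2 must lie in (0, 1)")

    def sweeps_cap(self, p: int) -> int:
        return self.max_inner_sweeps if self.max_inner_sweeps is not None else 10 * p + 100


@dataclass
class FitResult:
    """Solution of the penalized problem at one lambda."""

    beta: np.ndarray
    lam: float
    objective: float
    neg_log_likelihood: float
    n_outer: int
    converged: bool
    kkt_residual: float
    n_nonzero: int
    n_weight_clamped: int = 0
    stalled: bool = False
    objective_trace: np.ndarray = None  # penalized objective after each outer step


def soft_threshold(v: float, threshold: float) -> float:
    """sign(v) * max(|v| - threshold, 0)."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return np.sign(v) * np.maximum(np.abs(v) - threshold, 0.0)


def weighted_lasso_cd(A, b, lambda_vec, beta_init=None, inner_tol=1e-9, max_sweeps=1000):
    """Cyclic coordinate descent on the Gram form of a weighted Lasso problem.

    Minimizes (1/2) gamma^t A gamma - b^t gamma + sum_j lambda_vec_j |gamma_j|
    (the quadratic model of the penalized weighted least squares problem,
    expressed through A = X^t W X and b = X^t W z only).  Coordinate update:

        gamma_j <- S(b_j - sum_{k != j} A_jk gamma_k, lambda_j) / A_jj.

    Coordinates with A_jj = 0 are kept frozen at zero when penalized; a
    zero-curvature *unpenalized* coordinate is a collinear forced covariate
    and raises.

    After an initial full sweep, sweeps cycle over the active (nonzero)
    coordinates until stable, with full sweeps to verify global coordinate-wise
    optimality; every sweep counts against ``max_sweeps``.
    """
    A = np.asarray(A, dtype=float)
    b = np.asarray(b, dtype=float).ravel()
    p = b.shape[0]
    lambda_vec = np.asarray(lambda_vec, dtype=float).ravel()
    diag = np.diag(A).copy()
    dead = diag <= 0
    if np.any(dead & (lambda_vec == 0)):
        j = int(np.flatnonzero(dead & (lambda_vec == 0))[0])
        raise np.linalg.LinAlgError(
            f"zero curvature on unpenalized coordinate {j} (collinear forced covariate)"
        )
    gamma = np.zeros(p) if beta_init is None else np.asarray(beta_init, dtype=float).copy()
    gamma[dead] = 0.0
    Agamma = A @ gamma

    def sweep(idx):
        nonlocal Agamma
        max_delta = 0.0
        for j in idx:
            aj = diag[j]
            if aj <= 0.0:
                continue
            gj = b[j] - Agamma[j] + aj * gamma[j]
            new = soft_threshold(gj, lambda_vec[j]) / aj
            d = new - gamma[j]
            if d != 0.0:
                Agamma += A[:, j] * d
                gamma[j] = new
                ad = abs(d)
                if ad > max_delta:
                    max_delta = ad
        return max_delta

    all_idx = np.arange(p)
    n_sweeps = 0
    while n_sweeps < max_sweeps:
        delta = sweep(all_idx)
        n_sweeps += 1
        if delta <= inner_tol:
            break
        # active-set refinement
        while n_sweeps < max_sweeps:
            active = np.flatnonzero(gamma != 0.0)
            delta = sweep(active)
            n_sweeps += 1
            if delta <= inner_tol:
                break
    return gamma


@dataclass
class LineSearchStep:
    """Outcome of one backtracking line search."""

    t: float
    beta: np.ndarray
    objective: float
    armijo: bool    # True when the Armijo criterion itself was satisfied
    stalled: bool

    def __iter__(self):  # unpack as (t, beta, f, stalled) for convenience
        return iter((self.t, self.beta, self.objective, self.stalled))


def line_search(dm: DifferenceMatrix, beta, delta, lam, alpha1=0.01, alpha2=0.5, t_min=1e-12):
    """Armijo backtracking on the penalized objective along ``delta``.

    Starting at t = 1, shrink t <- alpha2 t until

        f(beta + t delta) <= f(beta) + alpha1 t D,

    with f the penalized objective and slope term

        D = g(beta)^t delta + lam (||beta + delta||_1,pen - ||beta||_1,pen),

    i.e. the model decrease of the full penalized objective (g the
    unpenalized gradient).  Including the penalty difference in D is what
    makes the criterion satisfiable arbitrarily close to the optimum: with
    the bare ``g^t delta`` slope the required decrease stays a fixed fraction
    of the penalty term while the attainable decrease vanishes, and the
    search jams at partial steps long before the subgradient conditions are
    met.  D is an upper bound on the directional derivative of f, and is
    strictly negative for any non-trivial coordinate-descent direction, so
    accepted steps strictly decrease f.

    Returns a :class:`LineSearchStep`; ``stalled`` is True only when no trial
    step decreased f at all.  If the Armijo criterion itself is never met
    before t underflows ``t_min``, the largest trial that strictly decreased
    f is accepted (``armijo=False``) so descent is never sacrificed.
    """
    beta = np.asarray(beta, dtype=float)
    delta = np.asarray(delta, dtype=float)
    f0 = likelihood.objective(dm, beta, lam)
    if not np.any(delta):
        return LineSearchStep(0.0, beta, f0, armijo=False, stalled=True)
    mask = dm.penalty_mask
    penalty_change = lam * float(
        np.abs((beta + delta)[mask]).sum() - np.abs(beta[mask]).sum()
    )
    slope = float(likelihood.gradient(dm, beta) @ delta) + penalty_change
    t = 1.0
    best = None  # largest decreasing trial seen: (t, trial, f_trial)
    while True:
        trial = beta + t * delta
        f_trial = likelihood.objective(dm, trial, lam)
        if f_trial <= f0 + alpha1 * t * slope:
            return LineSearchStep(t, trial, f_trial, armijo=True, stalled=False)
        if best is None and f_trial < f0:
            best = (t, trial, f_trial)
        t *= alpha2
        if t < t_min:
            if best is not None:
                return LineSearchStep(best[0], best[1], best[2], armijo=False, stalled=False)
            return LineSearchStep(0.0, beta, f0, armijo=False, stalled=True)


try:  # numba accelerates the row-wise Gram accumulation for sparse designs
    import numba

    @numba.njit(cache=True)
    def _csr_weighted_gram(indptr, indices, data, w, p):  # pragma: no cover
        A = np.zeros((p, p))
        for r in range(len(indptr) - 1):
            wr = w[r]
            lo, hi = indptr[r], indptr[r + 1]
            for a in range(lo, hi):
                ja = indices[a]
                wv = wr * data[a]
                for b in range(lo, hi):
                    A[ja, indices[b]] += wv * data[b]
        return A

except ImportError:  # pragma: no cover
    _csr_weighted_gram = None


def gram_system(dm: DifferenceMatrix, state):
    """A = X^t W X and b = X^t W z from the IRLS state, without forming z.

    Uses W z = W eta + r (the identity W_ln d_n = r_ln), which stays finite
    even when d_n itself would overflow.  For sparse X the Gram matrix is
    accumulated row-block-wise straight into the dense p x p array.
    """
    X = dm.X
    w = state["w"]
    if dm.is_sparse:
        Xc = X.tocsr()
        if _csr_weighted_gram is not None:
            A = _csr_weighted_gram(Xc.indptr, Xc.indices, Xc.data, w, Xc.shape[1])
        else:
            Xw = Xc.copy()
            Xw.data *= np.repeat(w, np.diff(Xc.indptr))
            A = np.asarray((Xc.T @ Xw).todense())
    else:
        A = (X * w[:, None]).T @ X
    b = np.asarray(X.T @ (w * state["eta"] + state["r"])).ravel()
    return A, b


def _kkt_from_grad(g: np.ndarray, beta: np.ndarray, lam: float, mask: np.ndarray) -> float:
    res = np.abs(g).astype(float)
    nz = mask & (beta != 0)
    res[nz] = np.abs(g[nz] + lam * np.sign(beta[nz]))
    z = mask & (beta == 0)
    res[z] = np.maximum(np.abs(g[z]) - lam, 0.0)
    return float(res.max()) if res.size else 0.0


def kkt_residual(dm: DifferenceMatrix, beta, lam: float) -> float:
    """Max violation of the subgradient stationarity conditions at ``beta``.

    |g_j| for forced j; |g_j + lam sign(beta_j)| for penalized nonzero j;
    max(|g_j| - lam, 0) for penalized zero j.  Zero iff beta is optimal.
    """
    beta = np.asarray(beta, dtype=float)
    g = likelihood.gradient(dm, beta)
    return _kkt_from_grad(g, beta, lam, dm.penalty_mask)


def fit(dm: DifferenceMatrix, lam: float, beta_init=None, config: SolverConfig | None = None) -> FitResult:
    """Minimize the L1-penalized negative conditional log-likelihood at ``lam``."""
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    config = config or SolverConfig()
    p = dm.n_predictors
    beta = np.zeros(p) if beta_init is None else np.asarray(beta_init, dtype=float).copy()
    lam_vec = np.where(dm.penalty_mask, lam, 0.0)
    max_sweeps = config.sweeps_cap(p)

    converged = False
    stalled = False
    n_clamped_total = 0
    state = likelihood.stratum_state(dm, beta, weight_floor=config.weight_floor)
    f = state["nll"] + lam * likelihood.penalty_l1(dm, beta)
    trace = [f]
    n_outer = 0
    n_flat = 0  # consecutive steps with objective change below fp resolution
    for n_outer in range(1, config.max_outer + 1):
        n_clamped_total += state["n_clamped"]
        A, b = gram_system(dm, state)
        gamma = weighted_lasso_cd(
            A, b, lam_vec, beta_init=beta, inner_tol=config.inner_tol, max_sweeps=max_sweeps
        )
        delta = gamma - beta
        if np.max(np.abs(delta)) <= config.step_tol:
            converged = True
            break
        step = line_search(dm, beta, delta, lam, config.alpha1, config.alpha2, config.t_min)
        if step.stalled:
            if np.max(np.abs(delta)) <= 1e-6:
                # no decrease found along a tiny step: fixed point reached to
                # floating-point resolution
                converged = True
            else:
                stalled = True
                logger.warning(
                    "line search stalled on a large step at outer %d (lambda=%.3g)",
                    n_outer, lam,
                )
            break
        f_new = step.objective
        if not np.isfinite(f_new):
            raise FloatingPointError(
                f"non-finite objective at outer iteration {n_outer}: f={f_new}, t={step.t}, "
                f"max|beta|={np.max(np.abs(step.beta))}"
            )
        rel_change = abs(f_new - f) / max(abs(f_new), 1e-300)
        beta, f = step.beta, f_new
        # partial steps scale coordinates by (1 - t) instead of zeroing them;
        # collapse the resulting sub-resolution residues so sparsity (and the
        # sign pattern entering the KKT conditions) is exact
        residue = dm.penalty_mask & (beta != 0) & (np.abs(beta) <= config.snap_tol)
        if residue.any():
            beta = np.where(residue, 0.0, beta)
            f = likelihood.objective(dm, beta, lam)
        trace.append(f)
        state = likelihood.stratum_state(dm, beta, weight_floor=config.weight_floor)
        if config.verbose:
            logger.info(
                "outer %d: f=%.10g t=%.3g armijo=%s rel=%.3g",
                n_outer, f, step.t, step.armijo, rel_change,
            )
        if np.max(np.abs(state["eta"])) > 30:
            logger.warning(
                "large linear predictor (|x beta| > 30) at lambda=%.3g: "
                "possible separation, coefficients may diverge", lam
            )
        # once the objective cannot be resolved in double precision for two
        # consecutive steps and the subgradient certificate holds, further
        # iteration is unmeasurable refinement: fixed point at floating-point
        # resolution.  Without the certificate the loop continues — the
        # coefficients can still improve through occasional larger steps even
        # while the objective is flat.
        n_flat = n_flat + 1 if rel_change < 1e-15 else 0
        if n_flat >= 2:
            g = -np.asarray(dm.X.T @ state["r"]).ravel()
            if _kkt_from_grad(g, beta, lam, dm.penalty_mask) <= config.kkt_flat_tol:
                converged = True
                break
        # the relative-objective test is only meaningful after a step that
        # satisfied the Armijo criterion; fallback steps can be tiny while the
        # iterate is still contracting toward the fixed point.  The objective
        # is flat near the optimum, so the tau test alone can fire one Newton
        # iteration early — require the subgradient conditions too.
        if step.armijo and rel_change <= config.tau:
            g = -np.asarray(dm.X.T @ state["r"]).ravel()
            if _kkt_from_grad(g, beta, lam, dm.penalty_mask) <= config.kkt_tol:
                converged = True
                break

    nll = likelihood.neg_log_likelihood(dm, beta)
    return FitResult(
        beta=beta,
        lam=lam,
        objective=nll + lam * likelihood.penalty_l1(dm, beta),
        neg_log_likelihood=nll,
        n_outer=n_outer,
        converged=converged,
        kkt_residual=kkt_residual(dm, beta, lam),
        n_nonzero=int(np.count_nonzero(beta[dm.penalty_mask])),
        n_weight_clamped=n_clamped_total,
        stalled=stalled,
        objective_trace=np.asarray(trace),
    )
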