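"""Regularization path: lambda_max, the lambda grid, and warm-started fits.

lambda_max is the smallest penalty at which every penalized coefficient is
zero; it equals the largest absolute gradient coordinate of the negative
conditional log-likelihood at the null model (beta = 0 when nothing is
forced, otherwise at the forced-covariates-only maximum conditional
likelihood fit).  The grid runs from lambda_max down to epsilon * lambda_max,
equally spaced on the log or linear scale, and each fit is warm-started from
the previous solution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import likelihood, solver
from .data import DifferenceMatrix


@dataclass
class RegularizationPath:
    """Coefficients and diagnostics along a decreasing lambda grid."""

    lambdas: np.ndarray            # (T,), strictly decreasing
    coefficients: np.ndarray       # (T, p)
    df: np.ndarray                 # nonzero penalized count per lambda
    neg_log_likelihoods: np.ndarray
    converged: np.ndarray          # bool per lambda
    kkt_residuals: np.ndarray
    variable_names: list
    penalty_mask: np.ndarray
    n_strata: int

    def to_frame(self) -> pd.DataFrame:
        """Path as a table: lambda, df, neg_log_lik, then one column per coefficient."""
        out = pd.DataFrame(
            {"lambda": self.lambdas, "df": self.df, "neg_log_lik": self.neg_log_likelihoods}
        )
        coef = pd.DataFrame(self.coefficients, columns=self.variable_names)
        return pd.concat([out, coef], axis=1)

    def plot(self, ax=None, penalized_only: bool = True):
        """Coefficient trace versus lambda (log x-axis, decreasing)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        cols = np.flatnonzero(self.penalty_mask) if penalized_only else np.arange(len(self.variable_names))
        for j in cols:
            ax.plot(self.lambdas, self.coefficients[:, j], label=self.variable_names[j])
        ax.set_xscale("log")
        ax.invert_xaxis()
        ax.set_xlabel(r"$\lambda$")
        ax.set_ylabel("coefficient")
        return ax


def lambda_max(dm: DifferenceMatrix, config: solver.SolverConfig | None = None) -> float:
    """Smallest lambda at which all penalized coefficients are zero.

    With no forced covariates this is ``max_j |g_j(0)|`` over penalized j —
    for equal strata of size M + 1, ``max_j |sum_n sum_l x_lnj / (M + 1)|``.
    With forced covariates the gradient is taken at the forced-only maximum
    conditional likelihood fit, so that the first path point has exactly zero
    penalized support.
    """
    mask = dm.penalty_mask
    if not mask.any():
        raise ValueError("no penalized columns: lambda_max undefined")
    X = dm.X
    if dm.is_sparse:
        col_nonzero = np.asarray((X != 0).sum(axis=0)).ravel() > 0
    else:
        col_nonzero = np.any(X != 0, axis=0)
    if not col_nonzero[mask].any():
        raise ValueError("all penalized columns are identically zero")
    if mask.all():
        beta0 = np.zeros(dm.n_predictors)
    else:
        beta0 = _forced_only_fit(dm, config)
    g = likelihood.gradient(dm, beta0)
    lam = float(np.max(np.abs(g[mask])))
    if lam <= 0:
        raise ValueError("gradient vanishes on all penalized columns; lambda_max is zero")
    return lam


def _forced_only_fit(dm: DifferenceMatrix, config=None) -> np.ndarray:
    """Unpenalized fit with all penalized coefficients clamped at zero."""
    forced = ~dm.penalty_mask
    sub = DifferenceMatrix(
        X=dm.X[:, np.flatnonzero(forced)],
        row_stratum=dm.row_stratum,
        stratum_sizes=dm.stratum_sizes,
        penalty_mask=np.zeros(int(forced.sum()), dtype=bool),
        variable_names=[n for n, f in zip(dm.variable_names, forced) if f],
    )
    res = solver.fit(sub, 0.0, config=config)
    beta0 = np.zeros(dm.n_predictors)
    beta0[forced] = res.beta
    return beta0


def make_grid(lambda_max_value: float, epsilon: float = 0.01, T: int = 100, scale: str = "log") -> np.ndarray:
    """T lambdas from lambda_max down to epsilon * lambda_max, endpoints exact."""
    if not (0 < epsilon < 1):
        raise ValueError("epsilon must lie in (0, 1)")
    if T < 2:
        raise ValueError("T must be >= 2")
    if lambda_max_value <= 0:
        raise ValueError("lambda_max must be positive")
    lo = epsilon * lambda_max_value
    if scale == "log":
        grid = np.geomspace(lambda_max_value, lo, T)
    elif scale == "linear":
        grid = np.linspace(lambda_max_value, lo, T)
    else:
        raise ValueError("scale must be 'log' or 'linear'")
    grid[0], grid[-1] = lambda_max_value, lo
    return grid


def fit_path(dm: DifferenceMatrix, grid, config: solver.SolverConfig | None = None) -> RegularizationPath:
    """Fit the full path over a decreasing grid with warm starts.

    The first fit starts from beta = 0; each subsequent fit starts from the
    previous converged solution.  Fits that fail to converge are flagged and
    the path continues (the next warm start falls back to the last converged
    solution); if every fit fails, an error is raised.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or len(grid) == 0 or np.any(np.diff(grid) >= 0):
        raise ValueError("grid must be a non-empty strictly decreasing vector")
    p = dm.n_predictors
    T = len(grid)
    coefs = np.zeros((T, p))
    df = np.zeros(T, dtype=int)
    nlls = np.full(T, np.nan)
    conv = np.zeros(T, dtype=bool)
    kkt = np.full(T, np.nan)
    warm = np.zeros(p)
    for t, lam in enumerate(grid):
        res = solver.fit(dm, lam, beta_init=warm, config=config)
        coefs[t] = res.beta
        df[t] = res.n_nonzero
        nlls[t] = res.neg_log_likelihood
        conv[t] = res.converged
        kkt[t] = res.kkt_residual
        if res.converged:
            warm = res.beta
    if not conv.any():
        raise RuntimeError("no lambda on the grid produced a converged fit")
    return RegularizationPath(
        lambdas=grid,
        coefficients=coefs,
        df=df,
        neg_log_likelihoods=nlls,
        converged=conv,
        kkt_residuals=kkt,
        variable_names=list(dm.variable_names),
        penalty_mask=dm.penalty_mask.copy(),
        n_strata=dm.n_strata,
    )
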