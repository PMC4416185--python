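"""Choosing lambda on the grid: likelihood-based K-fold CV or BIC.

Cross-validation operates on *strata*, never on rows: matched sets are the
independent sampling units of the conditional likelihood, so a stratum's
rows always travel together.  The CV criterion is the held-out conditional
log-likelihood; BIC is 2 * nll + df * log(N) with N the number of strata and
df the count of nonzero penalized coefficients plus the forced covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import likelihood, path as path_mod, solver
from .data import DifferenceMatrix, MatchedDataset, ValidationError, build_differences


@dataclass
class SelectionResult:
    criterion: str                  # "cv" or "bic"
    lambdas: np.ndarray
    values: np.ndarray              # per-lambda criterion (mean held-out loglik, or BIC)
    selected_lambda: float
    selected_index: int
    beta: np.ndarray                # full-data solution at the selected lambda
    df: int
    variable_names: list
    penalty_mask: np.ndarray
    fold_values: np.ndarray | None = None   # (K, T) held-out loglik per fold (CV only)
    seed: int | None = None

    def odds_ratios(self) -> pd.DataFrame:
        return odds_ratios(self)


def _as_dm(data) -> DifferenceMatrix:
    if isinstance(data, MatchedDataset):
        return build_differences(data)
    return data


def make_folds(n_strata: int, K: int, seed: int) -> list[np.ndarray]:
    """Shuffle strata by ``seed`` and split into K near-equal folds."""
    if K < 2:
        raise ValueError("K must be >= 2")
    if n_strata < K:
        raise ValueError("need at least K strata")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_strata)
    return [np.sort(f) for f in np.array_split(perm, K)]


def heldout_log_likelihood(dm_test: DifferenceMatrix, beta) -> float:
    """Conditional log-likelihood of held-out strata: -sum log(1 + sum e^{-x beta})."""
    return -likelihood.neg_log_likelihood(dm_test, beta)


def cv_select(
    data,
    grid,
    K: int = 10,
    seed: int = 0,
    config: solver.SolverConfig | None = None,
    full_path: path_mod.RegularizationPath | None = None,
) -> SelectionResult:
    """K-fold likelihood-based cross-validation over the lambda grid.

    For each fold the path is fitted (warm-started) on the remaining strata
    and the held-out conditional log-likelihood recorded per lambda; the
    selected lambda maximizes the fold-mean, ties broken toward larger
    lambda.  Lambdas that failed to converge in any fold (or on the full
    data) are excluded.  The returned coefficients come from the full-data
    path, fitted here if not supplied.
    """
    dm = _as_dm(data)
    grid = np.asarray(grid, dtype=float)
    folds = make_folds(dm.n_strata, K, seed)
    T = len(grid)
    fold_ll = np.full((K, T), np.nan)
    fold_conv = np.ones((K, T), dtype=bool)
    all_strata = np.arange(dm.n_strata)
    for k, test in enumerate(folds):
        train = np.setdiff1d(all_strata, test)
        dm_train = dm.subset_strata(train)
        if not dm_train.informative_strata().any():
            raise ValidationError(
                f"fold {k} leaves no informative training strata; use fewer folds"
            )
        dm_test = dm.subset_strata(test)
        p = path_mod.fit_path(dm_train, grid, config=config)
        fold_conv[k] = p.converged
        for t in range(T):
            if p.converged[t]:
                fold_ll[k, t] = heldout_log_likelihood(dm_test, p.coefficients[t])
    if full_path is None:
        full_path = path_mod.fit_path(dm, grid, config=config)
    usable = fold_conv.all(axis=0) & full_path.converged
    if not usable.any():
        raise RuntimeError("no lambda converged in every fold")
    mean_ll = np.where(usable, np.nanmean(fold_ll, axis=0), -np.inf)
    idx = int(np.argmax(mean_ll))  # first max = largest lambda on a decreasing grid
    beta = full_path.coefficients[idx]
    return SelectionResult(
        criterion="cv",
        lambdas=grid,
        values=mean_ll,
        selected_lambda=float(grid[idx]),
        selected_index=idx,
        beta=beta,
        df=int(full_path.df[idx]),
        variable_names=full_path.variable_names,
        penalty_mask=full_path.penalty_mask,
        fold_values=fold_ll,
        seed=seed,
    )


def bic_select(p: path_mod.RegularizationPath) -> SelectionResult:
    """BIC(lambda) = 2 nll + (df_penalized + n_forced) log(N); minimizer selected.

    N is the number of strata (each matched set contributes one multinomial
    observation to the conditional likelihood).  Ties break toward larger
    lambda; non-converged entries are excluded.
    """
    n_forced = int((~p.penalty_mask).sum())
    df_total = p.df + n_forced
    bic = 2.0 * p.neg_log_likelihoods + df_total * np.log(p.n_strata)
    bic = np.where(p.converged, bic, np.inf)
    idx = int(np.argmin(bic))
    return SelectionResult(
        criterion="bic",
        lambdas=p.lambdas,
        values=bic,
        selected_lambda=float(p.lambdas[idx]),
        selected_index=idx,
        beta=p.coefficients[idx],
        df=int(p.df[idx]),
        variable_names=p.variable_names,
        penalty_mask=p.penalty_mask,
    )


def odds_ratios(result: SelectionResult) -> pd.DataFrame:
    """Odds ratios exp(beta_j) for nonzero penalized and all forced covariates."""
    rows = []
    for j, name in enumerate(result.variable_names):
        b = result.beta[j]
        forced = not result.penalty_mask[j]
        if b != 0 or forced:
            rows.append({"variable": name, "coef": float(b), "odds_ratio": float(np.exp(b)),
                         "penalized": not forced})
    return pd.DataFrame(rows, columns=["variable", "coef", "odds_ratio", "penalized"])
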