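"""Model / Results front-end for penalized conditional logistic regression.

Usage mirrors the statsmodels idiom: build the model from data, call a fit
method, get a results object carrying estimates and diagnostics with a
``summary()``::

    model = ConditionalLogitLasso.from_dataframe(df, stratum_col="stratum",
                                                 case_col="case",
                                                 unpenalized=["age65"])
    path = model.fit_path(n_lambdas=50)
    sel = model.select(method="cv", folds=10, seed=7)
    print(sel.summary())
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import likelihood, path as path_mod, selection as sel_mod, solver
from .data import (
    DifferenceMatrix,
    MatchedDataset,
    build_differences,
    drop_concordant_strata,
    read_long_format,
    standardize_differences,
)


class ConditionalLogitLasso:
    """L1-penalized conditional logistic regression on matched data.

    Parameters
    ----------
    data : MatchedDataset (long format, one case per stratum).
    drop_concordant : remove strata whose case and controls have identical
        covariates; leaves all estimates unchanged, shrinks the likelihood
        by a constant per dropped stratum.  Off by default.
    standardize : scale penalized columns to unit variance on the difference
        scale before fitting and back-transform the coefficients.  Off by
        default (binary exposures are typically left on their natural scale).
    """

    def __init__(self, data: MatchedDataset, drop_concordant: bool = False,
                 standardize: bool = False):
        self.data = data
        dm = build_differences(data)
        self.n_dropped_concordant = 0
        if drop_concordant:
            dm, self.n_dropped_concordant = drop_concordant_strata(dm)
        self._scales = np.ones(dm.n_predictors)
        if standardize:
            dm, self._scales = standardize_differences(dm)
        self.differences: DifferenceMatrix = dm
        self.standardized = standardize

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, stratum_col: str = "stratum",
                       case_col: str = "case", covariate_cols=None,
                       unpenalized=(), **kwargs) -> "ConditionalLogitLasso":
        import io

        buf = io.StringIO()
        df.to_csv(buf, index=False)
        buf.seek(0)
        data = read_long_format(buf, stratum_col=stratum_col, case_col=case_col,
                                covariate_cols=covariate_cols, unpenalized=unpenalized,
                                sep=",")
        return cls(data, **kwargs)

    # ------------------------------------------------------------------
    @property
    def variable_names(self):
        return self.differences.variable_names

    def lambda_max(self, config: solver.SolverConfig | None = None) -> float:
        return path_mod.lambda_max(self.differences, config=config)

    def fit(self, lam: float, beta_init=None,
            config: solver.SolverConfig | None = None) -> "LassoFitResults":
        """Fit at a single penalty level."""
        res = solver.fit(self.differences, lam, beta_init=beta_init, config=config)
        return LassoFitResults(self, res)

    def fit_path(self, lambdas=None, epsilon: float = 0.01, n_lambdas: int = 100,
                 scale: str = "log",
                 config: solver.SolverConfig | None = None) -> "LassoPathResults":
        """Fit the warm-started regularization path."""
        if lambdas is None:
            lam_max = self.lambda_max(config=config)
            lambdas = path_mod.make_grid(lam_max, epsilon=epsilon, T=n_lambdas, scale=scale)
        raw = path_mod.fit_path(self.differences, lambdas, config=config)
        return LassoPathResults(self, raw)

    def select(self, method: str = "cv", lambdas=None, epsilon: float = 0.01,
               n_lambdas: int = 100, scale: str = "log", folds: int = 10,
               seed: int = 0,
               config: solver.SolverConfig | None = None) -> "LassoSelectionResults":
        """Fit the path and choose lambda by CV or BIC."""
        if lambdas is None:
            lam_max = self.lambda_max(config=config)
            lambdas = path_mod.make_grid(lam_max, epsilon=epsilon, T=n_lambdas, scale=scale)
        raw_path = path_mod.fit_path(self.differences, lambdas, config=config)
        if method == "cv":
            raw = sel_mod.cv_select(self.differences, lambdas, K=folds, seed=seed,
                                    config=config, full_path=raw_path)
        elif method == "bic":
            raw = sel_mod.bic_select(raw_path)
        else:
            raise ValueError("method must be 'cv' or 'bic'")
        return LassoSelectionResults(self, raw, LassoPathResults(self, raw_path))


class LassoFitResults:
    """Estimates and diagnostics of a single-lambda fit."""

    def __init__(self, model: ConditionalLogitLasso, raw: solver.FitResult):
        self.model = model
        self.raw = raw
        self.params = raw.beta / model._scales
        self.lam = raw.lam
        self.converged = raw.converged
        self.n_iter = raw.n_outer
        self.kkt_residual = raw.kkt_residual
        self.neg_log_likelihood = raw.neg_log_likelihood
        self.objective = raw.objective
        self.df = raw.n_nonzero

    def odds_ratios(self) -> pd.DataFrame:
        names = self.model.variable_names
        mask = self.model.differences.penalty_mask
        rows = [
            {"variable": names[j], "coef": float(b), "odds_ratio": float(np.exp(b)),
             "penalized": bool(mask[j])}
            for j, b in enumerate(self.params) if b != 0 or not mask[j]
        ]
        return pd.DataFrame(rows, columns=["variable", "coef", "odds_ratio", "penalized"])

    def summary(self) -> str:
        lines = [
            "Conditional logistic Lasso fit",
            "=" * 46,
            f"strata:            {self.model.differences.n_strata}",
            f"lambda:            {self.lam:.6g}",
            f"df (nonzero pen.): {self.df}",
            f"-log L:            {self.neg_log_likelihood:.6f}",
            f"objective:         {self.objective:.6f}",
            f"converged:         {self.converged} ({self.n_iter} outer iterations)",
            f"KKT residual:      {self.kkt_residual:.3g}",
            "",
            self.odds_ratios().to_string(index=False),
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "lambda": float(self.lam),
            "df": int(self.df),
            "neg_log_likelihood": float(self.neg_log_likelihood),
            "objective": float(self.objective),
            "converged": bool(self.converged),
            "kkt_residual": float(self.kkt_residual),
            "coefficients": {n: float(b) for n, b in zip(self.model.variable_names, self.params)
                             if b != 0 or not self.model.differences.penalty_mask[
                                 self.model.variable_names.index(n)]},
        }


class LassoPathResults:
    """Regularization path on the original covariate scale."""

    def __init__(self, model: ConditionalLogitLasso, raw: path_mod.RegularizationPath):
        self.model = model
        self.raw = raw
        self.lambdas = raw.lambdas
        self.coefficients = raw.coefficients / model._scales
        self.df = raw.df
        self.neg_log_likelihoods = raw.neg_log_likelihoods
        self.converged = raw.converged

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"lambda": self.lambdas, "df": self.df,
                            "neg_log_lik": self.neg_log_likelihoods})
        return pd.concat([out, pd.DataFrame(self.coefficients,
                                            columns=self.raw.variable_names)], axis=1)

    def plot(self, ax=None, penalized_only: bool = True):
        scaled = path_mod.RegularizationPath(
            lambdas=self.lambdas, coefficients=self.coefficients, df=self.df,
            neg_log_likelihoods=self.neg_log_likelihoods, converged=self.converged,
            kkt_residuals=self.raw.kkt_residuals, variable_names=self.raw.variable_names,
            penalty_mask=self.raw.penalty_mask, n_strata=self.raw.n_strata,
        )
        return scaled.plot(ax=ax, penalized_only=penalized_only)

    def summary(self) -> str:
        t = self.to_frame()[["lambda", "df", "neg_log_lik"]]
        return "Regularization path\n" + "=" * 46 + "\n" + t.to_string(index=False)


class LassoSelectionResults:
    """Selected model after CV or BIC, with its path."""

    def __init__(self, model: ConditionalLogitLasso, raw: sel_mod.SelectionResult,
                 path_results: LassoPathResults):
        self.model = model
        self.raw = raw
        self.path = path_results
        self.criterion = raw.criterion
        self.selected_lambda = raw.selected_lambda
        self.params = raw.beta / model._scales
        self.df = raw.df

    def odds_ratios(self) -> pd.DataFrame:
        scaled = sel_mod.SelectionResult(
            criterion=self.raw.criterion, lambdas=self.raw.lambdas,
            values=self.raw.values, selected_lambda=self.raw.selected_lambda,
            selected_index=self.raw.selected_index, beta=self.params, df=self.raw.df,
            variable_names=self.raw.variable_names, penalty_mask=self.raw.penalty_mask,
        )
        return sel_mod.odds_ratios(scaled)

    def summary(self) -> str:
        lines = [
            f"Model selection ({self.criterion.upper()})",
            "=" * 46,
            f"strata:          {self.model.differences.n_strata}",
            f"grid size:       {len(self.raw.lambdas)}",
            f"selected lambda: {self.selected_lambda:.6g}",
            f"selected df:     {self.df}",
            "",
            self.odds_ratios().to_string(index=False),
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "criterion": self.criterion,
            "selected_lambda": float(self.selected_lambda),
            "df": int(self.df),
            "seed": self.raw.seed,
            "coefficients": {n: float(b) for n, b in zip(self.raw.variable_names, self.params)
                             if b != 0 or not self.raw.penalty_mask[
                                 self.raw.variable_names.index(n)]},
            "odds_ratios": {r["variable"]: r["odds_ratio"]
                            for _, r in self.odds_ratios().iterrows()},
        }
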