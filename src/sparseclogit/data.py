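"""Matched case-control data structures and ingestion.

A matched (1:1 or 1:M) case-control or case-crossover dataset is a set of
strata, each containing exactly one case and at least one control.  All
fitting operates on the within-stratum *difference matrix*: for stratum ``n``
with case covariates ``u_0n`` and control covariates ``u_in``, the rows
``x_in = u_0n - u_in``.  On that scale the conditional likelihood takes the
form of a no-intercept logistic-type likelihood with diagonal curvature
weights, which is what makes large-N fitting cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp


class ValidationError(ValueError):
    """Raised when input data violate the matched-design invariants."""


def _is_sparse(mat) -> bool:
    return sp.issparse(mat)


@dataclass
class MatchedDataset:
    """Long-format matched data: one row per subject-in-stratum.

    Parameters
    ----------
    stratum_id : array of opaque labels, one per row.  Strata are ordered by
        first appearance; rows of one stratum need not be contiguous on input
        (they are made contiguous, preserving within-stratum order).
    case_indicator : 0/1 array, one per row; exactly one 1 per stratum.
    covariates : (n_rows, p) ndarray or scipy.sparse matrix.
    penalty_mask : boolean (p,); True = penalized, False = forced
        (always in the model, unpenalized).  Defaults to all-penalized.
    variable_names : length-p unique names; defaults to x1..xp.
    """

    stratum_id: np.ndarray
    case_indicator: np.ndarray
    covariates: object
    penalty_mask: np.ndarray = None
    variable_names: list = None

    def __post_init__(self):
        self.stratum_id = np.asarray(self.stratum_id)
        self.case_indicator = np.asarray(self.case_indicator)
        if not _is_sparse(self.covariates):
            self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
        else:
            self.covariates = self.covariates.tocsr().astype(float)
        n_rows, p = self.covariates.shape
        if self.penalty_mask is None:
            self.penalty_mask = np.ones(p, dtype=bool)
        self.penalty_mask = np.asarray(self.penalty_mask, dtype=bool)
        if self.variable_names is None:
            self.variable_names = [f"x{j + 1}" for j in range(p)]
        self.variable_names = list(self.variable_names)
        self._validate()
        # make strata contiguous, ordered by first appearance, within-stratum
        # row order preserved
        codes, uniques = pd.factorize(self.stratum_id)
        order = np.argsort(codes, kind="stable")
        if not np.array_equal(order, np.arange(n_rows)):
            self.stratum_id = self.stratum_id[order]
            self.case_indicator = self.case_indicator[order]
            self.covariates = self.covariates[order]
            codes = codes[order]
        self._codes = codes
        self._labels = uniques

    def _validate(self):
        n_rows, p = self.covariates.shape
        if self.stratum_id.shape[0] != n_rows or self.case_indicator.shape[0] != n_rows:
            raise ValidationError("stratum_id, case_indicator and covariates must align row-wise")
        y = self.case_indicator
        if not np.isin(y, [0, 1]).all():
            raise ValidationError("case indicator must be coded 0/1")
        self.case_indicator = y.astype(np.int8)
        if len(set(self.variable_names)) != p:
            raise ValidationError("variable_names must be unique")
        if len(self.variable_names) != p or self.penalty_mask.shape[0] != p:
            raise ValidationError("penalty_mask and variable_names must have length p")
        if _is_sparse(self.covariates):
            bad = ~np.isfinite(self.covariates.data)
        else:
            bad = ~np.isfinite(self.covariates)
        if bad.any():
            if _is_sparse(self.covariates):
                cols = sorted(set(self.covariates.tocoo().col[~np.isfinite(self.covariates.tocoo().data)]))
            else:
                cols = sorted(set(np.where(bad)[0] if bad.ndim == 1 else np.where(bad)[1]))
            names = [self.variable_names[c] for c in cols]
            raise ValidationError(f"missing/non-finite covariate values in columns: {names}")
        # per-stratum case counts
        df = pd.DataFrame({"s": self.stratum_id, "y": self.case_indicator})
        counts = df.groupby("s", sort=False)["y"].agg(["sum", "count"])
        bad_cases = counts.index[counts["sum"] != 1]
        if len(bad_cases):
            raise ValidationError(
                f"each stratum must contain exactly one case; violated by strata: "
                f"{list(bad_cases[:5])}"
            )
        no_controls = counts.index[counts["count"] < 2]
        if len(no_controls):
            raise ValidationError(
                f"each stratum needs at least one control; violated by strata: "
                f"{list(no_controls[:5])}"
            )

    # ------------------------------------------------------------------
    @property
    def n_strata(self) -> int:
        return len(self._labels)

    @property
    def n_predictors(self) -> int:
        return self.covariates.shape[1]

    @property
    def stratum_sizes(self) -> np.ndarray:
        """Number of controls M_n per stratum (stratum size minus the case)."""
        return np.bincount(self._codes) - 1

    def summary(self) -> dict:
        """Ingestion summary: strata count, size histogram, p, forced names."""
        sizes = self.stratum_sizes
        hist = {int(k): int(v) for k, v in zip(*np.unique(sizes, return_counts=True))}
        return {
            "n_strata": int(self.n_strata),
            "n_rows": int(self.covariates.shape[0]),
            "controls_per_stratum_histogram": hist,
            "p": int(self.n_predictors),
            "n_penalized": int(self.penalty_mask.sum()),
            "forced_variables": [n for n, m in zip(self.variable_names, self.penalty_mask) if not m],
        }


@dataclass
class DifferenceMatrix:
    """Stacked within-stratum difference rows x_in = u_0n - u_in.

    Rows of a stratum are contiguous; stratum ``n`` occupies
    ``starts[n]:starts[n] + stratum_sizes[n]``.  A 1:1 design has one row per
    stratum.
    """

    X: object
    row_stratum: np.ndarray
    stratum_sizes: np.ndarray
    penalty_mask: np.ndarray
    variable_names: list

    def __post_init__(self):
        self.row_stratum = np.asarray(self.row_stratum, dtype=np.intp)
        self.stratum_sizes = np.asarray(self.stratum_sizes, dtype=np.intp)
        self.penalty_mask = np.asarray(self.penalty_mask, dtype=bool)
        if self.X.shape[0] != int(self.stratum_sizes.sum()):
            raise ValidationError("X must have sum(M_n) rows")
        self.starts = np.concatenate([[0], np.cumsum(self.stratum_sizes)[:-1]])

    @property
    def n_strata(self) -> int:
        return len(self.stratum_sizes)

    @property
    def n_predictors(self) -> int:
        return self.X.shape[1]

    @property
    def is_sparse(self) -> bool:
        return _is_sparse(self.X)

    def subset_strata(self, strata: np.ndarray) -> "DifferenceMatrix":
        """Restrict to the given stratum indices (order preserved as given)."""
        strata = np.asarray(strata, dtype=np.intp)
        row_blocks = [np.arange(self.starts[n], self.starts[n] + self.stratum_sizes[n]) for n in strata]
        rows = np.concatenate(row_blocks) if row_blocks else np.empty(0, dtype=np.intp)
        sizes = self.stratum_sizes[strata]
        return DifferenceMatrix(
            X=self.X[rows],
            row_stratum=np.repeat(np.arange(len(strata)), sizes),
            stratum_sizes=sizes,
            penalty_mask=self.penalty_mask,
            variable_names=self.variable_names,
        )

    def informative_strata(self) -> np.ndarray:
        """Boolean mask of strata with at least one nonzero difference row."""
        if self.is_sparse:
            Xc = self.X.tocsr()
            row_nonzero = np.diff(Xc.indptr) > 0
            # explicit zeros guard
            if Xc.nnz and not Xc.data.all():
                row_nonzero = np.asarray((Xc != 0).sum(axis=1)).ravel() > 0
        else:
            row_nonzero = np.any(self.X != 0, axis=1)
        out = np.zeros(self.n_strata, dtype=bool)
        np.logical_or.at(out, self.row_stratum, row_nonzero)
        return out


def build_differences(data: MatchedDataset) -> DifferenceMatrix:
    """Construct the difference matrix: one row per control, x = u_case - u_control."""
    y = data.case_indicator.astype(bool)
    codes = data._codes
    n = data.covariates.shape[0]
    case_row_of = np.empty(data.n_strata, dtype=np.intp)
    case_row_of[codes[y]] = np.flatnonzero(y)
    control_rows = np.flatnonzero(~y)
    case_rows = case_row_of[codes[control_rows]]
    X = data.covariates[case_rows] - data.covariates[control_rows]
    if _is_sparse(X):
        X = X.tocsr()
        X.eliminate_zeros()
    return DifferenceMatrix(
        X=X,
        row_stratum=codes[control_rows],
        stratum_sizes=data.stratum_sizes,
        penalty_mask=data.penalty_mask.copy(),
        variable_names=list(data.variable_names),
    )


def drop_concordant_strata(dm: DifferenceMatrix):
    """Remove strata whose difference rows are all exactly zero.

    Such strata contribute the constant log(M_n + 1) to the negative
    log-likelihood and nothing to the gradient, so dropping them leaves every
    fitted coefficient vector unchanged.

    Returns ``(filtered, n_dropped)``.
    """
    keep = dm.informative_strata()
    n_dropped = int((~keep).sum())
    if not keep.any():
        raise ValidationError("no informative strata: every matched set is concordant")
    if n_dropped == 0:
        return dm, 0
    return dm.subset_strata(np.flatnonzero(keep)), n_dropped


def drop_rare_predictors(data: MatchedDataset, min_subjects: int):
    """Remove penalized covariates observed (nonzero) in fewer than ``min_subjects`` rows.

    Forced covariates are never removed.  Returns ``(dataset, removed_names)``.
    """
    if min_subjects < 0:
        raise ValueError("min_subjects must be >= 0")
    U = data.covariates
    if _is_sparse(U):
        counts = np.asarray((U != 0).sum(axis=0)).ravel()
    else:
        counts = np.count_nonzero(U, axis=0)
    drop = (counts < min_subjects) & data.penalty_mask
    if not drop.any():
        return data, []
    keep = ~drop
    removed = [n for n, d in zip(data.variable_names, drop) if d]
    new = MatchedDataset(
        stratum_id=data.stratum_id.copy(),
        case_indicator=data.case_indicator.copy(),
        covariates=U[:, keep],
        penalty_mask=data.penalty_mask[keep],
        variable_names=[n for n, k in zip(data.variable_names, keep) if k],
    )
    return new, removed


def standardize_differences(dm: DifferenceMatrix):
    """Scale penalized columns of X to unit variance on the difference scale.

    Returns ``(scaled_dm, scales)`` where ``scales`` is the per-column divisor
    (1 for forced and constant columns).  Coefficients fitted on the scaled
    matrix are back-transformed by dividing by ``scales``... fitted beta_orig =
    beta_scaled / scales.
    """
    X = dm.X
    n = X.shape[0]
    if _is_sparse(X):
        mean = np.asarray(X.mean(axis=0)).ravel()
        mean_sq = np.asarray(X.multiply(X).mean(axis=0)).ravel()
        var = mean_sq - mean**2
    else:
        var = X.var(axis=0)
    sd = np.sqrt(var)
    scales = np.ones(dm.n_predictors)
    use = dm.penalty_mask & (sd > 0)
    scales[use] = sd[use]
    if _is_sparse(X):
        Xs = X @ sp.diags(1.0 / scales)
        Xs = Xs.tocsr()
    else:
        Xs = X / scales
    scaled = replace(dm, X=Xs)
    return scaled, scales


# ----------------------------------------------------------------------
# ingestion

def read_long_format(
    source,
    stratum_col: str = "stratum",
    case_col: str = "case",
    covariate_cols=None,
    unpenalized=(),
    sep=None,
) -> MatchedDataset:
    """Read long-format delimited text (CSV/TSV) into a :class:`MatchedDataset`.

    Parameters
    ----------
    source : path or file-like with a header row.
    stratum_col, case_col : names of the stratum-identifier and 0/1 case
        columns.
    covariate_cols : explicit covariate column names; default: every other
        column.
    unpenalized : iterable of covariate names to force into the model.
    sep : field delimiter; ``None`` sniffs (handles both CSV and TSV).
    """
    df = pd.read_csv(source, sep=sep, engine="python" if sep is None else "c")
    for col in (stratum_col, case_col):
        if col not in df.columns:
            raise ValidationError(f"required column {col!r} not found in input")
    if covariate_cols is None:
        covariate_cols = [c for c in df.columns if c not in (stratum_col, case_col)]
    if not covariate_cols:
        raise ValidationError("no covariate columns found")
    missing = [c for c in covariate_cols if c not in df.columns]
    if missing:
        raise ValidationError(f"covariate columns not found: {missing}")
    U = df[covariate_cols]
    na_cols = [c for c in covariate_cols if U[c].isna().any()]
    if na_cols:
        raise ValidationError(f"missing covariate values in columns: {na_cols}")
    unknown = set(unpenalized) - set(covariate_cols)
    if unknown:
        raise ValidationError(f"unpenalized names not among covariates: {sorted(unknown)}")
    mask = np.array([c not in set(unpenalized) for c in covariate_cols])
    return MatchedDataset(
        stratum_id=df[stratum_col].to_numpy(),
        case_indicator=df[case_col].to_numpy(),
        covariates=U.to_numpy(dtype=float),
        penalty_mask=mask,
        variable_names=list(covariate_cols),
    )


def read_sparse_format(
    mtx_source,
    meta_source,
    stratum_col: str = "stratum",
    case_col: str = "case",
    variable_names=None,
    unpenalized=(),
) -> MatchedDataset:
    """Read a MatrixMarket exposure matrix plus a sidecar CSV of stratum/case columns.

    Row i of the MTX matrix is the exposure vector of row i of the sidecar.
    """
    from scipy.io import mmread

    U = sp.csr_matrix(mmread(mtx_source))
    meta = pd.read_csv(meta_source)
    for col in (stratum_col, case_col):
        if col not in meta.columns:
            raise ValidationError(f"required column {col!r} not found in sidecar")
    if len(meta) != U.shape[0]:
        raise ValidationError("sidecar row count does not match matrix rows")
    if variable_names is None:
        variable_names = [f"x{j + 1}" for j in range(U.shape[1])]
    mask = np.array([c not in set(unpenalized) for c in variable_names])
    return MatchedDataset(
        stratum_id=meta[stratum_col].to_numpy(),
        case_indicator=meta[case_col].to_numpy(),
        covariates=U,
        penalty_mask=mask,
        variable_names=list(variable_names),
    )
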