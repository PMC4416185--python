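"""Synthetic matched case-control and case-crossover data with known effects.

Covariates are drawn first; the case within each matched set is then chosen
by the exact conditional model: subject ``i`` becomes the case with
probability ``exp(u_i beta) / sum_l exp(u_l beta)``.  The stratum intercepts
``alpha_n`` cancel from that probability, so they are generated (and echoed)
but never influence case assignment — matching the estimand of conditional
logistic regression exactly, with no rejection-sampling approximation.

Randomness flows from a single seed through independent child streams
(exposures, case assignment, intercepts), so changing the intercept
distribution cannot perturb the exposures or case draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .data import MatchedDataset


@dataclass
class SimulationDesign:
    """Study conditions for a simulated matched design.

    n_strata : number of matched sets N.
    n_controls : controls per stratum M (scalar).
    n_predictors : p.
    beta_true : length-p log odds ratios (default all zero).
    exposure_prevalence : scalar or length-p marginal P(u = 1) for binary
        predictors, each in (0, 1).
    predictor_kind : "binary" or "gaussian".
    within_stratum_correlation : probability that a subject copies the
        stratum-level latent exposure rather than drawing independently
        (binary), or the share of stratum-level variance (gaussian); induces
        the exposure similarity that matching creates in real data.
    alpha_mean, alpha_sd : distribution of the stratum intercepts alpha_n
        (generated, echoed, and — by construction — irrelevant to the data).
    sparse : store exposures as a scipy.sparse matrix (binary,
        uncorrelated designs only); for rare exposures at large N.
    """

    n_strata: int
    n_controls: int = 1
    n_predictors: int = 1
    beta_true: np.ndarray = None
    exposure_prevalence: float = 0.2
    predictor_kind: str = "binary"
    within_stratum_correlation: float = 0.0
    alpha_mean: float = 0.0
    alpha_sd: float = 1.0
    seed: int = 0
    sparse: bool = False

    def __post_init__(self):
        if self.beta_true is None:
            self.beta_true = np.zeros(self.n_predictors)
        self.beta_true = np.asarray(self.beta_true, dtype=float)
        if self.beta_true.shape[0] != self.n_predictors:
            raise ValueError("beta_true must have length n_predictors")
        prev = np.broadcast_to(np.asarray(self.exposure_prevalence, dtype=float),
                               (self.n_predictors,)).copy()
        if self.predictor_kind == "binary" and not ((prev > 0) & (prev < 1)).all():
            raise ValueError("exposure prevalences must lie in (0, 1)")
        self.exposure_prevalence = prev
        if self.predictor_kind not in ("binary", "gaussian"):
            raise ValueError("predictor_kind must be 'binary' or 'gaussian'")
        if not (0 <= self.within_stratum_correlation <= 1):
            raise ValueError("within_stratum_correlation must lie in [0, 1]")
        if self.n_strata < 1 or self.n_controls < 1 or self.n_predictors < 1:
            raise ValueError("n_strata, n_controls, n_predictors must be positive")
        if self.sparse and (self.predictor_kind != "binary" or self.within_stratum_correlation > 0):
            raise ValueError("sparse generation supports uncorrelated binary exposures only")


@dataclass
class SimulatedData:
    """Generated dataset plus the truth that produced it."""

    data: MatchedDataset
    beta_true: np.ndarray
    alpha: np.ndarray          # stratum intercepts (unused by the conditional model)
    case_position: np.ndarray  # index of the case within each stratum


def _softmax_case_draw(eta_by_stratum: np.ndarray, rng) -> np.ndarray:
    """Draw one case index per stratum with P(i) = e^{eta_i} / sum_l e^{eta_l}.

    Gumbel-max: argmax(eta + Gumbel noise) is an exact draw from the softmax.
    """
    g = rng.gumbel(size=eta_by_stratum.shape)
    return np.argmax(eta_by_stratum + g, axis=1)


def _binary_exposures(design: SimulationDesign, n_subjects_per_stratum: int, rng):
    N, S, p = design.n_strata, n_subjects_per_stratum, design.n_predictors
    prev = design.exposure_prevalence
    rho = design.within_stratum_correlation
    u = (rng.random((N, S, p)) < prev).astype(np.float64)
    if rho > 0:
        shared = (rng.random((N, 1, p)) < prev).astype(np.float64)
        copy = rng.random((N, S, p)) < rho
        u = np.where(copy, np.broadcast_to(shared, (N, S, p)), u)
    return u


def _gaussian_exposures(design: SimulationDesign, n_subjects_per_stratum: int, rng):
    N, S, p = design.n_strata, n_subjects_per_stratum, design.n_predictors
    rho = design.within_stratum_correlation
    e = rng.standard_normal((N, S, p))
    if rho > 0:
        s = rng.standard_normal((N, 1, p))
        e = np.sqrt(rho) * s + np.sqrt(1 - rho) * e
    return e


def _sparse_exposures(design: SimulationDesign, n_subjects_per_stratum: int, rng) -> sp.csr_matrix:
    n_rows = design.n_strata * n_subjects_per_stratum
    cols, rows = [], []
    for j in range(design.n_predictors):
        k = rng.binomial(n_rows, design.exposure_prevalence[j])
        rj = rng.choice(n_rows, size=k, replace=False)
        rows.append(rj)
        cols.append(np.full(k, j, dtype=np.intp))
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    U = sp.coo_matrix(
        (np.ones(len(rows)), (rows, cols)),
        shape=(n_rows, design.n_predictors),
    ).tocsr()
    return U


def simulate_matched(design: SimulationDesign) -> SimulatedData:
    """Generate a 1:M individually matched case-control dataset.

    Each stratum holds M + 1 subjects; covariates are drawn per
    ``predictor_kind``; the case is the subject drawn from the within-stratum
    softmax of ``u beta``.
    """
    S = design.n_controls + 1
    rng = np.random.default_rng(design.seed)
    exposure_rng, case_rng, alpha_rng = rng.spawn(3)
    if design.sparse:
        U = _sparse_exposures(design, S, exposure_rng)
        eta = np.asarray(U @ design.beta_true).reshape(design.n_strata, S)
    else:
        u = (
            _binary_exposures(design, S, exposure_rng)
            if design.predictor_kind == "binary"
            else _gaussian_exposures(design, S, exposure_rng)
        )
        eta = u @ design.beta_true
        U = u.reshape(design.n_strata * S, design.n_predictors)
    case_pos = _softmax_case_draw(eta, case_rng)
    alpha = alpha_rng.normal(design.alpha_mean, design.alpha_sd, size=design.n_strata)

    y = np.zeros(design.n_strata * S, dtype=np.int8)
    y[np.arange(design.n_strata) * S + case_pos] = 1
    stratum_id = np.repeat(np.arange(design.n_strata), S)
    data = MatchedDataset(
        stratum_id=stratum_id,
        case_indicator=y,
        covariates=U,
        variable_names=[f"x{j + 1}" for j in range(design.n_predictors)],
    )
    return SimulatedData(data=data, beta_true=design.beta_true.copy(),
                         alpha=alpha, case_position=case_pos)


def simulate_case_crossover(
    design: SimulationDesign, n_periods: int = 5, serial_correlation: float = 0.0
) -> SimulatedData:
    """Generate a case-crossover dataset: each subject is their own stratum.

    Binary exposure follows a stationary first-order two-state chain across
    the ``n_periods`` periods, with marginal prevalence pi and lag-one
    correlation ``serial_correlation`` (transitions P(1->1) = pi + rho(1-pi),
    P(0->1) = pi(1-rho)).  The case period is drawn from the softmax of
    ``u beta`` over periods, giving a 1:(n_periods-1) matched structure.
    The default of five periods mirrors a 1:4 design (crash day plus four
    monthly control days).
    """
    if n_periods < 2:
        raise ValueError("n_periods must be >= 2")
    if not (0 <= serial_correlation <= 1):
        raise ValueError("serial_correlation must lie in [0, 1]")
    if design.predictor_kind != "binary":
        raise ValueError("case-crossover generation supports binary exposures only")
    N, p = design.n_strata, design.n_predictors
    prev = design.exposure_prevalence
    rho = serial_correlation
    rng = np.random.default_rng(design.seed)
    exposure_rng, case_rng, alpha_rng = rng.spawn(3)

    u = np.empty((N, n_periods, p))
    u[:, 0] = (exposure_rng.random((N, p)) < prev).astype(float)
    p11 = prev + rho * (1 - prev)
    p01 = prev * (1 - rho)
    for t in range(1, n_periods):
        draw = exposure_rng.random((N, p))
        stay = u[:, t - 1] * (draw < p11)
        switch = (1 - u[:, t - 1]) * (draw < p01)
        u[:, t] = stay + switch

    eta = u @ design.beta_true
    case_pos = _softmax_case_draw(eta, case_rng)
    alpha = alpha_rng.normal(design.alpha_mean, design.alpha_sd, size=N)

    y = np.zeros(N * n_periods, dtype=np.int8)
    y[np.arange(N) * n_periods + case_pos] = 1
    data = MatchedDataset(
        stratum_id=np.repeat(np.arange(N), n_periods),
        case_indicator=y,
        covariates=u.reshape(N * n_periods, p),
        variable_names=[f"x{j + 1}" for j in range(p)],
    )
    return SimulatedData(data=data, beta_true=design.beta_true.copy(),
                         alpha=alpha, case_position=case_pos)
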