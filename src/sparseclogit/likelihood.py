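"""Conditional log-likelihood of matched designs, in difference form.

For stratum ``n`` with difference rows ``x_ln`` (one per control,
``l = 1..M_n``) the conditional probability that the observed case is the
case is ``1 / d_n`` with denominator

    d_n = 1 + sum_l exp(-x_ln beta),

so the negative conditional log-likelihood is ``sum_n log d_n``.  Its
gradient is ``-X^t r`` with residuals ``r_ln = exp(-x_ln beta) / d_n``, and
the IRLS curvature weights are diagonal on this scale:

    W_ln = exp(-x_ln beta) / d_n^2,      z_ln = x_ln beta + d_n,

with working response ``z``.  All quantities are evaluated with the largest
per-stratum exponent factored out, so they stay finite for any finite beta.
"""

from __future__ import annotations

import numpy as np

from .data import DifferenceMatrix

#: default floor applied to IRLS weights (guards the Gram diagonal near separation)
WEIGHT_FLOOR = 1e-10

_LOG_D_CAP = 700.0  # exp() overflow guard when materializing d_n itself


def _check_beta(dm: DifferenceMatrix, beta) -> np.ndarray:
    beta = np.asarray(beta, dtype=float).ravel()
    if beta.shape[0] != dm.n_predictors:
        raise ValueError(f"beta must have length p={dm.n_predictors}")
    if not np.isfinite(beta).all():
        raise ValueError("beta contains non-finite entries")
    return beta


def stratum_state(dm: DifferenceMatrix, beta, weight_floor: float = 0.0):
    """Per-row and per-stratum quantities at ``beta``.

    Returns a dict with:
      eta        X beta, per row
      log_d      log d_n, per stratum
      nll        sum_n log d_n
      r          exp(-eta) / d_n, per row (the gradient residuals)
      w          exp(-eta) / d_n^2, per row, floored at ``weight_floor``
      n_clamped  number of floored weights
    """
    beta = _check_beta(dm, beta)
    eta = dm.X @ beta
    neg = -eta
    starts = dm.starts
    # factor out the per-stratum max exponent: log d = m + log(e^{-m} + S)
    m = np.maximum.reduceat(neg, starts)
    m = np.maximum(m, 0.0)
    m_rep = np.repeat(m, dm.stratum_sizes)
    expterms = np.exp(neg - m_rep)
    S = np.add.reduceat(expterms, starts)
    log_d = m + np.log(np.exp(-m) + S)
    denom_scaled = np.exp(-m) + S  # = d_n * e^{-m}
    r = expterms / np.repeat(denom_scaled, dm.stratum_sizes)
    w = r * np.exp(-np.repeat(log_d, dm.stratum_sizes))
    n_clamped = 0
    if weight_floor > 0:
        clip = w < weight_floor
        n_clamped = int(clip.sum())
        if n_clamped:
            w = np.where(clip, weight_floor, w)
    return {
        "eta": eta,
        "log_d": log_d,
        "nll": float(log_d.sum()),
        "r": r,
        "w": w,
        "n_clamped": n_clamped,
    }


def neg_log_likelihood(dm: DifferenceMatrix, beta) -> float:
    """Negative conditional log-likelihood sum_n log(1 + sum_l exp(-x_ln beta))."""
    return stratum_state(dm, beta)["nll"]


def gradient(dm: DifferenceMatrix, beta) -> np.ndarray:
    """Gradient of the negative conditional log-likelihood: -X^t r."""
    state = stratum_state(dm, beta)
    return -np.asarray(dm.X.T @ state["r"]).ravel()


def weights_working_response(dm: DifferenceMatrix, beta, weight_floor: float = WEIGHT_FLOOR):
    """Diagonal IRLS weights W and working response z at ``beta``.

    Satisfies the identity ``-X^t W (z - X beta) = gradient`` exactly (before
    flooring): ``z - X beta = d_n`` per row and ``W_ln d_n = r_ln``.
    """
    state = stratum_state(dm, beta, weight_floor=weight_floor)
    d = np.exp(np.minimum(state["log_d"], _LOG_D_CAP))
    z = state["eta"] + np.repeat(d, dm.stratum_sizes)
    return state["w"], z


def objective(dm: DifferenceMatrix, beta, lam: float) -> float:
    """Penalized objective: neg_log_likelihood + lam * ||beta_penalized||_1."""
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    beta = _check_beta(dm, beta)
    return neg_log_likelihood(dm, beta) + lam * float(np.abs(beta[dm.penalty_mask]).sum())


def penalty_l1(dm: DifferenceMatrix, beta) -> float:
    beta = np.asarray(beta, dtype=float)
    return float(np.abs(beta[dm.penalty_mask]).sum())
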