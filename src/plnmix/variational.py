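"""Variational Gaussian estimation of a single MPLN distribution.

The MPLN marginal likelihood involves a d-dimensional integral with no closed
form.  Following the standard variational treatment of latent-Gaussian count
models, the posterior of each latent row ``X_i`` is approximated by an
independent Gaussian with mean ``m_i`` and *diagonal* covariance
``diag(s_i^2)``, chosen to minimize the KL divergence to the true posterior —
equivalently, to maximize the evidence lower bound (ELBO)

    sum_ij [ y_ij (o_ij + m_ij) - e^{o_ij + m_ij + s_ij^2/2} - log y_ij! ]
    - sum_i KL( N(m_i, diag(s_i^2)) || N(mu, Sigma) ),

where ``o_ij`` are log-scale normalization offsets.  Estimation alternates:

* a variational step — quasi-Newton ascent on (m_i, log s_i^2) per row, with
  analytic gradients; rows are independent given (mu, Sigma) so all rows are
  optimized jointly in one call;
* a model step — closed-form weighted updates
  ``mu = sum w_i m_i / sum w_i`` and
  ``Sigma = sum w_i [(m_i - mu)(m_i - mu)^T + diag(s_i^2)] / sum w_i``,
  ridge-regularized to stay positive-definite.

The ELBO never decreases across outer iterations (up to numerical tolerance),
and is a true lower bound on the log-likelihood.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize
from scipy.special import gammaln

from .distributions import MPLNParams

__all__ = [
    "VariationalState",
    "MPLNFit",
    "elbo",
    "update_variational",
    "update_model",
    "fit_mpln",
]

#: relative ridge added to the Sigma update diagonal (times trace/d)
RIDGE = 1e-8
#: initial variational variance
S2_INIT = 0.1
#: inner quasi-Newton iteration cap per variational sweep
INNER_MAXITER = 50


@dataclass
class VariationalState:
    """Per-observation approximating-Gaussian means ``M`` (n, d) and
    variances ``S2`` (n, d), all positive."""

    M: np.ndarray
    S2: np.ndarray

    def __post_init__(self):
        self.M = np.asarray(self.M, dtype=float)
        self.S2 = np.asarray(self.S2, dtype=float)
        if self.M.shape != self.S2.shape or self.M.ndim != 2:
            raise ValueError("M and S2 must be equal-shape (n, d) matrices")
        if np.any(self.S2 <= 0):
            raise ValueError("variational variances must be positive")

    def copy(self) -> "VariationalState":
        return VariationalState(self.M.copy(), self.S2.copy())


@dataclass
class MPLNFit:
    """Fitted MPLN parameters with the final variational state and the ELBO
    trace of the outer iterations."""

    params: MPLNParams
    vstate: VariationalState
    elbo_trace: np.ndarray
    converged: bool
    n_iter: int

    @property
    def elbo(self) -> float:
        return float(self.elbo_trace[-1])


def _as_offsets(offsets, n: int, d: int) -> np.ndarray:
    if offsets is None:
        return np.zeros((n, d))
    O = np.asarray(offsets, dtype=float)
    if O.ndim == 0:
        return np.full((n, d), float(O))
    if O.ndim == 1:
        if O.shape[0] != n:
            raise ValueError(f"offset vector length {O.shape[0]} != n = {n}")
        return np.repeat(O[:, None], d, axis=1)
    if O.shape != (n, d):
        raise ValueError(f"offsets shape {O.shape} != ({n}, {d})")
    return O


def elbo_rows(Y, params: MPLNParams, vstate: VariationalState, offsets=None):
    """Per-row ELBO contributions J_i (length n); their sum is the ELBO.

    These are the quantities mixture responsibilities are built from.
    """
    Y = np.asarray(Y, dtype=float)
    n, d = Y.shape
    O = _as_offsets(offsets, n, d)
    M, S2 = vstate.M, vstate.S2
    mu, Sigma = params.mu, params.Sigma
    cho = linalg.cho_factor(Sigma, lower=True)
    logdet = 2.0 * np.log(np.diag(cho[0])).sum()
    Sinv = linalg.cho_solve(cho, np.eye(d))
    A = np.exp(O + M + 0.5 * S2)
    pois = (Y * (O + M) - A - gammaln(Y + 1.0)).sum(axis=1)
    Dm = M - mu
    kl = 0.5 * (
        S2 @ np.diag(Sinv)
        + np.einsum("ij,jk,ik->i", Dm, Sinv, Dm)
        - d
        + logdet
        - np.log(S2).sum(axis=1)
    )
    return pois - kl


def elbo(Y, params: MPLNParams, vstate: VariationalState, offsets=None) -> float:
    """Evidence lower bound on the MPLN log-likelihood of ``Y``."""
    return float(elbo_rows(Y, params, vstate, offsets).sum())


def _elbo_negobj_grad(theta, Y, O, mu, Sinv, dSinv, logdet_half_terms):
    """Negative ELBO and gradient in the flattened (M, log S2) variables.
    Constant-in-vstate terms are included so the value equals -elbo()."""
    n, d = Y.shape
    M = theta[: n * d].reshape(n, d)
    logS2 = theta[n * d:].reshape(n, d)
    S2 = np.exp(logS2)
    A = np.exp(O + M + 0.5 * S2)
    Dm = M - mu
    DmSinv = Dm @ Sinv
    val = (
        (Y * (O + M) - A).sum()
        - 0.5 * (S2 @ dSinv).sum()
        - 0.5 * np.einsum("ij,ij->", DmSinv, Dm)
        + 0.5 * logS2.sum()
        + logdet_half_terms
    )
    gM = Y - A - DmSinv
    gS2 = -0.5 * A - 0.5 * dSinv[None, :] + 0.5 / S2
    g = np.concatenate([gM.ravel(), (gS2 * S2).ravel()])
    return -val, -g


def update_variational(
    Y,
    params: MPLNParams,
    vstate: VariationalState,
    offsets=None,
    max_inner: int = INNER_MAXITER,
) -> VariationalState:
    """One variational sweep: quasi-Newton ascent on (M, log S2) with analytic
    gradients.  Rows are independent, so all are optimized in one L-BFGS call.
    If the line search fails the previous state is kept (with a warning);
    the ELBO never decreases."""
    Y = np.asarray(Y, dtype=float)
    n, d = Y.shape
    O = _as_offsets(offsets, n, d)
    mu, Sigma = params.mu, params.Sigma
    cho = linalg.cho_factor(Sigma, lower=True)
    Sinv = linalg.cho_solve(cho, np.eye(d))
    dSinv = np.diag(Sinv).copy()
    logdet = 2.0 * np.log(np.diag(cho[0])).sum()
    const = (
        -gammaln(Y + 1.0).sum()
        + 0.5 * n * d
        - 0.5 * n * logdet
    )
    theta0 = np.concatenate([vstate.M.ravel(), np.log(vstate.S2).ravel()])
    res = optimize.minimize(
        _elbo_negobj_grad,
        theta0,
        args=(Y, O, mu, Sinv, dSinv, const),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_inner, "ftol": 1e-12, "gtol": 1e-9},
    )
    f0 = _elbo_negobj_grad(theta0, Y, O, mu, Sinv, dSinv, const)[0]
    if res.fun > f0:
        warnings.warn("variational line search failed to improve; state retained")
        return vstate
    M = res.x[: n * d].reshape(n, d)
    S2 = np.exp(res.x[n * d:].reshape(n, d))
    return VariationalState(M, S2)


def update_model(vstate: VariationalState, weights=None) -> MPLNParams:
    """Closed-form (mu, Sigma) maximizer of the ELBO for a fixed variational
    state, optionally weighted (mixture responsibilities).  The Sigma update
    adds a ridge of ``RIDGE * trace/d`` to the diagonal to guarantee positive
    definiteness."""
    M, S2 = vstate.M, vstate.S2
    n, d = M.shape
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0):
            raise ValueError("weights must be a nonnegative length-n vector")
    wsum = w.sum()
    if wsum <= 0:
        raise ValueError("weights must not all be zero")
    mu = (w @ M) / wsum
    Dm = M - mu
    Sigma = (Dm.T * w) @ Dm / wsum + np.diag((w @ S2) / wsum)
    ridge = RIDGE * np.trace(Sigma) / d
    Sigma[np.diag_indices_from(Sigma)] += max(ridge, 1e-300)
    return MPLNParams(mu=mu, Sigma=Sigma)


def fit_mpln(
    Y,
    offsets=None,
    init: MPLNParams | None = None,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> MPLNFit:
    """Fit a single MPLN to an (n, d) count matrix by alternating variational
    and model updates until the relative ELBO change falls below ``tol``.

    ``offsets`` are log-scale normalization constants (scalar, per-sample
    vector, or full matrix).  Initialization: m_ij = log(y_ij + 0.5) - o_ij,
    s_ij^2 = 0.1; (mu, Sigma) from the model step unless ``init`` is given.
    """
    Y = np.asarray(Y)
    if Y.ndim != 2:
        raise ValueError("Y must be an (n, d) matrix")
    n, d = Y.shape
    if n <= d:
        warnings.warn(f"n = {n} <= d = {d}: covariance estimate will be unstable")
    O = _as_offsets(offsets, n, d)
    M0 = np.log(Y + 0.5) - O
    vstate = VariationalState(M0, np.full((n, d), S2_INIT))
    params = init if init is not None else update_model(vstate)
    trace = [elbo(Y, params, vstate, O)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        vstate = update_variational(Y, params, vstate, O)
        params = update_model(vstate)
        trace.append(elbo(Y, params, vstate, O))
        denom = max(abs(trace[-2]), 1.0)
        if abs(trace[-1] - trace[-2]) / denom < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"MPLN fit did not converge in {max_iter} iterations")
    return MPLNFit(params, vstate, np.array(trace), converged, it)
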