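"""Maximum-likelihood fitting of Poisson, NB, and PLN to univariate count
vectors, plus the percentage relative-bias summary used by the simulation
studies.

The Poisson MLE is closed form (the sample mean).  NB and PLN are maximized
by quasi-Newton ascent over an unconstrained internal parameterization
(log mean / log shape for the NB; mu / log sigma2 for the PLN), initialized
at the moment-matching inversion of the sample moments.  The PLN likelihood
is evaluated by Gauss-Hermite quadrature (`pln_logpmf`); counts are
aggregated to unique values first, so a fit costs O(#unique * #nodes) per
objective evaluation regardless of n.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from scipy.special import digamma, gammaln, logsumexp

from .distributions import (
    GH_NODES,
    MomentPair,
    NBParams,
    PLNParams,
    PoissonParams,
    _gh_nodes,
    nb_match_moments,
    nb_moments,
    pln_match_moments,
    pln_moments,
    poisson_moments,
)

__all__ = [
    "UnivariateFit",
    "BiasSummary",
    "fit_poisson",
    "fit_nb",
    "fit_pln",
    "relative_bias_pct",
    "summarize_bias",
]

#: gradient max-norm convergence tolerance for quasi-Newton fits
GRAD_TOL = 1e-8
MAX_ITER = 500
#: NB shape cap: beyond this the fit is indistinguishable from Poisson
NB_SHAPE_CAP = 1e8
#: PLN latent-variance lower bound; below it the exact Poisson branch applies
PLN_SIGMA2_MIN = 1e-10
_RATE_FLOOR = 1e-8


@dataclass(frozen=True)
class UnivariateFit:
    """Result of fitting one family to one count vector."""

    family: str  # "poisson" | "nb" | "pln"
    params: object
    fitted_moments: MomentPair
    loglik: float
    converged: bool
    n_iter: int


@dataclass(frozen=True)
class BiasSummary:
    """Mean and spread of percentage relative biases across replicates."""

    mean_relative_bias_pct: float
    sd_relative_bias_pct: float
    n_replicates: int


def _validate_counts(y) -> np.ndarray:
    y = np.asarray(y)
    if y.size == 0:
        raise ValueError("count vector must be nonempty")
    yf = y.astype(float)
    if np.any(~np.isfinite(yf)) or np.any(yf < 0) or np.any(yf != np.floor(yf)):
        raise ValueError("counts must be nonnegative integers")
    return yf


def _minimize_with_restart(fun, theta0, args, bounds):
    """L-BFGS-B with one cold restart from the stalled point: the line search
    can fail on the nearly flat ridge at the equi-dispersion boundary, where
    a fresh Hessian approximation usually recovers."""
    opts = {"maxiter": MAX_ITER, "gtol": GRAD_TOL, "ftol": 1e-13}
    res = optimize.minimize(
        fun, theta0, args=args, jac=True, method="L-BFGS-B", bounds=bounds,
        options=opts,
    )
    if not res.success:
        res2 = optimize.minimize(
            fun, res.x, args=args, jac=True, method="L-BFGS-B", bounds=bounds,
            options=opts,
        )
        if res2.fun <= res.fun:
            res2.nit += res.nit
            res = res2
    return res


def _box_converged(res, bounds) -> bool:
    """Projected-gradient convergence for box-constrained minimization:
    coordinates pinned at a bound with the gradient pushing outward count as
    stationary (the over/under-dispersion boundaries are legitimate optima).
    The tolerance scales with the objective magnitude, since the likelihood
    and its gradient both grow with the sample size."""
    tol = 1e-5 * max(1.0, abs(float(res.fun)))
    g = np.array(res.jac, dtype=float, copy=True)
    for i, (lo, hi) in enumerate(bounds):
        if lo is not None and res.x[i] <= lo + 1e-6 and g[i] > 0:
            g[i] = 0.0
        if hi is not None and res.x[i] >= hi - 1e-6 and g[i] < 0:
            g[i] = 0.0
    return bool(res.success) or float(np.max(np.abs(g))) < tol


def fit_poisson(y) -> UnivariateFit:
    """Closed-form Poisson MLE: rate = sample mean."""
    y = _validate_counts(y)
    rate = float(y.mean())
    if rate <= 0:
        warnings.warn(
            "all counts are zero; Poisson rate floored at a small positive value"
        )
        rate = _RATE_FLOOR
    params = PoissonParams(rate)
    ll = float(stats.poisson.logpmf(y, rate).sum())
    return UnivariateFit("poisson", params, poisson_moments(params), ll, True, 0)


def _aggregate(y: np.ndarray):
    vals, counts = np.unique(y, return_counts=True)
    return vals, counts.astype(float)


def _nb_negll_grad(theta, vals, cnts):
    """Negative log-likelihood and gradient in (log mean, log shape)."""
    logm, loga = theta
    m, a = math.exp(logm), math.exp(loga)
    p = a / (a + m)
    ll = (cnts * stats.nbinom.logpmf(vals, a, p)).sum()
    n = cnts.sum()
    sy = (cnts * vals).sum()
    # d/dm and d/da of the NB log-likelihood (size a, mean m parameterization)
    dm = sy / m - (n + sy / a) / (1.0 + m / a)
    da = (
        (cnts * digamma(vals + a)).sum()
        - n * digamma(a)
        + n * (math.log(a) - math.log(a + m))
        + n
        - (n * a + sy) / (a + m)
    )
    return -ll, -np.array([dm * m, da * a])


def fit_nb(y) -> UnivariateFit:
    """NB MLE over (log mean, log shape); shape capped at ``NB_SHAPE_CAP``
    (under-dispersed samples push the shape to the Poisson limit)."""
    y = _validate_counts(y)
    m0 = float(y.mean())
    if m0 <= 0:
        warnings.warn("all counts are zero; NB mean floored")
        m0 = _RATE_FLOOR
    v0 = float(y.var(ddof=1)) if y.size > 1 else m0
    v0 = max(v0, m0 * (1.0 + 1e-6))
    init = nb_match_moments(MomentPair(m0, v0))
    theta0 = np.array([math.log(m0), math.log(min(init.shape, NB_SHAPE_CAP))])
    vals, cnts = _aggregate(y)
    bounds = [(None, None), (math.log(1e-8), math.log(NB_SHAPE_CAP))]
    res = _minimize_with_restart(_nb_negll_grad, theta0, (vals, cnts), bounds)
    m, a = math.exp(res.x[0]), math.exp(res.x[1])
    params = NBParams(shape=a, scale=m / a)
    converged = _box_converged(res, bounds)
    if not converged:
        warnings.warn(f"NB fit did not converge: {res.message}")
    return UnivariateFit("nb", params, nb_moments(params), -float(res.fun), converged, res.nit)


def _pln_negll_grad(theta, vals, cnts, t, logw):
    """Negative PLN log-likelihood and gradient in (mu, log sigma2),
    aggregated over unique count values with multiplicities.  Uses the
    mode-adapted quadrature of ``pln_logpmf``; node positions are treated as
    fixed in the gradient (their contribution is of the order of the
    quadrature error)."""
    from .distributions import _pln_logpmf_nodes

    mu, logs2 = theta
    s2 = math.exp(logs2)
    lp, x, p = _pln_logpmf_nodes(vals, mu, s2, t, logw)
    z = (x - mu) / s2  # d g / d mu at each node
    dmu = (p * z).sum(axis=1)
    # d lp / d log sigma2 = sum_k p_k [ (x_k-mu)^2/(2 s2) - 1/2 ]
    ds2 = (p * (0.5 * s2 * z**2 - 0.5)).sum(axis=1)
    ll = (cnts * lp).sum()
    g_mu = (cnts * dmu).sum()
    g_logs2 = (cnts * ds2).sum()  # already in d/d log sigma2 via chain factor s2
    return -ll, -np.array([g_mu, g_logs2])


def fit_pln(y, n_nodes: int = GH_NODES) -> UnivariateFit:
    """PLN MLE over (mu, log sigma2) with sigma2 bounded below at 1e-10;
    the boundary coincides with the exact Poisson branch of the pmf."""
    y = _validate_counts(y)
    m0 = float(y.mean())
    if m0 <= 0:
        warnings.warn("all counts are zero; PLN mean floored")
        m0 = _RATE_FLOOR
    v0 = float(y.var(ddof=1)) if y.size > 1 else m0
    v0 = max(v0, m0 * (1.0 + 1e-6))
    init = pln_match_moments(MomentPair(m0, v0))
    theta0 = np.array([init.mu, math.log(max(init.sigma2, 1e-8))])
    vals, cnts = _aggregate(y)
    t, logw = _gh_nodes(n_nodes)
    bounds = [(None, None), (math.log(PLN_SIGMA2_MIN), None)]
    res = _minimize_with_restart(
        _pln_negll_grad, theta0, (vals, cnts, t, logw), bounds
    )
    params = PLNParams(mu=float(res.x[0]), sigma2=math.exp(res.x[1]))
    converged = _box_converged(res, bounds)
    if not converged:
        warnings.warn(f"PLN fit did not converge: {res.message}")
    return UnivariateFit(
        "pln", params, pln_moments(params), -float(res.fun), converged, res.nit
    )


def relative_bias_pct(estimate: float, truth: float) -> float:
    """Percentage relative bias (estimate - truth) / truth * 100."""
    if truth == 0:
        raise ValueError("relative bias is undefined for truth = 0")
    return (estimate - truth) / truth * 100.0


def summarize_bias(estimates, truth: float) -> BiasSummary:
    """Mean and sample sd of per-replicate percentage relative biases."""
    estimates = np.asarray(estimates, dtype=float)
    if estimates.size < 2:
        raise ValueError("need at least 2 replicates to summarize bias")
    biases = (estimates - truth) / truth * 100.0
    return BiasSummary(
        float(biases.mean()), float(biases.std(ddof=1)), int(estimates.size)
    )
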