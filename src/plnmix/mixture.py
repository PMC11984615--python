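"""Model-based clustering with finite mixtures of MPLN distributions.

A G-component mixture f(y) = sum_g pi_g f(y; mu_g, Sigma_g) is fitted by a
variational EM: each component keeps its own per-observation variational
state, responsibilities are computed from the per-row, per-component ELBO
contributions J_ig (the standard variational surrogate for the intractable
component densities), and the M-step reuses the closed-form weighted MPLN
updates.  The number of components is chosen by BIC on the ELBO-based
log-likelihood surrogate, and observations are assigned by maximum a
posteriori responsibility.

Because responsibilities come from an approximation, a two-step hybrid
refinement is provided: the variational partition is frozen, and within each
cluster the latent rows are sampled by random-walk Metropolis with conjugate
normal-inverse-Wishart draws of (mu_g, Sigma_g), yielding posterior means and
credible intervals under the true posterior.  The partition itself is never
altered by the refinement.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, stats
from scipy.special import gammaln, logsumexp
from sklearn.cluster import KMeans

from ._rng import as_rng, spawn_seedseqs
from .distributions import MPLNParams
from .variational import (
    MPLNFit,
    VariationalState,
    _as_offsets,
    elbo_rows,
    fit_mpln,
    update_model,
    update_variational,
)

__all__ = [
    "MixtureFit",
    "ModelSelection",
    "e_step",
    "m_step",
    "bic",
    "n_free_params",
    "fit_mixture",
    "select_model",
    "map_assign",
    "hybrid_refine",
]

#: defaults for the hybrid sampler's weak normal-inverse-Wishart prior
NIW_KAPPA0 = 0.01
NIW_PSI0_SCALE = 1.0  # Psi0 = scale * I
RWM_TARGET_ACCEPT = 0.3


@dataclass
class MixtureFit:
    """A fitted G-component MPLN mixture.

    ``elbo`` is the mixture log-likelihood surrogate
    sum_i log sum_g pi_g exp(J_ig); ``labels`` are 0-based MAP assignments.
    Components are reported in order of decreasing mixing weight.
    """

    G: int
    pi: np.ndarray
    components: list[MPLNParams]
    vstates: list[VariationalState]
    resp: np.ndarray
    elbo: float
    elbo_trace: np.ndarray
    bic: float
    labels: np.ndarray
    converged: bool
    n_iter: int


@dataclass
class ModelSelection:
    """Fits over a range of G with the BIC-minimizing model selected
    (ties broken toward the smaller G)."""

    fits: dict[int, MixtureFit]
    chosen_G: int
    criterion: str = "BIC"
    failures: dict[int, str] = field(default_factory=dict)

    @property
    def best(self) -> MixtureFit:
        return self.fits[self.chosen_G]

    def bic_table(self):
        return {G: f.bic for G, f in sorted(self.fits.items())}


def _component_elbos(Y, O, components, vstates) -> np.ndarray:
    """J matrix (n, G): per-row ELBO contribution under each component."""
    return np.column_stack(
        [elbo_rows(Y, comp, vs, O) for comp, vs in zip(components, vstates)]
    )


def e_step(Y, offsets, pi, components, vstates) -> np.ndarray:
    """Responsibilities z_ig proportional to pi_g exp(J_ig), rows normalized
    with log-sum-exp stabilization."""
    Y = np.asarray(Y, dtype=float)
    O = _as_offsets(offsets, *Y.shape)
    J = _component_elbos(Y, O, components, vstates)
    return _resp_from_J(J, pi)


def _resp_from_J(J: np.ndarray, pi: np.ndarray) -> np.ndarray:
    logr = np.log(pi)[None, :] + J
    norm = logsumexp(logr, axis=1)
    bad = ~np.isfinite(norm)
    if np.any(bad):
        warnings.warn(
            f"{int(bad.sum())} observations had vanishing density under every "
            "component; assigning uniform responsibilities"
        )
        logr[bad] = 0.0
        norm = logsumexp(logr, axis=1)
    return np.exp(logr - norm[:, None])


def m_step(Y, resp, vstates):
    """Mixing weights pi_g = mean responsibility; component (mu_g, Sigma_g)
    from the weighted closed-form MPLN model update.  Components with fewer
    than d+1 effective observations get an inflated ridge."""
    Y = np.asarray(Y, dtype=float)
    n, d = Y.shape
    resp = np.asarray(resp, dtype=float)
    pi = resp.sum(axis=0) / n
    components = []
    for g in range(resp.shape[1]):
        w = resp[:, g]
        comp = update_model(vstates[g], weights=np.maximum(w, 1e-300))
        if w.sum() < d + 1:
            warnings.warn(
                f"component {g} has {w.sum():.2f} effective observations "
                f"(< d+1 = {d + 1}); inflating covariance ridge"
            )
            Sigma = comp.Sigma.copy()
            Sigma[np.diag_indices_from(Sigma)] += 1e-3 * np.trace(Sigma) / d
            comp = MPLNParams(comp.mu, Sigma)
        components.append(comp)
    return pi, components


def n_free_params(G: int, d: int) -> int:
    """(G-1) mixing weights + G*d means + G*d(d+1)/2 covariance entries."""
    return (G - 1) + G * d + G * d * (d + 1) // 2


def bic(fit: MixtureFit, n: int) -> float:
    """Bayesian information criterion -2*loglik + p*log n on the ELBO-based
    surrogate log-likelihood; smaller is better."""
    d = fit.components[0].d
    p = n_free_params(fit.G, d)
    return -2.0 * fit.elbo + p * math.log(n)


def map_assign(resp) -> np.ndarray:
    """Row-wise argmax responsibility (0-based); ties go to the lowest index."""
    resp = np.asarray(resp)
    return resp.argmax(axis=1)


def _one_start(Y, O, G, labels0, tol, max_iter):
    """Run variational EM from an initial hard labeling; returns the pieces of
    a MixtureFit (unordered components)."""
    n, d = Y.shape
    M0 = np.log(Y + 0.5) - O
    resp = np.zeros((n, G))
    resp[np.arange(n), labels0] = 1.0
    vstates = [VariationalState(M0.copy(), np.full((n, d), 0.1)) for _ in range(G)]
    pi, components = m_step(Y, resp, vstates)
    pi = np.maximum(pi, 1e-12)
    pi /= pi.sum()
    trace = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        vstates = [
            update_variational(Y, components[g], vstates[g], O) for g in range(G)
        ]
        J = _component_elbos(Y, O, components, vstates)
        resp = _resp_from_J(J, pi)
        pi, components = m_step(Y, resp, vstates)
        pi = np.maximum(pi, 1e-12)
        pi /= pi.sum()
        trace.append(float(logsumexp(np.log(pi)[None, :] + J, axis=1).sum()))
        if len(trace) > 1:
            denom = max(abs(trace[-2]), 1.0)
            if abs(trace[-1] - trace[-2]) / denom < tol:
                converged = True
                break
    return pi, components, vstates, resp, np.array(trace), converged, it


def fit_mixture(
    Y,
    offsets=None,
    G: int = 1,
    n_starts: int = 10,
    seed=None,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> MixtureFit:
    """Fit a G-component MPLN mixture, keeping the best of ``n_starts``
    k-means-on-log-counts initializations (per-start seeds derived from the
    master seed)."""
    Y = np.asarray(Y)
    if Y.ndim != 2:
        raise ValueError("Y must be an (n, d) matrix")
    n, d = Y.shape
    if not 1 <= G <= n:
        raise ValueError(f"G must be in [1, n], got {G}")
    O = _as_offsets(offsets, n, d)
    L = np.log(Y + 0.5) - O
    seeds = spawn_seedseqs(seed, n_starts)
    best = None
    errors = []
    for s, ss in enumerate(seeds):
        try:
            if G == 1:
                labels0 = np.zeros(n, dtype=int)
            else:
                km_seed = int(ss.generate_state(1)[0] % (2**31))
                labels0 = KMeans(
                    n_clusters=G, n_init=1, random_state=km_seed
                ).fit_predict(L)
            result = _one_start(Y.astype(float), O, G, labels0, tol, max_iter)
        except Exception as exc:  # pragma: no cover - defensive per-start guard
            errors.append(f"start {s}: {exc!r}")
            continue
        if best is None or result[4][-1] > best[4][-1]:
            best = result
        if G == 1:
            break  # all starts identical
    if best is None:
        raise RuntimeError(
            "every mixture start failed:\n" + "\n".join(errors)
        )
    pi, components, vstates, resp, trace, converged, it = best
    # report components in decreasing mixing-weight order
    order = np.argsort(-pi, kind="stable")
    pi = pi[order]
    components = [components[g] for g in order]
    vstates = [vstates[g] for g in order]
    resp = resp[:, order]
    fit = MixtureFit(
        G=G,
        pi=pi,
        components=components,
        vstates=vstates,
        resp=resp,
        elbo=float(trace[-1]),
        elbo_trace=trace,
        bic=math.nan,
        labels=map_assign(resp),
        converged=converged,
        n_iter=it,
    )
    fit.bic = bic(fit, n)
    return fit


def select_model(
    Y,
    offsets=None,
    G_range=range(1, 6),
    n_starts: int = 10,
    seed=None,
    **kwargs,
) -> ModelSelection:
    """Fit the mixture for each G in ``G_range`` and select the BIC
    minimizer (ties toward smaller G).  Per-G failures are recorded; at least
    one G must succeed."""
    G_list = sorted(set(int(g) for g in G_range))
    seeds = spawn_seedseqs(seed, len(G_list))
    fits: dict[int, MixtureFit] = {}
    failures: dict[int, str] = {}
    for G, ss in zip(G_list, seeds):
        try:
            fits[G] = fit_mixture(
                Y, offsets=offsets, G=G, n_starts=n_starts, seed=ss, **kwargs
            )
        except Exception as exc:
            failures[G] = repr(exc)
            warnings.warn(f"mixture fit failed for G={G}: {exc!r}")
    if not fits:
        raise RuntimeError(f"all candidate G failed: {failures}")
    chosen = min(fits, key=lambda G: (fits[G].bic, G))
    return ModelSelection(fits=fits, chosen_G=chosen, failures=failures)


# ---------------------------------------------------------------------------
# two-step hybrid refinement
# ---------------------------------------------------------------------------

@dataclass
class PosteriorSummary:
    """Posterior summaries for one cluster from the hybrid sampler."""

    mu_mean: np.ndarray
    Sigma_mean: np.ndarray
    mu_ci: np.ndarray  # (2, d): 2.5% and 97.5% quantiles
    Sigma_ci: np.ndarray  # (2, d, d)
    acceptance_rate: float
    n_samples: int


def _log_target_rows(X, Ycl, Ocl, mu, Sinv):
    """Unnormalized log posterior of each latent row given (mu, Sigma)."""
    pois = (Ycl * (Ocl + X) - np.exp(Ocl + X)).sum(axis=1)
    Dm = X - mu
    return pois - 0.5 * np.einsum("ij,jk,ik->i", Dm, Sinv, Dm)


def hybrid_refine(
    Y,
    offsets,
    fit: MixtureFit,
    n_mcmc: int = 1000,
    burnin: int = 500,
    seed=None,
):
    """Bayesian refinement of a converged variational mixture fit.

    The variational MAP partition is treated as final; within each cluster the
    latent rows are updated by adaptive random-walk Metropolis (target
    acceptance 0.3) and (mu_g, Sigma_g) are drawn from their conjugate
    normal-inverse-Wishart conditional (prior: nu0 = d+2, Psi0 = I,
    kappa0 = 0.01, mu0 = the variational estimate).  Chains start at the
    variational estimates.

    Returns ``(components, summaries)``: posterior-mean parameters per
    cluster and per-cluster :class:`PosteriorSummary`.  With ``n_mcmc = 0``
    the variational estimates are returned unchanged (summaries ``None``).
    """
    if n_mcmc == 0:
        return list(fit.components), None
    Y = np.asarray(Y, dtype=float)
    n, d = Y.shape
    O = _as_offsets(offsets, n, d)
    rng = as_rng(seed)
    labels = fit.labels
    components = []
    summaries = []
    nu0 = d + 2
    Psi0 = NIW_PSI0_SCALE * np.eye(d)
    for g in range(fit.G):
        idx = np.flatnonzero(labels == g)
        if idx.size == 0:
            warnings.warn(f"cluster {g} is empty; keeping variational estimates")
            components.append(fit.components[g])
            summaries.append(None)
            continue
        Ycl, Ocl = Y[idx], O[idx]
        m = idx.size
        mu0 = fit.components[g].mu.copy()
        mu, Sigma = mu0.copy(), fit.components[g].Sigma.copy()
        X = fit.vstates[g].M[idx].copy()
        scale = 2.38 / math.sqrt(d)
        mus, Sigmas = [], []
        n_acc = 0.0
        n_prop = 0.0
        total = burnin + n_mcmc
        for t in range(total):
            Sinv = np.linalg.inv(Sigma)
            # random-walk Metropolis on the latent rows (rows independent)
            prop = X + scale * rng.standard_normal(X.shape)
            lp_cur = _log_target_rows(X, Ycl, Ocl, mu, Sinv)
            lp_prop = _log_target_rows(prop, Ycl, Ocl, mu, Sinv)
            accept = np.log(rng.random(m)) < lp_prop - lp_cur
            X[accept] = prop[accept]
            acc_rate = accept.mean()
            n_acc += accept.sum()
            n_prop += m
            if t < burnin:  # Robbins-Monro adaptation toward 0.3 acceptance
                scale *= math.exp((acc_rate - RWM_TARGET_ACCEPT) / math.sqrt(t + 1.0))
            # conjugate NIW draw of (mu, Sigma) given the latent rows
            xbar = X.mean(axis=0)
            S = (X - xbar).T @ (X - xbar)
            kappa_n = NIW_KAPPA0 + m
            nu_n = nu0 + m
            dev = (xbar - mu0)[:, None]
            Psi_n = Psi0 + S + (NIW_KAPPA0 * m / kappa_n) * (dev @ dev.T)
            mu_n = (NIW_KAPPA0 * mu0 + m * xbar) / kappa_n
            Sigma = stats.invwishart.rvs(df=nu_n, scale=Psi_n, random_state=rng)
            Sigma = np.atleast_2d(Sigma)
            mu = rng.multivariate_normal(mu_n, Sigma / kappa_n)
            if t >= burnin:
                mus.append(mu.copy())
                Sigmas.append(Sigma.copy())
        mus = np.array(mus)
        Sigmas = np.array(Sigmas)
        acc = n_acc / n_prop
        if not (0.05 <= acc <= 0.7):
            warnings.warn(
                f"cluster {g}: Metropolis acceptance rate {acc:.3f} outside "
                "[0.05, 0.7] after adaptation"
            )
        components.append(MPLNParams(mus.mean(axis=0), Sigmas.mean(axis=0)))
        summaries.append(
            PosteriorSummary(
                mu_mean=mus.mean(axis=0),
                Sigma_mean=Sigmas.mean(axis=0),
                mu_ci=np.quantile(mus, [0.025, 0.975], axis=0),
                Sigma_ci=np.quantile(Sigmas, [0.025, 0.975], axis=0),
                acceptance_rate=float(acc),
                n_samples=n_mcmc,
            )
        )
    return components, summaries
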