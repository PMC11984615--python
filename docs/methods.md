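# Methods

## Model

The package implements the Poisson-lognormal (PLN) hierarchy and its
multivariate extension (MPLN). An observation is a vector of counts
`Y = (Y_1, ..., Y_d)`; conditionally on a latent Gaussian vector
`X ~ N(mu, Sigma)` the entries are independent Poisson with rates
`exp(X_j + o_j)`, where `o_j` is a known log-scale offset (normalization
constant). The univariate PLN is the `d = 1` case; the negative binomial
(NB) arises from the same construction with a Gamma-distributed rate, and
the Poisson is the `sigma2 = 0` degenerate limit.

Observed-space moments are closed-form (see README). Two consequences drive
the design:

* `exp(sigma2) - 1` is the over-dispersion factor, so any mean/variance pair
  with `variance >= mean` is reachable and moment matching is invertible
  (`sigma2 = log(1 + (v - m)/m^2)`, `mu = log m - sigma2/2`); the NB
  inversion `alpha = m^2/(v - m)` requires strict over-dispersion.
* The observed correlation `(e^{Sjk}-1) / sqrt((e^{Sjj}-1+1/E_j)(e^{Skk}-1+1/E_k))`
  is an attenuated, sign-preserving image of the latent correlation, exact
  zero included. The attenuation statement holds for **correlations**, not
  covariances: `Cov(Y_j, Y_k) = E_j E_k (e^{Sjk} - 1)` grows with the means
  and can exceed `|Sigma_jk|` arbitrarily. The `1/E(Y)` terms are a Poisson
  noise floor: at fixed variance/mean ratio the observed correlation range
  approaches the latent range only once `e^{Sjj} - 1` dominates `1/E(Y)`,
  which requires either large means *and* appreciable over-dispersion.
  (At mean 10^4 with variance/mean 5, the ratio caps near 0.80 regardless
  of sample size; at variance/mean 50 it reaches ~0.98.)

## Univariate likelihood: mode-adapted quadrature

The PLN pmf is a one-dimensional integral with no closed form. A fixed
Gauss–Hermite rule centered at `mu` and scaled by `sigma` fails for
sequencing-scale counts: the conditional posterior of `X` given `Y = y` has
width roughly `1/sqrt(y)`, which for `y ~ 1000` and small `sigma2` falls
*between* the nodes of a prior-scaled rule, visibly biasing maximum
likelihood fits. `pln_logpmf` therefore centers the 50-node rule at the
integrand's mode (found by a few Newton steps on the strictly concave
log-integrand) and scales it by the local curvature
`1/sqrt(e^{x*} + 1/sigma2)`. Accuracy was verified against dense-grid
trapezoidal integration (an independent oracle) at ~1e-11 absolute error in
the log across the support, including deep tails; the pmf sums to 1 to
better than 1e-12 over a truncation covering the latent 8-sigma tail. The
`sigma2 <= 1e-10` branch evaluates the exact Poisson pmf instead; node
counts above 200 are rejected because the raw Hermite weights overflow.

ML fitting (`fit_nb`, `fit_pln`) runs L-BFGS-B with analytic gradients over
unconstrained parameterizations: `(log mean, log shape)` for NB (shape
capped at 1e8, where the fit is numerically Poisson) and `(mu, log sigma2)`
for PLN (`sigma2 >= 1e-10`). Counts are aggregated to unique values first,
so the cost per objective evaluation is `O(#unique x nodes)` independent of
n. Initialization is the moment-matching inversion with the sample variance
floored at `mean (1 + 1e-6)`. The optimizer targets gradient tolerance 1e-8
within 500 iterations; if the line search stalls (common on the flat ridge
at the equi-dispersion boundary) it is restarted once from the stalled
point, and a fit is declared converged when the projected gradient is below
`1e-5 x |loglik|` — boundary-pinned coordinates with outward-pointing
gradients count as stationary, since the dispersion boundaries are
legitimate optima.

## Variational MPLN estimation

The latent posterior per observation is approximated by a Gaussian with
mean `m_i` and *diagonal* covariance `diag(s_i^2)` (the standard choice in
the variational PLN literature; it trades posterior-correlation fidelity
for `O(nd)` scaling). The evidence lower bound is

```
ELBO = sum_ij [ y_ij (o_ij + m_ij) - e^{o_ij + m_ij + s_ij^2/2} - log y_ij! ]
       - sum_i KL( N(m_i, diag(s_i^2)) || N(mu, Sigma) )
```

Estimation alternates (i) joint L-BFGS ascent on all `(m_i, log s_i^2)`
with analytic gradients — rows are conditionally independent, so one call
optimizes all rows; at most 50 inner iterations per sweep — and (ii) the
closed-form weighted updates `mu = sum w_i m_i / sum w_i`,
`Sigma = sum w_i [(m_i - mu)(m_i - mu)^T + diag(s_i^2)] / sum w_i`, with a
relative ridge `1e-8 x trace/d` on the diagonal to guarantee positive
definiteness. Initialization: `m_ij = log(y_ij + 0.5) - o_ij`,
`s_ij^2 = 0.1`. The outer loop stops when the relative ELBO change drops
below 1e-6 (default; cap 1000 iterations); the trace is monotone up to
1e-8 relative tolerance by construction. Offsets enter only through the
rate exponent, so shifting all offsets by `c` shifts `mu` by `-c` and
leaves `Sigma` invariant.

For equi-dispersed data the MLE sits at the `Sigma -> 0` boundary, which
coordinate ascent approaches sublinearly; such fits converge in value
(correlations stabilize within ~1e-4 well before the tolerance triggers)
but use many more outer iterations.

## Mixtures, BIC, and hybrid refinement

A `G`-component mixture keeps a separate variational state per component;
responsibilities are `z_ig ∝ pi_g exp(J_ig)` where `J_ig` is row `i`'s
ELBO contribution under component `g` — the standard variational surrogate
for the intractable component density. Because each row's variational
parameters enter `J_ig` only through that row, the unweighted per-row
optimum is also the responsibility-weighted optimum, and the surrogate
log-likelihood `sum_i log sum_g pi_g exp(J_ig)` ascends monotonically.
Initialization is k-means on `log(y + 0.5) - o` with 10 restarts by default
(per-start seeds spawned from the master seed); the best final surrogate
wins. BIC is `-2 loglik~ + p log n` with
`p = (G-1) + G d + G d(d+1)/2`; `select_model` takes the minimizer, ties
toward the smaller `G`. Components are reported in decreasing-weight order
and MAP labels are 0-based in the library (the CLI writes 1-based labels).
Components that fall below `d + 1` effective observations get an inflated
covariance ridge and a warning.

Because responsibilities come from an approximation, `hybrid_refine`
re-estimates the selected model under the exact posterior while treating
the variational partition as final: within each cluster, latent rows are
updated by adaptive random-walk Metropolis (scale adapted during burn-in
toward 0.3 acceptance by a Robbins–Monro recursion) and `(mu_g, Sigma_g)`
are drawn from their conjugate normal–inverse-Wishart conditional with a
weak prior (`nu0 = d + 2`, `Psi0 = I`, `kappa0 = 0.01`, `mu0` = the
variational estimate, which also initializes the chain). A random-walk
sampler was chosen for dependence-free simplicity; the latent-row target is
log-concave, so mixing is unproblematic at these scales. Posterior means
and 95% quantile intervals are reported; an acceptance rate outside
[0.05, 0.7] after adaptation triggers a warning. With `n_mcmc = 0` the
variational estimates pass through unchanged. Recovery checks compare the
posterior mean to the generating value on the scale of the posterior
standard deviation, which dominates the chain's Monte-Carlo error at these
run lengths.

## Normalization offsets

`tmm_factors` implements the trimmed-mean-of-M-values recipe: reference =
sample whose upper-quartile depth-normalized count is closest to the
across-sample mean; M- and A-values over features positive in both sample
and reference; two-sided trims of 30% (M) and 5% (A); precision weights
from the binomial delta-method variance; factor = 2^(weighted mean M).
These constants are the canonical published ones, not tuned. The returned
factors are *effective* size factors — TMM scaling times relative library
size — rescaled to geometric mean 1 so they are jointly identifiable with
`mu` (a pure depth doubling doubles the factor). `median_ratio_size_factors`
is the median, over features positive in every sample, of the count over
the feature's across-sample geometric mean; the median is taken of the
ratios themselves (medians of logs differ when the middle pair is averaged).
Offsets are per-sample scalars, `log(factor)`, broadcast across features.

## Synthetic-data generators and study conditions

`run_table1` reproduces the univariate recovery study at its stated
conditions: nine scenarios (mean 1000: Poisson; NB and PLN at variances
5000, 10000, 20000, 50000), 100 replicates of N = 1000 counts, all three
families fitted to every replicate, percentage relative bias
`(estimate - truth)/truth x 100` summarized per scenario x model cell.

`run_scenarios_AF` generates the six multivariate settings. Dimensions and
covariances are not externally specified, so the package fixes them once:
d = 5, marginal mean 500, variance/mean 10; A/B/C use independent Poisson /
NB / PLN margins; D sets all latent correlations to +0.5, E to −0.2 (the
most negative exchangeable value that stays positive-definite at d = 5 with
margin), F uses two blocks (+0.5 within, −0.3 between), positive-definite
by construction and checked at build time. `correlation_mapping` draws
bivariate PLN samples over a latent-correlation grid (default 41 points in
[−0.99, 0.99], n = 5000) and records Spearman correlations in both spaces;
`qq_compare` draws moment-matched NB and PLN samples and returns paired
empirical quantiles.

All drivers expand a single master seed into per-scenario and per-replicate
substreams (`SeedSequence.spawn`), so every experiment is bit-reproducible
from (spec, seed).

What the generators do *not* emulate: library-size variation unless offsets
are supplied, zero inflation beyond what the model implies, feature-count
dimensions beyond the low tens, and any real-data preprocessing (DE
pre-filtering, taxon selection). Passing tests therefore demonstrate
correctness of the estimators under the model and robustness to the
misspecifications actually simulated (NB/Poisson data fitted by PLN and
vice versa), not performance on arbitrary real datasets.

## Problem sizes in the test suite

The acceptance-style tests run the univariate study at full scale (9 x 100
x N = 1000). Replicated multivariate studies are sized for desk-scale
runtimes as the package's own choice of study conditions: scenarios A–F use
30 replicates at n = 1000, d = 5; the mixture ARI/BIC study uses 20
replicates at n = 500, d = 3 with G in {1, 2, 3} and 2 starts; hybrid
refinement checks use single datasets of n = 500 with chains of 500–800
total iterations. Thresholds (sd < 1%, |bias| < 0.3%, sign recovery >= 95%,
ARI >= 0.9, BIC hit rate >= 90%, entrywise correlation error < 0.1) follow
the claims the package makes for these designs.

## Known limitations

* The diagonal variational family underestimates posterior covariance; the
  ELBO-based BIC surrogate inherits this, which is precisely why the hybrid
  refinement exists.
* Equi- or under-dispersed data push `Sigma` to its boundary, where
  convergence is slow (in iterations, not in the quantities of interest).
* No covariate effects on `mu`, zero-inflated variants, structured
  (factor-analytic or sparse-precision) covariances, or gene-length
  normalization.
* `hybrid_refine` samples within fixed clusters only; it never revisits the
  partition, by design.
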