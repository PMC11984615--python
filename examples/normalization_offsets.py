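"""Depth normalization as log offsets in the MPLN latent exponent.

Samples are simulated with 3x different sequencing depths; TMM and
median-of-ratios factors recover the depth ratios, and fitting with the
resulting offsets removes the depth effect from the latent means.
"""

import numpy as np

from plnmix import MPLNParams, compute_offsets, fit_mpln, mpln_sample

rng = np.random.default_rng(8)
gen = MPLNParams(np.log([200.0, 120.0, 300.0, 80.0]), 0.15 * np.eye(4) + 0.04)
n = 60
depth = np.repeat([1.0, 3.0], [30, 30])  # second half sequenced 3x deeper
Y = mpln_sample(gen, n, offsets=np.log(depth), seed=rng)

for method in ("tmm", "median_ratio"):
    spec = compute_offsets(Y, method=method)
    ratio = spec.factors[30:].mean() / spec.factors[:30].mean()
    print(f"{method:13s}: deep/shallow factor ratio = {ratio:.2f} (truth 3.0)")

spec = compute_offsets(Y, method="tmm")
fit_raw = fit_mpln(Y)
fit_off = fit_mpln(Y, offsets=spec.offsets)
# factors have geometric mean 1, so the average depth is absorbed into mu;
# subtract it to compare against the generating means
shift = np.mean(np.log(depth))
print("\nlatent variances (generating)  :", np.round(np.diag(gen.Sigma), 3))
print("fit without offsets            :", np.round(np.diag(fit_raw.params.Sigma), 3))
print("fit with TMM offsets           :", np.round(np.diag(fit_off.params.Sigma), 3))
print("\nlatent means (generating)      :", np.round(gen.mu + shift, 2))
print("fit with TMM offsets           :", np.round(fit_off.params.mu, 2))
print(
    "\nWithout offsets the unmodeled 3x depth split inflates every latent "
    "variance\nby roughly (log 3)^2 / 4 ~ 0.30; with offsets the generating "
    "covariance and\nmeans are recovered."
)
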