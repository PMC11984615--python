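"""Between-sample normalization factors and their conversion to log offsets.

Sequencing depth differs between samples, so raw counts are not comparable
across rows.  The MPLN framework absorbs depth differences through a
log-scale offset added to the latent exponent (Poisson rate e^{x + o}).
Two standard factor estimators are provided:

* ``tmm_factors`` — trimmed mean of M-values: log-ratios against a reference
  sample are trimmed (30% two-sided on M, 5% on A) and averaged with
  precision weights.  The returned factors are *effective* size factors —
  the TMM scaling factor multiplied by relative library size — so that
  dividing counts by them makes samples directly comparable; they are
  rescaled to geometric mean 1.

* ``median_ratio_size_factors`` — median-of-ratios: each sample's factor is
  the median, over features positive in every sample, of the count divided
  by that feature's across-sample geometric mean.

Offsets are simply the log factors, broadcast across features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "OffsetSpec",
    "tmm_factors",
    "median_ratio_size_factors",
    "to_offsets",
    "compute_offsets",
]

TMM_TRIM_M = 0.30  # two-sided trim fraction on M-values (log-ratios)
TMM_TRIM_A = 0.05  # two-sided trim fraction on A-values (abundance)


@dataclass(frozen=True)
class OffsetSpec:
    """Per-sample normalization factors and their log offsets."""

    method: str  # "tmm" | "median_ratio" | "none" | "user"
    factors: np.ndarray
    offsets: np.ndarray

    def __post_init__(self):
        factors = np.asarray(self.factors, dtype=float)
        offsets = np.asarray(self.offsets, dtype=float)
        object.__setattr__(self, "factors", factors)
        object.__setattr__(self, "offsets", offsets)
        if np.any(factors <= 0):
            raise ValueError("factors must be positive")
        if not np.allclose(offsets, np.log(factors), atol=1e-12):
            raise ValueError("offsets must equal log(factors)")


def _validate_matrix(Y) -> np.ndarray:
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2:
        raise ValueError("count matrix must be 2-dimensional (samples x features)")
    if np.any(Y < 0) or np.any(Y != np.floor(Y)):
        raise ValueError("counts must be nonnegative integers")
    return Y


def tmm_factors(Y) -> np.ndarray:
    """Effective TMM size factors, rescaled to geometric mean 1.

    The reference is the sample whose upper-quartile depth-normalized count is
    closest to the across-sample mean of that quantity.  For each sample,
    M-values (log2 ratios of depth-normalized counts vs the reference) and
    A-values (average log2 abundance) are computed over features positive in
    both; after two-sided trimming (30% on M, 5% on A) the factor is 2 to the
    precision-weighted mean M, with weights from the binomial delta-method
    variance.  The result is multiplied by relative library size (effective
    factor convention), then rescaled.
    """
    Y = _validate_matrix(Y)
    n, d = Y.shape
    if n < 2:
        raise ValueError("TMM needs at least 2 samples")
    lib = Y.sum(axis=1)
    if np.any(lib <= 0):
        raise ValueError("every sample must have at least one positive count")
    # reference: upper quartile of depth-normalized counts closest to the mean
    uq = np.array([np.quantile(Y[s] / lib[s], 0.75) for s in range(n)])
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    yr, Nr = Y[ref], lib[ref]
    tmm = np.ones(n)
    for s in range(n):
        if s == ref:
            continue
        ok = (Y[s] > 0) & (yr > 0)
        if not np.any(ok):
            raise ValueError(
                f"sample {s} shares no positive feature with the reference"
            )
        ys, Ns = Y[s][ok], lib[s]
        yrk = yr[ok]
        M = np.log2((ys / Ns) / (yrk / Nr))
        A = 0.5 * (np.log2(ys / Ns) + np.log2(yrk / Nr))
        if np.max(np.abs(M)) < 1e-6:
            continue  # identical composition
        w = 1.0 / ((Ns - ys) / (Ns * ys) + (Nr - yrk) / (Nr * yrk))
        loM, hiM = np.quantile(M, [TMM_TRIM_M, 1.0 - TMM_TRIM_M])
        loA, hiA = np.quantile(A, [TMM_TRIM_A, 1.0 - TMM_TRIM_A])
        keep = (M >= loM) & (M <= hiM) & (A >= loA) & (A <= hiA)
        if not np.any(keep):
            keep = np.ones_like(M, dtype=bool)
        tmm[s] = 2.0 ** (np.sum(w[keep] * M[keep]) / np.sum(w[keep]))
    factors = tmm * lib  # effective factor: TMM scaling x library size
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


def median_ratio_size_factors(Y) -> np.ndarray:
    """Median-of-ratios size factors.

    factor_s = median over features positive in all samples of
    y_sf / geomean_f, where geomean_f is the feature's geometric mean across
    samples.  Raises if no feature is positive everywhere (a pseudo-count of
    1 added to Y beforehand is the documented workaround for sparse data).
    """
    Y = _validate_matrix(Y)
    all_pos = np.all(Y > 0, axis=0)
    if not np.any(all_pos):
        raise ValueError(
            "no feature is positive in every sample; median-of-ratios is "
            "undefined. Consider adding a pseudo-count (e.g. Y + 1) first."
        )
    Yp = Y[:, all_pos]
    geomean = np.exp(np.mean(np.log(Yp), axis=0))
    # median of the ratios themselves (not of log-ratios: the two differ when
    # the middle pair is averaged at an even feature count)
    return np.median(Yp / geomean[None, :], axis=1)


def to_offsets(factors) -> np.ndarray:
    """Elementwise log of positive normalization factors."""
    factors = np.asarray(factors, dtype=float)
    if np.any(factors <= 0):
        raise ValueError("factors must be positive")
    return np.log(factors)


def compute_offsets(Y, method: str = "tmm", factors=None) -> OffsetSpec:
    """One-stop construction of an :class:`OffsetSpec` from a count matrix.

    ``method``: "tmm", "median_ratio", "none" (all-zero offsets), or "user"
    (supply ``factors`` directly).
    """
    if method == "tmm":
        f = tmm_factors(Y)
    elif method == "median_ratio":
        f = median_ratio_size_factors(Y)
    elif method == "none":
        f = np.ones(np.asarray(Y).shape[0])
    elif method == "user":
        if factors is None:
            raise ValueError("method='user' requires factors")
        f = np.asarray(factors, dtype=float)
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    return OffsetSpec(method=method, factors=f, offsets=to_offsets(f))
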