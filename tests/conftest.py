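import numpy as np
import pytest

from plnmix import MPLNParams, mpln_sample


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


def make_two_cluster_counts(n, d, shift, seed, balance=0.5):
    """Counts from a well-separated two-component MPLN mixture, with labels.

    Component latent means differ by +/- ``shift`` in alternating
    coordinates; shared moderate latent covariance.
    """
    r = np.random.default_rng(seed)
    base = np.log(np.linspace(100, 400, d))
    delta = shift * np.where(np.arange(d) % 2 == 0, 1.0, -1.0)
    Sigma = 0.25 * np.eye(d) + 0.05
    p1 = MPLNParams(base, Sigma)
    p2 = MPLNParams(base + delta, Sigma)
    z = r.random(n) < balance
    Y = np.where(z[:, None], mpln_sample(p1, n, seed=r), mpln_sample(p2, n, seed=r))
    return Y, z.astype(int), (p1, p2)
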