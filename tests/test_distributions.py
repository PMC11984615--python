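"""Closed-form moments, moment matching, quadrature pmf, and samplers."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.special import gammaln, logsumexp

from plnmix import (
    MomentPair,
    MPLNParams,
    NBParams,
    PLNParams,
    PoissonParams,
    UnderDispersionError,
    latent_cov_entry,
    mpln_moments,
    mpln_sample,
    nb_match_moments,
    nb_moments,
    nb_sample,
    pln_logpmf,
    pln_match_moments,
    pln_moments,
    pln_sample,
    poisson_sample,
)


def dense_pln_logpmf(y, mu, sigma2):
    """Independent brute-force oracle: trapezoidal log-integration on a dense
    grid covering both the latent prior and the Poisson likelihood peak."""
    lo = min(mu - 20 * math.sqrt(sigma2), (math.log(y + 0.5) if y > 0 else mu - 40) - 5)
    hi = max(mu + 20 * math.sqrt(sigma2), (math.log(y + 1.5) if y > 0 else mu) + 5)
    x = np.linspace(lo, hi, 400_000)
    g = (
        y * x
        - np.exp(x)
        - gammaln(y + 1)
        - (x - mu) ** 2 / (2 * sigma2)
        - 0.5 * math.log(2 * math.pi * sigma2)
    )
    return logsumexp(g) + math.log(x[1] - x[0])


class TestMoments:
    @pytest.mark.parametrize(
        "mu,sigma2,mean,var",
        [
            (math.log(1000), 0.0, 1000.0, 1000.0),
            (0.0, 2.0, math.e, math.e + math.e**2 * (math.e**2 - 1)),
        ],
    )
    def test_pln_moments_closed_form(self, mu, sigma2, mean, var):
        mp = pln_moments(PLNParams(mu, sigma2))
        assert mp.mean == pytest.approx(mean, rel=1e-12)
        assert mp.variance == pytest.approx(var, rel=1e-12)

    def test_nb_moments_and_inversion(self):
        params = nb_match_moments(MomentPair(1000, 5000))
        assert params.shape == pytest.approx(250.0)
        assert params.scale == pytest.approx(4.0)
        mp = nb_moments(params)
        assert (mp.mean, mp.variance) == (pytest.approx(1000), pytest.approx(5000))

    def test_pln_inversion_example(self):
        params = pln_match_moments(MomentPair(1000, 50000))
        assert params.sigma2 == pytest.approx(math.log(1.049), rel=1e-10)
        assert params.mu == pytest.approx(math.log(1000) - params.sigma2 / 2)

    @pytest.mark.parametrize("matcher", [pln_match_moments, nb_match_moments])
    def test_under_dispersion_rejected(self, matcher):
        with pytest.raises(UnderDispersionError):
            matcher(MomentPair(10, 5))
        with pytest.raises(UnderDispersionError):
            nb_match_moments(MomentPair(10, 10))  # alpha -> infinity limit

    @given(
        m=st.floats(0.01, 1e5),
        ratio=st.floats(1.0, 100.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_moment_matching_round_trips(self, m, ratio):
        target = MomentPair(m, m * ratio)
        back = pln_moments(pln_match_moments(target))
        assert back.mean == pytest.approx(m, rel=1e-10)
        assert back.variance == pytest.approx(target.variance, rel=1e-10)
        if ratio > 1.0 + 1e-9:
            back = nb_moments(nb_match_moments(target))
            assert back.mean == pytest.approx(m, rel=1e-10)
            assert back.variance == pytest.approx(target.variance, rel=1e-10)

    @given(mu=st.floats(-3, 10), sigma2=st.floats(0, 5))
    @settings(max_examples=200, deadline=None)
    def test_overdispersion_identity(self, mu, sigma2):
        """V(Y) = E(Y) + E(Y)^2 (e^{sigma2} - 1) exactly."""
        mp = pln_moments(PLNParams(mu, sigma2))
        assert mp.variance == pytest.approx(
            mp.mean + mp.mean**2 * math.expm1(sigma2), rel=1e-12
        )
        assert mp.variance >= mp.mean


class TestLogPmf:
    def test_sigma2_zero_is_exact_poisson(self):
        y = np.arange(20)
        got = pln_logpmf(y, PLNParams(math.log(5), 0.0))
        np.testing.assert_allclose(got, stats.poisson.logpmf(y, 5.0), rtol=1e-12)

    @pytest.mark.parametrize("y", [0, 1, 50, 1000, 3000])
    @pytest.mark.parametrize("mu,sigma2", [(0.0, 1.0), (6.8838, 0.04784)])
    def test_matches_dense_integration(self, y, mu, sigma2):
        got = pln_logpmf(y, PLNParams(mu, sigma2))
        want = dense_pln_logpmf(y, mu, sigma2)
        assert got == pytest.approx(want, abs=1e-8)

    def test_pmf_normalizes(self):
        # truncation point covers the lognormal latent tail to 8 sigma plus
        # the Poisson spread; residual mass beyond it is < 1e-12
        params = PLNParams(math.log(50), 0.5)
        rate_hi = math.exp(params.mu + 8 * math.sqrt(params.sigma2))
        ymax = int(rate_hi + 12 * math.sqrt(rate_hi))
        total = np.exp(pln_logpmf(np.arange(ymax + 1), params)).sum()
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_offset_shifts_rate(self):
        base = pln_logpmf(7, PLNParams(1.0, 0.3), offset=0.5)
        shifted = pln_logpmf(7, PLNParams(1.5, 0.3), offset=0.0)
        assert base == pytest.approx(shifted, rel=1e-12)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            pln_logpmf(-1, PLNParams(0.0, 1.0))
        with pytest.raises(ValueError):
            pln_logpmf(2.5, PLNParams(0.0, 1.0))


class TestSamplers:
    def test_pln_sample_moments(self):
        params = pln_match_moments(MomentPair(1000, 20000))
        y = pln_sample(params, 10**6, seed=1)
        mp = pln_moments(params)
        se_mean = math.sqrt(mp.variance / y.size)
        assert abs(y.mean() - mp.mean) < 3 * se_mean
        m4 = np.mean((y - y.mean()) ** 4)
        se_var = math.sqrt((m4 - y.var() ** 2) / y.size)
        assert abs(y.var(ddof=1) - mp.variance) < 3 * se_var

    def test_sigma2_zero_draws_match_poisson(self):
        """Chi-square goodness of fit of sigma2=0 PLN draws vs Poisson."""
        rate = 30.0
        y = pln_sample(PLNParams(math.log(rate), 0.0), 10**5, seed=2)
        lo, hi = 10, 55
        edges = np.arange(lo, hi)
        obs = np.bincount(np.clip(y, lo, hi) - lo, minlength=hi - lo + 1)
        probs = stats.poisson.pmf(edges, rate)
        exp = np.concatenate(
            [
                [stats.poisson.cdf(lo, rate)],
                probs[1:],
                [stats.poisson.sf(hi - 1, rate)],
            ]
        )
        stat, p = stats.chisquare(obs, exp * y.size)
        assert p > 0.001

    @pytest.mark.parametrize(
        "draw",
        [
            lambda s: poisson_sample(PoissonParams(10), 100, seed=s),
            lambda s: nb_sample(NBParams(5, 2), 100, seed=s),
            lambda s: pln_sample(PLNParams(2.0, 0.5), 100, seed=s),
            lambda s: mpln_sample(
                MPLNParams([1.0, 2.0], [[0.5, 0.1], [0.1, 0.4]]), 50, seed=s
            ),
        ],
    )
    def test_seed_determinism(self, draw):
        np.testing.assert_array_equal(draw(123), draw(123))

    def test_mpln_sigma_to_zero_is_poisson_rows(self):
        params = MPLNParams([2.0, 3.0], 1e-12 * np.eye(2))
        y = mpln_sample(params, 20000, seed=3)
        np.testing.assert_allclose(
            y.mean(axis=0), np.exp([2.0, 3.0]), rtol=0.05
        )
        np.testing.assert_allclose(
            y.var(axis=0), np.exp([2.0, 3.0]), rtol=0.1
        )

    def test_mpln_offsets_shape_mismatch(self):
        params = MPLNParams([1.0, 1.0], np.eye(2) * 0.1)
        with pytest.raises(ValueError):
            mpln_sample(params, 10, offsets=np.zeros((5, 2)), seed=0)


class TestMPLNMoments:
    def test_diagonal_latent_gives_zero_observed_covariance(self):
        params = MPLNParams([1.0, 2.0, 0.5], np.diag([0.3, 0.2, 0.5]))
        _, cov, cor = mpln_moments(params)
        off = ~np.eye(3, dtype=bool)
        assert np.all(cov[off] == 0.0)
        assert np.all(cor[off] == 0.0)

    def test_d1_reduces_to_univariate(self):
        params = MPLNParams([1.3], [[0.7]])
        m, cov, cor = mpln_moments(params)
        uni = pln_moments(PLNParams(1.3, 0.7))
        assert m[0] == pytest.approx(uni.mean, rel=1e-12)
        assert cov[0, 0] == pytest.approx(uni.variance, rel=1e-12)
        assert cor[0, 0] == 1.0

    def test_matches_empirical_moments_d3(self):
        Sigma = np.array([[0.5, 0.2, -0.15], [0.2, 0.4, 0.1], [-0.15, 0.1, 0.6]])
        params = MPLNParams([3.0, 3.5, 2.5], Sigma)
        m, cov, _ = mpln_moments(params)
        Y = mpln_sample(params, 10**6, seed=5)
        n = Y.shape[0]
        se_mean = np.sqrt(np.diag(cov) / n)
        assert np.all(np.abs(Y.mean(axis=0) - m) < 3 * se_mean)
        emp_cov = np.cov(Y.T)
        for j in range(3):
            for k in range(3):
                prods = (Y[:, j] - Y[:, j].mean()) * (Y[:, k] - Y[:, k].mean())
                se = prods.std(ddof=1) / math.sqrt(n)
                assert abs(emp_cov[j, k] - cov[j, k]) < 3 * se

    def test_correlation_closed_form(self):
        """Observed Pearson correlation equals the printed ratio
        (e^{Sjk}-1) / sqrt((e^{Sjj}-1 + 1/E_j)(e^{Skk}-1 + 1/E_k))."""
        sjj = skk = 0.683
        sjk = latent_cov_entry(0.9, sjj, skk)
        assert sjk == pytest.approx(0.9 * 0.683, rel=1e-12)
        params = MPLNParams([2.0, 3.0], [[sjj, sjk], [sjk, skk]])
        m, _, cor = mpln_moments(params)
        want = math.expm1(sjk) / math.sqrt(
            (math.expm1(sjj) + 1 / m[0]) * (math.expm1(skk) + 1 / m[1])
        )
        assert cor[0, 1] == pytest.approx(want, rel=1e-12)

    @pytest.mark.parametrize(
        "cor_x,sjj,skk,want", [(0.0, 2.0, 2.0, 0.0), (0.5, 4.0, 1.0, 1.0)]
    )
    def test_latent_cov_entry_examples(self, cor_x, sjj, skk, want):
        assert latent_cov_entry(cor_x, sjj, skk) == pytest.approx(want, abs=1e-15)

    def test_latent_cov_entry_rejects_non_pd(self):
        with pytest.raises(ValueError):
            latent_cov_entry(1.0, 1.0, 1.0)

    @given(
        mu1=st.floats(-1, 6),
        mu2=st.floats(-1, 6),
        s11=st.floats(0.01, 3.0),
        s22=st.floats(0.01, 3.0),
        rho=st.one_of(
            st.just(0.0),
            st.floats(-0.95, 0.95, allow_subnormal=False).filter(
                lambda r: abs(r) > 1e-8
            ),
        ),
    )
    @settings(max_examples=200, deadline=None)
    def test_attenuation_and_sign_preservation(self, mu1, mu2, s11, s22, rho):
        """Observed-space correlation is strictly attenuated relative to the
        latent correlation whenever the latter is nonzero, the sign always
        carries over, and zero maps to zero exactly."""
        sjk = latent_cov_entry(rho, s11, s22)
        params = MPLNParams([mu1, mu2], [[s11, sjk], [sjk, s22]])
        _, cov, cor = mpln_moments(params)
        if rho == 0.0:
            assert cov[0, 1] == 0.0
            assert cor[0, 1] == 0.0
        else:
            assert abs(cor[0, 1]) < abs(rho)
            assert np.sign(cov[0, 1]) == np.sign(sjk)
            assert np.sign(cor[0, 1]) == np.sign(sjk)


class TestParamValidation:
    @pytest.mark.parametrize(
        "bad",
        [
            lambda: PoissonParams(0.0),
            lambda: NBParams(-1.0, 2.0),
            lambda: NBParams(1.0, 0.0),
            lambda: PLNParams(0.0, -0.1),
            lambda: MPLNParams([0.0, 0.0], [[1.0, 2.0], [2.0, 1.0]]),  # not PD
            lambda: MPLNParams([0.0], [[1.0, 0.0], [0.0, 1.0]]),  # shape
            lambda: MomentPair(-1.0, 1.0),
        ],
    )
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            bad()
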