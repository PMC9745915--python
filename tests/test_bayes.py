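"""Bayesian posterior draws, the HPD estimator and the two HPD intervals."""

import math

import numpy as np
import pytest
from scipy import stats

from dlnq import (
    GroupSummary,
    PercentileSpec,
    bayes_interval,
    bs1_lambda_draw,
    bs2_lambda_draw,
    draw_sigma2_mu,
    fgci_interval,
    hpd,
    sample_delta_lognormal,
    summarize,
)
from dlnq.bayes import bs2_t_star


def _summary(n=40, n0=4, ybar=1.2, s2=0.8):
    return GroupSummary(n=n, n0=n0, n1=n - n0, ybar1=ybar, s2_1=s2,
                        delta_hat=n0 / n)


class TestPosteriorDraws:
    def test_sigma2_posterior_mean(self, rng):
        s = _summary(n=30, n0=0, ybar=0.0, s2=1.0)  # n1 = 30
        sigma2, _ = draw_sigma2_mu(s, 200_000, rng)
        df = s.n1 - 1
        expected = (df * s.s2_1 / 2) / (df / 2 - 1)  # inverse-gamma mean
        assert np.mean(sigma2) == pytest.approx(expected, rel=0.02)

    def test_mu_posterior_mean_is_ybar(self, rng):
        s = _summary()
        _, mu = draw_sigma2_mu(s, 100_000, rng)
        assert abs(np.mean(mu) - s.ybar1) < 3 * np.std(mu) / math.sqrt(mu.size)

    def test_seed_reproducibility(self):
        s = _summary()
        a = draw_sigma2_mu(s, 100, np.random.default_rng(3))
        b = draw_sigma2_mu(s, 100, np.random.default_rng(3))
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])


class TestLambdaDraws:
    def test_bs1_reduces_to_mu_at_median_eta(self):
        # choose v so the truncated beta gives Q_eta = 0.5: requires
        # Q_delta = (p - 0.5)/(1 - 0.5) = 2p - 1
        s = _summary()
        p = 0.6
        q_delta = 2 * p - 1
        a, b = s.n0 + 0.5, s.n1 + 0.5
        v = stats.beta.cdf(q_delta, a, b) / stats.beta.cdf(p, a, b)
        lam = bs1_lambda_draw(2.5, 0.7, s, p, 0.0, float(s.n1 - 1), v)
        assert lam == pytest.approx(2.5, abs=1e-9)

    def test_bs1_v_to_zero_gives_eta_p(self):
        s = _summary()
        direct = bs1_lambda_draw(1.0, 0.5, s, 0.95, 0.2, 30.0, 0.0)
        d = math.sqrt(30.0 / (s.n1 - 1))
        expected = 1.0 + math.sqrt(0.5) / math.sqrt(s.n1) * (
            0.2 + stats.norm.ppf(0.95) * math.sqrt(s.n1)
        ) / d
        assert direct == pytest.approx(expected, rel=1e-12)

    def test_bs2_sigma_zero_limit(self, spec95):
        s = _summary()
        assert bs2_lambda_draw(1.7, 1e-18, s, spec95) == pytest.approx(1.7, abs=1e-6)

    def test_bs2_central_t_when_eta_half(self):
        s = GroupSummary(n=10, n0=6, n1=4, ybar1=1.0, s2_1=0.5, delta_hat=0.6)
        spec = PercentileSpec(p=0.8, alpha=0.05)
        assert bs2_t_star(s, spec) == pytest.approx(stats.t.ppf(0.95, 3))

    def test_bs2_factor_constant_across_draws(self, spec95, rng):
        s = _summary()
        sigma2, mu = draw_sigma2_mu(s, 100, rng)
        lam = bs2_lambda_draw(mu, sigma2, s, spec95)
        t_implied = (lam - mu) * math.sqrt(s.n1) / np.sqrt(sigma2)
        assert np.allclose(t_implied, t_implied[0])


class TestHpd:
    def test_integer_grid_first_window(self):
        lo, hi = hpd(np.arange(1, 101), 0.05)
        assert (lo, hi) == (1.0, 95.0)

    def test_standard_normal_interval(self, rng):
        draws = rng.standard_normal(200_000)
        lo, hi = hpd(draws, 0.05)
        assert lo == pytest.approx(-1.96, abs=0.05)
        assert hi == pytest.approx(1.96, abs=0.05)

    def test_no_wider_than_equal_tails(self, rng):
        for _ in range(20):
            draws = rng.gamma(2.0, size=300)
            lo, hi = hpd(draws, 0.1)
            qlo, qhi = np.quantile(draws, [0.05, 0.95])
            assert hi - lo <= qhi - qlo + 1e-12

    def test_minimal_window_vs_exhaustive_search(self, rng):
        for _ in range(10):
            draws = np.sort(rng.lognormal(size=150))
            lo, hi = hpd(draws, 0.2)
            w = math.ceil(0.8 * draws.size)
            best = min(
                (draws[j + w - 1] - draws[j], j) for j in range(draws.size - w + 1)
            )
            assert hi - lo == pytest.approx(best[0])
            # contiguous order-statistic pair containing >= w draws
            assert np.sum((draws >= lo) & (draws <= hi)) >= w

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            hpd([1.0, 2.0], 1.5)


class TestBayesInterval:
    @pytest.mark.parametrize("variant", ["bs1", "bs2"])
    def test_seed_reproducibility(self, rain_summaries, spec95, variant):
        a = bayes_interval(rain_summaries, spec95, m=400, variant=variant, rng=5)
        b = bayes_interval(rain_summaries, spec95, m=400, variant=variant, rng=5)
        assert (a.log_L, a.log_U) == (b.log_L, b.log_U)

    @pytest.mark.parametrize("variant", ["bs1", "bs2"])
    def test_limits_ordered_positive(self, rain_summaries, spec95, variant):
        r = bayes_interval(rain_summaries, spec95, m=400, variant=variant, rng=6)
        assert 0 < r.L < r.U

    def test_unknown_variant_rejected(self, rain_summaries, spec95):
        with pytest.raises(ValueError, match="variant"):
            bayes_interval(rain_summaries, spec95, m=200, variant="bs3", rng=1)

    def test_bs1_matches_fgci_for_large_sample_matched_pivots(self, spec95):
        # the posterior of (mu, sigma2) and the fiducial pivots agree
        # asymptotically; under a common studentising convention the two
        # constructions give the same interval at large n
        rng = np.random.default_rng(7)
        s = summarize(sample_delta_lognormal(500, 1.0, 0.5, 0.1, rng))
        f = fgci_interval([s], spec95, m=20_000, rng=1, pivot_scaling="chi2")
        b = bayes_interval([s], spec95, m=20_000, variant="bs1", rng=2,
                           pivot_scaling="chi2")
        assert f.log_L == pytest.approx(b.log_L, abs=0.05)
        assert f.log_U == pytest.approx(b.log_U, abs=0.05)
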