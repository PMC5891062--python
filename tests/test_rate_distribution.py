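"""Gamma-Poisson fitting, goodness of fit, CV scaling, and nested ANOVA."""

import numpy as np
import pytest
from scipy import integrate, stats

from mutscape.rate_distribution import (cv_scaling, fit_gamma_poisson,
                                        goodness_of_fit, nb_pmf,
                                        nested_scale_anova)


def _nb_counts(rng, n, cv, mean):
    """Counts from the gamma-Poisson generative model with unit offsets."""
    alpha = rng.gamma(1 / cv ** 2, cv ** 2, n) if cv > 0 else np.ones(n)
    return rng.poisson(alpha * mean)


class TestNegativeBinomial:
    def test_pmf_equals_poisson_gamma_quadrature(self):
        """The NB pmf is the gamma mixture of Poissons (quadrature oracle)."""
        for count, mean, shape in [(3, 2.0, 5.0), (0, 1.5, 0.8), (10, 4.0, 30.0)]:
            oracle, err = integrate.quad(
                lambda a: stats.poisson.pmf(count, mean * a)
                * stats.gamma.pdf(a, shape, scale=1 / shape), 0, np.inf)
            assert err < 1e-8
            assert nb_pmf(count, mean, shape) == pytest.approx(oracle, abs=1e-8)

    def test_converges_to_poisson_at_large_shape(self):
        ks = np.arange(0, 30)
        nb = np.array([nb_pmf(k, 5.0, 1e6) for k in ks])
        po = stats.poisson.pmf(ks, 5.0)
        assert np.max(np.abs(nb - po)) < 1e-6


class TestFitGammaPoisson:
    def test_parameter_recovery_grid(self):
        """Median |cv_hat - cv| over a (cv, mean-count) grid stays below 0.02."""
        errors = []
        for cv in (0.1, 0.2, 0.4):
            for mean in (1.0, 5.0, 20.0):
                for seed in range(3):
                    rng = np.random.default_rng(1000 + seed)
                    counts = _nb_counts(rng, 2000, cv, mean)
                    fit = fit_gamma_poisson(counts, np.full(2000, 1e6))
                    errors.append(abs(fit.cv - cv))
        assert np.median(errors) < 0.02

    def test_recovery_with_ci_coverage(self):
        rng = np.random.default_rng(7)
        counts = _nb_counts(rng, 2500, 0.18, 4.2)
        fit = fit_gamma_poisson(counts, np.ones(2500))
        assert fit.cv == pytest.approx(0.18, abs=0.03)
        assert fit.cv_ci[0] <= 0.18 <= fit.cv_ci[1]
        assert fit.mean_rate == pytest.approx(counts.mean(), rel=1e-12)

    def test_poisson_limit(self):
        """Counts exactly proportional to offsets: CV ~ 0 and CI touches 0."""
        counts = np.full(100, 50)
        fit = fit_gamma_poisson(counts, np.full(100, 1.0))
        assert fit.cv < 0.01
        assert fit.cv_ci[0] == 0.0

    def test_window_permutation_invariance(self, rng):
        counts = _nb_counts(rng, 400, 0.3, 10.0)
        offsets = rng.uniform(0.5, 2.0, 400)
        fit = fit_gamma_poisson(counts, offsets)
        perm = rng.permutation(400)
        fit2 = fit_gamma_poisson(counts[perm], offsets[perm])
        assert fit2.shape == pytest.approx(fit.shape, rel=1e-6)

    def test_errors(self):
        with pytest.raises(ValueError):
            fit_gamma_poisson([0, 0, 0], [1, 1, 1])
        with pytest.raises(ValueError):
            fit_gamma_poisson([1, 2], [1, np.inf])
        with pytest.raises(ValueError):
            fit_gamma_poisson([5], [1])

    def test_loglik_unimodal_in_log_shape(self, rng):
        """The shape profile rises then falls: a single interior maximum, so
        the 1-D bounded optimizer cannot be trapped."""
        from mutscape.rate_distribution import nb_loglik
        counts = _nb_counts(rng, 500, 0.25, 8.0)
        mean = counts.mean()
        ls = np.linspace(np.log(0.5), np.log(500), 60)
        ll = np.array([nb_loglik(counts, np.full(500, mean), np.exp(x)) for x in ls])
        increasing = np.diff(ll) > 0
        # sign changes of the first difference: exactly one (+ -> -)
        assert increasing[0] and not increasing[-1]
        assert np.count_nonzero(np.diff(increasing.astype(int))) == 1


class TestGoodnessOfFit:
    def test_type_one_calibration(self):
        """Data simulated from the fitted model is rejected ~5% of the time."""
        rng = np.random.default_rng(11)
        rejections = 0
        n_reps = 400
        for _ in range(n_reps):
            counts = _nb_counts(rng, 500, 0.25, 5.0)
            offsets = np.ones(500)
            fit = fit_gamma_poisson(counts, offsets)
            _, _, p = goodness_of_fit(fit, counts, offsets)
            rejections += p < 0.05
        assert rejections / n_reps == pytest.approx(0.05, abs=0.03)

    def test_power_against_mixture(self):
        """A 50:50 mixture of well-separated rates is decisively rejected."""
        rng = np.random.default_rng(12)
        lo = _nb_counts(rng, 1000, 0.05, 2.0)
        hi = _nb_counts(rng, 1000, 0.05, 20.0)
        counts = np.concatenate([lo, hi])
        offsets = np.ones(2000)
        fit = fit_gamma_poisson(counts, offsets)
        _, _, p = goodness_of_fit(fit, counts, offsets)
        assert p < 0.001

    def test_too_few_bins(self):
        counts = np.array([0, 0, 1, 0])
        fit = fit_gamma_poisson(counts, np.ones(4))
        with pytest.raises(ValueError):
            goodness_of_fit(fit, counts, np.ones(4))


class TestCvScaling:
    def test_iid_fine_scale_gives_minus_half(self):
        """Aggregating i.i.d. fine-scale gamma rates: log CV falls with log
        width at slope -0.5."""
        rng = np.random.default_rng(21)
        n_fine, width = 10_000, 10_000
        alpha = rng.gamma(4.0, 0.25, n_fine)          # CV 0.5
        counts = rng.poisson(alpha * 100.0)
        by_width = {}
        for m in (1, 10, 100):
            agg = counts.reshape(-1, m).sum(axis=1)
            by_width[width * m] = (agg, np.full(agg.size, float(width * m)))
        profile = cv_scaling(by_width)
        assert profile.slope == pytest.approx(-0.5, abs=0.05)

    def test_block_constant_rates_flatten_fine_scales(self):
        """Rates constant within 10x blocks: the two finest scales share one CV."""
        rng = np.random.default_rng(22)
        block = rng.gamma(4.0, 0.25, 1000)
        alpha = np.repeat(block, 10)
        counts = rng.poisson(alpha * 50.0)
        by_width = {}
        for m in (1, 10, 100):
            agg = counts.reshape(-1, m).sum(axis=1)
            by_width[m] = (agg, np.full(agg.size, float(m)))
        profile = cv_scaling(by_width)
        cv1, cv10, cv100 = profile.cvs
        assert cv1 == pytest.approx(cv10, rel=0.05)
        assert cv100 == pytest.approx(cv10 / np.sqrt(10), rel=0.10)

    def test_aggregation_closed_form(self, rng):
        """CV of the mean of m i.i.d. variables is CV/sqrt(m)."""
        x = rng.gamma(4.0, 0.25, 100_000)
        m = 100
        agg = x.reshape(-1, m).mean(axis=1)
        assert agg.std() / agg.mean() == pytest.approx(
            (x.std() / x.mean()) / np.sqrt(m), rel=0.05)

    def test_needs_three_widths(self):
        with pytest.raises(ValueError):
            cv_scaling({1: ([1, 2], [1, 1]), 10: ([3, 4], [1, 1])})


class TestNestedScaleAnova:
    def test_type_one_calibration(self):
        """i.i.d. fine rates: ~5% rejection at alpha = 0.05."""
        rng = np.random.default_rng(31)
        rejections = 0
        n_reps = 400
        for _ in range(n_reps):
            counts = rng.poisson(20.0, 200)
            group = np.repeat(np.arange(20), 10)
            _, p = nested_scale_anova(counts, np.ones(200), group)
            rejections += p < 0.05
        assert rejections / n_reps == pytest.approx(0.05, abs=0.03)

    def test_power_with_coarse_variation(self):
        """Coarse-level multipliers with sd 0.3 are detected essentially always."""
        rng = np.random.default_rng(32)
        significant = 0
        n_reps = 50
        for _ in range(n_reps):
            coarse = rng.normal(1.0, 0.3, 20).clip(0.1)
            alpha = np.repeat(coarse, 10)
            counts = rng.poisson(alpha * 20.0)
            _, p = nested_scale_anova(counts, np.ones(200), np.repeat(np.arange(20), 10))
            significant += p < 0.001
        assert significant / n_reps >= 0.95

    def test_identical_rates_give_zero_f(self):
        f, p = nested_scale_anova([5, 5, 5, 5], [1, 1, 1, 1], [0, 0, 1, 1])
        assert f == 0.0

    def test_single_group_errors(self):
        with pytest.raises(ValueError):
            nested_scale_anova([1, 2, 3], [1, 1, 1], [0, 0, 0])
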