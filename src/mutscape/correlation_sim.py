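"""Monte-Carlo expected correlations under sampling error.

Observed correlations between windowed mutation densities are attenuated
by Poisson sampling noise: with a few dozen DNMs per megabase even a
perfectly shared underlying rate yields a weak correlation.  These
procedures compute the correlation *expected* under an explicit shared-
rate model so the observed value can be compared against it rather than
against 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .rate_distribution import RateDistFit, fit_gamma_poisson


@dataclass
class ExpectedCorrelation:
    observed_r: float
    expected_r_mean: float
    expected_r_sims: np.ndarray = field(repr=False)
    p_below: float          # fraction of sims with simulated r < observed
    n_sims: int
    seed: int | None

    @property
    def p_above(self) -> float:
        """Proportion of simulated correlations greater than the observed."""
        return 1.0 - self.p_below


def _pearson_rows(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r between each row of x and the matching row (or vector) y."""
    x = x - x.mean(axis=1, keepdims=True)
    y = np.atleast_2d(y)
    y = y - y.mean(axis=1, keepdims=True)
    num = (x * y).sum(axis=1)
    den = np.sqrt((x ** 2).sum(axis=1) * (y ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / den
    # a zero-variance vector carries no linear association
    return np.where(den == 0, 0.0, r)


def _pearson(x, y) -> float:
    x = np.asarray(x, dtype=float)
    return float(_pearson_rows(x[None, :], np.asarray(y, dtype=float)[None, :])[0])


def _finish(observed_r: float, r_sims: np.ndarray, seed) -> ExpectedCorrelation:
    r_sims = r_sims[np.isfinite(r_sims)]
    p_below = float(np.mean(r_sims < observed_r)) if np.isfinite(observed_r) else float("nan")
    return ExpectedCorrelation(
        observed_r=float(observed_r), expected_r_mean=float(r_sims.mean()),
        expected_r_sims=r_sims, p_below=p_below, n_sims=int(r_sims.size), seed=seed)


def simulate_common_distribution(counts_a, offsets_a, counts_b, offsets_b,
                                 n_sims: int = 100, seed: int | None = None,
                                 shared_cv: float | None = None) -> ExpectedCorrelation:
    """Expected correlation between two mutation categories sharing one
    gamma rate distribution and perfectly correlated rates.

    The shared CV is the mean of the CVs fitted to the two categories
    independently (overridable).  Each simulation draws one gamma
    multiplier per window and two Poisson counts scaled so each
    category's expected total equals its observed total; the Pearson
    correlation is computed between per-site densities.
    """
    counts_a = np.asarray(counts_a, dtype=float)
    counts_b = np.asarray(counts_b, dtype=float)
    offsets_a = np.asarray(offsets_a, dtype=float)
    offsets_b = np.asarray(offsets_b, dtype=float)
    if counts_a.size != counts_b.size:
        raise ValueError("categories must share the same windows")
    if counts_a.sum() < 1 or counts_b.sum() < 1:
        raise ValueError("zero total count in a category")
    if shared_cv is None:
        cv_a = fit_gamma_poisson(counts_a, offsets_a).cv
        cv_b = fit_gamma_poisson(counts_b, offsets_b).cv
        shared_cv = 0.5 * (cv_a + cv_b)
    rng = np.random.default_rng(seed)
    n = counts_a.size
    mu_a = counts_a.sum() / offsets_a.sum() * offsets_a
    mu_b = counts_b.sum() / offsets_b.sum() * offsets_b
    if shared_cv > 0:
        shape = 1.0 / shared_cv ** 2
        alpha = rng.gamma(shape, 1.0 / shape, size=(n_sims, n))
    else:
        alpha = np.ones((n_sims, n))
    sim_a = rng.poisson(alpha * mu_a)
    sim_b = rng.poisson(alpha * mu_b)
    r_sims = _pearson_rows(sim_a / offsets_a, sim_b / offsets_b)
    observed_r = _pearson(counts_a / offsets_a, counts_b / offsets_b)
    return _finish(observed_r, r_sims, seed)


def expected_correlation_given_rates(reference_counts, offsets, n_dnms_total: int,
                                     n_sims: int = 1000, seed: int | None = None,
                                     observed_counts=None) -> ExpectedCorrelation:
    """Correlation expected between DNM density and a reference rate
    (substitutions or SNPs) if the reference were a perfect, error-free
    measure of the mutation rate.

    DNMs are generated with per-window expectation proportional to the
    reference count, normalised so the expected total equals
    ``n_dnms_total``; each simulation's density is correlated against the
    reference per-site rate.
    """
    reference_counts = np.asarray(reference_counts, dtype=float)
    offsets = np.asarray(offsets, dtype=float)
    if reference_counts.sum() <= 0:
        raise ValueError("reference counts sum to zero")
    if n_dnms_total <= 0:
        raise ValueError("n_dnms_total must be positive")
    rng = np.random.default_rng(seed)
    expectation = n_dnms_total * reference_counts / reference_counts.sum()
    sims = rng.poisson(expectation, size=(n_sims, reference_counts.size))
    ref_rate = reference_counts / offsets
    r_sims = _pearson_rows(sims / offsets, ref_rate)
    observed_r = (_pearson(np.asarray(observed_counts, dtype=float) / offsets, ref_rate)
                  if observed_counts is not None else float("nan"))
    return _finish(observed_r, r_sims, seed)


def explainable_variance_ceiling(fit: RateDistFit, offsets, n_dnms_total: int,
                                 n_sims: int = 1000, seed: int | None = None) -> np.ndarray:
    """Distribution of r^2 between observed DNM density and the *true*
    rate when the truth is drawn from the fitted gamma distribution.

    This is the ceiling on the variance any set of genomic predictors
    could explain, given the sampling error in the DNM counts.  Returns
    the per-simulation r^2 values.
    """
    offsets = np.asarray(offsets, dtype=float)
    if fit.cv <= 0:
        warnings.warn("cv = 0: no rate variation, explainable variance is 0")
        return np.zeros(n_sims)
    rng = np.random.default_rng(seed)
    shape = fit.shape
    alpha = rng.gamma(shape, 1.0 / shape, size=(n_sims, offsets.size))
    expectation = alpha * offsets * (n_dnms_total / offsets.sum())
    sims = rng.poisson(expectation)
    r = _pearson_rows(sims / offsets, alpha)
    return r ** 2


def simulate_under_rate_model(predicted_rate_per_window, offsets, n_dnms_total: int,
                              n_sims: int = 1000, seed: int | None = None,
                              observed_counts=None) -> ExpectedCorrelation:
    """Expected DNM-density correlation under an external per-window rate
    model (e.g. a 7-mer model or a mutability-index model aggregated per
    window).

    The per-window expectation is predicted_rate x offset, normalised to
    ``n_dnms_total``; the simulated densities are correlated against the
    predicted rate.  Comparing ``observed_r`` with the simulated spread
    evaluates whether the model captures the real rate variation.
    """
    predicted = np.asarray(predicted_rate_per_window, dtype=float)
    offsets = np.asarray(offsets, dtype=float)
    if np.any(predicted < 0) or not np.any(predicted > 0):
        raise ValueError("predicted rates must be nonnegative and not all zero")
    if n_dnms_total <= 0:
        raise ValueError("n_dnms_total must be positive")
    rng = np.random.default_rng(seed)
    weight = predicted * offsets
    expectation = n_dnms_total * weight / weight.sum()
    sims = rng.poisson(expectation, size=(n_sims, predicted.size))
    r_sims = _pearson_rows(sims / offsets, predicted)
    observed_r = (_pearson(np.asarray(observed_counts, dtype=float) / offsets, predicted)
                  if observed_counts is not None else float("nan"))
    return _finish(observed_r, r_sims, seed)
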