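"""Equilibrium GC content: the S>W fraction, the mixture likelihood, the
spectrum estimator, the sequence-evolution simulator, and MI calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mutscape.gc_equilibrium import (MutationSpectrum, SWWindowSummary,
                                     _EqLikelihood, estimate_spectrum,
                                     evolve_to_equilibrium,
                                     expected_sw_fraction, fit_gc_equilibrium,
                                     mi_calibration, summarize_sw)
from mutscape.synthetic_data import SyntheticConfig, default_spectrum, generate_study
from mutscape.windows_io import CATEGORIES, GenomeWindow, WindowCountMatrix


def _simulate_summaries(rng, n_windows, fe_mean, fe_sd, mean_n=50):
    f = np.clip(rng.normal(0.41, 0.05, n_windows), 0.2, 0.7)
    fe = (np.clip(rng.normal(fe_mean, fe_sd, n_windows), 0.01, 0.99)
          if fe_sd > 0 else np.full(n_windows, fe_mean))
    x = f * (1 - fe) / (f * (1 - fe) + (1 - f) * fe)
    n = rng.poisson(mean_n, n_windows) + 1
    i = rng.binomial(n, x)
    return [SWWindowSummary(int(a), int(b), float(c)) for a, b, c in zip(i, n, f)]


class TestExpectedSwFraction:
    def test_identities(self):
        """x(0.5, fe) = 1 - fe; x(f, 0.5) = f; x(f, f) = 0.5 exactly."""
        for fe in (0.1, 0.32, 0.9):
            assert expected_sw_fraction(0.5, fe) == pytest.approx(1 - fe, abs=1e-15)
        for f in (0.2, 0.41, 0.8):
            assert expected_sw_fraction(f, 0.5) == pytest.approx(f, abs=1e-15)
        for v in (0.1, 0.32, 0.77):
            assert expected_sw_fraction(v, v) == pytest.approx(0.5, abs=1e-15)

    def test_monotone_grid(self):
        """x decreases in fe and increases in f on the open unit square."""
        grid = np.linspace(0.05, 0.95, 19)
        for f in grid:
            vals = [expected_sw_fraction(f, fe) for fe in grid]
            assert np.all(np.diff(vals) < 0)
        for fe in grid:
            vals = [expected_sw_fraction(f, fe) for f in grid]
            assert np.all(np.diff(vals) > 0)

    def test_boundaries_error(self):
        for f, fe in [(0.0, 0.3), (1.0, 0.3), (0.3, 0.0), (0.3, 1.0)]:
            with pytest.raises(ValueError):
                expected_sw_fraction(f, fe)


class TestMixtureLikelihood:
    def test_sigma_zero_equals_binomial(self, rng):
        """At sigma -> 0 the mixture collapses onto the plain binomial."""
        summ = _simulate_summaries(rng, 50, 0.32, 0.0)
        ll = _EqLikelihood([s.i for s in summ], [s.n for s in summ],
                           [s.f for s in summ], n_nodes=200)
        i = np.array([s.i for s in summ])
        n = np.array([s.n for s in summ])
        f = np.array([s.f for s in summ])
        fe = 0.32
        x = f * (1 - fe) / (f * (1 - fe) + (1 - f) * fe)
        binom = stats.binom.logpmf(i, n, x).sum()
        assert ll(fe, 1e-8) == pytest.approx(binom, rel=1e-6)

    def test_quadrature_node_doubling_stable(self, rng):
        summ = _simulate_summaries(rng, 100, 0.32, 0.05)
        args = ([s.i for s in summ], [s.n for s in summ], [s.f for s in summ])
        ll200 = _EqLikelihood(*args, n_nodes=200)
        ll400 = _EqLikelihood(*args, n_nodes=400)
        for theta in [(0.32, 0.05), (0.25, 0.1), (0.4, 0.02)]:
            assert ll200(*theta) == pytest.approx(ll400(*theta), abs=1e-6)


class TestFitGcEquilibrium:
    def test_inversion_at_half_gc(self):
        """Windows at f = 0.5 with i/n = 0.68: the mean equilibrium GC is
        the Eq-1 inversion 0.32, and no dispersion is needed."""
        summ = [SWWindowSummary(680, 1000, 0.5)] * 30
        fit = fit_gc_equilibrium(summ, n_nodes=64)
        assert fit.mean_fe == pytest.approx(0.32, abs=0.005)
        assert fit.cis["sigma_fe"][0] == 0.0

    def test_recovery_no_dispersion(self, rng):
        summ = _simulate_summaries(rng, 400, 0.32, 0.0)
        fit = fit_gc_equilibrium(summ, n_nodes=64)
        assert fit.mean_fe == pytest.approx(0.32, abs=0.01)
        assert fit.cis["sigma_fe"][0] == 0.0
        assert fit.cis["mean_fe"][0] <= 0.32 <= fit.cis["mean_fe"][1]

    def test_recovery_with_dispersion(self, rng):
        summ = _simulate_summaries(rng, 600, 0.32, 0.05)
        fit = fit_gc_equilibrium(summ, n_nodes=64)
        assert fit.mean_fe == pytest.approx(0.32, abs=0.015)
        assert fit.sigma_fe == pytest.approx(0.05, abs=0.02)
        assert fit.cis["sigma_fe"][0] > 0.0

    def test_errors(self):
        with pytest.raises(ValueError):
            fit_gc_equilibrium([SWWindowSummary(0, 0, 0.4)])


class TestEstimateSpectrum:
    def test_single_bin_equals_pooled_rates(self, small_study):
        matrix = small_study.dnm_counts
        spectra = estimate_spectrum(matrix, [0.0, 1.0])
        assert len(spectra) == 1
        spec = next(iter(spectra.values()))
        for cat in CATEGORIES:
            pooled = matrix.counts[cat].sum() / matrix.offsets(cat).sum()
            assert spec.rate(cat) == pytest.approx(pooled, rel=1e-12)

    def test_bin_without_cpg_sites_reports_nan(self):
        w = GenomeWindow("chr1", 0, 100, n_sites=100, n_cpg_sites=0,
                         n_strong_noncpg=50, n_weak=50, gc_content=0.5)
        counts = pd.DataFrame(np.zeros((1, 9), dtype=int), columns=list(CATEGORIES))
        counts.loc[0, "C>T"] = 3
        matrix = WindowCountMatrix(windows=[w], counts=counts)
        spec = next(iter(estimate_spectrum(matrix, [0.0, 1.0]).values()))
        assert np.isnan(spec.rate("CpG_C>T"))
        assert spec.rate("C>T") == pytest.approx(3 / 50)

    def test_generator_spectrum_recovered(self, small_study):
        """Relative category rates match the generator's spectrum within
        counting error."""
        spec = next(iter(estimate_spectrum(
            small_study.dnm_counts, [0.0, 1.0]).values()))
        truth = small_study.config.spectrum_truth
        est = np.array([spec.rate(c) for c in CATEGORIES])
        tru = np.array([truth.rate(c) for c in CATEGORIES])
        est /= est.sum()
        tru /= tru.sum()
        assert np.all(np.abs(est - tru) < 0.05)
        # the CpG transition elevation survives estimation
        assert spec.rate("CpG_C>T") / spec.rate("C>T") > 5


class TestEvolveToEquilibrium:
    TWO_STATE = MutationSpectrum(rates={
        "CpG_C>T": 1.4, "CpG_C>A": 0.6, "CpG_C>G": 0.3,
        "C>T": 1.4, "C>A": 0.6, "C<>G": 0.3,
        "T>C": 0.7, "T>G": 0.3, "T<>A": 0.2})

    def test_two_state_closed_form(self):
        """CpG rates equal to non-CpG, S>W total 2 vs W>S total 1: GC 1/3."""
        eq, _ = evolve_to_equilibrium(self.TWO_STATE, 0.5, mode="deterministic")
        assert eq == pytest.approx(1 / 3, abs=0.005)
        eq_s, _ = evolve_to_equilibrium(self.TWO_STATE, 0.5, mode="stochastic", seed=5)
        assert eq_s == pytest.approx(1 / 3, abs=0.005)

    def test_symmetric_spectrum_gives_half(self):
        sym = MutationSpectrum(rates={
            "CpG_C>T": 1.0, "CpG_C>A": 0.5, "CpG_C>G": 0.3,
            "C>T": 1.0, "C>A": 0.5, "C<>G": 0.3,
            "T>C": 1.0, "T>G": 0.5, "T<>A": 0.3})
        eq, _ = evolve_to_equilibrium(sym, 0.3, mode="deterministic")
        assert eq == pytest.approx(0.5, abs=0.005)

    def test_modes_agree_with_cpg_elevation(self):
        """Dinucleotide integration and sequence simulation agree within
        0.01 GC on the CpG-elevated default spectrum."""
        spec = default_spectrum()
        det, _ = evolve_to_equilibrium(spec, 0.41, mode="deterministic")
        sto, _ = evolve_to_equilibrium(spec, 0.41, mode="stochastic", seed=6)
        assert abs(det - sto) < 0.01

    def test_end_to_end_generator_oracle(self, small_study):
        """The spectrum estimated from synthetic DNMs evolves to the
        generator's configured equilibrium GC."""
        spec = next(iter(estimate_spectrum(
            small_study.dnm_counts, [0.0, 1.0]).values()))
        eq, _ = evolve_to_equilibrium(spec, 0.41, mode="deterministic")
        assert eq == pytest.approx(small_study.config.fe_mean, abs=0.02)

    def test_trajectory_starts_at_init(self):
        eq, traj = evolve_to_equilibrium(self.TWO_STATE, 0.5, mode="deterministic")
        assert traj[0] == pytest.approx(0.5, abs=1e-12)


class TestMiCalibration:
    def test_two_bins_exact_line(self):
        """With two bins the regression line passes through both points."""
        mi = np.array([10] * 1000 + [30] * 1000)
        dnm = np.zeros(2000, dtype=int)
        dnm[:20] = 1    # rate 0.02 at MI 10
        dnm[1000:1080] = 1  # rate 0.08 at MI 30
        intercept, slope, predict = mi_calibration(mi, dnm)
        assert predict(10) == pytest.approx(0.02, rel=1e-9)
        assert predict(30) == pytest.approx(0.08, rel=1e-9)

    def test_recovery_of_log_linear_rate(self, rng):
        """Sites with rate exp(-5 + 0.01 MI) recover the line within noise."""
        mi = rng.integers(0, 200, size=400_000)
        rate = np.exp(-5 + 0.01 * mi)
        dnm = rng.poisson(rate)
        intercept, slope, _ = mi_calibration(mi, dnm)
        assert intercept == pytest.approx(-5.0, abs=0.15)
        assert slope == pytest.approx(0.01, abs=0.002)

    def test_errors(self):
        with pytest.raises(ValueError):
            mi_calibration([5, 5, 5], [1, 0, 1])
        with pytest.raises(ValueError):
            mi_calibration([1, 2, 3], [0, 0, 0])


def test_summarize_sw_counts_classes(small_study):
    """i counts S>W events, n adds W>S, GC-conserving ones are excluded."""
    summ = summarize_sw(small_study.dnm_counts)
    counts = small_study.dnm_counts.counts
    sw = counts[["CpG_C>T", "CpG_C>A", "C>T", "C>A"]].sum(axis=1)
    ws = counts[["T>C", "T>G"]].sum(axis=1)
    assert [s.i for s in summ] == sw.tolist()
    assert [s.n for s in summ] == (sw + ws).tolist()
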