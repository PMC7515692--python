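"""KDE, peak finding, sum-of-Gaussians decomposition and peak areas."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from massphot.distribution import (
    find_peaks,
    fit_gaussian_mixture,
    initial_guesses,
    kde,
    peak_area,
)
from massphot.models import ContrastModel, GaussianPeak, KineticsModel, SpeciesDef
from massphot.simulate import simulate_event_stream


class TestKde:
    def test_normal_density_at_mode(self, rng):
        x = rng.normal(0.0, 1.0, 100_000)
        dens = kde(x, bandwidth=0.1)
        at_zero = np.interp(0.0, dens.grid, dens.density)
        assert at_zero == pytest.approx(1 / math.sqrt(2 * math.pi), rel=0.02)

    def test_density_normalized(self, rng):
        x = rng.exponential(2.0, 5000)
        dens = kde(x, bandwidth=0.3)
        assert np.trapezoid(dens.density, dens.grid) == pytest.approx(1.0, abs=1e-3)

    def test_two_separated_clusters_give_two_modes(self, rng):
        x = np.concatenate([rng.normal(-1, 0.01, 500), rng.normal(1, 0.01, 500)])
        dens = kde(x, bandwidth=0.05)
        assert len(find_peaks(dens, min_prominence=0.1)) == 2

    def test_fewer_than_two_events_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            kde([1.0], bandwidth=0.1)

    def test_grid_spans_data_with_margin(self, rng):
        x = rng.normal(5.0, 0.2, 1000)
        dens = kde(x, bandwidth=0.1)
        assert dens.grid[0] <= x.min() - 4 * 0.1 + 1e-12
        assert dens.grid[-1] >= x.max() + 4 * 0.1 - 1e-12
        assert dens.grid.size >= 512


class TestFindPeaks:
    def test_unimodal_gives_single_guess_at_mode(self, rng):
        x = rng.normal(0.005, 2e-4, 5000)
        dens = kde(x, bandwidth=1e-4)
        guesses = find_peaks(dens, min_prominence=0.05)
        assert len(guesses) == 1
        assert guesses[0][0] == pytest.approx(0.005, abs=1e-4)

    def test_six_species_ladder_gives_six_guesses(self, window):
        mixture = [
            SpeciesDef(f"{L}bp", L, "double", 1 / 6, 3000)
            for L in (100, 200, 400, 800, 1200, 2000)
        ]
        events = simulate_event_stream(
            mixture, ContrastModel(), KineticsModel(alpha=0.5), window, seed=4
        )
        dens = kde(events["contrast"].to_numpy(), bandwidth=2.1e-4)
        assert len(find_peaks(dens, min_prominence=0.02)) == 6

    def test_full_prominence_keeps_at_most_global_max(self, rng):
        x = np.concatenate([rng.normal(0, 0.05, 400), rng.normal(1, 0.05, 600)])
        dens = kde(x, bandwidth=0.05)
        assert len(find_peaks(dens, min_prominence=1.0)) <= 1

    def test_forced_component_count(self, rng):
        x = np.concatenate([rng.normal(0, 0.04, 3000), rng.normal(1, 0.04, 60)])
        dens = kde(x, bandwidth=0.04)
        guesses = initial_guesses(dens, n_components=2)
        assert len(guesses) == 2


class TestMixtureFit:
    def test_single_component_parameter_recovery(self, rng):
        mu, sigma, n = 0.005, 2e-4, 5000
        x = rng.normal(mu, sigma, n)
        bin_width = 2e-5
        fit = fit_gaussian_mixture(x, [(mu * 1.02, 1.0)], bin_width=bin_width)
        assert len(fit.peaks) == 1
        peak = fit.peaks[0]
        assert peak.mu == pytest.approx(mu, abs=3 * sigma / math.sqrt(n))
        # count-density convention: total area ~= n_events * bin_width
        assert peak.area == pytest.approx(n * bin_width, rel=0.05)

    def test_two_equal_components_have_equal_areas(self, rng):
        x = np.concatenate([rng.normal(0.002, 3e-4, 5000), rng.normal(0.010, 3e-4, 5000)])
        fit = fit_gaussian_mixture(x, [(0.002, 1.0), (0.010, 1.0)], bin_width=1e-4)
        a1, a2 = fit.peaks[0].area, fit.peaks[1].area
        assert a1 / a2 == pytest.approx(1.0, abs=0.1)

    def test_peaks_sorted_by_centroid(self, rng):
        x = np.concatenate([rng.normal(0.01, 3e-4, 3000), rng.normal(0.002, 3e-4, 3000)])
        fit = fit_gaussian_mixture(x, [(0.01, 1.0), (0.002, 1.0)], bin_width=1e-4)
        mus = [p.mu for p in fit.peaks]
        assert mus == sorted(mus)

    def test_underparameterized_fit_reports_large_residual(self, rng):
        x = np.concatenate([rng.normal(0.002, 2e-4, 4000), rng.normal(0.010, 2e-4, 4000)])
        under = fit_gaussian_mixture(x, [(0.006, 1.0)], bin_width=1e-4)
        full = fit_gaussian_mixture(x, [(0.002, 1.0), (0.010, 1.0)], bin_width=1e-4)
        assert len(under.peaks) == 1
        assert under.residual_rms > 3 * full.residual_rms

    def test_kde_target_matches_histogram_convention(self, rng):
        x = rng.normal(0.005, 3e-4, 8000)
        bin_width = 5e-5
        hist_fit = fit_gaussian_mixture(x, [(0.005, 1.0)], bin_width=bin_width)
        kde_fit = fit_gaussian_mixture(
            x, [(0.005, 1.0)], bin_width=bin_width, target="kde", bandwidth=5e-5
        )
        assert kde_fit.peaks[0].area == pytest.approx(hist_fit.peaks[0].area, rel=0.05)

    def test_too_few_events_rejected(self, rng):
        with pytest.raises(ValueError, match=">= 50"):
            fit_gaussian_mixture(rng.normal(size=10), [(0.0, 1.0)])

    def test_area_sum_matches_event_count_on_ladder(self, window):
        cm = ContrastModel()
        mixture = [
            SpeciesDef(f"{L}bp", L, "double", 0.25, 4000) for L in (200, 400, 800, 1200)
        ]
        events = simulate_event_stream(mixture, cm, KineticsModel(alpha=0.5), window, seed=6)
        x = events["contrast"].to_numpy()
        bin_width = cm.contrast_sd(200) / 4
        dens = kde(x, bandwidth=2.1e-4)
        fit = fit_gaussian_mixture(x, initial_guesses(dens, n_components=4), bin_width=bin_width)
        assert fit.total_area == pytest.approx(len(x) * bin_width, rel=0.05)

    def test_ladder_peak_means_recovered(self, window):
        # peak means within 0.5% of kappa * length across seeds; species are
        # sized for >= 3000 in-window events each so the sampling error of a
        # peak mean stays well inside the bound
        cm = ContrastModel()
        kin = KineticsModel(alpha=0.5)
        lengths = (100, 200, 400, 800, 1200, 2000)
        mixture = [
            SpeciesDef(
                f"{L}bp", L, "double", 1 / 6,
                int(np.ceil(3000 / window.observed_fraction(kin.rate(L)))),
            )
            for L in lengths
        ]
        bin_width = cm.contrast_sd(100) / 4
        for seed in range(10):
            events = simulate_event_stream(
                mixture, cm, KineticsModel(alpha=0.5), window, seed=seed
            )
            x = events["contrast"].to_numpy()
            dens = kde(x, bandwidth=2.1e-4)
            fit = fit_gaussian_mixture(
                x, initial_guesses(dens, n_components=6), bin_width=bin_width
            )
            for peak, L in zip(fit.peaks, lengths):
                assert peak.mu == pytest.approx(cm.kappa * L, rel=0.005)


class TestPeakArea:
    def test_unit_gaussian_closed_form(self):
        assert peak_area(GaussianPeak(A=1.0, mu=0.0, sigma=1.0)) == pytest.approx(
            math.sqrt(2 * math.pi), rel=1e-12
        )

    def test_narrow_peak_value(self):
        assert peak_area(GaussianPeak(A=50.0, mu=0.0, sigma=2e-4)) == pytest.approx(
            0.0250663, rel=1e-5
        )

    def test_zero_amplitude(self):
        assert peak_area(GaussianPeak(A=0.0, mu=1.0, sigma=1.0)) == 0.0

    @pytest.mark.parametrize("A,mu,sigma", [(1.0, 0.0, 1.0), (50.0, 5e-3, 2e-4), (7.3, -2.0, 0.37)])
    def test_matches_numerical_quadrature(self, A, mu, sigma):
        peak = GaussianPeak(A=A, mu=mu, sigma=sigma)
        numeric, _ = quad(
            lambda x: A * math.exp(-0.5 * ((x - mu) / sigma) ** 2),
            mu - 12 * sigma,
            mu + 12 * sigma,
        )
        assert peak_area(peak) == pytest.approx(numeric, rel=1e-6)

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ValueError):
            GaussianPeak(A=1.0, mu=0.0, sigma=0.0)
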