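"""Binding-rate estimation and the diffusion correction."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from massphot.kinetics import (
    correct_abundances,
    diffusion_correction,
    fit_binding_rate,
    mean_length,
    mole_fractions,
    scaling_alpha,
    species_rate,
)
from massphot.models import AbundanceEstimate, AcquisitionWindow, KineticsModel


def _truncated_exponential(rng, k, window, n):
    """Inverse-CDF sampling of an exponential truncated to the window."""
    u = rng.uniform(size=n)
    c0 = math.exp(-k * window.t0)
    c1 = math.exp(-k * window.t_final)
    return -np.log(c0 - u * (c0 - c1)) / k


class TestRateFit:
    def test_parameter_recovery(self, window, rng):
        k_true = 0.02
        times = _truncated_exponential(rng, k_true, window, 5000)
        fit = fit_binding_rate(times, window)
        assert abs(fit.k - k_true) < 3 * fit.stderr
        assert fit.stderr < 0.15 * k_true

    def test_matches_grid_search_likelihood_oracle(self, window, rng):
        times = _truncated_exponential(rng, 0.01, window, 2000)
        fit = fit_binding_rate(times, window)
        grid = np.linspace(1e-4, 0.05, 4000)
        L = window.duration
        u = times - window.t0

        def loglik(k):
            return len(u) * (math.log(k) - math.log1p(-math.exp(-k * L))) - k * u.sum()

        best = grid[np.argmax([loglik(k) for k in grid])]
        assert fit.k == pytest.approx(best, abs=2 * (grid[1] - grid[0]))

    def test_uniform_arrivals_flagged_nondepleting(self, window, rng):
        times = rng.uniform(window.t0, window.t_final, 500)
        # force the sample mean past the midpoint so the flat limit triggers
        times = window.t0 + (window.t_final - window.t0) * np.sort(
            np.clip((times - window.t0) / window.duration * 1.02, 0, 1)
        )
        fit = fit_binding_rate(times, window)
        if fit.nondepleting:
            assert fit.k == 0.0
        else:  # a barely-depleting draw is acceptable but must be tiny
            assert fit.k < 5e-3

    def test_too_few_events_rejected(self, window):
        with pytest.raises(ValueError, match=">= 50"):
            fit_binding_rate(np.linspace(20, 100, 20), window)

    def test_identical_times_rejected(self, window):
        with pytest.raises(ValueError, match="equal"):
            fit_binding_rate(np.full(100, 60.0), window)

    def test_times_outside_window_rejected(self, window):
        with pytest.raises(ValueError, match="window"):
            fit_binding_rate(np.linspace(1, 100, 100), window)


class TestMeanLength:
    def test_weighted_equal_abundances(self):
        assert mean_length([100, 300], [1.0, 1.0]) == pytest.approx(200.0)

    def test_weighted_unequal(self):
        assert mean_length([100, 300], [3.0, 1.0]) == pytest.approx(150.0)

    def test_literal_mode_divides_by_species_count(self):
        # with fractional abundances the printed /N convention gives
        # weighted/N, which is not a mean; it is kept behind a flag
        assert mean_length([100, 300], [0.75, 0.25], mode="literal") == pytest.approx(75.0)

    def test_effective_mode_is_power_mean(self):
        beta = -0.72
        lengths, a = np.array([200.0, 1200.0]), np.array([2.0, 1.0])
        expected = (np.sum(a * lengths**beta) / a.sum()) ** (1 / beta)
        got = mean_length(lengths, a, mode="effective", beta=beta)
        assert got == pytest.approx(expected, rel=1e-12)
        # power mean of a negative order lies below the arithmetic mean
        assert got < mean_length(lengths, a)

    def test_all_zero_abundances_rejected(self):
        with pytest.raises(ValueError):
            mean_length([100, 300], [0.0, 0.0])


class TestScalingLaw:
    def test_alpha_direct_evaluation(self):
        assert scaling_alpha(0.02, 200.0) == pytest.approx(0.02 * 200**0.72, rel=1e-12)
        assert scaling_alpha(0.02, 200.0) == pytest.approx(0.907, rel=1e-3)

    def test_alpha_degenerate_cases(self):
        assert scaling_alpha(0.02, 200.0, beta=0.0) == pytest.approx(0.02)
        assert scaling_alpha(0.02, 1.0) == pytest.approx(0.02)

    def test_species_rate_values(self):
        assert species_rate(1.0, 1) == pytest.approx(1.0)
        assert species_rate(0.5, 100) == pytest.approx(0.018155, rel=1e-3)

    def test_doubling_length_scales_rate_by_2_to_beta(self):
        ratio = species_rate(0.5, 800) / species_rate(0.5, 400)
        assert ratio == pytest.approx(2 ** -0.72, rel=1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            scaling_alpha(0.0, 100.0)
        with pytest.raises(ValueError):
            species_rate(0.5, 0)

    def test_kinetics_model_consistency_enforced(self):
        KineticsModel.from_average_rate(0.02, 200.0)  # consistent by construction
        with pytest.raises(ValueError, match="inconsistent"):
            KineticsModel(alpha=1.0, k=0.02, mean_length=200.0)


class TestDiffusionCorrection:
    def test_full_observation_needs_no_correction(self):
        window = AcquisitionWindow(t0=0.0, t_final=1e7)
        assert diffusion_correction(100.0, 0.01, window) == pytest.approx(100.0, rel=1e-9)

    @pytest.mark.parametrize(
        "k,expected", [(0.01, 166.26), (0.05, 212.23)],
    )
    def test_window_correction_values(self, window, k, expected):
        assert diffusion_correction(100.0, k, window) == pytest.approx(expected, abs=0.01)

    def test_matches_observed_fraction_integral_oracle(self, window):
        # correction factor == 1 / integral of k e^{-kt} over the window
        for k in np.logspace(-4, 0, 25):
            observed, _ = quad(lambda t: k * math.exp(-k * t), window.t0, window.t_final)
            assert diffusion_correction(1.0, k, window) == pytest.approx(
                1.0 / observed, rel=1e-9
            )

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        k=st.floats(1e-6, 1.0),
        t0=st.floats(0.0, 100.0),
        span=st.floats(1e-3, 1e4),
    )
    def test_factor_never_below_one(self, k, t0, span):
        window = AcquisitionWindow(t0=t0, t_final=t0 + span)
        assert diffusion_correction(1.0, k, window) >= 1.0

    def test_longer_movies_shrink_the_factor(self):
        k = 0.01
        factors = [
            diffusion_correction(1.0, k, AcquisitionWindow(15.0, tf))
            for tf in (60.0, 135.0, 600.0, 6000.0)
        ]
        assert factors == sorted(factors, reverse=True)
        assert factors[-1] == pytest.approx(math.exp(k * 15.0), rel=1e-6)

    def test_nonpositive_rate_rejected(self, window):
        with pytest.raises(ValueError):
            diffusion_correction(1.0, 0.0, window)


class TestMoleFractions:
    @staticmethod
    def _estimates(areas):
        return [
            AbundanceEstimate(label=str(i), length=100, raw_area=a, k_i=0.01, corrected_area=a)
            for i, a in enumerate(areas)
        ]

    def test_equal_areas_give_equal_fractions(self):
        ests = mole_fractions(self._estimates([2.0] * 6))
        assert all(e.mole_fraction == pytest.approx(1 / 6) for e in ests)

    def test_three_to_one(self):
        ests = mole_fractions(self._estimates([3.0, 1.0]))
        assert [e.mole_fraction for e in ests] == pytest.approx([0.75, 0.25])

    def test_fractions_sum_to_one(self, rng):
        ests = mole_fractions(self._estimates(rng.uniform(0.1, 5.0, 9).tolist()))
        assert sum(e.mole_fraction for e in ests) == pytest.approx(1.0, abs=1e-9)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            mole_fractions(self._estimates([0.0, 0.0]))


class TestCorrectAbundances:
    def test_corrected_never_below_raw(self, window, rng):
        times = _truncated_exponential(rng, 0.01, window, 500)
        estimates, model = correct_abundances(
            ["a", "b"], [200, 1200], [300.0, 200.0], times, window
        )
        for est in estimates:
            assert est.corrected_area >= est.raw_area
        assert model.alpha == pytest.approx(
            model.k / model.mean_length**model.beta, rel=1e-9
        )

    def test_nondepleting_times_raise(self, window, rng):
        times = np.linspace(window.t0, window.t_final, 200)
        with pytest.raises(ValueError, match="depletion"):
            correct_abundances(["a"], [200], [100.0], times, window)
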