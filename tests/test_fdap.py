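"""Reaction-diffusion FDAP model: forward solver, limits, and fitting."""

import numpy as np
import pytest

from axonmt import fdap
from axonmt.fdap import (
    FDAPCurve,
    ReactionDiffusionParams,
    SimulationGrid,
    bound_fraction,
    crank_nicolson_reference,
    fit_effective_diffusion,
    fit_reaction_diffusion,
    pure_diffusion_fdap,
    simulate_fdap,
    simulate_fdap_profiles,
)


def heat_kernel_box_survival(D, L, t, n=200_001):
    """Brute-force oracle: window-average survival of a box initial profile.

    Convolves the box [-L/2, L/2] with the 1D heat kernel and integrates the
    result over the window: F(t) = (1/L) * int (L - |u|) G(u, t) du over
    [-L, L], by fine-grid trapezoidal quadrature.
    """
    if t == 0:
        return 1.0
    u = np.linspace(-L, L, n)
    kernel = np.exp(-(u**2) / (4 * D * t)) / np.sqrt(4 * np.pi * D * t)
    return float(np.trapezoid((L - np.abs(u)) * kernel, u) / L)


class TestPureDiffusionClosedForm:
    def test_matches_heat_kernel_convolution_oracle(self):
        # the closed form itself is verified against brute-force convolution
        for D, L, t in [(3.0, 6.0, 3.0), (3.0, 6.0, 30.0), (0.5, 6.0, 10.0), (10.0, 4.0, 1.0)]:
            assert pure_diffusion_fdap(D, L, t) == pytest.approx(
                heat_kernel_box_survival(D, L, t), abs=1e-6
            )

    def test_no_decay_at_activation(self):
        assert pure_diffusion_fdap(3.0, 6.0, 0.0) == 1.0

    def test_infinite_diffusion_limit(self):
        assert pure_diffusion_fdap(1e9, 6.0, 1.0) < 1e-3

    def test_monotone_in_time_and_diffusion(self):
        t = np.linspace(0.0, 111.0, 112)
        values = pure_diffusion_fdap(3.0, 6.0, t)
        assert np.all(np.diff(values) < 0)
        assert np.all((values >= 0) & (values <= 1))
        faster = pure_diffusion_fdap(6.0, 6.0, t[1:])
        assert np.all(faster < values[1:])

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            pure_diffusion_fdap(3.0, 6.0, -1.0)
        with pytest.raises(ValueError):
            pure_diffusion_fdap(0.0, 6.0, 1.0)


class TestForwardModel:
    def test_all_bound_limit_is_constant(self):
        # k_off = 0 with equilibrium start puts all material in the immobile pool
        curve = simulate_fdap(ReactionDiffusionParams(3.0, 0.08, 0.0))
        assert len(curve.intensity) == 112
        np.testing.assert_allclose(curve.intensity, 1.0, atol=1e-12)

    def test_frozen_diffusion_limit_is_constant(self):
        curve = simulate_fdap(ReactionDiffusionParams(0.0, 0.05, 0.02))
        np.testing.assert_allclose(curve.intensity, 1.0)

    def test_pure_diffusion_limit_matches_closed_form(self):
        curve = simulate_fdap(ReactionDiffusionParams(3.0, 0.0, 0.05))
        closed = pure_diffusion_fdap(3.0, 6.0, curve.time_s)
        assert np.max(np.abs(curve.intensity - closed)) < 1e-3

    def test_intensity_starts_at_one_and_never_increases(self):
        curve = simulate_fdap(ReactionDiffusionParams(3.0, 0.07, 0.03))
        assert curve.intensity[0] == 1.0
        assert np.all(np.diff(curve.intensity) <= 1e-6)

    def test_mass_conserved_in_spectral_profiles(self):
        x, free, bound = simulate_fdap_profiles(
            ReactionDiffusionParams(3.0, 0.07, 0.03), times=[0.0, 5.0, 30.0, 111.0]
        )
        dx = x[1] - x[0]
        mass = (free + bound).sum(axis=1) * dx  # midpoint quadrature
        assert np.ptp(mass) / mass[0] < 1e-9

    def test_mass_conserved_in_finite_difference_reference(self):
        grid = SimulationGrid(domain_length_um=120.0, dx_um=0.1, dt_s=0.001)
        _, x, profiles = crank_nicolson_reference(
            ReactionDiffusionParams(3.0, 0.07, 0.03), grid, n_frames=8, return_profiles=True
        )
        dx = x[1] - x[0]
        mass = np.array([(f + b).sum() * dx for f, b in profiles])
        assert np.ptp(mass) / mass[0] < 1e-6

    def test_spectral_solver_agrees_with_finite_difference(self):
        params = ReactionDiffusionParams(3.0, 0.07, 0.03)
        grid = SimulationGrid(domain_length_um=120.0, dx_um=0.1, dt_s=0.001)
        reference = crank_nicolson_reference(params, grid, n_frames=15)
        spectral = simulate_fdap(params, n_frames=15)
        assert np.max(np.abs(reference.intensity - spectral.intensity)) < 2e-3

    def test_increasing_koff_never_raises_the_curve(self):
        for k_on in (0.02, 0.07, 0.2):
            previous = None
            for k_off in (0.01, 0.05, 0.2):
                curve = simulate_fdap(ReactionDiffusionParams(3.0, k_on, k_off), n_frames=60)
                if previous is not None:
                    assert np.all(curve.intensity <= previous + 1e-9)
                previous = curve.intensity

    def test_unstable_reference_configuration_is_named(self):
        grid = SimulationGrid(domain_length_um=120.0, dx_um=0.1, dt_s=0.05)
        with pytest.raises(ValueError, match="dt <= dx\\^2"):
            crank_nicolson_reference(ReactionDiffusionParams(3.0, 0.07, 0.03), grid)

    def test_negative_diffusion_rejected(self):
        with pytest.raises(ValueError):
            ReactionDiffusionParams(-1.0, 0.1, 0.1)


class TestBoundFraction:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(
        st.floats(min_value=0.0, max_value=100.0),
        st.floats(min_value=0.0, max_value=100.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_always_a_fraction(self, k_on, k_off):
        value = bound_fraction(k_on, k_off)
        assert 0.0 <= value <= 1.0

    @pytest.mark.parametrize(
        "k_on,k_off,expected",
        [(0.08, 0.02, 0.80), (0.0, 0.05, 0.0), (0.07, 0.03, 0.70), (0.0, 0.0, 0.0)],
    )
    def test_algebra(self, k_on, k_off, expected):
        assert bound_fraction(k_on, k_off) == pytest.approx(expected, abs=1e-12)

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            bound_fraction(-0.1, 0.1)


class TestKineticFit:
    @pytest.mark.parametrize("k_on,k_off", [(0.070, 0.030), (0.081, 0.019)])
    def test_noise_free_recovery(self, k_on, k_off):
        curve = simulate_fdap(ReactionDiffusionParams(3.0, k_on, k_off))
        fit = fit_reaction_diffusion(curve, D_fixed_um2_s=3.0)
        assert fit.converged
        assert fit.k_on_star_s == pytest.approx(k_on, rel=0.01)
        assert fit.k_off_s == pytest.approx(k_off, rel=0.01)
        assert fit.bound_fraction == pytest.approx(k_on / (k_on + k_off), abs=0.01)
        assert fit.bound_fraction == pytest.approx(
            bound_fraction(fit.k_on_star_s, fit.k_off_s), abs=1e-12
        )

    def test_constant_curve_reports_immobile_limit(self):
        curve = FDAPCurve(np.arange(112.0), np.ones(112))
        fit = fit_reaction_diffusion(curve, D_fixed_um2_s=3.0)
        assert fit.bound_fraction >= 0.99
        assert fit.at_bound

    def test_too_few_points_rejected(self):
        curve = FDAPCurve(np.arange(5.0), np.linspace(1, 0.8, 5))
        with pytest.raises(ValueError, match="10 time points"):
            fit_reaction_diffusion(curve, D_fixed_um2_s=3.0)

    def test_fast_exchange_flagged_as_unidentifiable(self):
        curve = simulate_fdap(ReactionDiffusionParams(3.0, 40.0, 10.0))
        fit = fit_reaction_diffusion(curve, D_fixed_um2_s=3.0)
        assert any("exchange-too-fast" in d for d in fit.diagnostics)


class TestEffectiveDiffusion:
    def test_pure_diffusion_recovers_d(self):
        curve = simulate_fdap(ReactionDiffusionParams(3.0, 0.0, 0.05))
        fit = fit_effective_diffusion(curve)
        assert fit.D_eff_um2_s == pytest.approx(3.0, rel=0.02)

    def test_fast_exchange_effective_diffusion(self):
        # classic limit: D_eff = D / (1 + k_on/k_off) = 3 / (1 + 4) = 0.6
        curve = simulate_fdap(ReactionDiffusionParams(3.0, 40.0, 10.0))
        fit = fit_effective_diffusion(curve)
        assert fit.D_eff_um2_s == pytest.approx(0.6, rel=0.10)

    def test_slow_exchange_poorly_fit_by_single_diffusion(self):
        fast = fit_effective_diffusion(simulate_fdap(ReactionDiffusionParams(3.0, 40.0, 10.0)))
        slow = fit_effective_diffusion(simulate_fdap(ReactionDiffusionParams(3.0, 0.004, 0.001)))
        assert slow.chi2 >= 10 * fast.chi2

    def test_non_decaying_curve_hits_lower_bound(self):
        curve = FDAPCurve(np.arange(112.0), np.ones(112))
        with pytest.warns(UserWarning, match="bound"):
            fit = fit_effective_diffusion(curve)
        assert fit.at_bound


class TestNoisyRecovery:
    def test_mean_bound_fraction_recovered_from_noisy_curves(self):
        # light version of the 20-curve battery in the acceptance suite
        from axonmt import synth

        curves, truth = synth.gen_fdap("h2o2", n_curves=6, noise_sd=0.02, seed=11)
        fits = [fit_reaction_diffusion(c, D_fixed_um2_s=3.0) for c in curves]
        mean_bf = np.mean([f.bound_fraction for f in fits])
        assert mean_bf == pytest.approx(truth["bound_fraction"].iloc[0], abs=0.03)
        assert sum(not f.converged for f in fits) <= 1
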