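"""Growth model, Arrhenius rate factors and fold-change laws."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from thermowire.errors import InvalidArgumentError
from thermowire.scaling import (
    DEFAULT_CONSTANTS,
    GrowthParams,
    ScalingParams,
    ThermalConstants,
    activation_energies,
    connectivity_fold_change,
    devtime_fold_change,
    rate_factor,
    relative_brain_stage,
    solve_growth,
    time_to_mass,
)

KT2 = 8.617e-5 * 273.0**2


class TestRateFactor:
    def test_unity_at_celsius_origin(self):
        assert rate_factor(0.0, 0.822, mode="linearized") == pytest.approx(1.0)
        assert rate_factor(0.0, 0.822, mode="exact") == pytest.approx(1.0)

    def test_linearized_closed_form_at_25(self):
        expected = np.exp(0.822 / KT2 * 25.0)
        assert rate_factor(25.0, 0.822) == pytest.approx(expected, rel=1e-12)

    def test_exact_vs_linearized_exponent_identity(self):
        # relative exponent difference at T is exactly 1 - 1/(1 + T/Ta) = T/(Ta+T)
        t = 32.0
        lin = np.log(rate_factor(t, 0.822, mode="linearized"))
        exact = np.log(rate_factor(t, 0.822, mode="exact"))
        assert (lin - exact) / lin == pytest.approx(t / (273.0 + t), rel=1e-12)
        assert (lin - exact) / lin == pytest.approx(0.105, abs=5e-4)

    def test_linearized_dominates_above_zero(self):
        temps = np.linspace(0.5, 32, 30)
        assert np.all(rate_factor(temps, 0.6) >= rate_factor(temps, 0.6, mode="exact"))

    def test_strictly_increasing_in_temperature(self):
        temps = np.linspace(-5, 35, 200)
        for mode in ("exact", "linearized"):
            vals = rate_factor(temps, 0.822, mode=mode)
            assert np.all(np.diff(vals) > 0)

    @pytest.mark.parametrize("bad", [np.nan, np.inf, 1 + 2j])
    def test_rejects_nonfinite_or_complex(self, bad):
        with pytest.raises(InvalidArgumentError):
            rate_factor(bad, 0.822)

    def test_rejects_nonpositive_activation_energy(self):
        with pytest.raises(InvalidArgumentError):
            rate_factor(25.0, -0.1)


class TestSolveGrowth:
    def test_matches_closed_form_sigmoid_across_study_range(self, growth_params):
        # (m/M)^(1/4) = 1 - exp(-a t / (4 M^(1/4))) for m0 = 0, z = 3/4
        for temp in [12.0, 18.0, 25.0, 31.0]:
            a = growth_params.base_rate * rate_factor(temp, growth_params.activation_energy)
            traj = solve_growth(growth_params, temp, t_end=5.0, n_steps=80)
            closed = (1.0 - np.exp(-a * traj.times / 4.0)) ** 4
            mask = closed > 0
            np.testing.assert_allclose(traj.masses[mask], closed[mask], rtol=1e-6)

    def test_small_mass_limit_is_quartic_in_time(self, growth_params):
        # m << M: integrating dm/dt = a m^(3/4) from 0 gives m = (a t / 4)^4
        a = growth_params.base_rate * rate_factor(25.0, growth_params.activation_energy)
        # saturation correction to the quartic is ~2*(a t/4); keep it < 1e-3
        t_end = 0.002 / a
        traj = solve_growth(growth_params, 25.0, t_end=t_end, n_steps=50)
        expected = (a * traj.times[1:] / 4.0) ** 4
        np.testing.assert_allclose(traj.masses[1:], expected, rtol=2e-3)

    def test_mass_monotone_and_bounded(self, growth_params):
        traj = solve_growth(growth_params, 31.0, t_end=50.0)
        assert np.all(np.diff(traj.masses) >= -1e-12)
        assert np.all(traj.masses < growth_params.asymptotic_mass + 1e-9)

    def test_long_time_limit_is_asymptotic_mass(self, growth_params):
        traj = solve_growth(growth_params, 25.0, t_end=2000.0)
        assert traj.masses[-1] == pytest.approx(growth_params.asymptotic_mass, rel=1e-6)

    def test_step_count_converged(self, growth_params):
        end_a = solve_growth(growth_params, 25.0, t_end=5.0, n_steps=200).masses[-1]
        end_b = solve_growth(growth_params, 25.0, t_end=5.0, n_steps=100).masses[-1]
        assert abs(end_a - end_b) / end_a < 1e-6

    def test_devtime_from_ode_reproduces_exponential_law(self, growth_params, fitted_scaling):
        # time to a fixed small target mass follows exp[-alpha (T - T0)]
        alpha_exact = growth_params.activation_energy / KT2
        scaling = ScalingParams(alpha=alpha_exact, beta=0.0)
        t0 = time_to_mass(growth_params, 25.0)
        for temp in np.linspace(12, 31, 8):
            ratio = time_to_mass(growth_params, float(temp)) / t0
            assert ratio == pytest.approx(devtime_fold_change(float(temp), scaling), rel=1e-4)

    def test_mass_unit_invariance_of_fold_change(self, growth_params):
        # rescaling the mass unit leaves developmental-time ratios unchanged
        scaled = GrowthParams(
            base_rate=growth_params.base_rate * 1000.0 ** 0.25,
            activation_energy=growth_params.activation_energy,
            asymptotic_mass=1000.0,
        )
        r1 = time_to_mass(growth_params, 18.0) / time_to_mass(growth_params, 25.0)
        r2 = time_to_mass(scaled, 18.0) / time_to_mass(scaled, 25.0)
        assert r1 == pytest.approx(r2, rel=1e-9)

    def test_invalid_params_rejected(self):
        with pytest.raises(InvalidArgumentError):
            GrowthParams(base_rate=1.0, activation_energy=0.8, asymptotic_mass=1.0,
                         initial_mass=2.0)
        with pytest.raises(InvalidArgumentError):
            GrowthParams(base_rate=1.0, activation_energy=0.8, asymptotic_mass=1.0,
                         exponent=1.0)


class TestFoldChangeLaws:
    def test_unity_at_reference(self, fitted_scaling):
        assert devtime_fold_change(25.0, fitted_scaling) == 1.0
        assert connectivity_fold_change(25.0, fitted_scaling) == 1.0

    def test_hand_values_at_18(self, fitted_scaling):
        assert devtime_fold_change(18.0, fitted_scaling) == pytest.approx(
            np.exp(0.128 * 7.0), rel=1e-12)
        assert devtime_fold_change(18.0, fitted_scaling) == pytest.approx(2.450, abs=5e-4)
        assert connectivity_fold_change(18.0, fitted_scaling) == pytest.approx(
            np.exp(0.133 * 7.0), rel=1e-12)
        assert connectivity_fold_change(18.0, fitted_scaling) == pytest.approx(2.537, abs=5e-4)

    def test_exponential_composition(self, fitted_scaling):
        # fold(T1) * e^{-alpha (T2-T1)} == fold(T2)
        f1 = devtime_fold_change(14.0, fitted_scaling)
        rel = np.exp(-fitted_scaling.alpha * (29.0 - 14.0))
        assert f1 * rel == pytest.approx(devtime_fold_change(29.0, fitted_scaling), rel=1e-12)

    def test_zero_beta_means_no_connectivity_change(self):
        flat = ScalingParams(alpha=0.128, beta=0.0)
        for t in [12.0, 18.0, 25.0, 31.0]:
            assert connectivity_fold_change(t, flat) == 1.0

    @settings(derandomize=True, max_examples=50)
    @given(t1=st.floats(10, 34), dt=st.floats(0.1, 5))
    def test_fold_laws_strictly_decreasing(self, fitted_scaling, t1, dt):
        assert devtime_fold_change(t1 + dt, fitted_scaling) < devtime_fold_change(t1, fitted_scaling)
        assert connectivity_fold_change(t1 + dt, fitted_scaling) < connectivity_fold_change(
            t1, fitted_scaling)


class TestActivationEnergies:
    def test_study_values(self, fitted_scaling):
        en = activation_energies(fitted_scaling)
        assert en.e == pytest.approx(0.128 * KT2, rel=1e-12)
        assert en.e == pytest.approx(0.822, abs=5e-4)
        assert round(en.e_prime, 2) == 0.61
        assert en.e_prime < en.e

    def test_zero_beta_collapses_gap(self):
        en = activation_energies(ScalingParams(alpha=0.128, beta=0.0))
        assert en.delta_e == 0.0
        assert en.e_prime == en.e

    def test_warns_on_negative_brain_energy(self):
        with pytest.warns(RuntimeWarning, match="non-positive brain activation"):
            activation_energies(ScalingParams(alpha=0.05, beta=0.3))


class TestRelativeBrainStage:
    def test_unity_at_reference(self, fitted_scaling):
        assert relative_brain_stage(25.0, fitted_scaling) == 1.0

    def test_matches_ode_ratio_at_proportional_times(self, growth_params, fitted_scaling):
        # brain state after fraction f of ontogenesis at 18 vs 25 °C, computed
        # by running the growth ODE with E' for the body-set durations
        en = activation_energies(fitted_scaling)
        body = GrowthParams(base_rate=0.05, activation_energy=en.e, asymptotic_mass=1.0)
        # brain base rate chosen tiny so n << M at all sampled fractions
        brain = GrowthParams(base_rate=1e-8, activation_energy=en.e_prime,
                             asymptotic_mass=1.0)
        t18, t25 = time_to_mass(body, 18.0), time_to_mass(body, 25.0)
        vals = []
        for frac in (0.25, 0.5, 0.75):
            n18 = solve_growth(brain, 18.0, t_end=frac * t18, n_steps=2).masses[-1]
            n25 = solve_growth(brain, 25.0, t_end=frac * t25, n_steps=2).masses[-1]
            vals.append(n18 / n25)
        expected = relative_brain_stage(18.0, fitted_scaling)
        np.testing.assert_allclose(vals, expected, rtol=1e-4)
        # and the advancement is independent of the ontogenetic fraction
        np.testing.assert_allclose(vals, vals[0], rtol=1e-6)

    def test_advanced_when_cold(self, fitted_scaling):
        assert relative_brain_stage(18.0, fitted_scaling) > 1.0
        assert relative_brain_stage(31.0, fitted_scaling) < 1.0


class TestParams:
    def test_scaling_gamma_consistency(self):
        s = ScalingParams(alpha=0.128, beta=0.133)
        assert s.gamma == pytest.approx(0.128 - 0.133 / 4.0, abs=1e-15)
        with pytest.raises(InvalidArgumentError):
            ScalingParams(alpha=0.128, beta=0.133, gamma=0.2)
        with pytest.raises(InvalidArgumentError):
            ScalingParams(alpha=0.1, beta=0.1, ref_temp=40.0)

    def test_constants_validation(self):
        with pytest.raises(InvalidArgumentError):
            ThermalConstants(boltzmann_k=-1.0)
        assert DEFAULT_CONSTANTS.kt2 == pytest.approx(KT2)

    def test_metabolic_provenance_consistency(self):
        GrowthParams(base_rate=2.0, activation_energy=0.8, asymptotic_mass=1.0,
                     metabolic_norm=4.0, cell_mass=1.0, cell_energy=2.0)
        with pytest.raises(InvalidArgumentError):
            GrowthParams(base_rate=1.0, activation_energy=0.8, asymptotic_mass=1.0,
                         metabolic_norm=4.0, cell_mass=1.0, cell_energy=2.0)
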