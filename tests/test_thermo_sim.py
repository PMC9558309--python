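"""Toy-lattice dynamics, canonical oracle, EVB energies, dataset generators."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from thermocap import (
    ActivationParams,
    EVBState,
    ThermostatConfig,
    build_harmonic_lattice,
    canonical_cv_oracle,
    eq1_dg,
    evb_fixed_mix,
    evb_ground_energy,
    fit_eq1,
    gen_eq1_dataset,
    gen_two_state_rates,
    instantaneous_temperature,
    rate_from_dg,
    simulate,
)
from thermocap.constants import R


class TestToySystem:
    def test_analytic_cp_is_equipartition(self):
        sys_ = build_harmonic_lattice(7)
        assert sys_.analytic_cp == pytest.approx(21 * R)

    def test_anharmonic_has_no_closed_form(self):
        assert build_harmonic_lattice(4, a_quartic=1.0).analytic_cp is None

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            build_harmonic_lattice(0)
        with pytest.raises(ValueError):
            build_harmonic_lattice(4, mass=-1.0)
        with pytest.raises(ValueError):
            build_harmonic_lattice(4, a_quartic=-0.1)

    def test_spring_dispersion_preserves_mean_scale(self):
        ks = build_harmonic_lattice(10).spring_constants
        assert ks.shape == (10, 3)
        assert np.all(ks > 0)
        # log-symmetric spread about the nominal constant
        assert np.exp(np.mean(np.log(ks))) == pytest.approx(72.0, rel=1e-9)


class TestSimulate:
    def test_microcanonical_energy_conservation(self):
        sys_ = build_harmonic_lattice(16)
        th = ThermostatConfig("none")
        traj = simulate(sys_, th, 300.0, n_steps=100_000, seed=4)
        e = traj.e_tot
        n = len(e)
        drift = abs(np.mean(e[-n // 10:]) - np.mean(e[: n // 10])) / np.mean(e)
        assert drift < 1e-4

    def test_langevin_equipartition(self):
        sys_ = build_harmonic_lattice(64)
        th = ThermostatConfig("langevin", tau=100.0)
        traj = simulate(sys_, th, 300.0, n_steps=100_000, sample_every=1, seed=9)
        t_kin = np.mean([instantaneous_temperature(k, sys_.n_df) for k in traj.ke])
        assert t_kin == pytest.approx(300.0, rel=0.01)

    def test_same_seed_identical_trajectories(self):
        sys_ = build_harmonic_lattice(8)
        th = ThermostatConfig("v_rescale", tau=50.0)
        a = simulate(sys_, th, 300.0, n_steps=2000, seed=5)
        b = simulate(sys_, th, 300.0, n_steps=2000, seed=5)
        np.testing.assert_array_equal(a.e_tot, b.e_tot)
        np.testing.assert_array_equal(a.ke, b.ke)

    def test_stochastic_thermostat_requires_seed(self):
        sys_ = build_harmonic_lattice(8)
        with pytest.raises(ValueError, match="seed"):
            simulate(sys_, ThermostatConfig("langevin"), 300.0, n_steps=100)

    def test_unstable_timestep_rejected(self):
        sys_ = build_harmonic_lattice(8, k_spring=500.0)
        with pytest.raises(ValueError, match="unstable"):
            simulate(sys_, ThermostatConfig("none"), 300.0, n_steps=100, dt=5.0)

    def test_records_dof_and_component_bookkeeping(self):
        sys_ = build_harmonic_lattice(8)
        traj = simulate(sys_, ThermostatConfig("berendsen", tau=100.0), 300.0,
                        n_steps=1000, seed=1)
        assert traj.n_df == 24
        np.testing.assert_allclose(traj.e_tot, traj.u_tot + traj.ke, atol=1e-9)


class TestInstantaneousTemperature:
    def test_definition(self):
        ke = 1.5 * R * 300.0
        assert instantaneous_temperature(ke, 3) == pytest.approx(300.0)

    def test_zero_ke(self):
        assert instantaneous_temperature(0.0, 10) == 0.0

    def test_maxwell_boltzmann_round_trip(self):
        rng = np.random.default_rng(11)
        n_df, T = 600, 300.0
        ke = 0.5 * R * T * rng.chisquare(n_df, size=4000)
        temps = 2.0 * ke / (n_df * R)
        assert np.mean(temps) == pytest.approx(T, rel=0.01)

    def test_zero_dof_rejected(self):
        with pytest.raises(ValueError):
            instantaneous_temperature(1.0, 0)


class TestCanonicalOracle:
    def test_harmonic_closed_form(self):
        sys_ = build_harmonic_lattice(5)
        assert canonical_cv_oracle(sys_, 300.0) == pytest.approx(15 * R, abs=1e-10)

    def test_pure_quartic_limit(self):
        # potential Cv per coordinate → R/4, total per coordinate → 3R/4
        sys_ = build_harmonic_lattice(1, a_quartic=1e9)
        cv = canonical_cv_oracle(sys_, 300.0)
        assert cv == pytest.approx(3 * 0.75 * R, rel=1e-3)

    def test_monotone_departure_with_anharmonicity(self):
        cvs = [
            canonical_cv_oracle(build_harmonic_lattice(1, a_quartic=a), 300.0)
            for a in (0.0, 1.0, 10.0, 100.0, 1e4)
        ]
        assert np.all(np.diff(cvs) < 0)  # quartic stiffening lowers Cv toward 3R·3/4

    def test_oracle_matches_langevin_sampling_on_anharmonic_system(self):
        """Independent cross-check: thermostatted sampling of an anharmonic
        lattice reproduces the quadrature heat capacity."""
        from thermocap import TemperatureEnsemble, cp_fluctuation

        sys_ = build_harmonic_lattice(16, a_quartic=30.0)
        th = ThermostatConfig("langevin", tau=10.0)
        trajs = tuple(
            simulate(sys_, th, T, n_steps=120_000, seed=21 + i)
            for i, T in enumerate((280.0, 300.0, 320.0))
        )
        est = cp_fluctuation(TemperatureEnsemble(trajs))
        oracle = canonical_cv_oracle(sys_, 300.0)
        assert est.value == pytest.approx(oracle, rel=0.05)


class TestEVB:
    def test_uncoupled_limit_selects_lower_state(self):
        assert evb_ground_energy(EVBState(3.0, 7.0, 0.0)) == 3.0
        assert evb_ground_energy(EVBState(9.0, -2.0, 0.0)) == -2.0

    def test_degenerate_case(self):
        assert evb_ground_energy(EVBState(4.0, 4.0, 1.5)) == pytest.approx(4.0 - 1.5)

    def test_fixed_mix_arithmetic(self):
        assert evb_fixed_mix(EVBState(10.0, 20.0, 0.0, c1_sq=0.5)) == 15.0
        assert evb_fixed_mix(EVBState(10.0, 20.0, 0.0, c1_sq=1.0)) == 10.0

    def test_gap_identity_at_even_mixing(self):
        s = EVBState(3.0, 11.0, 2.0, c1_sq=0.5)
        gap = evb_fixed_mix(s) - evb_ground_energy(s)
        assert gap == pytest.approx(0.5 * np.sqrt((3.0 - 11.0) ** 2 + 4 * 2.0**2))

    @given(
        e1=st.floats(-50, 50), e2=st.floats(-50, 50),
        h12=st.floats(0, 20), c1=st.floats(0, 1),
    )
    @settings(max_examples=100, deadline=None)
    def test_ground_state_bounds(self, e1, e2, h12, c1):
        """Secular ground state never exceeds min(ε1, ε2) nor the 50/50 mix."""
        s = EVBState(e1, e2, h12, c1_sq=c1)
        g = evb_ground_energy(s)
        assert g <= min(e1, e2) + 1e-9
        assert g <= evb_fixed_mix(EVBState(e1, e2, h12, c1_sq=0.5)) + 1e-9

    def test_validation(self):
        with pytest.raises(ValueError):
            EVBState(0.0, 0.0, -1.0)
        with pytest.raises(ValueError):
            EVBState(0.0, 0.0, 0.0, c1_sq=1.5)


class TestGenerators:
    TEMPS = (280.0, 290.0, 300.0, 310.0, 320.0)

    def test_noiseless_matches_forward_model(self):
        p = ActivationParams(10.5, -0.0062, -0.3)
        ds = gen_eq1_dataset(p, self.TEMPS)
        np.testing.assert_allclose(ds.values, eq1_dg(np.array(self.TEMPS), p))

    def test_seeded_reproducibility(self):
        p = ActivationParams(10.5, -0.0062, -0.3)
        a = gen_eq1_dataset(p, self.TEMPS, noise_sd=0.05, seed=13)
        b = gen_eq1_dataset(p, self.TEMPS, noise_sd=0.05, seed=13)
        np.testing.assert_array_equal(a.values, b.values)

    def test_round_trip_through_fit(self):
        p = ActivationParams(10.5, -0.0062, -0.3)
        fit = fit_eq1(gen_eq1_dataset(p, self.TEMPS))
        assert fit.dCp == pytest.approx(-0.3, rel=1e-6)

    def test_two_state_pure_tst_limit(self):
        chem = ActivationParams(10.5, -0.0062, 0.0)
        temps = np.array(self.TEMPS)
        ds = gen_two_state_rates(chem, dH_eq=500.0, dS_eq=0.11, temps=temps)
        np.testing.assert_allclose(
            ds.values, rate_from_dg(eq1_dg(temps, chem), temps), rtol=1e-12)

    def test_crossover_halves_rate(self):
        # at T* = ΔH_eq/ΔS_eq the inactive state is equally populated
        dH, dS = 30.0, 0.11
        t_star = dH / dS
        chem = ActivationParams(10.5, -0.0062, 0.0)
        temps = np.array([250.0, t_star, 330.0])
        ds = gen_two_state_rates(chem, dH, dS, temps)
        pure = rate_from_dg(eq1_dg(t_star, chem), t_star)
        assert ds.values[1] == pytest.approx(pure / 2.0, rel=1e-9)

    def test_inactive_state_produces_rate_optimum(self):
        """With the inactive-state parameters (ΔH_eq≈30, ΔS_eq≈0.11) the
        observed rate rises then falls; with this chemical barrier the
        optimum sits near 271 K, just below the crossover ΔH_eq/ΔS_eq."""
        chem = ActivationParams(10.5, -0.0062, 0.0)
        temps = np.linspace(255.0, 325.0, 71)
        ds = gen_two_state_rates(chem, 30.0, 0.11, temps)
        k = ds.values
        imax = int(np.argmax(k))
        assert 0 < imax < len(k) - 1
        assert k[imax] > k[0] and k[imax] > k[-1]
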