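"""Heat-capacity estimators, error protocols, differences and the binding cycle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from thermocap import (
    CpEstimate,
    EnergyTrajectory,
    TemperatureEnsemble,
    binding_cycle,
    cp_derivative,
    cp_difference,
    cp_fluctuation,
    cp_fluctuation_single,
    kinetic_correction,
    mean_energy,
)
from thermocap.constants import R


def _traj(values, T=300.0, n_df=None, component="e_tot"):
    values = np.asarray(values, dtype=float)
    kw = {component: values}
    return EnergyTrajectory(T, time=np.arange(values.size, dtype=float),
                            n_df=n_df, **kw)


class TestMeanEnergy:
    def test_constant_series(self):
        assert mean_energy(_traj([3.0] * 8)) == (3.0, 0.0)

    def test_simple_mean(self):
        mean, _ = mean_energy(_traj([1.0, 2.0, 3.0, 4.0]))
        assert mean == 2.5

    def test_stderr_is_half_block_gap(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 40)
        _, err = mean_energy(_traj(x))
        expected = abs(np.mean(x[:20]) - np.mean(x[20:])) / 2.0
        assert err == pytest.approx(expected)


class TestKineticCorrection:
    def test_rigid_water_molecule_gives_3R(self):
        assert kinetic_correction(6) == pytest.approx(3 * R)
        assert kinetic_correction(6) == pytest.approx(0.005962, abs=5e-7)

    def test_zero(self):
        assert kinetic_correction(0) == 0.0

    def test_free_particles(self):
        n = 17
        assert kinetic_correction(3 * n) == pytest.approx(1.5 * n * R)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            kinetic_correction(-1)


class TestDerivative:
    def test_perfect_line_recovers_slope(self):
        # constant series at each T, with means exactly linear in T
        s = 0.42
        trajs = tuple(_traj([s * T] * 10, T=T) for T in (280, 290, 300, 310, 320))
        est = cp_derivative(TemperatureEnsemble(trajs), kinetic="none")
        assert est.value == pytest.approx(s, abs=1e-12)
        assert est.err_regression == pytest.approx(0.0, abs=1e-12)
        assert est.err_block == pytest.approx(0.0, abs=1e-12)

    def test_two_temperatures_is_finite_difference(self):
        trajs = (_traj([10.0] * 6, T=290.0), _traj([14.0] * 6, T=310.0))
        est = cp_derivative(TemperatureEnsemble(trajs), kinetic="none")
        assert est.value == pytest.approx(0.2)
        assert est.err_regression is None

    def test_kinetic_auto_on_potential_component(self):
        s = 0.1
        trajs = tuple(
            _traj([s * T] * 10, T=T, n_df=12, component="u_tot")
            for T in (280, 300, 320)
        )
        est = cp_derivative(TemperatureEnsemble(trajs), component="u_tot")
        assert est.kinetic_correction == pytest.approx(6 * R)
        assert est.value == pytest.approx(s + 6 * R)
        est_none = cp_derivative(TemperatureEnsemble(trajs), component="u_tot",
                                 kinetic="none")
        assert est_none.value == pytest.approx(s)

    def test_kinetic_auto_without_ndf_raises(self):
        trajs = tuple(_traj([1.0, 2.0], T=T, component="u_tot") for T in (280, 300))
        with pytest.raises(ValueError, match="n_df"):
            cp_derivative(TemperatureEnsemble(trajs), component="u_tot")


class TestFluctuation:
    def test_constant_series_zero_variance(self):
        est = cp_fluctuation_single(_traj([5.0] * 10), kinetic="none")
        assert est.value == 0.0

    def test_gaussian_variance_definition(self):
        rng = np.random.default_rng(1)
        T, v = 300.0, 4.0
        x = rng.normal(0.0, np.sqrt(v), 200_000)
        est = cp_fluctuation_single(_traj(x, T=T))
        assert est.value == pytest.approx(v / (R * T * T), rel=0.01)

    def test_population_variance_used(self):
        x = np.array([1.0, 3.0])
        est = cp_fluctuation_single(_traj(x, T=300.0), n_blocks=None)
        assert est.value == pytest.approx(np.var(x) / (R * 300.0**2))

    def test_sem_over_temperatures(self):
        # engineer per-T estimates of exactly {1, 2, 3} kcal/mol/K
        temps = (280.0, 300.0, 320.0)
        targets = (1.0, 2.0, 3.0)
        trajs = []
        for T, c in zip(temps, targets):
            a = np.sqrt(c * R * T * T)  # two-point series [a, -a] has Var = a²
            trajs.append(_traj([a, -a], T=T))
        est = cp_fluctuation(TemperatureEnsemble(tuple(trajs)), kinetic="none")
        assert est.value == pytest.approx(2.0)
        assert est.err_sem == pytest.approx(np.std([1, 2, 3], ddof=1) / np.sqrt(3))
        assert est.err_sem == pytest.approx(0.577, abs=5e-4)

    def test_zero_spread_zero_sem(self):
        trajs = []
        for T in (280.0, 300.0):
            a = np.sqrt(2.0 * R * T * T)
            trajs.append(_traj([a, -a], T=T))
        est = cp_fluctuation(TemperatureEnsemble(tuple(trajs)), kinetic="none")
        assert est.value == pytest.approx(2.0)
        assert est.err_sem == pytest.approx(0.0, abs=1e-12)

    def test_component_equivalence_on_synthetic_canonical_series(self):
        """Cp from u_tot + N_df·R/2 matches Cp from e_tot when KE carries its
        canonical variance (N_df/2)·(R·T)² independent of U."""
        rng = np.random.default_rng(5)
        n_df, n = 300, 400_000
        trajs_e, trajs_u = [], []
        for T in (290.0, 310.0):
            var_ke = 0.5 * n_df * (R * T) ** 2
            u = rng.normal(0.0, 2.0, n)
            ke = rng.normal(0.5 * n_df * R * T, np.sqrt(var_ke), n)
            t = np.arange(n, dtype=float)
            trajs_e.append(EnergyTrajectory(T, t, e_tot=u + ke, n_df=n_df))
            trajs_u.append(EnergyTrajectory(T, t, u_tot=u, n_df=n_df))
        e_est = cp_fluctuation(TemperatureEnsemble(tuple(trajs_e)))
        u_est = cp_fluctuation(TemperatureEnsemble(tuple(trajs_u)), component="u_tot")
        err = np.sqrt((e_est.err_sem or 0) ** 2 + (u_est.err_sem or 0) ** 2)
        # at n = 4e5 the variance estimate itself has ~0.2% sampling error
        assert abs(e_est.value - u_est.value) <= max(3 * err, 0.01 * e_est.value)


class TestDifference:
    def test_reference_block_error_propagation(self):
        # worked difference: 38.95±0.08 and 39.05±0.09 → 0.10±0.12
        es = CpEstimate(38.95, "derivative", "e_tot", err_block=0.08)
        ts = CpEstimate(39.05, "derivative", "e_tot", err_block=0.09)
        d = cp_difference(es, ts)
        assert d.value == pytest.approx(0.10)
        assert d.err_block == pytest.approx(0.12, abs=5e-3)

    def test_reference_small_error_case(self):
        # 38.17±0.03 and 38.32±0.01 → 0.15±0.03
        es = CpEstimate(38.17, "derivative", "e_tot", err_block=0.03)
        ts = CpEstimate(38.32, "derivative", "e_tot", err_block=0.01)
        d = cp_difference(es, ts)
        assert d.value == pytest.approx(0.15)
        assert d.err_block == pytest.approx(0.0316, abs=5e-4)

    def test_self_difference(self):
        a = CpEstimate(40.0, "derivative", "e_tot", err_block=0.05)
        d = cp_difference(a, a)
        assert d.value == 0.0
        assert d.err_block == pytest.approx(np.sqrt(2) * 0.05)

    def test_tag_mismatch_raises(self):
        a = CpEstimate(1.0, "derivative", "e_tot")
        b = CpEstimate(1.0, "fluctuation", "e_tot")
        with pytest.raises(ValueError, match="mismatch"):
            cp_difference(a, b)
        c = CpEstimate(1.0, "derivative", "u_tot")
        with pytest.raises(ValueError, match="mismatch"):
            cp_difference(a, c)


class TestBindingCycle:
    def test_reference_activation_vs_apo(self):
        # TS 39.05, apo 38.80, Δ(wat−lig) = −0.09 → 0.16
        ts = CpEstimate(39.05, "derivative", "e_tot", err_block=0.09)
        apo = CpEstimate(38.80, "derivative", "e_tot", err_block=0.07)
        lig = CpEstimate(11.00, "derivative", "e_tot", err_block=0.02)
        pure = CpEstimate(11.00 - 0.09, "derivative", "e_tot", err_block=0.0)
        res = binding_cycle(ts, apo, lig, pure)
        assert res.delta_cp_bind == pytest.approx(0.16)
        assert res.err == pytest.approx(np.sqrt(0.09**2 + 0.07**2 + 0.02**2), abs=1e-12)

    def test_component_level_arithmetic_beats_rounding(self):
        """The ES′ binding difference from unrounded components is +0.01 even
        though rounding the final number to two decimals would print 0.00."""
        esp = CpEstimate(38.90, "derivative", "e_tot")
        apo = CpEstimate(38.80, "derivative", "e_tot")
        lig = CpEstimate(11.00, "derivative", "e_tot")
        pure = CpEstimate(11.00 - 0.09, "derivative", "e_tot")
        res = binding_cycle(esp, apo, lig, pure)
        assert res.delta_cp_bind == pytest.approx(0.01)

    def test_null_cycle(self):
        a = CpEstimate(5.0, "derivative", "e_tot")
        res = binding_cycle(a, a, a, a)
        assert res.delta_cp_bind == 0.0

    @given(vals=st.lists(st.floats(-100, 100), min_size=4, max_size=4))
    @settings(max_examples=50, deadline=None)
    def test_matches_signed_sum_oracle(self, vals):
        holo, apo, lig, pure = vals
        ests = [CpEstimate(v, "derivative", "e_tot") for v in vals]
        res = binding_cycle(*ests)
        oracle = holo - apo + pure - lig  # independent signed sum
        assert res.delta_cp_bind == pytest.approx(oracle, abs=1e-9)

    def test_dof_balance_enforced(self):
        a = CpEstimate(5.0, "derivative", "e_tot")
        with pytest.raises(ValueError, match="imbalance"):
            binding_cycle(a, a, a, a,
                          dof={"holo": 100, "apo": 90, "lig": 20, "pure": 9})
        res = binding_cycle(a, a, a, a,
                            dof={"holo": 100, "apo": 90, "lig": 20, "pure": 10})
        assert res.dof_balanced is True

    def test_tag_mismatch_raises(self):
        a = CpEstimate(5.0, "derivative", "e_tot")
        b = CpEstimate(5.0, "fluctuation", "e_tot")
        with pytest.raises(ValueError, match="tags"):
            binding_cycle(a, a, a, b)


class TestPresentation:
    def test_per_molecule_scaling(self):
        est = CpEstimate(4.104, "derivative", "e_tot", err_block=0.216)
        pm = est.per_molecule(216)
        assert pm.value == pytest.approx(0.019)
        assert pm.err_block == pytest.approx(0.001)

    def test_json_round_trip(self):
        est = CpEstimate(38.95, "derivative", "e_tot", err_block=0.08,
                         err_regression=0.14, temperatures=(280.0, 320.0),
                         n_samples_per_T=(100, 100))
        back = CpEstimate.from_json(est.to_json())
        assert back == est
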