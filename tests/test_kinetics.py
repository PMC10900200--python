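"""Kinetic network simulation: conservation, symmetry and closed-form limits."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import glycobalance as gb
from glycobalance.kinetics import time_to_asymptote

A0, L0 = 1e-3, 5e-4

rate_value = st.floats(1e-4, 1e3)


def _grid(t_end, n=200):
    return np.linspace(0.0, t_end, n)


class TestValidation:
    @pytest.mark.parametrize("bad", [0.0, -1.0, math.inf, math.nan])
    def test_nonpositive_rate_rejected(self, bad):
        with pytest.raises(gb.KineticsError):
            gb.RateConstants(bad, 1, 1, 1, 1, 1)

    def test_nonpositive_concentration_rejected(self, reference_rates):
        with pytest.raises(gb.KineticsError):
            gb.simulate_network(reference_rates, 0.0, L0, _grid(10))

    def test_grid_must_start_at_zero(self, reference_rates):
        with pytest.raises(gb.KineticsError):
            gb.simulate_network(reference_rates, A0, L0, np.array([1.0, 2.0]))

    def test_grid_must_increase(self, reference_rates):
        with pytest.raises(gb.KineticsError):
            gb.simulate_network(reference_rates, A0, L0, np.array([0.0, 2.0, 1.0]))


class TestSimulation:
    def test_symmetric_branches_give_equal_isomers(self):
        rates = gb.RateConstants(10, 0.002, 0.02, 0.002, 0.02, 0.002)
        traj = gb.simulate_network(rates, A0, L0, _grid(500))
        np.testing.assert_allclose(traj.Z, traj.E, rtol=1e-8)

    def test_mass_conservation(self, reference_rates):
        traj = gb.simulate_network(reference_rates, A0, L0, _grid(2000))
        amine, aldehyde = traj.conservation_error()
        assert amine <= 1e-9
        assert aldehyde <= 1e-9

    def test_branch_swap_swaps_trajectories(self, reference_rates):
        grid = _grid(1000)
        fwd = gb.simulate_network(reference_rates, A0, L0, grid)
        swp = gb.simulate_network(reference_rates.swapped_branches(), A0, L0, grid)
        np.testing.assert_allclose(fwd.Z, swp.E, rtol=1e-7, atol=1e-16)
        np.testing.assert_allclose(fwd.E, swp.Z, rtol=1e-7, atol=1e-16)
        np.testing.assert_allclose(fwd.A, swp.A, rtol=1e-7)

    def test_long_horizon_ratio_reaches_four(self, reference_rates):
        traj = gb.simulate_network(reference_rates, A0, L0, np.array([0.0, 1e5]))
        assert traj.Z[-1] / traj.E[-1] == pytest.approx(4.0, rel=1e-4)

    def test_trajectory_csv_round_trip(self, reference_rates, tmp_path):
        traj = gb.simulate_network(reference_rates, A0, L0, _grid(300, 30))
        path = tmp_path / "traj.csv"
        traj.to_csv(path)
        back = gb.Trajectory.from_csv(path, reference_rates, A0, L0)
        for field in ("t", "A", "L", "I", "Z", "E"):
            np.testing.assert_array_equal(getattr(traj, field), getattr(back, field))


class TestClosedForm:
    def test_all_rates_equal_gives_unity(self):
        rates = gb.RateConstants(*(0.5,) * 6)
        assert gb.closed_form_ratios(rates) == (1.0, 1.0)

    def test_proportional_branches(self):
        rates = gb.RateConstants(10, 0.002, 0.04, 0.003, 0.02, 0.003)
        keq, initial = gb.closed_form_ratios(rates)
        assert keq == pytest.approx(2.0)
        assert initial == pytest.approx(2.0)

    def test_reference_set_limits(self, reference_rates):
        keq, initial = gb.closed_form_ratios(reference_rates)
        assert (keq, initial) == (4.0, 2.0)
        # both limits recovered by integration
        long = gb.simulate_network(reference_rates, A0, L0, np.array([0.0, 1e5]))
        assert long.Z[-1] / long.E[-1] == pytest.approx(keq, rel=1e-4)
        short = gb.simulate_network(
            reference_rates, A0, L0, np.array([0.0, 1e-3]), rtol=1e-12, atol=1e-22
        )
        assert short.Z[-1] / short.E[-1] == pytest.approx(initial, rel=1e-4)

    @given(
        k1z=rate_value, k_m1z=rate_value, k1e=rate_value, k_m1e=rate_value
    )
    def test_detailed_balance_formula(self, k1z, k_m1z, k1e, k_m1e):
        rates = gb.RateConstants(10.0, 0.002, k1z, k_m1z, k1e, k_m1e)
        keq, initial = gb.closed_form_ratios(rates)
        assert keq > 0 and initial > 0
        assert keq == pytest.approx((k1z * k_m1e) / (k1e * k_m1z))

    def test_equilibrium_state_matches_detailed_balance(self, reference_rates):
        eq = gb.equilibrium_state(reference_rates, A0, L0)
        assert eq.Z / eq.E == pytest.approx(4.0, rel=1e-12)
        assert eq.I == pytest.approx(
            (reference_rates.k1 / reference_rates.k_m1) * eq.A * eq.L, rel=1e-10
        )
        assert eq.A + eq.I + eq.Z + eq.E == pytest.approx(A0, rel=1e-12)


class TestRegime:
    def test_fast_label(self):
        # k1*a0 = 10 min^-1 against 0.03 min^-1 of branch rates
        rates = gb.RateConstants(1e4, 2.0, 0.02, 0.002, 0.01, 0.004)
        assert gb.classify_regime(rates, A0) == "fast_preequilibrium"

    def test_slow_label(self):
        rates = gb.RateConstants(1.0, 0.0002, 0.06, 0.006, 0.04, 0.016)
        assert gb.classify_regime(rates, A0) == "slow_bimolecular"

    def test_intermediate_label(self, reference_rates):
        assert gb.classify_regime(reference_rates, A0) == "intermediate"

    def test_slow_regime_ratio_converges_before_concentrations(self):
        """The Z/E ratio pre-equilibrates ahead of the slow conversion."""
        sets = gb.sample_rate_constants("slow_bimolecular", 5, seed=101)
        for rates in sets:
            eq = gb.equilibrium_state(rates, A0, L0)
            traj = gb.simulate_network(rates, A0, L0, _grid(3000, 1500))
            ratio = traj.ratio()
            ratio[0] = eq.Z / eq.E  # 0/0 start treated as settled
            t_ratio = time_to_asymptote(traj.t, ratio, final=eq.Z / eq.E)
            t_z = time_to_asymptote(traj.t, traj.Z, final=eq.Z)
            t_e = time_to_asymptote(traj.t, traj.E, final=eq.E)
            assert t_ratio <= t_z
            assert t_ratio <= t_e


class TestAsymptoteTiming:
    def test_monotone_curve(self):
        t = np.linspace(0, 10, 101)
        y = 1 - np.exp(-t)
        # enters the 10% band of 1.0 at y = 0.9, i.e. t = ln 10
        assert time_to_asymptote(t, y, final=1.0) == pytest.approx(
            math.log(10), abs=0.1
        )

    def test_never_converges(self):
        t = np.linspace(0, 1, 10)
        assert time_to_asymptote(t, t * 0 + 5.0, final=100.0) == math.inf
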