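"""Ratio-curve construction and exponential fitting."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import glycobalance as gb
from glycobalance.ratiofit import InsufficientDataError, RatioExponentialModel

A0, L0 = 1e-3, 5e-4


def make_series(t, z, e, **meta):
    return gb.KineticSeries(t=t, z_signal=z, e_signal=e, meta=meta)


class TestBuildRatioSeries:
    def test_constant_ratio(self):
        t = np.arange(0.0, 100.0, 10.0)
        e = np.linspace(1.0, 5.0, t.size)
        tt, ratio = gb.build_ratio_series(make_series(t, 2 * e, e))
        np.testing.assert_allclose(ratio, 2.0)
        np.testing.assert_array_equal(tt, t)

    def test_zero_first_point_dropped(self):
        t = np.arange(0.0, 60.0, 10.0)
        e = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0])
        z = np.ones_like(e)
        tt, ratio = gb.build_ratio_series(make_series(t, z, e), 0.01)
        assert tt[0] == 10.0 and tt.size == 5
        assert np.all(np.isfinite(ratio))

    def test_insufficient_points_raise(self):
        t = np.arange(0.0, 50.0, 10.0)
        e = np.array([0.0, 0.0, 1.0, 0.001, 0.001])
        with pytest.raises(InsufficientDataError):
            gb.build_ratio_series(make_series(t, np.ones_like(e), e), 0.05)

    def test_matches_noiseless_trajectory(self, reference_rates):
        grid = np.arange(0.0, 600.1, 15.0)
        traj = gb.simulate_network(reference_rates, A0, L0, grid)
        series = make_series(grid, traj.Z * 100, traj.E * 100)
        tt, ratio = gb.build_ratio_series(series)
        expect = traj.Z[np.isin(grid, tt)] / traj.E[np.isin(grid, tt)]
        np.testing.assert_allclose(ratio, expect, rtol=1e-12)


class TestExponentialFit:
    def test_constant_curve_degenerate_fit(self):
        t = np.linspace(0, 100, 10)
        res = gb.fit_ratio_exponential((t, np.full(10, 3.5)), 1)
        assert res.keq == pytest.approx(3.5, abs=1e-8)
        assert res.amplitudes[0] == pytest.approx(0.0, abs=1e-8)
        assert res.initial_ratio == pytest.approx(3.5, abs=1e-7)

    def test_single_exponential_self_inversion(self):
        t = np.linspace(0, 400, 20)
        curve = 8.0 - 6.0 * np.exp(-t / 50.0)
        res = gb.fit_ratio_exponential((t, curve), 1)
        assert res.converged
        assert res.keq == pytest.approx(8.0, rel=1e-6)
        assert res.amplitudes[0] == pytest.approx(-6.0, rel=1e-6)
        assert res.timescales[0] == pytest.approx(50.0, rel=1e-6)
        assert res.initial_ratio == pytest.approx(2.0, rel=1e-6)

    def test_noiseless_slow_trajectory_recovers_keq(self):
        rates = gb.sample_rate_constants("slow_bimolecular", 1, seed=5)[0]
        keq_true, _ = gb.closed_form_ratios(rates)
        series, _ = gb.generate_experiment(
            rates, gb.ExperimentDesign(noise_rel_sd=0.0)
        )
        res = gb.select_fit(gb.build_ratio_series(series))
        assert res.keq == pytest.approx(keq_true, rel=0.01)

    def test_rescaling_invariance(self):
        rng = np.random.default_rng(0)
        t = np.linspace(0, 300, 25)
        z = (2.0 + np.exp(-t / 80.0)) * (1 + 0.02 * rng.standard_normal(25))
        e = np.ones(25) * (1 + 0.02 * rng.standard_normal(25))
        a = gb.select_fit(gb.build_ratio_series(make_series(t, z, e)))
        b = gb.select_fit(gb.build_ratio_series(make_series(t, 137.0 * z, 137.0 * e)))
        assert a.keq == pytest.approx(b.keq, rel=1e-9)
        assert a.initial_ratio == pytest.approx(b.initial_ratio, rel=1e-9)

    def test_too_few_points_raise(self):
        with pytest.raises(InsufficientDataError):
            RatioExponentialModel(np.arange(3.0), np.ones(3), 1)
        with pytest.raises(InsufficientDataError):
            RatioExponentialModel(np.arange(5.0), np.ones(5), 2)

    def test_summary_mentions_parameters(self):
        t = np.linspace(0, 400, 20)
        res = gb.fit_ratio_exponential((t, 8.0 - 6.0 * np.exp(-t / 50.0)), 1)
        text = res.summary()
        assert "Keq" in text and "converged" in text


class TestModelSelection:
    def test_single_exponential_data_selects_one(self):
        t = np.linspace(0, 400, 30)
        res = gb.select_fit((t, 5.0 - 3.0 * np.exp(-t / 60.0)))
        assert res.n_exponentials == 1

    def test_two_exponential_data_selects_two(self):
        # well-separated timescales, both amplitudes >= 20% of Keq
        t = np.linspace(0, 1200, 60)
        curve = 4.0 - 1.5 * np.exp(-t / 30.0) - 1.0 * np.exp(-t / 400.0)
        res = gb.select_fit((t, curve))
        assert res.n_exponentials == 2
        assert res.keq == pytest.approx(4.0, rel=1e-4)
        assert res.initial_ratio == pytest.approx(1.5, rel=1e-3)

    def test_constant_data_selects_one(self):
        t = np.linspace(0, 100, 12)
        res = gb.select_fit((t, np.full(12, 2.0)))
        assert res.n_exponentials == 1
        assert abs(res.amplitudes[0]) < 1e-6

    def test_selection_needs_six_points(self):
        with pytest.raises(InsufficientDataError):
            gb.select_fit((np.arange(5.0), np.ones(5)))


@given(scale=st.floats(0.1, 100.0))
def test_exact_model_recovery_under_scaling(scale):
    """Parameter recovery from exact model data at any curve magnitude."""
    t = np.linspace(0, 500, 24)
    curve = scale * (3.0 - 2.0 * np.exp(-t / 120.0))
    res = gb.fit_ratio_exponential((t, curve), 1)
    assert res.keq == pytest.approx(3.0 * scale, rel=1e-6)
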