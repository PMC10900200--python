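"""Free energy conversions, tier errors and class summaries."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import glycobalance as gb
from glycobalance.thermo import R_KCAL_PER_MOL_K

T = 293.0
RT = R_KCAL_PER_MOL_K * T

keq_values = st.floats(1e-3, 1e3)


class TestDeltaG:
    def test_unity_keq_is_zero(self):
        assert gb.delta_g_from_keq(1.0, 310.0) == 0.0

    @pytest.mark.parametrize(
        "keq, expected",
        [(8.0, -1.211), (0.45, 0.465), (1.3, -0.153)],
    )
    def test_printed_keq_values(self, keq, expected):
        assert gb.delta_g_from_keq(keq, T) == pytest.approx(expected, abs=5e-4)

    def test_nonpositive_keq_rejected(self):
        with pytest.raises(ValueError):
            gb.delta_g_from_keq(0.0)

    @given(keq=keq_values)
    def test_reciprocal_antisymmetry(self, keq):
        assert gb.delta_g_from_keq(1 / keq, T) == pytest.approx(
            -gb.delta_g_from_keq(keq, T), abs=1e-12
        )


class TestErrorTiers:
    @pytest.mark.parametrize(
        "keq, fraction",
        [(1.0, 0.05), (3.0, 0.05), (5.0, 0.075), (9.9, 0.075),
         (10.0, 0.10), (14.9, 0.10), (15.0, 0.15), (20.0, 0.15),
         (0.45, 0.05), (0.08, 0.10)],
    )
    def test_tier_assignment(self, keq, fraction):
        assert gb.assign_keq_error_tier(keq) == fraction

    @pytest.mark.parametrize(
        "fraction, bound",
        [(0.05, 0.03), (0.075, 0.05), (0.10, 0.08), (0.15, 0.10)],
    )
    def test_tier_bounds_hold_analytically(self, fraction, bound):
        """RT ln(1+f) at 293 K stays below the stated dG half-width."""
        assert gb.dg_error_from_keq_error(fraction, T) <= bound

    def test_zero_fraction_zero_error(self):
        assert gb.dg_error_from_keq_error(0.0, T) == 0.0

    def test_specific_values(self):
        assert gb.dg_error_from_keq_error(0.05, T) == pytest.approx(0.0284, abs=5e-4)
        assert gb.dg_error_from_keq_error(0.15, T) == pytest.approx(0.0814, abs=5e-4)

    def test_fraction_domain(self):
        with pytest.raises(ValueError):
            gb.dg_error_from_keq_error(1.0)


class TestErrorPropagation:
    @pytest.mark.parametrize(
        "a, b, expected", [(0.0, 0.04, 0.04), (0.03, 0.04, 0.05),
                           (0.03, 0.03, 0.0424)]
    )
    def test_quadrature(self, a, b, expected):
        assert gb.propagate_dg_error(a, b) == pytest.approx(expected, abs=5e-4)

    @given(a=st.floats(0, 1), b=st.floats(0, 1))
    def test_symmetric_and_dominating(self, a, b):
        err = gb.propagate_dg_error(a, b)
        assert err == gb.propagate_dg_error(b, a)
        assert err >= max(a, b)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            gb.propagate_dg_error(-0.01, 0.02)


class TestDifferentialQuantities:
    def rec(self, keq, balance_id, solvent="DCM"):
        return gb.free_energy_record(keq, T, balance_id=balance_id, solvent=solvent)

    def test_identical_inputs_give_zero(self):
        a = self.rec(2.0, "M")
        b = self.rec(2.0, "R0")
        assert gb.interaction_free_energy(a, b).value == pytest.approx(0.0)

    def test_m6_interaction_energy(self):
        out = gb.interaction_free_energy(self.rec(8.0, "M6"), self.rec(0.45, "R0"))
        assert out.value == pytest.approx(-1.677, abs=2e-3)
        assert out.quantity == "dG_int"

    def test_r6_interaction_energy(self):
        out = gb.interaction_free_energy(self.rec(1.3, "R6"), self.rec(0.45, "R0"))
        assert out.value == pytest.approx(-0.618, abs=2e-3)

    def test_m6_charge_contribution(self):
        out = gb.isostere_contribution(self.rec(8.0, "M6"), self.rec(1.3, "R6"), "charge")
        assert out.value == pytest.approx(-1.058, abs=2e-3)
        assert out.quantity == "dG_charge"

    def test_solvent_mismatch_rejected(self):
        with pytest.raises(ValueError):
            gb.interaction_free_energy(
                self.rec(8.0, "M6", "DCM"), self.rec(0.45, "R0", "MeCN")
            )

    def test_unregistered_pairing_rejected(self):
        with pytest.raises(ValueError):
            gb.isostere_contribution(
                self.rec(8.0, "M6"), self.rec(1.3, "R3"), "charge",
                registry={"M6": "R6"},
            )

    @given(keq_m=keq_values, keq_r=keq_values)
    def test_antisymmetry_under_swap(self, keq_m, keq_r):
        a, b = self.rec(keq_m, "a"), self.rec(keq_r, "b")
        assert gb.interaction_free_energy(a, b).value == pytest.approx(
            -gb.interaction_free_energy(b, a).value, abs=1e-12
        )

    @given(keq_m=keq_values, keq_i=keq_values, keq_r=keq_values)
    def test_chain_consistency(self, keq_m, keq_i, keq_r):
        """dG_int(model) - dG_int(isostere) equals the direct contribution."""
        model, iso, r0 = self.rec(keq_m, "M"), self.rec(keq_i, "I"), self.rec(keq_r, "R0")
        via_int = (
            gb.interaction_free_energy(model, r0).value
            - gb.interaction_free_energy(iso, r0).value
        )
        direct = gb.isostere_contribution(model, iso, "charge").value
        assert via_int == pytest.approx(direct, abs=1e-12)


class TestClassSummary:
    def rec(self, value):
        return gb.FreeEnergyRecord("dG_int", value, 0.03, T)

    def test_identical_values(self):
        frame = gb.summarize_complex_class([self.rec(-1.0)] * 3, ["x"] * 3)
        assert frame.loc[0, "mean"] == -1.0
        assert frame.loc[0, "sd"] == 0.0

    def test_two_value_class(self):
        frame = gb.summarize_complex_class(
            [self.rec(-1.2), self.rec(-1.93)], ["cat", "cat"]
        )
        assert frame.loc[0, "mean"] == pytest.approx(-1.565)
        assert frame.loc[0, "sd"] == pytest.approx(0.516, abs=1e-3)

    def test_ordering_most_stable_first(self):
        frame = gb.summarize_complex_class(
            [self.rec(-0.3), self.rec(-1.5), self.rec(-1.6), self.rec(-0.4)],
            ["weak", "strong", "strong", "weak"],
        )
        assert list(frame["complex_class"]) == ["strong", "weak"]

    def test_singleton_class_has_no_sd(self):
        frame = gb.summarize_complex_class([self.rec(-0.9)], ["solo"])
        assert math.isnan(frame.loc[0, "sd"])
        assert frame.loc[0, "n"] == 1
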