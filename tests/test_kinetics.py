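"""Closed-form rate law and macro/micro parameter maps."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hcdkin import (
    NO_INHIBITION,
    KineticParameters,
    MicroscopicRates,
    macro_from_micro,
    micro_from_macro,
    velocity_mM,
    velocity_uM,
)

# Frozen by direct hand evaluation of the closed form at the reported
# parameters and the standard assay load (160 µM NADPH, 60 µM 7HK);
# cross-checked against the mechanism steady-state oracle in
# test_mechanism.py.
V_STANDARD_ASSAY_UM_S = 1.8695697816582706


class TestRateLaw:
    def test_zero_substrate_gives_zero_velocity(self, reported_params):
        assert velocity_uM(reported_params, 0.0, 60.0) == 0.0
        assert velocity_uM(reported_params, 160.0, 0.0) == 0.0
        assert velocity_uM(reported_params, 0.0, 0.0) == 0.0

    def test_standard_assay_velocity(self, reported_params):
        v = velocity_uM(reported_params, 160.0, 60.0)
        assert v == pytest.approx(V_STANDARD_ASSAY_UM_S, rel=1e-12)
        assert v == pytest.approx(1.87, abs=0.005)

    def test_negative_concentration_rejected(self, reported_params):
        with pytest.raises(ValueError):
            velocity_uM(reported_params, -1.0, 60.0)

    def test_inhibition_term_matches_denominator_expansion(self, reported_params):
        """v(K_i)/v(inf) equals the denominator ratio; <1% change at 150 µM."""
        a, b = 160.0, 150.0
        v_inh = velocity_uM(reported_params, a, b)
        v_no = velocity_uM(reported_params.without_inhibition(), a, b)
        km = reported_params.km_nadph_uM
        ki_uM = reported_params.k_i_mM * 1e3
        kn, kb = reported_params.k_nadph_per_s, reported_params.k_bim_per_mM_s
        # full denominators (µM-scaled): ratio of v's is den_no/den_inh
        den_no = kn * a + kb * 1e-3 * b * (km + a)
        den_inh = kn * a + kb * 1e-3 * b * (km + a + a * b / ki_uM)
        assert v_inh / v_no == pytest.approx(den_no / den_inh, rel=1e-12)
        assert abs(v_inh / v_no - 1.0) < 0.01

    def test_monotone_increasing_in_nadph(self, reported_params):
        a = np.linspace(1.0, 500.0, 200)
        v = velocity_uM(reported_params, a, np.full_like(a, 60.0))
        assert np.all(np.diff(v) > 0)

    @given(
        ki=st.floats(1.0, 100.0),
        kb=st.floats(10.0, 5000.0),
        kn=st.floats(1.0, 100.0),
        km=st.floats(1.0, 100.0),
    )
    def test_unimodal_in_s7hk_with_finite_ki(self, ki, kb, kn, km):
        """v([7HK]) rises to a single maximum then decays toward 0."""
        p = KineticParameters.from_assay_units(99.0, kb, kn, km, ki)
        b = np.geomspace(0.1, 1e8, 400)
        v = velocity_uM(p, np.full_like(b, 100.0), b)
        d = np.diff(v)
        sign_changes = np.sum(np.diff(np.sign(d[d != 0])) != 0)
        assert sign_changes <= 1
        assert v[-1] < 0.05 * v.max()

    def test_bimolecular_limit_slope(self, reported_params):
        """dv/d[7HK] -> E0*k_bim at saturating NADPH, vanishing 7HK."""
        b = 1e-6  # µM
        v = velocity_uM(reported_params, 1e7, b)
        slope_per_uM = v / b
        expected = reported_params.e_total_mM * reported_params.k_bim_per_mM_s
        assert slope_per_uM == pytest.approx(expected, rel=1e-3)

    def test_velocity_linear_in_enzyme_total(self, reported_params):
        p2 = KineticParameters.from_assay_units(
            2 * reported_params.e_total_nM,
            reported_params.k_bim_per_mM_s,
            reported_params.k_nadph_per_s,
            reported_params.km_nadph_uM,
            reported_params.k_i_mM,
        )
        assert velocity_uM(p2, 160, 60) == pytest.approx(
            2 * velocity_uM(reported_params, 160, 60), rel=1e-12
        )

    @given(
        a=st.floats(0.1, 1000.0),
        b=st.floats(0.1, 1000.0),
    )
    def test_unit_round_trip(self, reported_params, a, b):
        """Evaluating in µM or in mM must agree to 1e-12 relative."""
        v_um = velocity_uM(reported_params, a, b)
        v_mm = velocity_mM(reported_params, a / 1e3, b / 1e3) * 1e3
        assert v_um == pytest.approx(v_mm, rel=1e-12)


class TestParameterValidation:
    @pytest.mark.parametrize("field_value", [0.0, -1.0, float("nan")])
    def test_nonpositive_parameters_rejected(self, field_value):
        with pytest.raises(ValueError):
            KineticParameters.from_assay_units(99.0, field_value, 27.0, 20.0, 22.0)

    def test_infinite_ki_is_the_no_inhibition_sentinel(self):
        p = KineticParameters.from_assay_units(99.0, 1490.0, 27.0, 20.0)
        assert p.k_i_mM == NO_INHIBITION
        assert not p.has_inhibition


class TestMacroMicroMaps:
    def test_km_nadph_from_elementary_constants(self):
        """(k_m1 + k_nadph)/k1 = (20+27)/2350 mM = 20 µM."""
        micro = MicroscopicRates(
            k1_per_mM_s=2350.0, k_m1_per_s=20.0, k_nadph_per_s=27.0,
            k2_per_mM_s=2980.0, k_m2_per_s=2700.0, k_7hk_per_s=2700.0,
            ka_per_mM_s=1.0, kd_per_s=22.0,
        )
        macro = macro_from_micro(micro, e_total_nM=99.0)
        assert macro.km_nadph_uM == pytest.approx(20.0, rel=1e-12)
        assert macro.k_i_mM == pytest.approx(22.0, rel=1e-12)

    def test_binding_limited_limit(self):
        """With k_m2 << k_7hk, k_bim -> k2."""
        micro = MicroscopicRates(
            k1_per_mM_s=1000.0, k_m1_per_s=10.0, k_nadph_per_s=27.0,
            k2_per_mM_s=500.0, k_m2_per_s=1e-9, k_7hk_per_s=2700.0,
            ka_per_mM_s=1.0, kd_per_s=22.0,
        )
        assert micro.k_bim_per_mM_s == pytest.approx(500.0, rel=1e-9)

    @pytest.mark.parametrize("commitment,excess", [(4.0, 100.0), (1.0, 10.0), (0.5, 300.0)])
    def test_macro_micro_round_trip(self, reported_params, commitment, excess):
        micro = micro_from_macro(reported_params, commitment, excess, ka_per_mM_s=2.0)
        back = macro_from_micro(micro, reported_params.e_total_nM)
        assert back.k_bim_per_mM_s == pytest.approx(reported_params.k_bim_per_mM_s, rel=1e-12)
        assert back.k_nadph_per_s == pytest.approx(reported_params.k_nadph_per_s, rel=1e-12)
        assert back.km_nadph_mM == pytest.approx(reported_params.km_nadph_mM, rel=1e-12)
        assert back.k_i_mM == pytest.approx(reported_params.k_i_mM, rel=1e-12)

    def test_defining_relations_solved_in_order(self, reported_params):
        micro = micro_from_macro(reported_params, commitment=4.0, excess=100.0)
        assert micro.k_nadph_per_s == 27.0
        assert micro.k_m1_per_s == pytest.approx(108.0)
        assert micro.k1_per_mM_s == pytest.approx((108.0 + 27.0) / 0.020)
        assert micro.k_7hk_per_s == pytest.approx(2700.0)

    def test_low_excess_warns(self, reported_params):
        with pytest.warns(UserWarning, match="excess"):
            micro_from_macro(reported_params, excess=1.0)

    def test_no_inhibition_maps_to_zero_ka(self, reported_params):
        micro = micro_from_macro(reported_params.without_inhibition())
        assert micro.ka_per_mM_s == 0.0
        assert math.isinf(macro_from_micro(micro, 99.0).k_i_mM)

    def test_invalid_free_choices_rejected(self, reported_params):
        with pytest.raises(ValueError):
            micro_from_macro(reported_params, commitment=0.0)
        with pytest.raises(ValueError):
            micro_from_macro(reported_params, excess=-1.0)
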