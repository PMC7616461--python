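"""Closed-form oxygen model: oracles, invariants and the grid search."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bhcal.oxymodel import (
    ArterialState,
    ModelConstants,
    VoxelResponse,
    arterial_o2_content,
    capillary_po2,
    cmro2_fick,
    dhb_concentration,
    m_calib,
    m_diffusion,
    oef_grid,
    severinghaus_saturation,
    solve_oef_grid,
)

C = ModelConstants()


def forward_frac_bold(oef0, cbf0, frac_cbf, arterial, c=C):
    """Independent forward oracle: frac_bold for which the calibration
    expression returns exactly m_diffusion(oef0)."""
    md = m_diffusion(oef0, cbf0, arterial.CaO2_0, arterial.Hb, c)
    cbf_ratio = 1.0 + frac_cbf
    phihb = c.phi * arterial.Hb
    num = 1.0 - (arterial.CaO2_bh / phihb) * (
        1.0 - oef0 * arterial.CaO2_0 / (cbf_ratio * arterial.CaO2_bh))
    den = 1.0 - (arterial.CaO2_0 / phihb) * (1.0 - oef0)
    braced = 1.0 - cbf_ratio ** c.alpha * (num / den) ** c.beta
    return md * braced, md


class TestSaturationAndContent:
    @pytest.mark.parametrize("pao2, expected", [
        # direct evaluation of the closed form
        (104.0, 1.0 / (23400.0 / (104.0 ** 3 + 150 * 104.0) + 1.0)),
        (127.0, 1.0 / (23400.0 / (127.0 ** 3 + 150 * 127.0) + 1.0)),
    ])
    def test_severinghaus_matches_closed_form(self, pao2, expected):
        assert severinghaus_saturation(pao2) == pytest.approx(expected, abs=1e-12)
        # frozen reference values
        assert severinghaus_saturation(104.0) == pytest.approx(0.97989, abs=1e-5)
        assert severinghaus_saturation(127.0) == pytest.approx(0.98881, abs=1e-5)

    def test_severinghaus_monotone_bounded(self):
        p = np.linspace(1, 600, 400)
        s = severinghaus_saturation(p)
        assert np.all(np.diff(s) > 0)
        assert np.all((s > 0) & (s < 1))
        assert severinghaus_saturation(1e6) == pytest.approx(1.0, abs=1e-6)

    def test_severinghaus_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            severinghaus_saturation(0.0)

    def test_content_examples(self):
        assert arterial_o2_content(15, 0.98, 100) == pytest.approx(
            15 * 1.34 * 0.98 + 0.3, abs=1e-12)
        assert arterial_o2_content(0, 0.0, 0) == 0.0
        chained = arterial_o2_content(15, severinghaus_saturation(127.0), 127.0)
        assert chained == pytest.approx(20.256, abs=1e-3)

    def test_content_linear_in_hb(self):
        sa = 0.97
        hbs = np.array([5.0, 10.0, 15.0])
        vals = arterial_o2_content(hbs, sa, 100.0)
        slopes = np.diff(vals) / np.diff(hbs)
        assert np.allclose(slopes, C.phi * sa)

    def test_content_rejects_negative(self):
        with pytest.raises(ValueError):
            arterial_o2_content(-1, 0.9, 100)


class TestDhbAndCapillaryPo2:
    def test_dhb_example(self):
        assert dhb_concentration(20.256, 15.0, 0.37) == pytest.approx(
            (1 - (20.256 / (1.34 * 15)) * 0.63) * 15, abs=1e-12)

    def test_dhb_limits(self):
        # full extraction: all haemoglobin deoxygenated
        assert dhb_concentration(20.0, 15.0, 0.999) == pytest.approx(15.0, rel=1e-2)
        # no arterial O2, no extraction: still fully deoxygenated
        assert dhb_concentration(0.0, 15.0, 0.0) == 15.0

    def test_dhb_monotone_in_oef(self):
        oefs = np.linspace(0.05, 0.95, 50)
        vals = dhb_concentration(20.0, 15.0, oefs)
        assert np.all(np.diff(vals) > 0)

    def test_capillary_po2_values(self):
        assert capillary_po2(0.37) == pytest.approx(
            26.0 * (2 / 0.37 - 1) ** (1 / 2.84), abs=1e-12)
        assert capillary_po2(1.0) == pytest.approx(26.0, abs=1e-12)
        assert capillary_po2(0.5) == pytest.approx(
            26.0 * 3 ** (1 / 2.84), abs=1e-12)

    def test_capillary_po2_decreasing(self):
        oefs = np.linspace(0.05, 1.0, 60)
        vals = capillary_po2(oefs)
        assert np.all(np.diff(vals) < 0)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            capillary_po2(0.0)
        with pytest.raises(ValueError):
            dhb_concentration(20.0, 0.0, 0.3)


class TestMaximumBoldExpressions:
    def test_m_diffusion_gm_typical(self, arterial):
        """Hand-arithmetic oracle for the grey-matter typical operating
        point (OEF 0.37, CBF 54, Hb 15); the result sits at ~10%,
        consistent with healthy grey matter."""
        cao2 = 15 * 1.34 * severinghaus_saturation(127.0) + 127 * 0.003
        consumption = 0.37 * (54 / 100) * (cao2 / 100 * 44.64)
        dhb = (1 - cao2 / (1.34 * 15) * 0.63) * 15
        po2c = 26.0 * (2 / 0.37 - 1) ** (1 / 2.84)
        oracle = 0.030 * 8.85 * consumption * dhb ** 1.3 / po2c
        got = m_diffusion(0.37, 54.0, arterial.CaO2_0, 15.0)
        assert got == pytest.approx(oracle, abs=1e-12)
        assert got == pytest.approx(0.0998, abs=1e-4)

    def test_m_diffusion_limits_and_monotonicity(self, arterial):
        # vanishes as oef -> 0 (evaluated just above the dissolved-O2
        # floor where the deoxyhaemoglobin term stays positive)
        small = m_diffusion(0.01, 54.0, arterial.CaO2_0, 15.0)
        assert 0 < small < 1e-4
        for hb in (8.0, 12.0, 15.0, 18.0):
            art = ArterialState.from_physiology(hb)
            for cbf in (20.0, 60.0, 100.0):
                vals = m_diffusion(oef_grid()[30:-1], cbf, art.CaO2_0, hb)
                assert np.all(np.diff(vals) > 0)

    def test_m_diffusion_independent_arithmetic_point(self):
        """Second operating point against step-by-step arithmetic."""
        art = ArterialState.from_physiology(14.0)
        sa = severinghaus_saturation(127.0)
        cao2 = 14 * 1.34 * sa + 0.381
        expected = (0.030 * 8.85
                    * (0.5 * 0.60 * cao2 * 0.4464)
                    * ((1 - cao2 / (1.34 * 14) * 0.5) * 14) ** 1.3
                    / (26 * 3 ** (1 / 2.84)))
        assert m_diffusion(0.5, 60.0, art.CaO2_0, 14.0) == pytest.approx(
            expected, rel=1e-12)

    def test_m_calib_zero_response(self, arterial):
        assert m_calib(0.0, 1.12, arterial.CaO2_bh, arterial.CaO2_0,
                       15.0, 0.37) == 0.0

    @pytest.mark.parametrize("oef0, cbf0, frac_cbf, hb", [
        (0.37, 54.0, 0.12, 15.0),
        (0.50, 60.0, 0.20, 13.0),
        (0.25, 40.0, 0.08, 16.0),
    ])
    def test_m_calib_forward_then_invert(self, oef0, cbf0, frac_cbf, hb):
        art = ArterialState.from_physiology(hb)
        fb, md = forward_frac_bold(oef0, cbf0, frac_cbf, art)
        got = m_calib(fb, 1.0 + frac_cbf, art.CaO2_bh, art.CaO2_0, hb, oef0)
        assert got == pytest.approx(md, rel=1e-12)

    def test_m_calib_inconsistent_never_raises(self, arterial):
        # a positive BOLD response inconsistent with the assumed
        # oef/flow pair yields a non-physical (non-positive) or
        # undefined M, never an exception; the grid solver drops it
        got = m_calib(0.01, 1.0001, arterial.CaO2_bh, arterial.CaO2_0,
                      15.0, 0.9)
        assert np.isnan(got) or got <= 0
        sol = solve_oef_grid(
            VoxelResponse(cbf0=54.0, frac_cbf=0.0001, frac_bold=0.2),
            arterial)
        assert isinstance(sol.valid, bool)


class TestGridSearch:
    def test_grid_cardinality_and_spacing(self):
        g = oef_grid()
        assert g.size == 1000
        assert g[0] == pytest.approx(0.001)
        assert g[-1] == pytest.approx(1.0)
        assert np.allclose(np.diff(g), 0.001)

    @pytest.mark.parametrize("oef_true", [0.25, 0.37, 0.55])
    def test_roundtrip_exact_on_grid(self, oef_true, arterial):
        fb, md = forward_frac_bold(oef_true, 54.0, 0.12, arterial)
        sol = solve_oef_grid(
            VoxelResponse(cbf0=54.0, frac_cbf=0.12, frac_bold=fb), arterial)
        assert sol.valid
        assert sol.oef0 == oef_true
        assert sol.M == pytest.approx(md, rel=1e-9)
        assert sol.residual == pytest.approx(0.0, abs=1e-12)

    def test_off_grid_truth_lands_on_neighbour(self, arterial):
        fb, _ = forward_frac_bold(0.2505, 54.0, 0.12, arterial)
        sol = solve_oef_grid(
            VoxelResponse(cbf0=54.0, frac_cbf=0.12, frac_bold=fb), arterial)
        assert sol.oef0 in (0.250, 0.251)

    def test_no_vasodilation_invalid(self, arterial):
        sol = solve_oef_grid(
            VoxelResponse(cbf0=54.0, frac_cbf=-0.05, frac_bold=0.005),
            arterial)
        assert not sol.valid

    def test_nonfinite_inputs_invalid_not_raising(self, arterial):
        sol = solve_oef_grid(
            VoxelResponse(cbf0=np.nan, frac_cbf=0.1, frac_bold=0.005),
            arterial)
        assert not sol.valid

    def test_single_sign_change_of_difference(self, arterial):
        """m_calib - m_diffusion crosses zero exactly once for
        forward-generated physiologic responses (unique grid solution)."""
        grid = oef_grid()[:-1]
        for oef_true in (0.2, 0.37, 0.6):
            fb, _ = forward_frac_bold(oef_true, 54.0, 0.12, arterial)
            mc = m_calib(fb, 1.12, arterial.CaO2_bh, arterial.CaO2_0,
                         15.0, grid)
            md = m_diffusion(grid, 54.0, arterial.CaO2_0, 15.0)
            diff = mc - md
            # candidate region: both expressions defined and positive
            ok = np.isfinite(diff) & (mc > 0)
            signs = np.sign(diff[ok])
            signs = signs[signs != 0]  # an exact root is the crossing
            changes = np.sum(np.diff(signs) != 0)
            assert changes == 1


class TestFick:
    def test_examples(self):
        assert cmro2_fick(20.0, 0.37, 54.0) == pytest.approx(
            0.37 * 0.54 * (0.20 * 44.64) * 100, rel=1e-12)
        assert cmro2_fick(20.0, 0.0, 54.0) == 0.0
        cao2 = 12 * 1.34 * 0.98
        assert cmro2_fick(cao2, 0.37, 54.0) == pytest.approx(140.5, abs=0.1)

    def test_scaling_conservation(self):
        base = cmro2_fick(20.0, 0.37, 54.0)
        assert cmro2_fick(20.0, 0.37, 54.0 * 3) == pytest.approx(3 * base)

    def test_rejects_negative(self):
        with pytest.raises(ValueError):
            cmro2_fick(-1.0, 0.3, 50.0)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    oef=st.floats(0.1, 0.8),
    cbf=st.floats(25.0, 90.0),
    frac=st.floats(0.03, 0.3),
    hb=st.floats(10.0, 18.0),
)
def test_roundtrip_property(oef, cbf, frac, hb):
    """Any on-grid OEF forward-generated through the calibration
    expression is recovered exactly by the grid search."""
    oef = round(oef, 3)
    art = ArterialState.from_physiology(hb)
    fb, _ = forward_frac_bold(oef, cbf, frac, art)
    sol = solve_oef_grid(
        VoxelResponse(cbf0=cbf, frac_cbf=frac, frac_bold=fb), art)
    assert sol.valid
    assert sol.oef0 == pytest.approx(oef, abs=1e-12)
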