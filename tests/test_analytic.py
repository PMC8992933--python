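"""Algebraic estimation methodology: worked numbers and structural limits."""
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from skyshine.analytic import (SkyshineScenario, akr_estimate,
                               bxs_for_background_akr,
                               bxs_for_high_radiation_area,
                               bxs_for_weekly_rooftop_limit, bxs_from_tvl,
                               classify_roof, d_max, geometry_factor,
                               k_for_mv, max_akr, max_weekly_dose,
                               rooftop_doses, tvl_for_mv, weekly_dose)


class TestGeometryFactor:
    def test_closed_form_values(self):
        assert geometry_factor(0.0) == pytest.approx(2.0)
        assert geometry_factor(0.5) == pytest.approx(1.0451, abs=2e-4)
        # asymptotically g(x) -> 3/(4x)
        assert geometry_factor(10.0) == pytest.approx(3.0 / 40.0, rel=5e-3)
        assert geometry_factor(100.0) < 0.008

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            geometry_factor(-0.1)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.floats(0.0, 20.0), st.floats(1e-6, 1.0))
    def test_strictly_decreasing_and_bounded(self, x, dx):
        g1, g2 = geometry_factor(x), geometry_factor(x + dx)
        assert 0.0 < g1 <= 2.0
        assert g2 < g1


class TestDMax:
    def test_nominal_vault(self):
        assert d_max(5.0, 3.0) == pytest.approx(10.8)

    def test_warns_at_validity_boundary(self):
        with pytest.warns(UserWarning):
            assert d_max(10.0, 3.0) == pytest.approx(18.3)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            d_max(0.0, 3.0)

    def test_matches_profile_argmax_within_ten_percent(self):
        """The linear fit locates the true maximum of the AKR profile to
        better than 10% across the stated validity range h/d_w in (0.3, 1.2)."""
        for d_w in np.linspace(3.0, 12.0, 5):
            for ratio in np.linspace(0.35, 1.15, 4):
                h = ratio * d_w
                scn = SkyshineScenario(k=100.0, d_w=d_w, h=h)
                ds_true, _ = max_akr(scn)
                assert abs(d_max(d_w, h) - ds_true) / ds_true < 0.10


class TestAkrEstimate:
    def test_linearity_in_bxs_and_monotone_tail(self):
        scn = SkyshineScenario(k=85.0, d_w=5.0, h=3.0, b_xs=0.5)
        a = akr_estimate(scn, 12.0)
        assert akr_estimate(scn.with_(b_xs=1.0), 12.0) == pytest.approx(2 * a)
        # beyond the peak the profile decays like 1/d_s (g -> 2)
        vals = [akr_estimate(scn, d) for d in (15.0, 60.0, 240.0, 960.0)]
        assert all(x > y for x, y in zip(vals, vals[1:]))
        assert vals[-1] < 0.05 * vals[0]

    def test_undefined_in_wall_shadow(self):
        scn = SkyshineScenario(k=85.0, d_w=5.0, h=3.0)
        with pytest.raises(ValueError):
            akr_estimate(scn, 5.0)

    def test_background_matching_transmission_18mv(self):
        """B_xs ~ 5.8e-4 keeps the peak below 0.1 uSv/hr at 18 MV."""
        scn = SkyshineScenario(k=85.0, d_w=5.0, h=3.0, f0=1600.0, d0_rate=600.0)
        bxs = bxs_for_background_akr(scn, 0.1)
        assert bxs == pytest.approx(5.8e-4, rel=0.10)
        _, akr = max_akr(scn.with_(b_xs=bxs))
        assert akr * 3.6 == pytest.approx(0.1, rel=1e-6)  # nSv/s -> uSv/hr

    def test_background_matching_transmission_4mv(self):
        scn = SkyshineScenario(k=150.0, d_w=5.0, h=3.0, f0=1600.0, d0_rate=600.0)
        assert bxs_for_background_akr(scn, 0.1) == pytest.approx(3.3e-4, rel=0.10)


class TestWeeklyDose:
    def test_worst_case_no_roof(self):
        """4 MV, W_p = 500 Gy, U = 0.25, T = 1, open roof -> ~110 uSv/wk."""
        scn = SkyshineScenario(k=150.0, d_w=5.0, h=3.0, f0=1600.0, b_xs=1.0,
                               w_p=500.0, use_factor=0.25, occupancy=1.0)
        _, hs = max_weekly_dose(scn)
        assert hs == pytest.approx(110.0, rel=0.10)

    def test_worst_case_low_occupancy(self):
        scn = SkyshineScenario(k=150.0, d_w=5.0, h=3.0, f0=1600.0, b_xs=1.0,
                               w_p=500.0, use_factor=0.25, occupancy=1 / 20)
        _, hs = max_weekly_dose(scn)
        assert hs == pytest.approx(5.5, rel=0.10)

    def test_occupancy_shielded_roof_coefficient(self):
        """Roof shielded for occupancy (20 uSv/wk budget, T_r = 1/20):
        max H_s = 5.7e-5 k uSv/wk -> 0.009 at 4 MV, 0.005 at 18 MV."""
        # (W_p U T_r) B_xs = 2e-5 (h+2)^2 and T_r = 1/20 => W_p U B_xs = 0.01
        base = SkyshineScenario(k=1.0, d_w=5.0, h=3.0, f0=1600.0, b_xs=1.0,
                                w_p=0.01, use_factor=1.0, occupancy=1.0)
        _, coeff = max_weekly_dose(base)
        assert coeff == pytest.approx(5.7e-5, rel=0.05)
        _, hs4 = max_weekly_dose(base.with_(k=150.0))
        _, hs18 = max_weekly_dose(base.with_(k=85.0))
        assert hs4 == pytest.approx(0.009, rel=0.10)
        assert hs18 == pytest.approx(0.005, rel=0.10)

    def test_high_radiation_area_coefficient(self):
        """Roof shielded against the 1 mSv-in-an-hour designation:
        max H_s = 5.7e-3 k T uSv/wk."""
        # W_p U B_xs = 4e-2 (h+2)^2 = 1.0 for h = 3
        scn = SkyshineScenario(k=1.0, d_w=5.0, h=3.0, f0=1600.0, b_xs=1.0,
                               w_p=1.0, use_factor=1.0, occupancy=1.0)
        _, coeff = max_weekly_dose(scn)
        assert coeff == pytest.approx(5.7e-3, rel=0.05)

    def test_profile_shape_matches_akr(self):
        scn = SkyshineScenario(k=100.0, d_w=5.0, h=3.0, w_p=500.0)
        r = weekly_dose(scn, 12.0) / weekly_dose(scn, 20.0)
        assert r == pytest.approx(akr_estimate(scn, 12.0)
                                  / akr_estimate(scn, 20.0), rel=1e-9)


class TestRoofTransmission:
    def test_tvl_definition(self):
        assert bxs_from_tvl(0.0, 35.0, 30.0) == 1.0
        assert bxs_from_tvl(35.0, 35.0, 30.0) == pytest.approx(0.1)
        assert bxs_from_tvl(35.0 + 60.0, 35.0, 30.0) == pytest.approx(1e-3)

    def test_negative_thickness_rejected(self):
        with pytest.raises(ValueError):
            bxs_from_tvl(-1.0, 35.0, 30.0)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.floats(0.0, 200.0), st.floats(0.0, 200.0))
    def test_monotone_in_thickness(self, t1, t2):
        lo, hi = sorted((t1, t2))
        assert bxs_from_tvl(hi, 45.0, 43.0) <= bxs_from_tvl(lo, 45.0, 43.0)

    def test_paper_thickness_anchors(self):
        """With the bundled concrete TVLs, the background-matching
        transmissions correspond to ~140 cm (18 MV) and ~110 cm (4 MV)."""
        from scipy.optimize import brentq
        tvl1, tvle = tvl_for_mv(18)
        t18 = brentq(lambda t: bxs_from_tvl(t, tvl1, tvle) - 5.8e-4, 0, 300)
        assert t18 == pytest.approx(140.0, rel=0.03)
        tvl1, tvle = tvl_for_mv(4)
        t4 = brentq(lambda t: bxs_from_tvl(t, tvl1, tvle) - 3.3e-4, 0, 300)
        assert t4 == pytest.approx(110.0, rel=0.03)


class TestRooftopDoses:
    def test_occupancy_criterion_algebra(self):
        # H_w,r = B_xs (W_p U T_r)/(h+2)^2 = 2e-5 => (W_p U T_r)B_xs = 2e-5(h+2)^2
        scn = SkyshineScenario(k=100.0, d_w=5.0, h=3.0, w_p=500.0,
                               use_factor=0.25, roof_occupancy=1 / 20,
                               b_xs=5e-4 / (500.0 * 0.25 * (1 / 20)))
        assert rooftop_doses(scn)["weekly_Sv"] == pytest.approx(2.0e-5)
        assert (bxs_for_weekly_rooftop_limit(scn) * 500.0 * 0.25 * (1 / 20)
                == pytest.approx(2e-5 * 25.0))

    def test_high_radiation_area_criterion_algebra(self):
        scn = SkyshineScenario(k=100.0, d_w=5.0, h=3.0, w_p=500.0,
                               use_factor=0.25)
        bxs = bxs_for_high_radiation_area(scn)
        assert bxs * 500.0 * 0.25 == pytest.approx(4e-2 * 25.0)
        assert rooftop_doses(scn.with_(b_xs=bxs))["hourly_Sv"] == \
            pytest.approx(1e-3)


class TestClassifyRoof:
    def test_zero_thickness_is_thin(self):
        r = classify_roof(0.0, 35.0)
        assert r["label"] == "thin" and r["mu_bar_t_r"] == 0.0
        assert "lowest MV" in r["advisory"]

    def test_mu_bar_definition_and_thick_label(self):
        r = classify_roof(92.0, 45.0)
        assert r["mu_bar_per_cm"] == pytest.approx(math.log(10) / 45.0)
        assert r["label"] == "thick"
        assert "highest MV" in r["advisory"]

    def test_mid_range_advisory(self):
        assert "independent" in classify_roof(40.0, 41.0)["advisory"]


class TestKTable:
    def test_tabulated_points(self):
        assert k_for_mv(4) == 150.0 and k_for_mv(18) == 85.0

    def test_interpolation_between_points(self):
        assert 100.0 < k_for_mv(8) < 140.0

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            k_for_mv(25)

    def test_for_mv_builder_applies_tvls(self):
        scn = SkyshineScenario.for_mv(18, t_r_cm=45.0)
        assert scn.k == 85.0
        assert scn.b_xs == pytest.approx(0.1)
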