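"""Dose predictors: scatter model, NCRP-style formula, compliance audits."""

import math

import numpy as np
import pytest

from skyshine import (
    BeamSpec,
    CalibrationConstant,
    DEFAULT_K,
    RoofShield,
    Scenario,
    VaultGeometry,
    facility_fixtures,
    find_dmax,
    ncrp151_rate,
    required_roof_transmission,
    roof_hourly_dose,
    scale_profile,
    skyshine_rate,
    total_weekly,
    wall_leakage_weekly,
    weekly_skyshine,
)


class TestSkyshineRate:
    def test_vanishes_at_the_wall(self, elder_beam_6mv, elder_geom, k6):
        rate = skyshine_rate(elder_geom.d_w + 1e-6, elder_beam_6mv, elder_geom, RoofShield(1.0), k6)
        assert 0 < rate < 1e-3

    def test_elder_worked_value(self, elder_beam_6mv, elder_geom, k6):
        # k=312, F0=1600, D0=600, B_xs=0.027, d_s=10.8 m -> ~4.53 nSv/s
        rate = skyshine_rate(10.8, elder_beam_6mv, elder_geom, RoofShield(0.027), k6)
        assert rate == pytest.approx(4.53, abs=0.01)

    def test_linear_in_field_area(self, elder_geom, k6, open_roof):
        b1 = BeamSpec(nominal_mv=6, field_area_f0=800.0, dose_rate_d0=600.0)
        b2 = BeamSpec(nominal_mv=6, field_area_f0=1600.0, dose_rate_d0=600.0)
        r1 = skyshine_rate(12.0, b1, elder_geom, open_roof, k6)
        r2 = skyshine_rate(12.0, b2, elder_geom, open_roof, k6)
        assert r2 == pytest.approx(2.0 * r1, rel=1e-12)

    def test_linear_in_transmission_and_dose_rate(self, elder_geom, k6):
        beam = BeamSpec(nominal_mv=6, field_area_f0=1600.0, dose_rate_d0=300.0)
        beam2 = BeamSpec(nominal_mv=6, field_area_f0=1600.0, dose_rate_d0=600.0)
        assert skyshine_rate(12.0, beam, elder_geom, RoofShield(0.5), k6) == pytest.approx(
            0.25 * skyshine_rate(12.0, beam2, elder_geom, RoofShield(1.0), k6), rel=1e-12
        )

    def test_shadow_boundary_rejected(self, elder_beam_6mv, elder_geom, k6, open_roof):
        with pytest.raises(ValueError, match="shadow"):
            skyshine_rate(4.5, elder_beam_6mv, elder_geom, open_roof, k6)

    def test_warns_beyond_attenuation_validity(self, elder_beam_6mv, elder_geom, k6, open_roof):
        with pytest.warns(UserWarning, match="attenuation"):
            skyshine_rate(150.0, elder_beam_6mv, elder_geom, open_roof, k6)

    def test_six_vs_eighteen_mv_ratio_is_k_ratio(self, elder_geom, open_roof):
        # equal F0, D0, B_xs: the only energy dependence left is k
        beam = BeamSpec(nominal_mv=6, field_area_f0=1600.0, dose_rate_d0=400.0)
        for d_s in (6.0, 12.0, 30.0):
            r6 = skyshine_rate(d_s, beam, elder_geom, open_roof, DEFAULT_K[6])
            r18 = skyshine_rate(d_s, beam, elder_geom, open_roof, DEFAULT_K[18])
            assert r6 / r18 == pytest.approx(312.0 / 160.0, rel=1e-12)

    def test_far_field_one_over_ds(self, elder_beam_6mv, elder_geom, k6, open_roof):
        # d_s * rate -> 2 k (F0/400)(D0/400) B_xs
        d_s = 1e5 * (elder_geom.d_w + elder_geom.h)
        with pytest.warns(UserWarning):
            rate = skyshine_rate(d_s, elder_beam_6mv, elder_geom, open_roof, k6)
        expected = 2.0 * k6.k * (1600.0 / 400.0) * (600.0 / 400.0)
        assert d_s * rate == pytest.approx(expected, rel=1e-3)

    def test_single_interior_maximum_every_facility(self):
        for preset in facility_fixtures():
            g = preset.geometry
            grid = np.linspace(g.d_w + 0.01 * g.h, g.d_w + 20 * g.h, 3000)
            vals = np.array(
                [skyshine_rate(d, preset.beam, g, preset.roof, preset.k) for d in grid]
            )
            signs = np.sign(np.diff(vals))
            changes = np.sum(np.abs(np.diff(signs[signs != 0])) > 0)
            assert changes == 1, preset.name


class TestWeeklySkyshine:
    def test_worst_case_peak_near_ten(self, nominal_geom, worst_case_scenario, open_roof, k6):
        dose = weekly_skyshine(12.0, worst_case_scenario, 1600.0, nominal_geom, open_roof, k6)
        assert dose == pytest.approx(9.44, abs=0.03)

    def test_zero_occupancy_zero_dose(self, nominal_geom, open_roof, k6, worst_case_scenario):
        tiny = Scenario(workload_w=500.0, use_factor_u=0.25, occupancy_t=1e-12)
        ref = weekly_skyshine(12.0, worst_case_scenario, 1600.0, nominal_geom, open_roof, k6)
        small = weekly_skyshine(12.0, tiny, 1600.0, nominal_geom, open_roof, k6)
        assert small == pytest.approx(ref * 1e-12 / (1.0 / 20.0), rel=1e-9)

    def test_shielded_roof_peak(self, nominal_geom, worst_case_scenario, k6):
        # B_xs = 0.018 scales the ~9.44 peak to ~0.17 uSv/week
        d = find_dmax(nominal_geom)
        dose = weekly_skyshine(d, worst_case_scenario, 1600.0, nominal_geom, RoofShield(0.018), k6)
        assert dose == pytest.approx(9.44 * 0.018, abs=0.005)

    def test_unit_conversion_identity_with_rate(self, k6):
        # weekly == rate * 6000 W U T / (1000 D0): pins the 1.5e-2 constant
        rng = np.random.default_rng(42)
        for _ in range(100):
            geom = VaultGeometry(d_w=rng.uniform(2, 8), h=rng.uniform(1, 6))
            d_s = geom.d_w + rng.uniform(0.5, 50)
            f0 = rng.uniform(100, 1600)
            d0 = rng.uniform(100, 800)
            b = RoofShield(rng.uniform(0.01, 1.0))
            scen = Scenario(
                workload_w=rng.uniform(100, 1000),
                use_factor_u=rng.uniform(0.05, 1.0),
                occupancy_t=rng.uniform(0.01, 1.0),
            )
            beam = BeamSpec(nominal_mv=6, field_area_f0=f0, dose_rate_d0=d0)
            weekly = weekly_skyshine(d_s, scen, f0, geom, b, k6)
            rate = skyshine_rate(d_s, beam, geom, b, k6)
            expected = rate * 6000.0 * scen.workload_w * scen.use_factor_u * scen.occupancy_t / (
                1000.0 * d0
            )
            assert weekly == pytest.approx(expected, rel=1e-12)


class TestNcrp151:
    def test_field_area_ratio_follows_omega_power(self):
        # (Omega_40/Omega_10)^1.3 = 16^1.3 ~ 36.8 with small-field Omega
        g = VaultGeometry(d_w=5.0, h=3.0, d_i=6.0)
        r = RoofShield(1.0)
        b40 = BeamSpec(nominal_mv=6, field_area_f0=1600.0, dose_rate_d0=400.0)
        b10 = BeamSpec(nominal_mv=6, field_area_f0=100.0, dose_rate_d0=400.0)
        r40 = ncrp151_rate(20.0, b40, g, r, exact_solid_angle=False)
        r10 = ncrp151_rate(20.0, b10, g, r, exact_solid_angle=False)
        assert r40 / r10 == pytest.approx(16.0**1.3, rel=1e-9)

    def test_worked_value(self):
        # B_xs=1, D0=400 cGy/min=240 Gy/h, 40x40, d_i=6, d_s=10 -> ~1.46e5 nSv/h
        g = VaultGeometry(d_w=5.0, h=3.0, d_i=6.0)
        beam = BeamSpec(nominal_mv=6, field_area_f0=1600.0, dose_rate_d0=400.0)
        rate = ncrp151_rate(10.0, beam, g, RoofShield(1.0))
        assert rate == pytest.approx(1.46e5, rel=0.005)

    def test_inverse_square_in_distance(self):
        g = VaultGeometry(d_w=5.0, h=3.0, d_i=6.0)
        beam = BeamSpec(nominal_mv=6, field_area_f0=1600.0, dose_rate_d0=400.0)
        r1 = ncrp151_rate(10.0, beam, g, RoofShield(1.0))
        r2 = ncrp151_rate(20.0, beam, g, RoofShield(1.0))
        assert r1 / r2 == pytest.approx(4.0, rel=1e-12)

    def test_per_second_conversion(self):
        g = VaultGeometry(d_w=5.0, h=3.0, d_i=6.0)
        beam = BeamSpec(nominal_mv=6, field_area_f0=1600.0, dose_rate_d0=400.0)
        hourly = ncrp151_rate(10.0, beam, g, RoofShield(1.0))
        per_s = ncrp151_rate(10.0, beam, g, RoofShield(1.0), per_second=True)
        assert per_s == pytest.approx(hourly / 3600.0, rel=1e-12)


class TestWallLeakage:
    def test_primary_worked_value(self, worst_case_scenario):
        geom = VaultGeometry(d_w=5.0, h=4.0)
        # P (6.3/10)^2 = 3.969
        assert wall_leakage_weekly(9.0, worst_case_scenario, geom) == pytest.approx(3.969)

    def test_primary_reference_point(self, worst_case_scenario):
        geom = VaultGeometry(d_w=5.0, h=4.0)
        # d_s + 1 = d_w + 1.3 recovers the design goal exactly
        assert wall_leakage_weekly(5.3, worst_case_scenario, geom) == pytest.approx(10.0)

    def test_secondary_reference_point(self):
        geom = VaultGeometry(d_w=5.0, h=4.0)
        scen = Scenario(
            workload_w=500.0, use_factor_u=0.25, occupancy_t=0.05, wall_type="secondary"
        )
        assert wall_leakage_weekly(5.3, scen, geom) == pytest.approx(10.0)


class TestTotalWeekly:
    def test_breakdown_sums(self, nominal_geom, worst_case_scenario, open_roof, k6):
        res = total_weekly(9.0, worst_case_scenario, 1600.0, nominal_geom, open_roof, k6)
        assert res.value == pytest.approx(res.skyshine + res.wall_leakage, rel=1e-12)
        assert res.units == "uSv/week"

    def test_worst_case_four_meters_beyond_wall(
        self, nominal_geom, worst_case_scenario, open_roof, k6
    ):
        # paper: "about 13 uSv at about 4 m from the side wall"
        res = total_weekly(9.0, worst_case_scenario, 1600.0, nominal_geom, open_roof, k6)
        assert res.value == pytest.approx(12.5, abs=0.1)

    def test_worst_case_at_dmax(self, nominal_geom, worst_case_scenario, open_roof, k6):
        # paper: "about 12 uSv" at d_max
        d = find_dmax(nominal_geom)
        res = total_weekly(d, worst_case_scenario, 1600.0, nominal_geom, open_roof, k6)
        assert res.value == pytest.approx(11.7, abs=0.1)

    def test_opaque_roof_leaves_leakage_only(self, nominal_geom, worst_case_scenario, k6):
        res = total_weekly(
            9.0, worst_case_scenario, 1600.0, nominal_geom, RoofShield(1e-12), k6
        )
        assert res.skyshine < 1e-9
        assert res.value == pytest.approx(res.wall_leakage, rel=1e-6)


class TestRoofCompliance:
    def test_unshielded_hourly_dose(self, nominal_geom, worst_case_scenario, open_roof):
        # W_h=800 cGy, U=0.25, h=4: 800*0.25/36 cGy = 5555.6 mrem
        dose = roof_hourly_dose(worst_case_scenario, nominal_geom, open_roof)
        assert dose == pytest.approx(5555.56, abs=0.1)

    def test_required_transmission_for_high_radiation_limit(
        self, nominal_geom, worst_case_scenario
    ):
        b = required_roof_transmission(100.0, worst_case_scenario, nominal_geom)
        assert b == pytest.approx(0.018, abs=0.0005)

    def test_limit_at_unshielded_dose_gives_unity(self, nominal_geom, worst_case_scenario):
        unshielded = roof_hourly_dose(worst_case_scenario, nominal_geom, RoofShield(1.0))
        assert required_roof_transmission(unshielded, worst_case_scenario, nominal_geom) == 1.0

    def test_taller_vault_allows_more_transmission(self, worst_case_scenario):
        b4 = required_roof_transmission(100.0, worst_case_scenario, VaultGeometry(d_w=5, h=4))
        b10 = required_roof_transmission(100.0, worst_case_scenario, VaultGeometry(d_w=5, h=10))
        assert b10 > b4

    def test_inverse_square_in_height(self, worst_case_scenario, open_roof):
        d4 = roof_hourly_dose(worst_case_scenario, VaultGeometry(d_w=5, h=4), open_roof)
        d10 = roof_hourly_dose(worst_case_scenario, VaultGeometry(d_w=5, h=10), open_roof)
        assert d4 / d10 == pytest.approx((12.0 / 6.0) ** 2, rel=1e-12)


class TestFindDmax:
    def test_nominal_vault(self, nominal_geom):
        d = find_dmax(nominal_geom)
        assert d == pytest.approx(12.15, abs=0.05)
        assert (d - nominal_geom.d_w) / nominal_geom.h == pytest.approx(1.79, abs=0.02)

    def test_elder_vault_ratio(self, elder_geom):
        d = find_dmax(elder_geom)
        assert (d - elder_geom.d_w) / elder_geom.h == pytest.approx(1.8, abs=0.05)

    def test_scale_invariance(self, nominal_geom):
        d1 = find_dmax(nominal_geom)
        d10 = find_dmax(VaultGeometry(d_w=10 * nominal_geom.d_w, h=10 * nominal_geom.h))
        assert d10 == pytest.approx(10 * d1, rel=1e-3)

    def test_is_the_argmax_of_the_rate(self, nominal_geom, elder_beam_6mv, open_roof, k6):
        d = find_dmax(nominal_geom)
        peak = skyshine_rate(d, elder_beam_6mv, nominal_geom, open_roof, k6)
        for eps in (-0.5, 0.5):
            assert skyshine_rate(d + eps, elder_beam_6mv, nominal_geom, open_roof, k6) < peak


class TestScaleProfile:
    def test_identity_scaling(self):
        assert scale_profile(7.7, d0=1.0, b_xs=1.0, f0=100.0) == pytest.approx(7.7)

    def test_worked_value(self):
        # 4.53 / (600 * 0.027 * 16) = 0.01748
        assert scale_profile(4.53, d0=600.0, b_xs=0.027, f0=1600.0) == pytest.approx(
            0.01748, abs=1e-5
        )

    def test_round_trip(self):
        vals = np.array([1.0, 2.5, 7.3])
        scaled = scale_profile(vals, d0=600.0, b_xs=0.027, f0=1600.0)
        back = scale_profile(scaled, d0=600.0, b_xs=0.027, f0=1600.0, invert=True)
        assert np.allclose(back, vals, rtol=1e-12)

    def test_nonpositive_factors_rejected(self):
        with pytest.raises(ValueError):
            scale_profile(1.0, d0=0.0, b_xs=1.0, f0=100.0)


class TestValidation:
    def test_roof_transmission_bounds(self):
        for bad in (0.0, -0.5, 1.5):
            with pytest.raises(ValueError):
                RoofShield(bad)

    def test_calibration_constant_positive(self):
        with pytest.raises(ValueError):
            CalibrationConstant(-1.0)

    def test_default_k_values(self):
        assert {mv: c.k for mv, c in DEFAULT_K.items()} == {6: 312.0, 10: 200.0, 18: 160.0}

    def test_scenario_factor_bounds(self):
        with pytest.raises(ValueError):
            Scenario(workload_w=500.0, use_factor_u=1.5, occupancy_t=0.05)
        with pytest.raises(ValueError):
            Scenario(workload_w=-1.0, use_factor_u=0.25, occupancy_t=0.05)
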