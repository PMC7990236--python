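"""Nitrogen flux operators: frozen arithmetic examples and sign structure."""

import numpy as np
import pytest

import nitroshed as ns
from nitroshed import fluxes as fx
from nitroshed.params import DepositionParams, derived_don_dry_rate, derived_don_wet_concentration


@pytest.fixture
def lt():
    return ns.EAST_RIVER["LT"]


class TestSoilTemperatureFactor:
    @pytest.mark.parametrize(
        "t_soil,expected",
        [(5.0, 1.0), (7.0, 12.0), (3.0, 1.0 / 12.0), (9.0, 144.0)],
    )
    def test_reference_points(self, t_soil, expected):
        assert fx.soil_temperature_factor(t_soil) == pytest.approx(expected)

    def test_warns_on_extreme_amplification(self):
        with pytest.warns(RuntimeWarning):
            fx.soil_temperature_factor(20.0)  # 12**7.5 ~ 1.3e8


class TestLandcoverWeightedRate:
    def test_no_cover_no_rate(self):
        k = fx.landcover_weighted_rate(
            {"df": 1.0, "cf": 1.0, "ms": 1.0, "ww": 1.0},
            {"df": 0.0, "cf": 0.0, "ms": 0.0, "ww": 0.0},
            alpha=1.0,
        )
        assert k == 0.0

    def test_single_cover_identity(self):
        k = fx.landcover_weighted_rate(
            {"df": 0.0, "cf": 0.0, "ms": 0.05, "ww": 0.0},
            {"df": 0.0, "cf": 0.0, "ms": 1.0, "ww": 0.0},
            alpha=1.0,
        )
        assert k == pytest.approx(0.05)

    def test_lt_nitrification_weighting_by_hand(self, lt):
        # C2 nitrification rates over LT's cover mix at alpha = 1:
        # 0.05*(0.330 + 0.135 + 0.422) + 0.09*0.075 = 0.05110 day^-1
        scenario = ns.load_scenario("C2")
        k = fx.landcover_weighted_rate(
            scenario.vadose_rates.k_nit, lt.cover_fractions, alpha=1.0
        )
        assert k == pytest.approx(0.05110)

    def test_no_area_factor(self, lt):
        # the weighted rate multiplies a pool mass, so it must be area-free:
        # scaling the watershed area cannot change it
        bigger = ns.SubWatershedDescriptor(
            "LT2", lt.area * 10, lt.frac_deciduous, lt.frac_coniferous,
            lt.frac_meadow, lt.frac_willow, lt.mancos_fraction, None,
        )
        scenario = ns.load_scenario("C2")
        k1 = fx.landcover_weighted_rate(scenario.vadose_rates.k_nit, lt.cover_fractions, 1.0)
        k2 = fx.landcover_weighted_rate(scenario.vadose_rates.k_nit, bigger.cover_fractions, 1.0)
        assert k1 == k2


class TestUptake:
    def test_max_uptake_scales_with_area_and_alpha(self):
        d = ns.SubWatershedDescriptor("X", 1.0e6, 0, 0, 1.0, 0, 0, None)
        params = ns.UptakeParams(
            f_max={c: {"a": 1e-5, "n": 1e-5, "o": 1e-5} for c in ("df", "cf", "ms", "ww")}
        )
        f = fx.max_uptake_flux(d, params, alpha=1.0)
        assert f == pytest.approx([10.0, 10.0, 10.0])
        assert fx.max_uptake_flux(d, params, alpha=0.0) == pytest.approx([0.0] * 3)
        d2 = ns.SubWatershedDescriptor("Y", 2.0e6, 0, 0, 1.0, 0, 0, None)
        assert fx.max_uptake_flux(d2, params, 1.0) == pytest.approx(2 * f)

    def test_monod_zero_and_half_saturation(self):
        assert fx.monod_uptake_flux(0.0, 100.0, 10.0, 0.1) == 0.0
        # N = K_m * V_s is the half-saturation point
        assert fx.monod_uptake_flux(10.0, 100.0, 10.0, 0.1) == pytest.approx(5.0)

    def test_monod_frozen_example(self):
        assert fx.monod_uptake_flux(30.0, 100.0, 10.0, 0.1) == pytest.approx(7.5)

    def test_monod_requires_positive_volume(self):
        with pytest.raises(ValueError):
            fx.monod_uptake_flux(1.0, 0.0, 1.0, 0.1)


class TestDeposition:
    def test_wet_scales_with_water_flux(self):
        p = DepositionParams()
        flux = fx.wet_deposition_flux(p, 1000.0)
        assert flux[1] == pytest.approx(11.0)  # nitrate: 0.011 mol/m3 * 1000 m3/day
        assert fx.wet_deposition_flux(p, 0.0) == pytest.approx([0.0] * 3)

    def test_negative_water_flux_clamps_optionally(self):
        p = DepositionParams(clamp_wet_deposition=True)
        assert fx.wet_deposition_flux(p, -500.0) == pytest.approx([0.0] * 3)
        p2 = DepositionParams()
        assert fx.wet_deposition_flux(p2, -500.0)[1] == pytest.approx(-5.5)

    def test_don_wet_concentration_from_quarter_rule(self):
        # DON = 25% of TDN given inorganic wet concentrations (0.0068, 0.011)
        derived = derived_don_wet_concentration(0.0068, 0.011)
        assert derived == pytest.approx(0.0059333, rel=1e-4)
        assert derived == pytest.approx(0.0058, abs=1.5e-4)  # published rounding

    def test_don_dry_rate_from_quarter_rule(self):
        # same rule applied to the published per-area dry rates (1.29, 0.28)
        assert derived_don_dry_rate(1.29, 0.28) == pytest.approx(0.52, abs=0.005)

    def test_default_dry_rates_reproduce_annual_totals(self):
        p = DepositionParams()
        area = ns.total_area(ns.EAST_RIVER)
        annual = p.dry_rate() * area * 365.0
        assert annual == pytest.approx([7.99e4, 1.73e4, 3.24e4], rel=1e-6)


class TestWeathering:
    def test_zero_rates_zero_flux(self, lt):
        p = ns.WeatheringParams(rate_nh4=0.0, rate_no3=0.0, rate_don=0.0)
        v, g = fx.weathering_fluxes(p, lt)
        assert v == pytest.approx([0.0] * 3)
        assert g == pytest.approx([0.0] * 3)

    def test_lt_don_vadose_flux_by_hand(self, lt):
        # 0.9 * 7.5e-6 mol/m2/day * 0.18 * 1.49e7 m2 = 18.10 mol/day
        p = ns.WeatheringParams()
        v, _ = fx.weathering_fluxes(p, lt)
        assert v[2] == pytest.approx(0.9 * 7.5e-6 * 0.18 * 1.49e7)
        assert v[2] == pytest.approx(18.1, abs=0.01)

    def test_groundwater_share_uses_full_area_by_default(self, lt):
        p = ns.WeatheringParams()
        _, g = fx.weathering_fluxes(p, lt)
        assert g[2] == pytest.approx(0.1 * 7.5e-6 * 1.49e7)
        p2 = ns.WeatheringParams(groundwater_area_mode="mancos_area")
        _, g2 = fx.weathering_fluxes(p2, lt)
        assert g2[2] == pytest.approx(g[2] * 0.18)

    def test_annualized_rate_in_reported_band(self):
        # 7.5e-6 mol/m2/day -> 27.4 mol/ha/yr; the high scenario reaches 82
        from nitroshed.units import mol_per_m2_day_to_mol_per_ha_yr

        assert mol_per_m2_day_to_mol_per_ha_yr(7.5e-6) == pytest.approx(27.375)
        assert mol_per_m2_day_to_mol_per_ha_yr(2.25e-5) == pytest.approx(82.125)


class TestFixationAndLitter:
    def test_fixation_gated_by_frozen_soil(self, lt):
        p = ns.FixationParams()
        assert fx.fixation_flux(p, lt, -2.0, 1e-5) == 0.0
        expected = 1e-5 * 0.01 * lt.frac_meadow * lt.area
        assert fx.fixation_flux(p, lt, 2.0, 1e-5) == pytest.approx(expected)

    def test_gpp_asymptote_and_cold_limit(self):
        assert fx.spruce_gpp(1e3) == pytest.approx(1.51 / 0.2375)
        assert fx.spruce_gpp(0.0) == pytest.approx(1.51 / 1.2375)

    def test_spruce_litter_at_zero_gpp(self, lt):
        # force GPP = 0: the exponential collapses to upsilon * 0.0057
        p = ns.LitterParams(upsilon=0.5, gpp_coeffs=(0.0, 1.0, 1.0))
        flux = fx.litter_flux(p, lt, day_of_year=30, t_air=0.0)
        expected = 0.5 * 0.0057 * lt.frac_coniferous * lt.area / 14.0
        assert flux == pytest.approx(expected)

    def test_interval_rates_switch_by_season(self, lt):
        p = ns.LitterParams(deciduous=(1.0, 2.0, 3.0), meadow=(4.0, 5.0), willow=(0, 0, 0), upsilon=0.0)
        base = lt.area / 14.0
        f_spring = fx.litter_flux(p, lt, 100, 0.0)
        f_autumn = fx.litter_flux(p, lt, 300, 0.0)
        assert f_spring == pytest.approx((1.0 * 0.330 + 4.0 * 0.422) * base)
        assert f_autumn == pytest.approx((3.0 * 0.330 + 5.0 * 0.422) * base)


class TestCattle:
    def test_no_herd_no_flux(self):
        assert fx.cattle_don_flux(ns.CattleParams(), "LT", 100) == 0.0

    def test_full_herd_in_lower_triangle(self):
        # 500 head * (8.6 + 15) mol/head/day
        assert fx.cattle_don_flux(ns.CattleParams(), "LT", 220) == pytest.approx(11800.0)

    def test_autumn_split(self):
        assert fx.cattle_don_flux(ns.CattleParams(), "ME", 260) == pytest.approx(7080.0)
        assert fx.cattle_don_flux(ns.CattleParams(), "Copper", 260) == pytest.approx(2360.0)

    def test_overlapping_schedule_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            ns.CattleParams(schedule=(((1, 100), "LT", 0.5), ((50, 60), "LT", 0.5)))


class TestTransportFluxes:
    def test_interflow(self):
        assert fx.interflow_nitrogen_flux(100.0, 10.0, 1.0) == 0.0
        assert fx.interflow_nitrogen_flux(100.0, 10.0, 0.4) == pytest.approx(6.0)

    def test_interflow_equals_concentration_times_flow(self):
        v_s, q_s, n = 1.0e5, 5.0e3, 42.0
        tau = v_s / q_s
        assert fx.interflow_nitrogen_flux(n, tau, 0.3) == pytest.approx(
            (1 - 0.3) * q_s * n / v_s
        )

    def test_groundwater_exchange_signs(self):
        assert fx.groundwater_exchange_flux(1000.0, 100.0, 20.0, 1000.0, 0.0) == 0.0
        assert fx.groundwater_exchange_flux(1000.0, 100.0, 20.0, 1000.0, 50.0) == pytest.approx(10.0)
        assert fx.groundwater_exchange_flux(1000.0, np.nan, 20.0, 1000.0, -50.0) == pytest.approx(-1.0)

    def test_vadose_groundwater_exchange_signs(self):
        assert fx.vadose_groundwater_nitrogen_flux(50.0, 1e5, 100.0, 1e6, 0.0, 0.5) == 0.0
        assert fx.vadose_groundwater_nitrogen_flux(50.0, 1e5, 100.0, 1e6, 2000.0, 0.5) == pytest.approx(0.5)
        assert fx.vadose_groundwater_nitrogen_flux(50.0, 1e5, 100.0, 1e6, -1000.0, 0.5) == pytest.approx(-0.1)


class TestTemperatureCorrections:
    def test_stream_rate_reference(self):
        assert fx.temperature_corrected_stream_rate(1.5, 20.0) == pytest.approx(1.5)

    def test_stream_rate_cold_water(self):
        assert fx.temperature_corrected_stream_rate(1.5, 10.0) == pytest.approx(
            1.5 * 1.07**-10, rel=1e-9
        )
        assert fx.temperature_corrected_stream_rate(1.5, 10.0) == pytest.approx(0.7625, abs=2e-4)

    def test_groundwater_denit_reference_and_gate(self):
        p = ns.GroundwaterDenitParams(k_den_max=0.02)
        assert fx.groundwater_denit_rate(p, 3.8, 2e5) == pytest.approx(0.02)
        assert fx.groundwater_denit_rate(p, 3.8, 5e4) == 0.0
        p2 = ns.GroundwaterDenitParams(k_den_max=0.001)
        assert fx.groundwater_denit_rate(p2, 0.8, 2e5) == pytest.approx(0.001 * 0.3**3)


class TestDerivativeAssembly:
    def test_all_zero(self):
        zero = np.zeros(3)
        d = fx.vadose_zone_derivatives(zero, zero, zero, zero, 0, 0, 0, zero, 0, 0, 0, zero, zero)
        assert d == pytest.approx(zero)

    def test_nitrification_is_zero_sum_transfer(self):
        zero = np.zeros(3)
        pools = np.array([10.0, 5.0, 0.0])
        d = fx.vadose_zone_derivatives(
            zero, zero, zero, zero, 0.2, 0, 0, pools, 0, 0, 0, zero, zero
        )
        assert d[0] == pytest.approx(-2.0)
        assert d[1] == pytest.approx(2.0)
        assert d.sum() == pytest.approx(0.0)

    def test_stream_export_rate(self):
        zero = np.zeros(3)
        pools = np.array([0.0, 100.0, 0.0])
        d = fx.stream_derivatives(zero, zero, zero, zero, 0, 0, 0, 0, pools, tau_r=2.0)
        assert d[1] == pytest.approx(-50.0)

    def test_stream_mineralization_zero_sum(self):
        zero = np.zeros(3)
        pools = np.array([0.0, 0.0, 30.0])
        d = fx.stream_derivatives(zero, zero, zero, zero, 0, 0, 0, 1.5, pools, tau_r=np.inf)
        assert d[0] == pytest.approx(45.0)
        assert d[2] == pytest.approx(-45.0)
        assert d.sum() == pytest.approx(0.0)

    def test_groundwater_weathering_only_growth(self):
        zero = np.zeros(3)
        w = np.array([1.0, 2.0, 3.0])
        d = fx.groundwater_derivatives(zero, zero, w, 0.0, zero)
        assert d == pytest.approx(w)

    def test_groundwater_denitrification_targets_nitrate_only(self):
        zero = np.zeros(3)
        pools = np.array([10.0, 10.0, 10.0])
        d = fx.groundwater_derivatives(zero, zero, zero, 0.1, pools)
        assert d == pytest.approx([0.0, -1.0, 0.0])
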