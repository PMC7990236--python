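"""Back-calculated water flows: algebraic examples, routing, and exact
re-integration of the storage series (water closure)."""

import numpy as np
import pytest

import nitroshed as ns
from nitroshed.hydrology import (
    back_calculate_soil_flow,
    derive_hydro_fluxes,
    groundwater_balance,
    groundwater_temperature,
    residence_times,
    stream_balance_discharge,
    stream_temperature,
)
from nitroshed.watershed import BaseflowSchedule

WINTER_BETA = 0.9  # schedule default for an October start


class TestSoilFlow:
    def test_steady_storage_routes_all_input(self, single_basin, forcing_factory):
        # constant V_s: the whole net input leaves laterally
        series = forcing_factory(single_basin, infilt=100.0)
        q_s = back_calculate_soil_flow(series, "X")
        assert q_s == pytest.approx(np.full(47, 2400.0))  # 100 m3/hr = 2400 m3/day

    def test_storage_drawdown_adds_to_outflow(self, single_basin, forcing_factory):
        v_s = 1.0e5 - 50.0 * np.arange(48)  # drops 50 m3 every hour
        series = forcing_factory(single_basin, V_s=v_s, infilt=0.0)
        q_s = back_calculate_soil_flow(series, "X")
        assert q_s == pytest.approx(np.full(47, 50.0 * 24.0))

    def test_zero_everything_gives_zero(self, single_basin, forcing_factory):
        series = forcing_factory(single_basin)
        assert back_calculate_soil_flow(series, "X") == pytest.approx(np.zeros(47))


class TestGroundwaterBalance:
    def test_positive_soil_flow_splits_by_beta(self, single_basin, forcing_factory):
        series = forcing_factory(single_basin)
        q_s = np.full(47, 1000.0)
        q_g = groundwater_balance(series, "X", q_s, np.full(47, 0.5))
        assert q_g == pytest.approx(np.full(47, 500.0))

    def test_negative_soil_flow_draws_storage(self, single_basin, forcing_factory):
        # V_g falls at exactly the upward flow rate: no exchange with stream
        v_g = 1.0e6 - (200.0 / 24.0) * np.arange(48)
        series = forcing_factory(single_basin, V_g=v_g)
        q_g = groundwater_balance(series, "X", np.full(47, -200.0), np.full(47, 0.5))
        assert q_g == pytest.approx(np.zeros(47), abs=1e-6)


class TestStreamBalance:
    def test_headwater_sum_of_inputs(self, single_basin, forcing_factory):
        series = forcing_factory(single_basin, qq=20.0 / 24.0)
        q_r, raw = stream_balance_discharge(
            series,
            "X",
            q_s=np.zeros(47),
            q_g=np.full(47, 100.0),
            beta=np.full(47, 0.5),
            upstream_q_r=np.zeros(47),
        )
        assert q_r == pytest.approx(np.full(47, 120.0))
        assert raw == pytest.approx(q_r)

    def test_negative_balance_floored_and_reported(self, single_basin, forcing_factory):
        series = forcing_factory(single_basin)
        q_r, raw = stream_balance_discharge(
            series,
            "X",
            q_s=np.zeros(47),
            q_g=np.full(47, -100.0),
            beta=np.full(47, 0.5),
            upstream_q_r=np.zeros(47),
        )
        assert np.all(q_r == 0.0)
        assert raw == pytest.approx(np.full(47, -100.0))

    def test_routing_sums_upstream_outlets(self, two_node_descriptors, forcing_factory):
        # headwater A receives overland flow only; terminal B has no local
        # input, so its outlet discharge equals A's
        series = forcing_factory(
            two_node_descriptors, qq={"A": 240.0 / 24.0, "B": 0.0}
        )
        hydro = derive_hydro_fluxes(series, two_node_descriptors)
        assert hydro.data["A"]["Q_r_m3_day"].to_numpy() == pytest.approx(np.full(47, 240.0))
        assert hydro.data["B"]["Q_r_m3_day"].to_numpy() == pytest.approx(np.full(47, 240.0))


class TestResidenceTimes:
    def test_definition(self):
        assert residence_times(np.array([1000.0]), np.array([100.0]))[0] == 10.0

    def test_undefined_for_nonpositive_flow(self):
        tau = residence_times(np.array([1000.0, 1000.0]), np.array([0.0, -5.0]))
        assert np.isnan(tau).all()

    def test_halves_when_flow_doubles(self):
        v = np.array([1234.0])
        assert residence_times(v, np.array([20.0]))[0] == pytest.approx(
            residence_times(v, np.array([10.0]))[0] / 2.0
        )


class TestTemperatures:
    def test_constant_map(self):
        assert stream_temperature(np.array([-30.0, 0.0, 30.0]), (4.0, 0.0)) == pytest.approx(
            np.full(3, 4.0)
        )

    def test_floor_at_zero(self):
        assert stream_temperature(np.array([-10.0]), (0.0, 1.0))[0] == 0.0

    def test_monotone_for_positive_slope(self):
        grid = np.linspace(-20, 30, 101)
        t_w = stream_temperature(grid, (3.5, 0.6))
        assert np.all(np.diff(t_w) >= 0)

    def test_groundwater_temperature_is_mean(self, forcing_factory):
        descs = {
            sid: ns.SubWatershedDescriptor(sid, 1e6, 0, 0, 0, 0, 0, None if sid == "E" else "E")
            for sid in "ABCDE"
        }
        t_soils = {"A": 0.0, "B": 0.0, "C": 0.0, "D": 0.0, "E": 10.0}
        series = forcing_factory(descs, T_soil=t_soils)
        assert groundwater_temperature(series) == pytest.approx(np.full(48, 2.0))
        # permutation invariance
        shuffled = {k: descs[k] for k in "EDCBA"}
        series2 = forcing_factory(shuffled, T_soil=t_soils)
        assert groundwater_temperature(series2) == pytest.approx(np.full(48, 2.0))


class TestWaterClosure:
    def test_reintegration_reproduces_storages(self, east_river):
        """Integrating the back-calculated flows forward recovers every
        storage series exactly (the balance equations are inverted)."""
        series = ns.generate_synthetic_forcing(
            ns.SyntheticForcingConfig(seed=21, n_years=1), east_river
        )
        hydro = derive_hydro_fluxes(series, east_river)
        day = 1.0 / 24.0
        for sid in east_river:
            f = series.data[sid]
            h = hydro.data[sid]
            v_s = f["V_s_m3"].to_numpy()
            v_g = f["V_g_m3"].to_numpy()
            v_r = f["V_r_m3"].to_numpy()
            q_s = h["Q_s_m3_day"].to_numpy()
            q_g = h["Q_g_m3_day"].to_numpy()
            q_r_raw = h["Q_r_raw_m3_day"].to_numpy()
            beta = h["beta"].to_numpy()
            infilt = h["infilt_m3_day"].to_numpy()
            qq = h["qq_m3_day"].to_numpy()

            rebuilt_vs = v_s[0] + np.concatenate([[0], np.cumsum((infilt - q_s) * day)])
            assert rebuilt_vs == pytest.approx(v_s, rel=1e-9)

            recharge = np.where(q_s > 0, beta * q_s, q_s)
            rebuilt_vg = v_g[0] + np.concatenate([[0], np.cumsum((recharge - q_g) * day)])
            assert rebuilt_vg == pytest.approx(v_g, rel=1e-9)

            upstream = sum(
                hydro.data[u]["Q_r_raw_m3_day"].to_numpy()
                for u, ud in east_river.items()
                if ud.downstream_id == sid
            )
            inflow = (1 - beta) * np.clip(q_s, 0, None) + q_g + qq + upstream
            rebuilt_vr = v_r[0] + np.concatenate([[0], np.cumsum((inflow - q_r_raw) * day)])
            assert rebuilt_vr == pytest.approx(v_r, rel=1e-9)

    def test_routing_conservation_at_terminal(self, east_river):
        """Before flooring, terminal discharge equals the watershed-summed
        local stream inputs minus total stream storage change."""
        series = ns.generate_synthetic_forcing(
            ns.SyntheticForcingConfig(seed=22, n_years=1), east_river
        )
        hydro = derive_hydro_fluxes(series, east_river)
        total_inputs = 0.0
        total_dvr = 0.0
        for sid in east_river:
            h = hydro.data[sid]
            q_s = h["Q_s_m3_day"].to_numpy()
            beta = h["beta"].to_numpy()
            total_inputs = total_inputs + (
                (1 - beta) * np.clip(q_s, 0, None)
                + h["Q_g_m3_day"].to_numpy()
                + h["qq_m3_day"].to_numpy()
            )
            v_r = series.data[sid]["V_r_m3"].to_numpy()
            total_dvr = total_dvr + np.diff(v_r) * 24.0
        terminal_raw = hydro.data["LT"]["Q_r_raw_m3_day"].to_numpy()
        assert terminal_raw == pytest.approx(total_inputs - total_dvr, rel=1e-9, abs=1e-4)


def test_beta_resolution_uses_schedule(self=None):
    sched = BaseflowSchedule()
    assert sched.beta("LT", 280) == 0.7  # monsoon season
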