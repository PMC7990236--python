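"""Integrator correctness: analytic oracles, convergence order, conservation,
determinism, and output plumbing."""

import dataclasses
import json

import numpy as np
import pandas as pd
import pytest

import nitroshed as ns
from nitroshed.simulator import _StepInputs, initialize_state, rk4_step
from nitroshed.hydrology import derive_hydro_fluxes


def _decay_inputs(forcing_factory, single_basin, tau_r_days=1.0, n_hours=48):
    """Step inputs where the only active process is stream export at a
    constant hydraulic rate 1/tau_r: dN/dt = -N/tau_r exactly."""
    v_r = 1.0e3
    qq_per_hr = v_r / tau_r_days / 24.0  # Q_r = V_r / tau
    series = forcing_factory(single_basin, n_hours=n_hours, V_r=v_r, qq=qq_per_hr)
    hydro = derive_hydro_fluxes(series, single_basin)
    return _StepInputs(hydro, single_basin, ns.tracer_parameters(), seed=0, tracer=True)


class TestRK4:
    def test_zero_derivatives_leave_state_unchanged(self, forcing_factory, single_basin):
        series = forcing_factory(single_basin)
        hydro = derive_hydro_fluxes(series, single_basin)
        inputs = _StepInputs(hydro, single_basin, ns.tracer_parameters(), 0, tracer=True)
        pools = np.zeros((1, 3, 3))
        pools[0, 0, 1] = 100.0  # vadose nitrate, no flow: nothing moves
        new, combined, events = rk4_step(inputs, 0, pools, 1 / 24)
        assert new == pytest.approx(pools)
        assert events == 0

    def test_single_step_matches_exponential_decay(self, forcing_factory, single_basin):
        inputs = _decay_inputs(forcing_factory, single_basin)
        pools = np.zeros((1, 3, 3))
        pools[0, 1, 1] = 100.0  # stream nitrate
        dt = 1.0 / 24.0
        new, _, _ = rk4_step(inputs, 0, pools, dt)
        exact = 100.0 * np.exp(-dt / 1.0)
        # theoretical RK4 truncation is (k*dt)^5/120 ~ 1.0e-9 relative
        assert abs(new[0, 1, 1] - exact) / exact < 1e-8

    def test_fourth_order_convergence(self, forcing_factory, single_basin):
        """Halving the step shrinks the global error on linear decay ~16x."""
        inputs = _decay_inputs(forcing_factory, single_basin)

        def global_error(dt, horizon=1.0):
            n = int(round(horizon / dt))
            pools = np.zeros((1, 3, 3))
            pools[0, 1, 1] = 100.0
            for _ in range(n):
                pools, _, _ = rk4_step(inputs, 0, pools, dt)
            return abs(pools[0, 1, 1] - 100.0 * np.exp(-horizon))

        e_coarse = global_error(1.0 / 12.0)
        e_fine = global_error(1.0 / 24.0)
        assert 12.0 < e_coarse / e_fine < 20.0

    def test_long_horizon_agreement_with_analytic_decay(self, forcing_factory, single_basin):
        inputs = _decay_inputs(forcing_factory, single_basin, tau_r_days=2.0)
        dt = 1.0 / 24.0  # k*dt = 1/48, well inside the accuracy regime
        pools = np.zeros((1, 3, 3))
        pools[0, 1, 1] = 100.0
        for _ in range(48):  # one e-folding time
            pools, _, _ = rk4_step(inputs, 0, pools, dt)
        exact = 100.0 * np.exp(-1.0)
        assert abs(pools[0, 1, 1] - exact) / exact < 1e-8


class TestConservation:
    def test_tracer_mode_closes_exactly(self, tracer_result, closure_residual):
        """With reactions and sources off, initial mass = final mass +
        cumulative outlet export."""
        res = tracer_result
        led = res.ledger.window_totals(0, len(res.time), res.config.dt_days)
        export = led["stream_export"][res.ledger.terminal_index].sum()
        initial = res.pools[0].sum()
        final = res.pools[-1].sum()
        assert abs(final + export - initial) / initial < 1e-6
        assert closure_residual(res) < 1e-6

    def test_full_reaction_ledger_closure(self, c2_result, closure_residual):
        """Ledger-integrated sources - sinks - export equals the state mass
        change even with every reaction on and the limiter active."""
        assert closure_residual(c2_result) < 1e-6

    def test_pools_never_negative(self, c2_result):
        assert c2_result.pools.min() >= 0.0

    def test_species_transfers_zero_sum(self, c2_result):
        """Nitrification/mineralization only move mass between species:
        their ledger totals appear symmetrically (source col = sink col)."""
        led = c2_result.ledger
        nit = led.array("nitrification_vadose")
        assert np.all(nit[:, :, [1, 2]] == 0.0)  # mass leaves the NH4 column only
        mineral = led.array("mineralization_stream")
        assert np.all(mineral[:, :, [0, 1]] == 0.0)  # and DON for mineralization


class TestSimulateDriver:
    def test_identical_seeds_bitwise_identical(self, short_forcing):
        cfg = dict(scenario="C2", forcing=short_forcing, seed=9, duration_days=5)
        a = ns.simulate(ns.SimulationConfig(**cfg))
        b = ns.simulate(ns.SimulationConfig(**cfg))
        assert np.array_equal(a.pools, b.pools)
        assert np.array_equal(a.ledger.values, b.ledger.values)

    def test_output_row_bookkeeping(self, short_forcing):
        res = ns.simulate(
            ns.SimulationConfig(scenario="C2", forcing=short_forcing, seed=1, duration_days=2)
        )
        conc = res.concentrations_uM()
        assert len(conc) == 48 * 5 * 3 * 3

    def test_declaration_order_does_not_change_results(self, forcing_factory, two_node_descriptors):
        series = forcing_factory(two_node_descriptors, n_hours=72, infilt=50.0, qq=5.0)
        flipped = {k: two_node_descriptors[k] for k in ("B", "A")}
        r1 = ns.simulate(
            ns.SimulationConfig(scenario="C2", forcing=series, descriptors=two_node_descriptors, seed=3)
        )
        r2 = ns.simulate(
            ns.SimulationConfig(scenario="C2", forcing=series, descriptors=flipped, seed=3)
        )
        for sid in ("A", "B"):
            i1 = r1.subwatersheds.index(sid)
            i2 = r2.subwatersheds.index(sid)
            assert r1.pools[:, i1] == pytest.approx(r2.pools[:, i2], rel=1e-12)

    def test_forcing_shorter_than_duration_fails_early(self, short_forcing):
        with pytest.raises(ValueError, match="duration"):
            ns.simulate(
                ns.SimulationConfig(scenario="C2", forcing=short_forcing, duration_days=4000)
            )


class TestInitialization:
    def test_explicit_pools_returned_unchanged(self, forcing_factory, single_basin):
        series = forcing_factory(single_basin)
        hydro = derive_hydro_fluxes(series, single_basin)
        inputs = _StepInputs(hydro, single_basin, ns.tracer_parameters(), 0, tracer=True)
        pools = np.full((1, 3, 3), 7.0)
        cfg = ns.SimulationConfig(initial="explicit", initial_pools=pools)
        state = initialize_state(cfg, inputs)
        assert state.pools == pytest.approx(pools)

    def test_spinup_trivial_with_no_sources_or_sinks(self, forcing_factory, single_basin):
        # zero flow, zero reactions: already steady, one repeat suffices
        series = forcing_factory(single_basin, n_hours=72)
        hydro = derive_hydro_fluxes(series, single_basin)
        inputs = _StepInputs(hydro, single_basin, ns.tracer_parameters(), 0, tracer=True)
        cfg = ns.SimulationConfig(initial="spinup", spinup_days=2)
        state = initialize_state(cfg, inputs)
        expected = cfg.initial_concentrations_uM["s"]["n"] / 1000.0 * 1.0e5
        assert state.pools[0, 0, 1] == pytest.approx(expected)

    def test_spinup_reaches_source_sink_steady_state(self, forcing_factory, single_basin):
        """Constant litter source S and advective sink at rate Q_s/V_s drive
        the vadose DON pool to the closed-form steady state S*V_s/Q_s."""
        v_s = 1.0e5
        q_s_per_hr = v_s / 20.0 / 24.0  # tau_s = 20 days
        series = forcing_factory(single_basin, n_hours=91 * 24, infilt=q_s_per_hr, V_s=v_s)
        scenario = dataclasses.replace(
            ns.tracer_parameters(),
            litter=ns.LitterParams(meadow=(0.014, 0.014), gpp_coeffs=(0.0, 1.0, 1.0)),
        )
        hydro = derive_hydro_fluxes(series, single_basin)
        inputs = _StepInputs(hydro, single_basin, scenario, 0, tracer=False)
        cfg = ns.SimulationConfig(initial="spinup", spinup_days=90)
        state = initialize_state(cfg, inputs)
        source = 0.014 * single_basin["X"].frac_meadow * single_basin["X"].area / 14.0
        steady = source * 20.0  # S * tau_s
        assert state.pools[0, 0, 2] == pytest.approx(steady, rel=0.05)


class TestWriteOutputs:
    def test_files_round_trip_and_manifest(self, tmp_path, short_forcing):
        res = ns.simulate(
            ns.SimulationConfig(scenario="C2", forcing=short_forcing, seed=17, duration_days=3)
        )
        paths = ns.write_outputs(res, tmp_path / "run")
        conc = pd.read_csv(paths["concentrations"], parse_dates=["timestamp"])
        in_memory = res.concentrations_uM()
        assert conc["concentration_uM"].to_numpy() == pytest.approx(
            in_memory["concentration_uM"].to_numpy()
        )
        manifest = json.loads(paths["manifest"].read_text())
        assert manifest["seed"] == 17
        ledger = pd.read_csv(paths["ledger"])
        assert {"timestamp", "subwatershed", "flux", "species", "mol_per_day"} <= set(
            ledger.columns
        )
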