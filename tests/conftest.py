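"""Shared fixtures: hand-built watersheds and forcing, plus session-scoped
simulation runs reused across test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import nitroshed as ns
from nitroshed.forcing import ForcingSeries

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def east_river():
    return dict(ns.EAST_RIVER)


@pytest.fixture
def single_basin():
    """One self-contained sub-watershed (terminal outlet)."""
    return {
        "X": ns.SubWatershedDescriptor(
            "X", 1.0e6, 0.0, 0.0, 1.0, 0.0, 0.5, None
        )
    }


@pytest.fixture
def two_node_descriptors():
    """Headwater A draining into terminal B."""
    return {
        "A": ns.SubWatershedDescriptor("A", 1.0e6, 0.1, 0.2, 0.3, 0.1, 0.5, "B"),
        "B": ns.SubWatershedDescriptor("B", 2.0e6, 0.2, 0.1, 0.4, 0.1, 0.2, None),
    }


@pytest.fixture
def forcing_factory():
    """Build a ForcingSeries from scalars, arrays, or per-sub dicts."""

    def make(
        descriptors,
        n_hours=48,
        start="2014-10-01",
        V_s=1.0e5,
        V_g=1.0e6,
        V_r=1.0e3,
        infilt=0.0,
        qq=0.0,
        T_soil=4.0,
        T_air=6.0,
    ):
        time = pd.date_range(start, periods=n_hours, freq="h")

        def arr(value, sid):
            if isinstance(value, dict):
                value = value[sid]
            return np.broadcast_to(np.asarray(value, float), (n_hours,)).copy()

        data = {
            sid: pd.DataFrame(
                {
                    "V_s_m3": arr(V_s, sid),
                    "V_g_m3": arr(V_g, sid),
                    "V_r_m3": arr(V_r, sid),
                    "infilt_minus_ets_m3_per_hr": arr(infilt, sid),
                    "qq_minus_etr_m3_per_hr": arr(qq, sid),
                    "T_soil_C": arr(T_soil, sid),
                    "T_air_C": arr(T_air, sid),
                },
                index=time,
            )
            for sid in descriptors
        }
        return ForcingSeries(time=time, data=data)

    return make


def external_closure_residual(result: ns.SimulationResult) -> float:
    """Relative error of (mass change) vs (ledger sources - sinks - export)."""
    led = result.ledger.window_totals(0, len(result.time), result.config.dt_days)
    ext_in = sum(
        led[n].sum()
        for n in (
            "wet_dep_vadose_in",
            "dry_dep",
            "weathering_vadose",
            "weathering_gw",
            "fixation",
            "litter",
            "cattle",
            "wet_dep_stream_in",
        )
    )
    ext_out = sum(
        led[n].sum()
        for n in (
            "wet_dep_vadose_out",
            "uptake_vadose",
            "denitrification_vadose",
            "wet_dep_stream_out",
            "uptake_stream",
            "denitrification_stream",
            "denitrification_gw",
        )
    )
    export = led["stream_export"][result.ledger.terminal_index].sum()
    d_mass = result.pools[-1].sum() - result.pools[0].sum()
    scale = max(abs(result.pools[0].sum()), abs(ext_in), 1.0)
    return abs(d_mass - (ext_in - ext_out - export)) / scale


@pytest.fixture
def closure_residual():
    return external_closure_residual


@pytest.fixture(scope="session")
def synthetic_forcing_2yr():
    return ns.generate_synthetic_forcing(
        ns.SyntheticForcingConfig(seed=11, n_years=2), dict(ns.EAST_RIVER)
    )


@pytest.fixture(scope="session")
def c2_result(synthetic_forcing_2yr):
    """Two simulated years of the C2 scenario on shared synthetic forcing."""
    config = ns.SimulationConfig(
        scenario="C2", forcing=synthetic_forcing_2yr, seed=11
    )
    return ns.simulate(config)


@pytest.fixture(scope="session")
def tracer_result():
    """One simulated year with every reaction and source switched off."""
    config = ns.SimulationConfig(
        scenario="C2",
        forcing=ns.SyntheticForcingConfig(seed=11, n_years=1),
        seed=11,
        tracer_mode=True,
    )
    return ns.simulate(config)


@pytest.fixture(scope="session")
def short_forcing():
    return ns.generate_synthetic_forcing(
        ns.SyntheticForcingConfig(seed=5, n_years=1), dict(ns.EAST_RIVER)
    )


def run_short(forcing, scenario, days=30, seed=5):
    return ns.simulate(
        ns.SimulationConfig(scenario=scenario, forcing=forcing, seed=seed, duration_days=days)
    )


@pytest.fixture(scope="session")
def c2_short(short_forcing):
    return run_short(short_forcing, ns.load_scenario("C2"))


@pytest.fixture(scope="session")
def nc_short(short_forcing):
    return run_short(short_forcing, ns.load_scenario("NC"))


@pytest.fixture(scope="session")
def nm1_short(short_forcing):
    return run_short(short_forcing, ns.load_scenario("NM1"))


@pytest.fixture(scope="session")
def c1_no_mancos_short(short_forcing):
    scenario = ns.load_scenario(
        "C1", weathering=ns.WeatheringParams(rate_nh4=0.0, rate_no3=0.0, rate_don=0.0)
    )
    return run_short(short_forcing, scenario)
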