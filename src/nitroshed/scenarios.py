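"""The six equifinal calibration scenarios.

Manual calibration of a >20-parameter watershed model against stream
nitrate alone admits many parameter sets that fit equally well
(equifinality).  Six named regions of the parameter space are packaged:

* **C1** — subsurface-dominated cycling: low in-stream reactivity, high
  vadose-zone rate constants, moderate shale weathering, moderate
  groundwater denitrification.
* **C2** — surface-dominated cycling (the most plausible set): high
  in-stream reactivity, low vadose-zone rates, moderate weathering, low
  groundwater denitrification.
* **C3** — both surface and subsurface cycling with the largest shale
  weathering flux that still calibrates, and high groundwater
  denitrification.
* **NM1 / NM2** — no-shale analogues of C1 / C2 (weathering rates zero).
* **NC** — C2 without cattle (herd size zero, litter raised to compensate).

Every parameter is overridable via ``dataclasses.replace`` or keyword
overrides to :func:`load_scenario`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .params import (
    CattleParams,
    DepositionParams,
    FixationParams,
    GroundwaterDenitParams,
    LitterParams,
    StreamRateParams,
    UptakeParams,
    VadoseRateTable,
    WeatheringParams,
)

__all__ = [
    "ScenarioParameterSet",
    "SCENARIO_NAMES",
    "load_scenario",
    "scenario_from_config",
    "tracer_parameters",
]

SCENARIO_NAMES = ("C1", "C2", "C3", "NM1", "NM2", "NC")


@dataclass
class ScenarioParameterSet:
    """A complete nitrogen-model parameterization."""

    name: str
    vadose_rates: VadoseRateTable
    stream_rates: StreamRateParams
    gw_denit: GroundwaterDenitParams
    weathering: WeatheringParams
    litter: LitterParams
    cattle: CattleParams = field(default_factory=CattleParams)
    deposition: DepositionParams = field(default_factory=DepositionParams)
    uptake: UptakeParams = field(default_factory=UptakeParams)
    fixation: FixationParams = field(default_factory=FixationParams)


def _vadose(k_nit, k_nit_ww, k_min, k_min_ms, k_den, k_den_ww) -> VadoseRateTable:
    return VadoseRateTable(
        k_nit={"df": k_nit, "cf": k_nit, "ms": k_nit, "ww": k_nit_ww},
        k_min={"df": k_min, "cf": k_min, "ms": k_min_ms, "ww": k_min},
        k_den={"df": k_den, "cf": k_den, "ms": k_den, "ww": k_den_ww},
    )


def _build_scenarios() -> dict[str, ScenarioParameterSet]:
    med_mancos = WeatheringParams(rate_nh4=2.0e-7, rate_no3=7.5e-6, rate_don=7.5e-6)
    high_mancos = WeatheringParams(rate_nh4=6.0e-7, rate_no3=2.25e-5, rate_don=2.25e-5)
    no_mancos = WeatheringParams(rate_nh4=0.0, rate_no3=0.0, rate_don=0.0)

    return {
        "C1": ScenarioParameterSet(
            name="C1",
            vadose_rates=_vadose(2.5, 2.5, 2.4, 1.8, 1.2, 6.0),
            stream_rates=StreamRateParams(k20_nit=0.3, k20_up=1.0, k20_den=0.4),
            gw_denit=GroundwaterDenitParams(k_den_max=0.02),
            weathering=med_mancos,
            litter=LitterParams(
                deciduous=(0.001, 5e-6, 0.002),
                willow=(5e-4, 5e-6, 0.002),
                meadow=(5e-8, 5e-7),
                upsilon=0.5,
            ),
        ),
        "C2": ScenarioParameterSet(
            name="C2",
            vadose_rates=_vadose(0.05, 0.09, 0.2, 0.15, 0.001, 0.001),
            stream_rates=StreamRateParams(k20_nit=5.0, k20_up=2.0, k20_den=1.0),
            gw_denit=GroundwaterDenitParams(k_den_max=0.001),
            weathering=med_mancos,
            litter=LitterParams(
                deciduous=(6e-4, 3e-6, 0.0012),
                willow=(3e-4, 3e-6, 0.0012),
                meadow=(3e-8, 3e-7),
                upsilon=0.3,
            ),
        ),
        "C3": ScenarioParameterSet(
            name="C3",
            vadose_rates=_vadose(2.5, 2.5, 2.4, 1.8, 7.5, 7.5),
            stream_rates=StreamRateParams(k20_nit=5.0, k20_up=1.0, k20_den=1.0),
            gw_denit=GroundwaterDenitParams(k_den_max=2.5),
            weathering=high_mancos,
            litter=LitterParams(
                deciduous=(2e-4, 1e-6, 4e-4),
                willow=(1e-4, 1e-6, 4e-4),
                meadow=(1e-8, 1e-7),
                upsilon=0.1,
            ),
        ),
        "NM1": ScenarioParameterSet(
            name="NM1",
            vadose_rates=_vadose(2.5, 2.5, 2.4, 1.8, 0.2, 1.0),
            stream_rates=StreamRateParams(k20_nit=0.3, k20_up=1.0, k20_den=0.4),
            gw_denit=GroundwaterDenitParams(k_den_max=0.001),
            weathering=no_mancos,
            litter=LitterParams(
                deciduous=(0.001, 5e-6, 0.002),
                willow=(5e-4, 5e-6, 0.002),
                meadow=(5e-8, 5e-7),
                upsilon=0.5,
            ),
        ),
        "NM2": ScenarioParameterSet(
            name="NM2",
            vadose_rates=_vadose(0.05, 0.09, 0.2, 0.15, 5e-4, 5e-4),
            stream_rates=StreamRateParams(k20_nit=5.0, k20_up=2.0, k20_den=0.5),
            gw_denit=GroundwaterDenitParams(k_den_max=5e-4),
            weathering=no_mancos,
            litter=LitterParams(
                deciduous=(7e-4, 3e-6, 0.007),
                willow=(3e-4, 3e-6, 0.00125),
                meadow=(3e-8, 3e-7),
                upsilon=0.3,
            ),
        ),
        "NC": ScenarioParameterSet(
            name="NC",
            vadose_rates=_vadose(0.05, 0.09, 0.2, 0.15, 0.001, 0.001),
            stream_rates=StreamRateParams(k20_nit=5.0, k20_up=2.0, k20_den=1.0),
            gw_denit=GroundwaterDenitParams(k_den_max=0.001),
            weathering=med_mancos,
            litter=LitterParams(
                deciduous=(0.0014, 7e-6, 0.0028),
                willow=(7e-4, 7e-6, 0.0028),
                meadow=(7e-8, 7e-7),
                upsilon=0.7,
            ),
            cattle=CattleParams(n_cows=0),
        ),
    }


def load_scenario(name: str, **overrides) -> ScenarioParameterSet:
    """Return a packaged scenario parameter set by name.

    Keyword overrides replace whole parameter blocks, e.g.
    ``load_scenario("C1", weathering=WeatheringParams(0, 0, 0))``.
    """
    scenarios = _build_scenarios()
    if name not in scenarios:
        raise KeyError(f"unknown scenario {name!r}; valid names: {', '.join(SCENARIO_NAMES)}")
    scenario = scenarios[name]
    if overrides:
        scenario = replace(scenario, **overrides)
    return scenario


def scenario_from_config(source, base: str = "C2", name: str | None = None) -> ScenarioParameterSet:
    """Build a parameter set from a hierarchical text config.

    ``source`` is a mapping, a YAML string, or a path to a YAML file using
    the calibration-table row names; unspecified values come from the
    ``base`` scenario::

        k_nit_s:  {df: 0.05, cf: 0.05, ms: 0.05, ww: 0.09}   # day^-1
        k_min_s:  {df: 0.2, cf: 0.2, ms: 0.15, ww: 0.7}
        k_den_s:  {df: 0.001, cf: 0.001, ms: 0.001, ww: 0.001}
        F_o_lit:  {df: [6.0e-4, 3.0e-6, 1.2e-3],             # g N m^-2 day^-1
                   ww: [3.0e-4, 3.0e-6, 1.2e-3],
                   ms: [3.0e-8, 3.0e-7],
                   upsilon: 0.3}
        k20_nit_r: 5.0      # day^-1 at 20 C
        k20_up_r: 2.0
        k20_den_r: 1.0
        k_den_max_g: 0.001  # day^-1 at 3.8 C
        M_o: 7.5e-6         # mol m^-2 day^-1
        M_n: 7.5e-6
        M_a: 2.0e-7
        n_cows: 500
    """
    import os

    import yaml

    if isinstance(source, dict):
        cfg = dict(source)
    else:
        text = (
            open(source).read()
            if isinstance(source, (os.PathLike,)) or (isinstance(source, str) and os.path.exists(source))
            else source
        )
        cfg = yaml.safe_load(text) or {}

    scenario = load_scenario(base)
    rates = {
        key: dict(getattr(scenario.vadose_rates, attr))
        for key, attr in (("k_nit_s", "k_nit"), ("k_min_s", "k_min"), ("k_den_s", "k_den"))
    }
    for key in rates:
        rates[key].update(cfg.get(key, {}))
    vadose = VadoseRateTable(
        k_nit=rates["k_nit_s"], k_min=rates["k_min_s"], k_den=rates["k_den_s"]
    )

    lit_cfg = cfg.get("F_o_lit", {})
    litter = replace(
        scenario.litter,
        deciduous=tuple(lit_cfg.get("df", scenario.litter.deciduous)),
        willow=tuple(lit_cfg.get("ww", scenario.litter.willow)),
        meadow=tuple(lit_cfg.get("ms", scenario.litter.meadow)),
        upsilon=lit_cfg.get("upsilon", scenario.litter.upsilon),
    )
    stream = replace(
        scenario.stream_rates,
        k20_nit=cfg.get("k20_nit_r", scenario.stream_rates.k20_nit),
        k20_up=cfg.get("k20_up_r", scenario.stream_rates.k20_up),
        k20_den=cfg.get("k20_den_r", scenario.stream_rates.k20_den),
    )
    gw = replace(scenario.gw_denit, k_den_max=cfg.get("k_den_max_g", scenario.gw_denit.k_den_max))
    weathering = replace(
        scenario.weathering,
        rate_don=cfg.get("M_o", scenario.weathering.rate_don),
        rate_no3=cfg.get("M_n", scenario.weathering.rate_no3),
        rate_nh4=cfg.get("M_a", scenario.weathering.rate_nh4),
    )
    cattle = replace(scenario.cattle, n_cows=cfg.get("n_cows", scenario.cattle.n_cows))
    return replace(
        scenario,
        name=name or f"{base}+config",
        vadose_rates=vadose,
        litter=litter,
        stream_rates=stream,
        gw_denit=gw,
        weathering=weathering,
        cattle=cattle,
    )


def tracer_parameters(name: str = "tracer") -> ScenarioParameterSet:
    """A conservative-transport parameter set: every reaction, source and
    sink off.  Nitrogen then moves only with water (advection, interflow,
    groundwater exchange, routing, outlet export), which makes total mass
    plus cumulative export an exact invariant — the basis of the
    conservation tests."""
    return ScenarioParameterSet(
        name=name,
        vadose_rates=VadoseRateTable(),
        stream_rates=StreamRateParams(k20_min=0.0),
        gw_denit=GroundwaterDenitParams(k_den_max=0.0),
        weathering=WeatheringParams(rate_nh4=0.0, rate_no3=0.0, rate_don=0.0),
        litter=LitterParams(),
        cattle=CattleParams(n_cows=0),
        deposition=DepositionParams(
            wet_conc_nh4=0.0,
            wet_conc_no3=0.0,
            wet_conc_don=0.0,
            dry_rate_nh4=0.0,
            dry_rate_no3=0.0,
            dry_rate_don=0.0,
        ),
        uptake=UptakeParams(
            f_max={c: {"a": 0.0, "n": 0.0, "o": 0.0} for c in ("df", "cf", "ms", "ww")}
        ),
        fixation=FixationParams(lower=0.0, upper=0.0),
    )
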