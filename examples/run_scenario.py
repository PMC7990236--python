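"""Run the most plausible calibration scenario (C2) for one water year on
synthetic forcing and look at the simulated stream chemistry.

C2 represents a watershed dominated by in-stream nitrogen cycling: high
in-stream nitrification/uptake/denitrification rate constants and low
vadose-zone rate constants, with a moderate shale weathering source.
"""

import nitroshed as ns

result = ns.simulate(
    ns.SimulationConfig(
        scenario="C2",
        forcing=ns.SyntheticForcingConfig(seed=7, n_years=1),
        seed=7,
    )
)

conc = result.concentrations_uM()
stream = conc[conc["compartment"] == "r"]
print(f"scenario {result.scenario_name}, {len(result.time)} hourly steps\n")
print("stream concentration medians (uM) per sub-watershed:")
table = stream.pivot_table(
    index="subwatershed", columns="species", values="concentration_uM", aggfunc="median"
).rename(columns={"a": "NH4+", "n": "NO3-", "o": "DON"})
print(table.round(2).to_string())

report = ns.balance_checks(result)
print(
    f"\n(litter + cattle) / plant uptake = {report.litter_cattle_over_uptake:.2f}"
    f"   total sinks / total sources = {report.sinks_over_sources:.2f}"
)
print(
    "Concentrations peak during snowmelt (high-concentration meltwater flushing)"
    " and are drawn down through the growing season; the balance ratios are the"
    " two calibration diagnostics (target band 0.9-1.1 under calibrated forcing)."
)
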