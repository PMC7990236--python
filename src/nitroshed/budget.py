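"""Annual source/sink budgets, calibration balance checks, RMSE scoring and
scenario comparison.

Budgets aggregate the flux ledger over a water year (Oct 1 - Sep 30) into
the standard categories:

sources
    wet deposition (net, vadose + stream), dry deposition, shale (Mancos)
    weathering, biological fixation, plant litter, cattle excretion;
fates / sinks
    terrestrial plant uptake, subsurface denitrification (vadose +
    groundwater), in-stream loss (in-stream denitrification plus in-stream
    biological uptake), and the dissolved N flux sent downstream through the
    terminal outlet.

"New" N is the share entering from outside the plant-soil recycling loop:
atmospheric deposition, weathering and fixation (litter and cattle recycle
N that plants previously took up).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulator import FluxLedger, SimulationResult

__all__ = [
    "BudgetSummary",
    "CalibrationCheckReport",
    "ObservationSeries",
    "annual_budget",
    "balance_checks",
    "rmse",
    "load_observations",
    "compare_scenarios",
    "mancos_annual_source_closed_form",
]

SOURCE_CATEGORIES = ("wet_dep", "dry_dep", "mancos", "fixation", "litter", "cattle")
SINK_CATEGORIES = ("plant_uptake", "subsurface_denitrification", "instream_loss", "downstream_export")
NEW_N_CATEGORIES = ("wet_dep", "dry_dep", "mancos", "fixation")


@dataclass
class BudgetSummary:
    """Annual totals (mol yr^-1) and percentage shares per category."""

    water_year: int
    scenario: str
    sources: dict[str, float]
    sinks: dict[str, float]
    new_n_categories: tuple[str, ...] = NEW_N_CATEGORIES

    @property
    def total_sources(self) -> float:
        return sum(self.sources.values())

    @property
    def total_sinks(self) -> float:
        return sum(self.sinks.values())

    @property
    def source_shares_pct(self) -> dict[str, float]:
        total = self.total_sources
        return {k: 100.0 * v / total for k, v in self.sources.items()}

    @property
    def sink_shares_pct(self) -> dict[str, float]:
        total = self.total_sinks
        return {k: 100.0 * v / total for k, v in self.sinks.items()}

    @property
    def mancos_share_of_sources_pct(self) -> float:
        return 100.0 * self.sources["mancos"] / self.total_sources

    @property
    def mancos_share_of_new_pct(self) -> float:
        new = sum(self.sources[c] for c in self.new_n_categories)
        return 100.0 * self.sources["mancos"] / new if new > 0 else 0.0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"side": "source", "category": k, "mol_per_yr": v, "share_pct": s}
            for (k, v), s in zip(self.sources.items(), self.source_shares_pct.values())
        ] + [
            {"side": "sink", "category": k, "mol_per_yr": v, "share_pct": s}
            for (k, v), s in zip(self.sinks.items(), self.sink_shares_pct.values())
        ]
        df = pd.DataFrame(rows)
        df.insert(0, "water_year", self.water_year)
        df.insert(1, "scenario", self.scenario)
        return df


def _water_year_window(time: pd.DatetimeIndex, water_year: int) -> tuple[int, int]:
    """Step-index window [start, stop) of water year N (Oct 1 of N-1 through
    Sep 30 of N); fails if the ledger does not cover the full year."""
    start_ts = pd.Timestamp(year=water_year - 1, month=10, day=1)
    stop_ts = pd.Timestamp(year=water_year, month=10, day=1)
    start = int(np.searchsorted(time.values, np.datetime64(start_ts)))
    stop = int(np.searchsorted(time.values, np.datetime64(stop_ts)))
    if start >= len(time) or time[start] != start_ts:
        raise ValueError(f"ledger does not start water year {water_year} (needs {start_ts})")
    covered_until = time[stop - 1] + pd.Timedelta(hours=1)
    if covered_until < stop_ts:
        raise ValueError(
            f"ledger covers only up to {covered_until}; water year {water_year} is partial"
        )
    return start, stop


def category_totals(
    ledger: FluxLedger, start: int, stop: int, dt_days: float
) -> tuple[dict[str, float], dict[str, float]]:
    """Aggregate ledger fluxes over steps [start, stop) into the budget
    categories (mol per window)."""
    t = ledger.window_totals(start, stop, dt_days)
    term = ledger.terminal_index
    if term is None:
        raise ValueError("ledger has no terminal outlet recorded")
    sources = {
        "wet_dep": float(
            t["wet_dep_vadose_in"].sum()
            - t["wet_dep_vadose_out"].sum()
            + t["wet_dep_stream_in"].sum()
            - t["wet_dep_stream_out"].sum()
        ),
        "dry_dep": float(t["dry_dep"].sum()),
        "mancos": float(t["weathering_vadose"].sum() + t["weathering_gw"].sum()),
        "fixation": float(t["fixation"].sum()),
        "litter": float(t["litter"].sum()),
        "cattle": float(t["cattle"].sum()),
    }
    sinks = {
        "plant_uptake": float(t["uptake_vadose"].sum()),
        "subsurface_denitrification": float(
            t["denitrification_vadose"].sum() + t["denitrification_gw"].sum()
        ),
        "instream_loss": float(
            t["denitrification_stream"].sum() + t["uptake_stream"].sum()
        ),
        "downstream_export": float(t["stream_export"][term].sum()),
    }
    return sources, sinks


def annual_budget(result: SimulationResult, water_year: int) -> BudgetSummary:
    """Source/sink budget of one full water year from a simulation result."""
    start, stop = _water_year_window(result.time, water_year)
    sources, sinks = category_totals(result.ledger, start, stop, result.config.dt_days)
    return BudgetSummary(
        water_year=water_year,
        scenario=result.scenario_name,
        sources=sources,
        sinks=sinks,
    )


def mancos_annual_source_closed_form(descriptors, weathering, days: float = 365.0) -> float:
    """Closed-form annual shale weathering source (mol): the vadose share
    scales with sigma_i*A_i, the groundwater share with A_i (or sigma_i*A_i
    in mancos_area mode), constant in time — so the ledger total over any
    window of ``days`` days must equal this exactly."""
    total_rate = weathering.rate_nh4 + weathering.rate_no3 + weathering.rate_don
    acc = 0.0
    for d in descriptors.values():
        gw_area = d.area if weathering.groundwater_area_mode == "full_area" else d.mancos_fraction * d.area
        acc += (
            weathering.vadose_share * d.mancos_fraction * d.area
            + weathering.groundwater_share * gw_area
        ) * total_rate
    return acc * days


@dataclass
class CalibrationCheckReport:
    """Calibration balance diagnostics over a window.

    The manual calibration demands (1) annual litter + cattle DON release
    within +/-10% of plant uptake, and (2) total sinks within +/-10% of
    total sources.  A zero denominator makes a check indeterminate (never a
    pass).
    """

    litter_cattle_over_uptake: float
    sinks_over_sources: float
    band: tuple[float, float] = (0.9, 1.1)
    subsurface_drift: dict[str, float] = field(default_factory=dict)

    def _passes(self, ratio: float) -> bool:
        return np.isfinite(ratio) and self.band[0] <= ratio <= self.band[1]

    @property
    def litter_cattle_balance_ok(self) -> bool:
        return self._passes(self.litter_cattle_over_uptake)

    @property
    def sink_source_balance_ok(self) -> bool:
        return self._passes(self.sinks_over_sources)


def balance_checks(
    result: SimulationResult,
    start: int = 0,
    stop: int | None = None,
) -> CalibrationCheckReport:
    """Compute the +/-10% calibration balance ratios over a step window."""
    stop = len(result.time) if stop is None else stop
    sources, sinks = category_totals(result.ledger, start, stop, result.config.dt_days)
    uptake = sinks["plant_uptake"]
    recycled = sources["litter"] + sources["cattle"]
    total_sources = sum(sources.values())
    total_sinks = sum(sinks.values())
    ratio1 = recycled / uptake if uptake > 0 else float("nan")
    ratio2 = total_sinks / total_sources if total_sources > 0 else float("nan")

    pools = result.pools
    n = pools.shape[0] - 1
    drift = {}
    for ci, comp in (("vadose", 0), ("groundwater", 2)):
        start_mass = pools[0, :, comp, :].sum()
        end_mass = pools[n, :, comp, :].sum()
        drift[ci] = float((end_mass - start_mass) / start_mass) if start_mass > 0 else float("nan")
    return CalibrationCheckReport(
        litter_cattle_over_uptake=ratio1,
        sinks_over_sources=ratio2,
        subsurface_drift=drift,
    )


# ---------------------------------------------------------------------------
# observations and goodness of fit
# ---------------------------------------------------------------------------

ObservationSeries = pd.DataFrame  # columns: timestamp, subwatershed, species, concentration_uM


def load_observations(path) -> ObservationSeries:
    """Read an observation CSV (timestamp, subwatershed, species,
    concentration_uM)."""
    obs = pd.read_csv(path, parse_dates=["timestamp"])
    required = {"timestamp", "subwatershed", "species", "concentration_uM"}
    missing = required - set(obs.columns)
    if missing:
        raise ValueError(f"observation file missing columns {sorted(missing)}")
    if (obs["concentration_uM"] < 0).any():
        raise ValueError("negative observed concentrations")
    return obs


def rmse(
    observed: ObservationSeries,
    modeled: pd.DataFrame,
    species: str,
    subwatershed: str,
    compartment: str = "r",
    tolerance: str = "1h",
) -> float:
    """Root-mean-square error (uM) between observed concentrations and the
    nearest-in-time modeled value within ``tolerance``.

    ``modeled`` is a concentrations frame as produced by
    ``SimulationResult.concentrations_uM()``.  Raises if no observation
    matches a model timestamp.
    """
    obs = observed[
        (observed["subwatershed"] == subwatershed) & (observed["species"] == species)
    ].sort_values("timestamp")
    mod = modeled[
        (modeled["subwatershed"] == subwatershed)
        & (modeled["species"] == species)
        & (modeled["compartment"] == compartment)
    ].sort_values("timestamp")
    if obs.empty or mod.empty:
        raise ValueError(f"no data to match for ({subwatershed}, {species})")
    merged = pd.merge_asof(
        obs,
        mod[["timestamp", "concentration_uM"]].rename(
            columns={"concentration_uM": "modeled_uM"}
        ),
        on="timestamp",
        direction="nearest",
        tolerance=pd.Timedelta(tolerance),
    ).dropna(subset=["modeled_uM"])
    if merged.empty:
        raise ValueError("no observation matched a model timestamp within tolerance")
    residual = merged["concentration_uM"].to_numpy() - merged["modeled_uM"].to_numpy()
    return float(np.sqrt(np.mean(residual**2)))


def compare_scenarios(
    results: list[SimulationResult],
    water_year: int | None = None,
    observations: ObservationSeries | None = None,
) -> pd.DataFrame:
    """Side-by-side scenario comparison on identical forcing.

    One row per (scenario, sub-watershed): peak stream nitrate, budget
    shares (whole run, or one water year if given), and stream nitrate RMSE
    against observations if provided.  Mismatched forcing fingerprints
    raise, since cross-forcing comparisons are not meaningful.
    """
    if len(results) < 2:
        raise ValueError("need at least two runs to compare")
    fingerprints = {r.forcing_fingerprint for r in results}
    if len(fingerprints) != 1:
        raise ValueError("runs use different forcing; comparison refused")

    rows = []
    for r in results:
        if water_year is not None:
            summary = annual_budget(r, water_year)
        else:
            sources, sinks = category_totals(r.ledger, 0, len(r.time), r.config.dt_days)
            summary = BudgetSummary(0, r.scenario_name, sources, sinks)
        conc = r.concentrations_uM()
        stream_no3 = conc[(conc["compartment"] == "r") & (conc["species"] == "n")]
        for sid in r.subwatersheds:
            sub = stream_no3[stream_no3["subwatershed"] == sid]
            row = {
                "scenario": r.scenario_name,
                "subwatershed": sid,
                "peak_stream_no3_uM": float(sub["concentration_uM"].max()),
                "mean_stream_no3_uM": float(sub["concentration_uM"].mean()),
                "mancos_share_pct": summary.mancos_share_of_sources_pct,
                "mancos_share_of_new_pct": summary.mancos_share_of_new_pct,
                "total_sources_mol": summary.total_sources,
                "total_sinks_mol": summary.total_sinks,
            }
            if observations is not None:
                try:
                    row["rmse_no3_uM"] = rmse(observations, conc, "n", sid)
                except ValueError:
                    row["rmse_no3_uM"] = float("nan")
            rows.append(row)
    return pd.DataFrame(rows)
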