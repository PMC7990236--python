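"""Sub-watershed descriptors, routing topology and the seasonal baseflow index.

The model domain is a mountain headwater catchment discretized into five
sub-watersheds: three headwater catchments (EAQ, Rustlers, Copper) draining
into a middle reach (ME), which drains into a lower reach (LT) whose outlet
is the watershed terminus (the pumphouse, PH).  Each sub-watershed carries
static geometry (surface area), land-cover fractions used to weight biological
rate constants, and the fraction of its subsurface underlain by N-rich Mancos
shale, which controls the geogenic weathering source.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "SubWatershedDescriptor",
    "BaseflowSchedule",
    "EAST_RIVER",
    "topological_order",
    "total_area",
]

LAND_COVERS = ("df", "cf", "ms", "ww")  # deciduous, coniferous, meadow, willow


@dataclass(frozen=True)
class SubWatershedDescriptor:
    """Static properties of one sub-watershed.

    Parameters
    ----------
    id : str
        Sub-watershed label, e.g. ``"EAQ"``.
    area : float
        Surface area A_i in m^2.
    frac_deciduous, frac_coniferous, frac_meadow, frac_willow : float
        Land-cover fractions (unitless, each in [0, 1]; their sum may be
        below 1 — the remainder is barren/developed land with zero rates).
    mancos_fraction : float
        Fraction sigma_i of the sub-watershed underlain by Mancos shale
        within the upper saprolite (unitless).
    downstream_id : str or None
        Sub-watershed receiving this outlet's flow; ``None`` marks the
        terminal outlet.
    """

    id: str
    area: float
    frac_deciduous: float
    frac_coniferous: float
    frac_meadow: float
    frac_willow: float
    mancos_fraction: float
    downstream_id: str | None = None

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise ValueError(f"{self.id}: area must be positive, got {self.area}")
        fracs = (
            self.frac_deciduous,
            self.frac_coniferous,
            self.frac_meadow,
            self.frac_willow,
        )
        for name, f in zip(LAND_COVERS, fracs):
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"{self.id}: cover fraction {name}={f} outside [0, 1]")
        if sum(fracs) > 1.0 + 1e-9:
            raise ValueError(f"{self.id}: cover fractions sum to {sum(fracs)} > 1")
        if not 0.0 <= self.mancos_fraction <= 1.0:
            raise ValueError(
                f"{self.id}: mancos_fraction={self.mancos_fraction} outside [0, 1]"
            )

    @property
    def cover_fractions(self) -> dict[str, float]:
        """Land-cover fractions keyed by the short cover codes."""
        return {
            "df": self.frac_deciduous,
            "cf": self.frac_coniferous,
            "ms": self.frac_meadow,
            "ww": self.frac_willow,
        }


#: The five East River sub-watersheds (USGS National Land Cover Database
#: derived areas and cover fractions; Mancos fraction from geologic mapping).
EAST_RIVER: dict[str, SubWatershedDescriptor] = {
    d.id: d
    for d in (
        SubWatershedDescriptor("EAQ", 5.27e6, 0.131, 0.205, 0.310, 0.122, 0.70, "ME"),
        SubWatershedDescriptor("Rustlers", 1.48e7, 0.013, 0.189, 0.468, 0.118, 0.08, "ME"),
        SubWatershedDescriptor("Copper", 2.37e7, 0.023, 0.194, 0.278, 0.049, 0.01, "ME"),
        SubWatershedDescriptor("ME", 2.61e7, 0.125, 0.353, 0.274, 0.058, 0.18, "LT"),
        SubWatershedDescriptor("LT", 1.49e7, 0.330, 0.135, 0.422, 0.075, 0.18, None),
    )
}


def topological_order(descriptors: dict[str, SubWatershedDescriptor]) -> list[str]:
    """Order sub-watersheds so every upstream node precedes its receiver.

    Raises ``ValueError`` on routing cycles, dangling downstream ids, or a
    number of terminal outlets different from one.
    """
    terminals = [d.id for d in descriptors.values() if d.downstream_id is None]
    if len(terminals) != 1:
        raise ValueError(f"routing must have exactly one terminal outlet, got {terminals}")
    for d in descriptors.values():
        if d.downstream_id is not None and d.downstream_id not in descriptors:
            raise ValueError(f"{d.id}: unknown downstream id {d.downstream_id!r}")

    order: list[str] = []
    resolved: set[str] = set()
    remaining = dict(descriptors)
    while remaining:
        progressed = False
        for sid, d in list(remaining.items()):
            upstream = [u for u, ud in descriptors.items() if ud.downstream_id == sid]
            if all(u in resolved for u in upstream):
                order.append(sid)
                resolved.add(sid)
                del remaining[sid]
                progressed = True
        if not progressed:
            raise ValueError(f"routing cycle among {sorted(remaining)}")
    return order


def total_area(descriptors: dict[str, SubWatershedDescriptor]) -> float:
    """Whole-watershed surface area in m^2."""
    return sum(d.area for d in descriptors.values())


@dataclass
class BaseflowSchedule:
    """Seasonal baseflow index beta per sub-watershed.

    beta is the fraction of positive vadose-zone outflow Q_s routed to
    groundwater (the remaining 1-beta reaches the stream as interflow).
    Four hydrograph seasons partition the year by day-of-year windows.

    Default beta values are placeholders: the site-specific seasonal indices
    come from unpublished flow-partitioning work and are expected to be
    overridden per application.
    """

    #: (start_doy, end_doy) inclusive; winter wraps around the new year.
    season_windows: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {
            "winter": (305, 59),
            "rising": (60, 151),
            "falling": (152, 212),
            "monsoon": (213, 304),
        }
    )
    #: per sub-watershed, beta per season; ``"*"`` applies to all ids.
    betas: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "*": {"winter": 0.9, "rising": 0.5, "falling": 0.6, "monsoon": 0.7}
        }
    )

    def __post_init__(self) -> None:
        for sid, per_season in self.betas.items():
            for season, b in per_season.items():
                if not 0.0 <= b <= 1.0:
                    raise ValueError(f"beta[{sid}][{season}]={b} outside [0, 1]")

    def season_of(self, day_of_year: int) -> str:
        for season, (start, end) in self.season_windows.items():
            if start <= end:
                if start <= day_of_year <= end:
                    return season
            elif day_of_year >= start or day_of_year <= end:  # wrap-around window
                return season
        raise ValueError(f"day-of-year {day_of_year} not covered by season windows")

    def beta(self, subwatershed_id: str, day_of_year: int) -> float:
        season = self.season_of(day_of_year)
        per_season = self.betas.get(subwatershed_id, self.betas.get("*"))
        if per_season is None or season not in per_season:
            raise KeyError(f"no beta for ({subwatershed_id}, {season})")
        return per_season[season]
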