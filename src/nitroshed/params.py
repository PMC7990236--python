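"""Parameter containers for the nitrogen model.

Conventions: internal units are mol, m^3, days, deg C; nitrogen mass
conversions use 14 g mol^-1.  Species are indexed in the fixed order
(ammonium ``a``, nitrate ``n``, organic ``o``); land covers in the order
(deciduous ``df``, coniferous ``cf``, meadow ``ms``, willow ``ww``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SPECIES",
    "N_MOLAR_MASS_G",
    "DepositionParams",
    "WeatheringParams",
    "UptakeParams",
    "VadoseRateTable",
    "StreamRateParams",
    "GroundwaterDenitParams",
    "LitterParams",
    "CattleParams",
    "FixationParams",
    "derived_don_wet_concentration",
    "derived_don_dry_rate",
]

SPECIES = ("a", "n", "o")  # ammonium, nitrate, dissolved organic N
LAND_COVERS = ("df", "cf", "ms", "ww")
N_MOLAR_MASS_G = 14.0  # g N per mol


def derived_don_wet_concentration(nh4: float, no3: float, fraction: float = 0.25) -> float:
    """Wet-deposition DON concentration from the DON-is-a-fixed-fraction-of-TDN
    rule: DON = f*(NH4 + NO3 + DON)  =>  DON = f*(NH4+NO3)/(1-f)."""
    return fraction * (nh4 + no3) / (1.0 - fraction)


def derived_don_dry_rate(nh4: float, no3: float, fraction: float = 0.25) -> float:
    """Dry-deposition DON areal rate by the same fixed-fraction-of-total rule."""
    return fraction * (nh4 + no3) / (1.0 - fraction)


@dataclass
class DepositionParams:
    """Atmospheric deposition.

    Wet deposition is a concentration (mol m^-3) carried by the net water
    fluxes into each compartment; dry deposition is an areal rate
    (mol m^-2 day^-1) applied over the sub-watershed area to the vadose zone.

    The default wet concentrations are long-term precipitation averages from
    the in-watershed atmospheric monitoring station (0.011 mol m^-3 nitrate,
    0.0068 mol m^-3 ammonium), with DON set to 25% of TDN.  The default dry
    rates are scaled so that watershed-total annual dry deposition matches
    the station's annual totals (1.73e4 mol NO3-, 7.99e4 mol NH4+,
    3.24e4 mol DON per year over 8.477e7 m^2); the station's published
    per-area figures (0.28, 1.29, 0.52 mol m^-2 day^-1) carry a unit error
    of about six orders of magnitude and are retained here only as the
    source of the NH4:NO3:DON ratio.
    """

    wet_conc_nh4: float = 0.0068
    wet_conc_no3: float = 0.011
    wet_conc_don: float = field(default_factory=lambda: derived_don_wet_concentration(0.0068, 0.011))
    dry_rate_nh4: float = 7.99e4 / (8.477e7 * 365.0)
    dry_rate_no3: float = 1.73e4 / (8.477e7 * 365.0)
    dry_rate_don: float = 3.24e4 / (8.477e7 * 365.0)
    #: floor the (signed) wet-deposition term at zero instead of letting a
    #: negative net water flux remove N at precipitation concentration
    clamp_wet_deposition: bool = False

    def wet_conc(self) -> np.ndarray:
        return np.array([self.wet_conc_nh4, self.wet_conc_no3, self.wet_conc_don])

    def dry_rate(self) -> np.ndarray:
        return np.array([self.dry_rate_nh4, self.dry_rate_no3, self.dry_rate_don])


@dataclass
class WeatheringParams:
    """Geogenic (shale weathering) N source.

    ``rate_*`` are areal mobilization fluxes in mol m^-2 day^-1, constant in
    time.  ``vadose_share`` of the flux enters the vadose zone scaled by the
    shale fraction sigma_i; the remainder is released to groundwater from
    fractured bedrock, by default over the full sub-watershed area
    (``groundwater_area_mode="full_area"``; set ``"mancos_area"`` to scale
    the groundwater term by sigma_i as well).
    """

    rate_nh4: float = 2.0e-7
    rate_no3: float = 7.5e-6
    rate_don: float = 7.5e-6
    vadose_share: float = 0.9
    groundwater_share: float = 0.1
    groundwater_area_mode: str = "full_area"

    def __post_init__(self) -> None:
        if min(self.rate_nh4, self.rate_no3, self.rate_don) < 0:
            raise ValueError("weathering rates must be >= 0")
        if abs(self.vadose_share + self.groundwater_share - 1.0) > 1e-9:
            raise ValueError("vadose_share + groundwater_share must equal 1")
        if self.groundwater_area_mode not in ("full_area", "mancos_area"):
            raise ValueError(f"unknown groundwater_area_mode {self.groundwater_area_mode!r}")

    def rates(self) -> np.ndarray:
        return np.array([self.rate_nh4, self.rate_no3, self.rate_don])


@dataclass
class UptakeParams:
    """Plant N uptake (Monod kinetics).

    ``f_max`` holds the maximum areal uptake flux per land cover and species
    (mol m^-2 day^-1); ``k_m`` the half-saturation concentrations
    (mol m^-3).  The defaults are literature-plausible magnitudes assembled
    from root-uptake studies (they are not site-calibrated constants) and
    should be overridden where better constraints exist.  ``theta_soil`` is
    the base of the soil temperature correction alpha =
    theta_soil**((T_soil-5)/2); ``msr`` (root mass per area, g cm^-2) is
    retained as provenance metadata for the default table.
    """

    f_max: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            # cover -> {species: mol m^-2 day^-1}
            "df": {"a": 6.0e-5, "n": 4.0e-5, "o": 2.0e-5},
            "cf": {"a": 4.0e-5, "n": 2.5e-5, "o": 1.5e-5},
            "ms": {"a": 5.0e-5, "n": 5.0e-5, "o": 2.5e-5},
            "ww": {"a": 8.0e-5, "n": 6.0e-5, "o": 3.0e-5},
        }
    )
    k_m: dict[str, float] = field(
        default_factory=lambda: {"a": 0.01, "n": 0.015, "o": 0.02}
    )
    theta_soil: float = 12.0
    msr: float = 0.0017  # g cm^-2, metadata only

    def f_max_array(self) -> np.ndarray:
        """(n_cover, n_species) array in the canonical cover/species order."""
        return np.array(
            [[self.f_max[c][x] for x in SPECIES] for c in LAND_COVERS]
        )

    def k_m_array(self) -> np.ndarray:
        return np.array([self.k_m[x] for x in SPECIES])


@dataclass
class VadoseRateTable:
    """First-order vadose-zone rate constants per land cover (day^-1):
    nitrification (NH4->NO3), net mineralization (DON->NH4), and
    denitrification (NO3 -> gaseous loss)."""

    k_nit: dict[str, float] = field(
        default_factory=lambda: dict.fromkeys(LAND_COVERS, 0.0)
    )
    k_min: dict[str, float] = field(
        default_factory=lambda: dict.fromkeys(LAND_COVERS, 0.0)
    )
    k_den: dict[str, float] = field(
        default_factory=lambda: dict.fromkeys(LAND_COVERS, 0.0)
    )

    def __post_init__(self) -> None:
        for table in (self.k_nit, self.k_min, self.k_den):
            if any(v < 0 for v in table.values()):
                raise ValueError("rate constants must be >= 0")

    def as_arrays(self) -> dict[str, np.ndarray]:
        return {
            name: np.array([table[c] for c in LAND_COVERS])
            for name, table in (
                ("k_nit", self.k_nit),
                ("k_min", self.k_min),
                ("k_den", self.k_den),
            )
        }


@dataclass
class StreamRateParams:
    """In-stream first-order rate constants at the 20 deg C reference
    (day^-1), corrected to stream temperature with base ``theta_stream``:
    k(T) = k20 * theta_stream**(T_water - 20).

    ``k20_min`` (net mineralization of fresh terrestrial organic matter in
    the water column) defaults to 1.5 day^-1 and is treated as the same
    constant wherever stream mineralization appears.
    """

    k20_nit: float = 0.0
    k20_up: float = 0.0
    k20_den: float = 0.0
    k20_min: float = 1.5
    theta_stream: float = 1.07

    def __post_init__(self) -> None:
        if min(self.k20_nit, self.k20_up, self.k20_den, self.k20_min) < 0:
            raise ValueError("stream rate constants must be >= 0")


@dataclass
class GroundwaterDenitParams:
    """Groundwater denitrification: k = k_den_max * theta_gw**(T_ref - T_gw),
    referenced to the maximum groundwater temperature T_ref = 3.8 deg C, and
    active only while the vadose outflow Q_s exceeds ``q_s_threshold``
    (rapid recharge raising the water table into near-surface anoxic zones).
    """

    k_den_max: float = 0.0
    theta_gw: float = 0.3
    reference_temp: float = 3.8
    q_s_threshold: float = 1.0e5  # m^3 day^-1

    def __post_init__(self) -> None:
        if self.k_den_max < 0:
            raise ValueError("k_den_max must be >= 0")
        if self.q_s_threshold <= 0:
            raise ValueError("q_s_threshold must be > 0")


@dataclass
class LitterParams:
    """DON release from decomposing plant litter.

    For deciduous, willow and meadow covers the daily areal release rate
    (g N m^-2 day^-1) is a step function of day-of-year: three intervals
    (1-150, 151-250, 251-end) for deciduous/willow, two for meadow
    (before day 200, day 200 onward).  Coniferous (spruce) release follows
    gross primary productivity: GPP = 1.51/(0.2375 + exp(-0.21*T_air))
    (mg C m^-2 day^-1) and F_lit = upsilon*0.0057*exp(-0.293*GPP)
    (g N m^-2 day^-1), with scaling factor ``upsilon``.

    ``jitter`` = "uniform_multiplicative" multiplies each non-spruce rate by
    a mean-preserving uniform draw in ``jitter_bounds``; default off for
    reproducibility.
    """

    deciduous: tuple[float, float, float] = (0.0, 0.0, 0.0)
    willow: tuple[float, float, float] = (0.0, 0.0, 0.0)
    meadow: tuple[float, float] = (0.0, 0.0)
    upsilon: float = 0.0
    gpp_coeffs: tuple[float, float, float] = (1.51, 0.2375, 0.21)
    litter_coeffs: tuple[float, float] = (0.0057, -0.293)
    jitter: str = "off"
    jitter_bounds: tuple[float, float] = (0.5, 1.5)

    def interval_rate(self, cover: str, day_of_year: int, days_in_year: int = 365) -> float:
        """Step-function rate (g N m^-2 day^-1) for a non-spruce cover."""
        if cover == "ms":
            lo, hi = self.meadow
            return lo if day_of_year < 200 else hi
        rates = self.deciduous if cover == "df" else self.willow
        if day_of_year <= 150:
            return rates[0]
        if day_of_year <= 250:
            return rates[1]
        return rates[2]  # 251 .. days_in_year (366 in leap years)


@dataclass
class CattleParams:
    """DON input from cattle dung and urine.

    A herd of ``n_cows`` grazes the watershed from mid-July to mid-October;
    ``schedule`` lists ((start_doy, end_doy), subwatershed_id, herd fraction
    G_i).  Loads are mol N per cow per day reaching the soil (ammonia
    volatilization already discounted).
    """

    n_cows: int = 500
    load_dung: float = 8.6
    load_urine: float = 15.0
    # grazing calendar: whole herd in LT Jul 15 - Sep 8 (doy 196-251),
    # then split upstream Sep 9 - Oct 15 (doy 252-288)
    schedule: tuple = (
        ((196, 251), "LT", 1.0),
        ((252, 288), "ME", 0.6),
        ((252, 288), "Copper", 0.2),
        ((252, 288), "EAQ", 0.1),
        ((252, 288), "Rustlers", 0.1),
    )

    def __post_init__(self) -> None:
        if self.n_cows < 0 or self.load_dung < 0 or self.load_urine < 0:
            raise ValueError("cattle loads and head count must be >= 0")
        seen: dict[tuple[str, int], float] = {}
        totals: dict[int, float] = {}
        for (lo, hi), sid, g in self.schedule:
            for doy in range(lo, hi + 1):
                if (sid, doy) in seen:
                    raise ValueError(
                        f"overlapping cattle schedule entries for {sid} at day {doy}"
                    )
                seen[(sid, doy)] = g
                totals[doy] = totals.get(doy, 0.0) + g
        if any(t > 1.0 + 1e-9 for t in totals.values()):
            raise ValueError("herd fractions G_i sum to > 1 on some day")

    def herd_fraction(self, subwatershed_id: str, day_of_year: int) -> float:
        for (lo, hi), sid, g in self.schedule:
            if sid == subwatershed_id and lo <= day_of_year <= hi:
                return g
        return 0.0


@dataclass
class FixationParams:
    """Biological N fixation in meadows.

    While soil temperature is above 0 deg C, an areal NH4 input is drawn
    uniformly in [lower, upper] mol m^-2 day^-1 (one draw per sub-watershed
    per day) and applied over the N-fixer area: ``fixer_fraction`` of the
    meadow cover.
    """

    lower: float = 1e-8
    upper: float = 1e-4
    fixer_fraction: float = 0.01
    temperature_gate: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.lower <= self.upper:
            raise ValueError("need 0 <= lower <= upper")


def _replace(params, **kwargs):
    """dataclasses.replace re-exported for scenario construction."""
    return replace(params, **kwargs)
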