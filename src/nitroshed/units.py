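"""Unit conversions used throughout: nitrogen mass and areal flux scales.

Internal units are mol and m^2; reported budgets use mol yr^-1,
mol ha^-1 yr^-1 and kg N ha^-1 yr^-1 (14 g N per mol, 1 ha = 10^4 m^2).
Concentrations: 1 mol m^-3 = 1000 uM.
"""

from __future__ import annotations

N_MOLAR_MASS_G = 14.0
M2_PER_HA = 1.0e4
DAYS_PER_YEAR = 365.0

__all__ = [
    "mol_per_m2_day_to_mol_per_ha_yr",
    "mol_per_m2_yr_to_kg_per_ha_yr",
    "mol_per_yr_to_kg_per_ha_yr",
    "mol_per_m3_to_uM",
]


def mol_per_m2_day_to_mol_per_ha_yr(rate: float) -> float:
    return rate * M2_PER_HA * DAYS_PER_YEAR


def mol_per_m2_yr_to_kg_per_ha_yr(rate: float) -> float:
    return rate * M2_PER_HA * N_MOLAR_MASS_G / 1000.0


def mol_per_yr_to_kg_per_ha_yr(total_mol: float, area_m2: float) -> float:
    return total_mol * N_MOLAR_MASS_G / 1000.0 / (area_m2 / M2_PER_HA)


def mol_per_m3_to_uM(conc: float) -> float:
    return conc * 1000.0
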