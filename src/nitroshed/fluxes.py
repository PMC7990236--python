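"""Nitrogen source, sink and transformation flux operators.

Every operator is a pure function of state (pool masses in mol), hydrologic
forcing and parameters, returning fluxes in mol day^-1.  Species arrays are
ordered (ammonium, nitrate, DON); all functions broadcast over numpy arrays.

The compartment derivative assemblers at the bottom combine named component
fluxes into dN/dt per species; they are the single place the sign structure
of the model lives, and transformations (nitrification NH4->NO3,
mineralization DON->NH4) are strictly zero-sum across species.
"""

from __future__ import annotations

import numpy as np

from .params import (
    LAND_COVERS,
    N_MOLAR_MASS_G,
    SPECIES,
    CattleParams,
    DepositionParams,
    FixationParams,
    GroundwaterDenitParams,
    LitterParams,
    UptakeParams,
    WeatheringParams,
)
from .watershed import SubWatershedDescriptor

__all__ = [
    "soil_temperature_factor",
    "landcover_weighted_rate",
    "max_uptake_flux",
    "monod_uptake_flux",
    "wet_deposition_flux",
    "dry_deposition_flux",
    "weathering_fluxes",
    "fixation_flux",
    "spruce_gpp",
    "litter_flux",
    "cattle_don_flux",
    "interflow_nitrogen_flux",
    "groundwater_exchange_flux",
    "temperature_corrected_stream_rate",
    "vadose_groundwater_nitrogen_flux",
    "groundwater_denit_rate",
    "vadose_zone_derivatives",
    "stream_derivatives",
    "groundwater_derivatives",
]

ALPHA_WARN_THRESHOLD = 1e6


def soil_temperature_factor(t_soil, theta_soil: float = 12.0):
    """Unitless temperature factor alpha = theta**((T_soil - 5)/2).

    alpha = 1 at the 5 deg C reference.  With the default base 12 the factor
    grows steeply with warm soils; a warning fires beyond 1e6 since such
    values signal a parameterization outside the model's intended range.
    """
    alpha = np.power(theta_soil, (np.asarray(t_soil, float) - 5.0) / 2.0)
    if np.any(alpha > ALPHA_WARN_THRESHOLD):
        import warnings

        warnings.warn(
            f"soil temperature factor exceeded {ALPHA_WARN_THRESHOLD:g}; "
            "check theta_soil and the soil temperature range",
            RuntimeWarning,
            stacklevel=2,
        )
    return alpha


def landcover_weighted_rate(k_by_cover, cover_fractions, alpha):
    """Cover-weighted first-order rate constant (day^-1):
    k = alpha * sum_c k_c * rho_c.

    ``k_by_cover`` and ``cover_fractions`` are mappings keyed by the cover
    codes or arrays in the canonical (df, cf, ms, ww) order.  No area factor
    enters here: the result multiplies a pool mass directly.
    """
    if isinstance(k_by_cover, dict):
        k_by_cover = np.array([k_by_cover[c] for c in LAND_COVERS])
    if isinstance(cover_fractions, dict):
        cover_fractions = np.array([cover_fractions[c] for c in LAND_COVERS])
    return alpha * np.dot(np.asarray(k_by_cover, float), np.asarray(cover_fractions, float))


def max_uptake_flux(
    descriptor: SubWatershedDescriptor, params: UptakeParams, alpha
) -> np.ndarray:
    """Maximum plant uptake flux per species (mol day^-1):
    F_max = alpha * A_i * sum_c F_max,c * rho_c  (area is dimensionally
    required: the per-cover maxima are areal rates)."""
    fracs = np.array([descriptor.cover_fractions[c] for c in LAND_COVERS])
    per_area = fracs @ params.f_max_array()  # (3,) mol m^-2 day^-1
    return np.multiply.outer(np.asarray(alpha, float), descriptor.area * per_area)[()]


def monod_uptake_flux(n_pool, v_s, f_max, k_m):
    """Monod (saturating) uptake: F = F_max * N / (K_m * V_s + N).

    ``k_m`` is a half-saturation *concentration* (mol m^-3), so saturation is
    reached relative to the dissolved concentration N/V_s; F < F_max for any
    finite pool and F -> 0 as N -> 0.
    """
    v_s = np.asarray(v_s, float)
    if np.any(v_s <= 0):
        raise ValueError("monod_uptake_flux requires V_s > 0")
    n_pool = np.asarray(n_pool, float)
    return f_max * n_pool / (k_m * v_s + n_pool)


def wet_deposition_flux(params: DepositionParams, water_flux):
    """Wet deposition per species (mol day^-1): precipitation concentration
    times the signed net water flux ([Infilt - ET_s] for the vadose zone,
    [Q_q - ET_r] for the stream, m^3 day^-1).  With
    ``clamp_wet_deposition`` the term is floored at zero instead of removing
    N when the net water flux is negative."""
    flux = np.multiply.outer(np.asarray(water_flux, float), params.wet_conc())[()]
    if params.clamp_wet_deposition:
        flux = np.clip(flux, 0.0, None)
    return flux


def dry_deposition_flux(params: DepositionParams, descriptor: SubWatershedDescriptor):
    """Dry deposition per species (mol day^-1), applied to the vadose zone."""
    return params.dry_rate() * descriptor.area


def weathering_fluxes(
    params: WeatheringParams, descriptor: SubWatershedDescriptor
) -> tuple[np.ndarray, np.ndarray]:
    """Constant-in-time geogenic source per species (mol day^-1) as
    ``(vadose, groundwater)``.  The vadose share weathers from saprolite and
    scales with the shale fraction sigma_i; the groundwater share is
    released from fractured bedrock over the full area by default."""
    rates = params.rates()
    vadose = params.vadose_share * rates * descriptor.mancos_fraction * descriptor.area
    gw_area = (
        descriptor.area
        if params.groundwater_area_mode == "full_area"
        else descriptor.mancos_fraction * descriptor.area
    )
    groundwater = params.groundwater_share * rates * gw_area
    return vadose, groundwater


def fixation_flux(
    params: FixationParams,
    descriptor: SubWatershedDescriptor,
    t_soil,
    areal_draw,
):
    """NH4 input from meadow N-fixers (mol day^-1).

    ``areal_draw`` is the day's uniform draw in [lower, upper]
    (mol m^-2 day^-1); the active area is ``fixer_fraction`` of the meadow
    cover.  Frozen soils (T_soil <= gate) shut the flux off.
    """
    area = params.fixer_fraction * descriptor.frac_meadow * descriptor.area
    gate = np.asarray(t_soil, float) > params.temperature_gate
    return np.where(gate, np.asarray(areal_draw, float) * area, 0.0)[()]


def spruce_gpp(t_air, coeffs=(1.51, 0.2375, 0.21)):
    """Spruce gross primary productivity (mg C m^-2 day^-1) as a saturating
    function of air temperature: GPP = c0 / (c1 + exp(-c2 * T_air))."""
    c0, c1, c2 = coeffs
    return c0 / (c1 + np.exp(-c2 * np.asarray(t_air, float)))


def litter_flux(
    params: LitterParams,
    descriptor: SubWatershedDescriptor,
    day_of_year: int,
    t_air,
    days_in_year: int = 365,
    rng: np.random.Generator | None = None,
):
    """DON release from plant litter, summed over covers (mol day^-1).

    Deciduous, willow and meadow covers use seasonal step rates
    (g N m^-2 day^-1, optional mean-preserving multiplicative jitter);
    spruce release declines exponentially with GPP (litterfall concentrates
    in the cold season).  Grams convert to mol at 14 g N mol^-1.
    """
    c0, gamma = params.litter_coeffs
    gpp = spruce_gpp(t_air, params.gpp_coeffs)
    spruce_g = params.upsilon * c0 * np.exp(gamma * gpp)
    total_g = spruce_g * descriptor.frac_coniferous * descriptor.area
    for cover in ("df", "ms", "ww"):
        rate = params.interval_rate(cover, day_of_year, days_in_year)
        if params.jitter == "uniform_multiplicative" and rng is not None:
            rate *= rng.uniform(*params.jitter_bounds)
        total_g = total_g + rate * descriptor.cover_fractions[cover] * descriptor.area
    return total_g / N_MOLAR_MASS_G


def cattle_don_flux(params: CattleParams, subwatershed_id: str, day_of_year: int) -> float:
    """DON delivered to soil water by the grazing herd (mol day^-1):
    F = n_cows * G_i * (L_dung + L_urine)."""
    g = params.herd_fraction(subwatershed_id, day_of_year)
    return params.n_cows * g * (params.load_dung + params.load_urine)


def interflow_nitrogen_flux(n_s, tau_s, beta):
    """N carried to the stream by interflow (mol day^-1): the (1-beta) share
    of the vadose pool turnover, F = (1-beta) * N_s / tau_s.  Only defined
    while the vadose zone drains (Q_s > 0, tau_s finite); callers pass 0
    otherwise."""
    return (1.0 - np.asarray(beta, float)) * np.asarray(n_s, float) / np.asarray(tau_s, float)


def groundwater_exchange_flux(n_g, tau_g, n_r, v_r, q_g):
    """Signed groundwater-stream N exchange (mol day^-1, positive toward the
    stream).  Discharge (Q_g > 0) exports groundwater N at its turnover rate
    N_g/tau_g; recharge (Q_g < 0) carries stream N into groundwater at the
    stream concentration, (N_r/V_r)*Q_g."""
    q_g = np.asarray(q_g, float)
    v_r = np.asarray(v_r, float)
    if np.any(v_r <= 0):
        raise ValueError("groundwater_exchange_flux requires V_r > 0")
    discharge = np.where(q_g > 0, np.asarray(n_g, float) / np.where(np.asarray(tau_g, float) > 0, tau_g, np.inf), 0.0)
    recharge = np.where(q_g < 0, np.asarray(n_r, float) / v_r * q_g, 0.0)
    return (discharge + recharge)[()]


def temperature_corrected_stream_rate(k20, t_water, theta_stream: float = 1.07):
    """Arrhenius-style correction of an in-stream rate constant from its
    20 deg C reference: k = k20 * theta**(T_water - 20)."""
    return k20 * np.power(theta_stream, np.asarray(t_water, float) - 20.0)


def vadose_groundwater_nitrogen_flux(n_s, v_s, n_g, v_g, q_s, beta):
    """Signed N flow between vadose zone and groundwater (mol day^-1,
    positive downward).  Downward percolation (Q_s > 0) carries the beta
    share of the vadose outflow at the vadose concentration; upward flow
    (Q_s < 0) carries groundwater N at the groundwater concentration."""
    q_s = np.asarray(q_s, float)
    down = np.where(q_s > 0, beta * q_s * np.asarray(n_s, float) / np.asarray(v_s, float), 0.0)
    up = np.where(q_s < 0, q_s * np.asarray(n_g, float) / np.asarray(v_g, float), 0.0)
    return (down + up)[()]


def groundwater_denit_rate(params: GroundwaterDenitParams, t_gw, q_s):
    """Groundwater denitrification rate constant (day^-1):
    k = k_den_max * theta_gw**(T_ref - T_gw) while the vadose outflow
    exceeds the recharge threshold (water-table rise into near-surface
    anoxic zones), else 0."""
    k = params.k_den_max * np.power(
        params.theta_gw, params.reference_temp - np.asarray(t_gw, float)
    )
    return np.where(np.asarray(q_s, float) > params.q_s_threshold, k, 0.0)[()]


# ---------------------------------------------------------------------------
# compartment derivative assemblers
# ---------------------------------------------------------------------------


def vadose_zone_derivatives(
    wet_dep,
    dry_dep,
    weathering,
    uptake,
    k_nit: float,
    k_min: float,
    k_den: float,
    pools,
    fixation: float,
    litter: float,
    cattle: float,
    advection_out,
    advection_in,
) -> np.ndarray:
    """dN/dt of the vadose pools, per species (mol day^-1).

    ``pools`` and the per-species flux arrays are ordered (NH4, NO3, DON);
    ``advection_out`` is the per-species export with Q_s > 0 (split
    downstream into interflow and groundwater recharge), ``advection_in``
    the per-species gain from upward groundwater flow with Q_s < 0.
    Nitrification and mineralization appear with opposite signs in the
    paired species so they conserve N exactly.
    """
    n_a, n_n, n_o = np.asarray(pools, float)
    nit = k_nit * n_a
    mineral = k_min * n_o
    den = k_den * n_n
    base = (
        np.asarray(wet_dep, float)
        + np.asarray(dry_dep, float)
        + np.asarray(weathering, float)
        - np.asarray(uptake, float)
        - np.asarray(advection_out, float)
        + np.asarray(advection_in, float)
    )
    return base + np.array(
        [
            mineral - nit + fixation,  # NH4: gains mineralized DON, loses to NO3
            nit - den,  # NO3: gains nitrified NH4, loses to denitrification
            litter + cattle - mineral,  # DON
        ]
    )


def stream_derivatives(
    upstream_in,
    wet_dep,
    interflow,
    gw_exchange,
    k_nit: float,
    k_up: float,
    k_den: float,
    k_min: float,
    pools,
    tau_r: float,
) -> np.ndarray:
    """dN/dt of the stream pools, per species (mol day^-1).

    Export leaves at the hydraulic turnover rate N/tau_r (undefined tau_r,
    i.e. no discharge, means no export — pass tau_r = inf).  In-stream
    biological uptake applies to the inorganic species only.
    """
    n_a, n_n, n_o = np.asarray(pools, float)
    nit = k_nit * n_a
    mineral = k_min * n_o
    export = np.asarray(pools, float) / tau_r
    base = (
        np.asarray(upstream_in, float)
        + np.asarray(wet_dep, float)
        + np.asarray(interflow, float)
        + np.asarray(gw_exchange, float)
        - export
    )
    return base + np.array(
        [
            mineral - nit - k_up * n_a,
            nit - k_den * n_n - k_up * n_n,
            -mineral,
        ]
    )


def groundwater_derivatives(
    vz_flux,
    gw_exchange,
    weathering,
    k_den_g: float,
    pools,
) -> np.ndarray:
    """dN/dt of the groundwater pools, per species (mol day^-1):
    dN_g/dt = F_vz - F_gw + weathering - k_den_g * N_n (nitrate only)."""
    out = (
        np.asarray(vz_flux, float)
        - np.asarray(gw_exchange, float)
        + np.asarray(weathering, float)
    )
    out = out - k_den_g * np.asarray(pools, float) * np.array([0.0, 1.0, 0.0])
    return out


assert len(SPECIES) == 3  # derivative assemblers hard-code the species order
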