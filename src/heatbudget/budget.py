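"""Human energy-budget model for outdoor heat stress.

The budget is the net rate of heat gain per unit body surface area,

    budget = M + Rabs − Conv − Evap − TRemitted      [W/m²]

where M is metabolic heat production, Rabs the absorbed short- and
long-wave radiation, Conv the sensible convective exchange, Evap the
evaporative (sweat) loss and TRemitted the long-wave radiation emitted
by the clothing surface.  A sustained positive surplus indicates heat
stress; the five-level classification of the surplus lives in
:mod:`heatbudget.categorize`.

The model follows the COMFA lineage: the body is a clothed cylinder,
sensible heat flows from the core through a series network of tissue,
clothing and boundary-layer resistances, and a single parameter set —
:class:`PersonProfile` — switches between an adult and a child.  The
child differs only through its parameters (higher resting metabolic
rate per unit area, half the adult sweating capacity, smaller body and
hence higher surface-area-to-mass ratio); there is one code path.

Every sub-model constant (air volumetric heat capacity, psychrometric
constant, tissue-resistance ramp, wettedness ramp, sweat caps, ...)
lives in :class:`ConstantsRegistry` so the model can be recalibrated
from configuration without code changes.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .micromet import MicrometRecord
from .solar import SOLAR_CONSTANT_WM2, solar_elevation_deg

__all__ = [
    "PersonProfile",
    "SiteContext",
    "BudgetBreakdown",
    "ConstantsRegistry",
    "body_surface_area",
    "metabolic_heat",
    "core_temperature",
    "resistances",
    "absorbed_radiation",
    "convective_loss",
    "evaporative_loss",
    "emitted_longwave",
    "energy_budget",
    "saturation_vapor_pressure_kpa",
]

STEFAN_BOLTZMANN = 5.670374419e-8  # W m^-2 K^-4


@dataclass(frozen=True)
class ConstantsRegistry:
    """Physical and physiological constants of the budget sub-models.

    Units in field names or comments; all values must be positive.  The
    registry serializes with a run (see :func:`as_dict`) so every result
    carries the constants that produced it.
    """

    rho_cp: float = 1212.0  # volumetric heat capacity of air, J m^-3 K^-1
    gamma_kpa_k: float = 0.0667  # psychrometric constant, kPa/K
    nu_air: float = 1.6e-5  # kinematic viscosity of air, m^2/s
    k_air: float = 0.0267  # thermal conductivity of air, W m^-1 K^-1
    sigma: float = STEFAN_BOLTZMANN
    ground_emissivity: float = 0.95
    rt_rest_sm: float = 104.0  # tissue resistance at rest, s/m
    rt_min_sm: float = 10.0  # vasodilated floor, s/m
    k_rt: float = 0.25  # tissue-resistance drop per unit M, (s/m)/(W/m^2)
    w_min: float = 0.06  # minimum skin wettedness (insensible)
    m_wmax_wm2: float = 400.0  # M at which wettedness saturates, W/m^2
    s_cap_adult_wm2: float = 365.0  # adult maximum sweat evaporation, W/m^2
    tc_base_c: float = 36.5  # resting core temperature, °C
    tc_slope: float = 0.0043  # core-temperature rise per unit M, °C/(W/m^2)
    r_cv_sm: float = 150.0  # clothing vapor resistance, s/m
    wind_floor_ms: float = 0.3  # free-convection floor on wind speed, m/s
    solar_constant_wm2: float = SOLAR_CONSTANT_WM2

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"constant {f.name} must be positive")

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    def replace(self, **overrides) -> "ConstantsRegistry":
        return dataclasses.replace(self, **overrides)


DEFAULT_CONSTANTS = ConstantsRegistry()


@dataclass(frozen=True)
class PersonProfile:
    """Anthropometry, metabolism and clothing of one persona.

    ``sweat_capacity_factor`` scales the adult maximum evaporative
    capacity; 0.5 encodes the child's half sweating capacity.  ``met``
    is the activity multiple of the resting metabolic rate ``rmr_wm2``.
    """

    label: str
    age_class: str  # "child" or "adult"
    height_m: float
    mass_kg: float
    rmr_wm2: float
    met: float
    clo: float
    clothing_albedo: float = 0.37
    emissivity: float = 0.95
    sweat_capacity_factor: float = 1.0
    posture: str = "standing"
    work_fraction: float = 0.0  # mechanical work removed from M

    def __post_init__(self) -> None:
        if self.age_class not in ("child", "adult"):
            raise ValueError(f"age_class must be 'child' or 'adult', got {self.age_class!r}")
        if self.posture not in ("standing", "seated"):
            raise ValueError(f"posture must be 'standing' or 'seated', got {self.posture!r}")
        for name in ("height_m", "mass_kg", "rmr_wm2", "met", "clo"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 < self.sweat_capacity_factor <= 1.0):
            raise ValueError("sweat_capacity_factor must lie in (0, 1]")
        if self.met < 1.0:
            raise ValueError("met must be >= 1")
        if not (0.0 <= self.clothing_albedo <= 1.0 and 0.0 <= self.emissivity <= 1.0):
            raise ValueError("clothing_albedo and emissivity must lie in [0, 1]")


@dataclass(frozen=True)
class SiteContext:
    """Radiative environment of a location on or beside the field.

    ``shade_transmissivity`` is the fraction of solar radiation that
    penetrates overhead shade (1 = unshaded); ``sky_view_factor`` the
    fraction of the sky hemisphere visible.  The ground surface
    temperature used for terrestrial radiation is resolved in order:
    the record's measured ``ts_c`` when ``use_record_surface_temp``,
    else the fixed ``ground_surface_temp_c``, else air temperature
    (appropriate for irrigated grass).
    """

    sky_view_factor: float = 1.0
    shade_transmissivity: float = 1.0
    ground_albedo: float = 0.25
    ground_surface_temp_c: float | None = None
    use_record_surface_temp: bool = False
    diffuse_fraction: float = 0.15
    latitude_deg: float | None = None
    longitude_deg: float | None = None

    def __post_init__(self) -> None:
        for name in ("sky_view_factor", "shade_transmissivity", "ground_albedo", "diffuse_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    def resolve_ts_c(self, rec: MicrometRecord) -> float:
        if self.use_record_surface_temp:
            if rec.ts_c is None:
                raise ValueError(
                    f"site requires the record's ground-surface temperature (ts_c) "
                    f"but the record at {rec.timestamp} has none"
                )
            return rec.ts_c
        if self.ground_surface_temp_c is not None:
            return self.ground_surface_temp_c
        return rec.ta_c


@dataclass(frozen=True)
class BudgetBreakdown:
    """The five energy streams and the net budget for one observation.

    The conservation identity ``budget = m + rabs − conv − evap −
    tremit`` holds exactly (it is how ``budget_wm2`` is formed).
    Derived temperatures — core, skin, clothing surface — and the three
    series resistances are carried for diagnostics.
    """

    m_wm2: float
    rabs_wm2: float
    conv_wm2: float
    evap_wm2: float
    tremit_wm2: float
    budget_wm2: float
    tc_c: float
    tsk_c: float
    tsurf_c: float
    resistances: tuple[float, float, float]  # (ra, rc, rt), s/m


def body_surface_area(height_m: float, mass_kg: float) -> float:
    """DuBois body surface area, m²: 0.007184·(100·h)^0.725·m^0.425."""
    if height_m <= 0 or mass_kg <= 0:
        raise ValueError("height and mass must be positive")
    return 0.007184 * (100.0 * height_m) ** 0.725 * mass_kg**0.425


def metabolic_heat(profile: PersonProfile) -> float:
    """Metabolic heat production M = met · RMR · (1 − work_fraction), W/m²."""
    return profile.met * profile.rmr_wm2 * (1.0 - profile.work_fraction)


def core_temperature(m_wm2: float, constants: ConstantsRegistry = DEFAULT_CONSTANTS) -> float:
    """Core temperature closure: Tc = 36.5 + 0.0043·M (°C).

    A linear rise of the regulated core set-point with metabolic rate;
    it supplies the driving gradient for the sensible-heat network.
    """
    if m_wm2 < 0:
        raise ValueError("metabolic rate must be non-negative")
    return constants.tc_base_c + constants.tc_slope * m_wm2


# Hilpert correlation bands for a cylinder in cross-flow: (Re_max, C, n)
_HILPERT = (
    (4.0, 0.989, 0.330),
    (40.0, 0.911, 0.385),
    (4000.0, 0.683, 0.466),
    (40000.0, 0.193, 0.618),
    (4.0e5, 0.027, 0.805),
)


def resistances(
    profile: PersonProfile,
    rec: MicrometRecord,
    constants: ConstantsRegistry = DEFAULT_CONSTANTS,
) -> tuple[float, float, float]:
    """Series resistances (ra, rc, rt) of the sensible-heat network, s/m.

    * boundary layer ``ra``: the body as a cylinder of diameter
      d = BSA/(π·height) in cross-flow; Nu = C·Re^n with Hilpert
      coefficients per Reynolds band, ra = ρcp·d/(Nu·k_air).  Wind is
      floored at the free-convection threshold.
    * clothing ``rc``: clo·0.155·ρcp (1 clo = 0.155 m²K/W).
    * tissue ``rt``: linear vasodilation ramp with metabolic rate,
      clamped between the vasodilated floor and the resting value.
    """
    c = constants
    ws = max(rec.ws_ms, c.wind_floor_ms)
    bsa = body_surface_area(profile.height_m, profile.mass_kg)
    d = bsa / (math.pi * profile.height_m)
    re = ws * d / c.nu_air
    for re_max, coef, exp in _HILPERT:
        if re <= re_max:
            break
    nu = coef * re**exp
    ra = c.rho_cp * d / (nu * c.k_air)
    rc = profile.clo * 0.155 * c.rho_cp
    m = metabolic_heat(profile)
    rt = min(max(c.rt_rest_sm - c.k_rt * m, c.rt_min_sm), c.rt_rest_sm)
    return (ra, rc, rt)


def _idso_sky_emissivity(ta_c: float, e_air_kpa: float) -> float:
    """Idso clear-sky atmospheric emissivity (vapor pressure in hPa)."""
    ta_k = ta_c + 273.15
    return min(0.70 + 5.95e-5 * (10.0 * e_air_kpa) * math.exp(1500.0 / ta_k), 1.0)


def saturation_vapor_pressure_kpa(t_c):
    """Tetens saturation vapor pressure over water, kPa."""
    t = np.asarray(t_c, dtype=float)
    e = 0.6108 * np.exp(17.27 * t / (t + 237.3))
    return float(e) if np.ndim(t_c) == 0 else e


def absorbed_radiation(
    rec: MicrometRecord,
    site: SiteContext,
    profile: PersonProfile,
    elevation_deg: float | None = None,
    constants: ConstantsRegistry = DEFAULT_CONSTANTS,
) -> float:
    """Absorbed short- plus long-wave radiation on the body, W/m².

    Shortwave: global horizontal irradiance SR is split into diffuse
    K_d = diffuse_fraction·SR and beam-normal K_bn = (SR − K_d)/sin β;
    the vertical-cylinder interception factor is cos β/π.  Shade
    transmissivity τ attenuates the beam and sky-diffuse terms; half
    the ground-reflected flux reaches the (lower half of the) body:

        SW = (1 − α_clothing) · [ τ·(cos β/π)·K_bn + τ·0.5·SVF·K_d
                                  + 0.5·α_ground·SR ]

    Longwave: half the body's view is sky-weighted (SVF splits it
    between clear sky at Idso emissivity and surrounding obstructions
    radiating at air temperature), half sees the ground at its surface
    temperature:

        LW = ε · [ 0.5·SVF·ε_sky·σTa⁴ + 0.5·(1−SVF)·σTa⁴ + 0.5·ε_g·σTs⁴ ]
    """
    c = constants
    if elevation_deg is None:
        if site.latitude_deg is None or site.longitude_deg is None:
            raise ValueError(
                "absorbed_radiation needs a solar elevation: pass elevation_deg or "
                "configure site latitude/longitude"
            )
        elevation_deg = solar_elevation_deg(rec.timestamp, site.latitude_deg, site.longitude_deg)

    sr = rec.sr_wm2
    beta = math.radians(elevation_deg)
    if elevation_deg <= 2.0 and sr > 50.0:
        warnings.warn(
            f"solar elevation {elevation_deg:.1f}° with SR={sr:.0f} W/m² is "
            "inconsistent (sun at or below horizon); beam component suppressed",
            stacklevel=2,
        )

    tau = site.shade_transmissivity
    k_d = site.diffuse_fraction * sr
    if elevation_deg > 2.0:
        k_bn = min((sr - k_d) / math.sin(beta), c.solar_constant_wm2)
        f_cyl = math.cos(beta) / math.pi
        beam = tau * f_cyl * k_bn
    else:
        beam = 0.0
    shortwave = (1.0 - profile.clothing_albedo) * (
        beam + tau * 0.5 * site.sky_view_factor * k_d + 0.5 * site.ground_albedo * sr
    )

    ta_k = rec.ta_c + 273.15
    ts_k = site.resolve_ts_c(rec) + 273.15
    e_air = rec.rh_pct / 100.0 * saturation_vapor_pressure_kpa(rec.ta_c)
    eps_sky = _idso_sky_emissivity(rec.ta_c, e_air)
    svf = site.sky_view_factor
    longwave = profile.emissivity * (
        0.5 * svf * eps_sky * c.sigma * ta_k**4
        + 0.5 * (1.0 - svf) * c.sigma * ta_k**4
        + 0.5 * c.ground_emissivity * c.sigma * ts_k**4
    )

    rabs = shortwave + longwave
    if shortwave < 0 or longwave < 0:
        raise RuntimeError("negative radiation component — internal error")
    return rabs


def convective_loss(
    profile: PersonProfile,
    rec: MicrometRecord,
    constants: ConstantsRegistry = DEFAULT_CONSTANTS,
) -> tuple[float, float, float]:
    """Sensible convective flux through the series network, W/m².

    Returns ``(conv, tsk_c, tsurf_c)``: the flux ρcp·(Tc − Ta)/(rt+rc+ra)
    and the skin and clothing-surface temperatures read off the network
    nodes.  Negative conv means sensible heat gain (air hotter than
    core).
    """
    c = constants
    ra, rc, rt = resistances(profile, rec, c)
    m = metabolic_heat(profile)
    tc = core_temperature(m, c)
    flux = c.rho_cp * (tc - rec.ta_c) / (rt + rc + ra)
    tsk = rec.ta_c + flux * (ra + rc) / c.rho_cp
    tsurf = rec.ta_c + flux * ra / c.rho_cp
    return flux, tsk, tsurf


def evaporative_loss(
    profile: PersonProfile,
    rec: MicrometRecord,
    tsk_c: float,
    constants: ConstantsRegistry = DEFAULT_CONSTANTS,
) -> float:
    """Evaporative heat loss, W/m².

    Potential evaporation from fully wet skin follows the psychrometric
    form E_pot = (ρcp/γ)·(e_s(Tsk) − e_air)/(ra + r_cv); actual skin
    wettedness ramps linearly with metabolic rate from the insensible
    minimum to 1 at the saturation workload; the result is capped at
    the persona's sweating capacity (half the adult maximum for a
    child) and floored at zero (no condensation gain modelled).
    """
    c = constants
    ra, _, _ = resistances(profile, rec, c)
    e_air = rec.rh_pct / 100.0 * saturation_vapor_pressure_kpa(rec.ta_c)
    e_sk = saturation_vapor_pressure_kpa(tsk_c)
    e_pot = (c.rho_cp / c.gamma_kpa_k) * (e_sk - e_air) / (ra + c.r_cv_sm)
    m = metabolic_heat(profile)
    denom = max(c.m_wmax_wm2 - profile.rmr_wm2, 1.0)
    w = c.w_min + (1.0 - c.w_min) * (m - profile.rmr_wm2) / denom
    w = min(max(w, c.w_min), 1.0)
    cap = profile.sweat_capacity_factor * c.s_cap_adult_wm2
    return max(0.0, min(w * e_pot, cap))


def emitted_longwave(
    tsurf_c: float,
    profile: PersonProfile,
    constants: ConstantsRegistry = DEFAULT_CONSTANTS,
) -> float:
    """Long-wave radiation emitted by the clothing surface: ε·σ·Tsurf⁴, W/m²."""
    return profile.emissivity * constants.sigma * (tsurf_c + 273.15) ** 4


def energy_budget(
    profile: PersonProfile,
    rec: MicrometRecord,
    site: SiteContext,
    elevation_deg: float | None = None,
    constants: ConstantsRegistry = DEFAULT_CONSTANTS,
) -> BudgetBreakdown:
    """Full energy budget for one persona at one observation.

    Composes the five streams; adult and child share this single code
    path and differ only through the :class:`PersonProfile` parameters.
    """
    m = metabolic_heat(profile)
    tc = core_temperature(m, constants)
    ra, rc, rt = resistances(profile, rec, constants)
    rabs = absorbed_radiation(rec, site, profile, elevation_deg, constants)
    conv, tsk, tsurf = convective_loss(profile, rec, constants)
    evap = evaporative_loss(profile, rec, tsk, constants)
    tremit = emitted_longwave(tsurf, profile, constants)
    budget = m + rabs - conv - evap - tremit
    return BudgetBreakdown(
        m_wm2=m,
        rabs_wm2=rabs,
        conv_wm2=conv,
        evap_wm2=evap,
        tremit_wm2=tremit,
        budget_wm2=budget,
        tc_c=tc,
        tsk_c=tsk,
        tsurf_c=tsurf,
        resistances=(ra, rc, rt),
    )
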