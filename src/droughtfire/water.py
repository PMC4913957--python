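"""3-PG-style monthly soil-water balance.

Implements the water-balance subset of the 3-PG forest model: stomatal
modifiers for temperature, vapor pressure deficit, frost and soil water;
Penman-Monteith canopy transpiration with an LAI-coupled conductance and an
LAI-dependent daily transpiration ceiling; canopy rainfall interception; and
the monthly bookkeeping

    ASW(t + dt) = ASW(t) + P - E - T

with overflow above ASW_max lost as runoff/drainage.  The relative soil-water
availability fASW (the soil-water modifier, in [0, 1]) is the quantity the
fire classifier consumes.

Also provides two utilities discussed alongside the model: the number of
30-day months needed to transpire a full store dry at the ceiling rate, and a
simplified inversion recovering ASW_max from an observed maximum leaf area
index under a given climate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .climate import MonthlyClimate

__all__ = [
    "SiteParams",
    "WaterBalanceState",
    "ModifierSet",
    "MonthlyFlux",
    "WaterConfig",
    "SOIL_WATER_PARAMS",
    "temp_modifier",
    "sw_modifier",
    "vpd_modifier",
    "frost_modifier",
    "transpiration_ceiling",
    "monthly_transpiration",
    "interception_evap",
    "step_month",
    "simulate_fasw",
    "drawdown_months",
    "supportable_lai",
    "invert_asw_max",
    "NoSolutionError",
]

#: Soil-water modifier constants (c_theta, n_theta) per texture class,
#: following common 3-PG practice: coarse soils release freely then cut off
#: sharply; clays restrict earlier but more gradually.
SOIL_WATER_PARAMS: dict[str, tuple[float, float]] = {
    "sand": (0.7, 9.0),
    "sandy_loam": (0.6, 7.0),
    "clay_loam": (0.5, 5.0),
    "clay": (0.4, 3.0),
}

DEFAULT_TEMP_PARAMS = (-7.0, 18.0, 40.0)  # (t_min, t_opt, t_max) deg C
STOMATAL_SHUTDOWN_C = -2.0  # photosynthesis/conductance truncated to zero below


class NoSolutionError(RuntimeError):
    """Raised when the ASW_max inversion cannot bracket a solution."""


@dataclass(frozen=True)
class WaterConfig:
    """Tunable physical constants of the water balance.

    Attributes
    ----------
    k_vpd : stomatal sensitivity to daytime VPD, mbar^-1.
    lai_sat : LAI above which canopy conductance and the transpiration
        ceiling saturate (m2 m-2).
    t_plateau : maximum average daily transpiration at saturating LAI
        (mm day-1).
    i_max : maximum fraction of rainfall intercepted (and evaporated) by a
        closed canopy.
    gs_per_lai : maximum stomatal conductance contribution per unit LAI
        (m s-1).
    g_bl : canopy boundary-layer conductance (m s-1).
    rad_abs_frac, rad_offset_w : net-radiation linearization
        R_net = rad_offset_w + rad_abs_frac * SW over the daylight window.
    support_threshold : fraction of unrestricted growing-season transpiration
        demand a site must be able to meet for an LAI to count as supportable
        (used by the ASW_max inversion).
    """

    k_vpd: float = 0.05
    lai_sat: float = 5.0
    t_plateau: float = 3.0
    i_max: float = 0.15
    gs_per_lai: float = 0.006
    g_bl: float = 0.2
    rad_abs_frac: float = 0.8
    rad_offset_w: float = -90.0
    daylight_seconds: float = 43200.0
    support_threshold: float = 0.5


DEFAULT_CONFIG = WaterConfig()


@dataclass(frozen=True)
class SiteParams:
    """Static pixel attributes.

    ``fertility`` (the 3-PG soil fertility rating S_f in [0, 1]) is carried
    for completeness but plays no role in the fire logic.
    """

    lai_max: float  # m2 m-2, satellite-calibrated range 0.5-6.0
    asw_max: float  # mm, field capacity minus wilting point over the root zone
    soil_class: str = "sandy_loam"
    fertility: float = 0.5
    temp_params: tuple[float, float, float] = DEFAULT_TEMP_PARAMS

    def __post_init__(self) -> None:
        if self.asw_max <= 0:
            raise ValueError(f"asw_max must be > 0, got {self.asw_max}")
        if self.soil_class not in SOIL_WATER_PARAMS:
            raise ValueError(
                f"unknown soil_class {self.soil_class!r}; "
                f"expected one of {sorted(SOIL_WATER_PARAMS)}"
            )
        tn, to, tx = self.temp_params
        if not tn < to < tx:
            raise ValueError(f"temp_params must be ordered t_min < t_opt < t_max, got {self.temp_params}")


@dataclass(frozen=True)
class WaterBalanceState:
    """Running state of the monthly update: soil store, snow store, month count."""

    asw: float  # mm, available soil water at the start of the month
    month_index: int = 0
    snow: float = 0.0  # mm water equivalent held as snow

    def __post_init__(self) -> None:
        if self.asw < 0 or self.snow < 0:
            raise ValueError("asw and snow must be >= 0")


@dataclass(frozen=True)
class ModifierSet:
    """Stomatal restriction multipliers, each in [0, 1] (0 = full shutdown)."""

    f_temp: float
    f_vpd: float
    f_frost: float
    f_sw: float

    def __post_init__(self) -> None:
        for name in ("f_temp", "f_vpd", "f_frost", "f_sw"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")

    @property
    def product(self) -> float:
        return self.f_temp * self.f_vpd * self.f_frost * self.f_sw


@dataclass(frozen=True)
class MonthlyFlux:
    """Water fluxes of one monthly step (all mm/month) plus the reported fASW."""

    transpiration: float
    interception_evap: float
    runoff: float
    fasw: float


def temp_modifier(t_mean: float, temp_params: Sequence[float] = DEFAULT_TEMP_PARAMS) -> float:
    """Temperature modifier on the standard 3-PG form.

    f_T = ((T - Tmin)/(Topt - Tmin)) * ((Tmax - T)/(Tmax - Topt))^p with
    p = (Tmax - Topt)/(Topt - Tmin), zero outside (Tmin, Tmax), and forced to
    zero below -2 deg C where stomata are closed regardless.
    """
    tn, to, tx = temp_params
    if not tn < to < tx:
        raise ValueError(f"temp_params must satisfy t_min < t_opt < t_max, got {temp_params}")
    t = float(t_mean)
    if t < STOMATAL_SHUTDOWN_C or t <= tn or t >= tx:
        return 0.0
    power = (tx - to) / (to - tn)
    val = ((t - tn) / (to - tn)) * ((tx - t) / (tx - to)) ** power
    return float(min(max(val, 0.0), 1.0))


def sw_modifier(asw: float, asw_max: float, soil_class: str = "sandy_loam") -> float:
    """Soil-water modifier fASW = 1 / (1 + ((1 - r)/c)^n), r = ASW/ASW_max.

    Strictly increasing in the stored fraction r; equals 1 at field capacity.
    """
    if asw_max <= 0:
        raise ValueError(f"asw_max must be > 0, got {asw_max}")
    if not 0.0 <= asw <= asw_max * (1 + 1e-9):
        raise ValueError(f"asw={asw} outside [0, asw_max={asw_max}]")
    c, n = SOIL_WATER_PARAMS[soil_class]
    r = min(asw / asw_max, 1.0)
    return float(1.0 / (1.0 + ((1.0 - r) / c) ** n))


def vpd_modifier(vpd_day: float, k_vpd: float = DEFAULT_CONFIG.k_vpd) -> float:
    """VPD modifier exp(-k_D * D), strictly decreasing in daytime VPD (mbar)."""
    if vpd_day < 0:
        raise ValueError(f"vpd_day must be >= 0, got {vpd_day}")
    return float(math.exp(-k_vpd * vpd_day))


def frost_modifier(frost_days: float, ndays: float) -> float:
    """Fraction of the month with open stomata: 1 - frost_days / days-in-month."""
    if not 0 <= frost_days <= ndays:
        raise ValueError(f"frost_days={frost_days} outside [0, {ndays}]")
    return float(1.0 - frost_days / ndays)


def transpiration_ceiling(lai: float, config: WaterConfig = DEFAULT_CONFIG) -> float:
    """Maximum average daily transpiration (mm day-1) as a function of LAI.

    Linear in LAI below the saturation value (~5 m2 m-2), flat at the plateau
    rate (~3 mm day-1) above it: shading progressively restricts stomatal
    opening in dense canopies, so added leaf area stops adding transpiration.
    """
    if lai < 0:
        raise ValueError(f"lai must be >= 0, got {lai}")
    return config.t_plateau * min(lai / config.lai_sat, 1.0)


# Penman-Monteith constants at the monthly scale (canopy energy balance):
_E20 = 2.2          # slope of SVP curve / psychrometric constant near 20 C
_RHO_AIR = 1.2      # kg m-3
_LAMBDA = 2.46e6    # J kg-1, latent heat of vaporization
_VPD_CONV = 0.000622  # (kg water / kg air) per mbar of VPD


def monthly_transpiration(
    climate: MonthlyClimate,
    site: SiteParams,
    mods: ModifierSet,
    config: WaterConfig = DEFAULT_CONFIG,
) -> float:
    """Canopy transpiration for one month (mm) from the Penman-Monteith equation.

    Canopy conductance is stomatal conductance scaled by LAI (saturating at
    ``lai_sat``) and multiplied by the four restriction modifiers.  The result
    is capped by the LAI-dependent daily transpiration ceiling times the
    number of days in the month, which enforces the observed plateau in dense
    stands irrespective of the radiative demand.
    """
    ndays = climate.ndays
    phys = mods.product
    if phys <= 0.0:
        return 0.0
    g_c = config.gs_per_lai * min(site.lai_max, config.lai_sat) * phys
    if g_c <= 0.0:
        return 0.0

    sw_watts = climate.radiation * 1e6 / (ndays * config.daylight_seconds)
    net_rad = config.rad_offset_w + config.rad_abs_frac * sw_watts
    demand = _RHO_AIR * _LAMBDA * _VPD_CONV * climate.vpd_day * config.g_bl
    flux = (_E20 * net_rad + demand) / (1.0 + _E20 + config.g_bl / g_c)  # J m-2 s-1
    daily = max(flux, 0.0) / _LAMBDA * config.daylight_seconds  # mm day-1
    daily = min(daily, transpiration_ceiling(site.lai_max, config))
    return float(daily * ndays)


def interception_evap(
    precip: float, lai: float, config: WaterConfig = DEFAULT_CONFIG
) -> float:
    """Rainfall intercepted by the canopy and lost to evaporation (mm).

    A fixed maximum fraction of rainfall for closed canopies, scaled down
    linearly with LAI below saturation.  Never exceeds the rainfall itself.
    """
    if precip < 0:
        raise ValueError(f"precip must be >= 0, got {precip}")
    if lai < 0:
        raise ValueError(f"lai must be >= 0, got {lai}")
    return float(config.i_max * min(lai / config.lai_sat, 1.0) * precip)


def step_month(
    state: WaterBalanceState,
    climate: MonthlyClimate,
    site: SiteParams,
    config: WaterConfig = DEFAULT_CONFIG,
) -> tuple[WaterBalanceState, MonthlyFlux]:
    """One monthly update of the soil-water store.

    Order of operations: snow routing (sub-zero months bank their
    precipitation, released in the first above-freezing month — a crude
    stand-in, since a monthly model cannot track snow accurately), canopy
    interception of the liquid input, stomatal modifiers evaluated at the
    start-of-month store, Penman-Monteith transpiration limited to the water
    actually present, then the store update with overflow above ASW_max lost
    as runoff.  The reported fASW is the soil-water modifier evaluated at the
    mean of the start- and end-of-month store.
    """
    ndays = climate.ndays

    if climate.tmean < 0.0:
        liquid = 0.0
        snow = state.snow + climate.precip
    else:
        liquid = climate.precip + state.snow
        snow = 0.0

    evap = interception_evap(liquid, site.lai_max, config)
    mods = ModifierSet(
        f_temp=temp_modifier(climate.tmean, site.temp_params),
        f_vpd=vpd_modifier(climate.vpd_day, config.k_vpd),
        f_frost=frost_modifier(climate.frost_days, ndays),
        f_sw=sw_modifier(state.asw, site.asw_max, site.soil_class),
    )
    transp = monthly_transpiration(climate, site, mods, config)
    transp = min(transp, max(state.asw + liquid - evap, 0.0))

    raw = state.asw + liquid - evap - transp
    runoff = max(raw - site.asw_max, 0.0)
    asw_new = min(max(raw, 0.0), site.asw_max)

    fasw = sw_modifier(0.5 * (state.asw + asw_new), site.asw_max, site.soil_class)
    new_state = WaterBalanceState(asw=asw_new, month_index=state.month_index + 1, snow=snow)
    return new_state, MonthlyFlux(
        transpiration=transp, interception_evap=evap, runoff=runoff, fasw=fasw
    )


def simulate_fasw(
    site: SiteParams,
    climate_series: Iterable[MonthlyClimate],
    init_asw: float | str = "field-capacity",
    config: WaterConfig = DEFAULT_CONFIG,
) -> pd.DataFrame:
    """Run the monthly balance over a contiguous climate series.

    Returns a DataFrame with one row per month: ``year, month, asw_start,
    asw_end, snow_end, fasw, transpiration, interception, precip, runoff``.
    The series must be contiguous in (year, month); gaps raise ``ValueError``.
    Water mass closes exactly: sum(P) - sum(E) - sum(T) - sum(runoff) equals
    the change in stored water (soil + snow).
    """
    months = list(climate_series)
    if not months:
        raise ValueError("empty climate series")
    for prev, cur in zip(months, months[1:]):
        expect = (prev.year + 1, 1) if prev.month == 12 else (prev.year, prev.month + 1)
        if (cur.year, cur.month) != expect:
            raise ValueError(
                f"gap in climate series: {prev.year}-{prev.month:02d} is followed "
                f"by {cur.year}-{cur.month:02d}"
            )

    asw0 = site.asw_max if init_asw == "field-capacity" else float(init_asw)
    state = WaterBalanceState(asw=asw0)
    rows = []
    for clim in months:
        start = state.asw
        state, flux = step_month(state, clim, site, config)
        rows.append(
            {
                "year": clim.year,
                "month": clim.month,
                "asw_start": start,
                "asw_end": state.asw,
                "snow_end": state.snow,
                "fasw": flux.fasw,
                "transpiration": flux.transpiration,
                "interception": flux.interception_evap,
                "precip": clim.precip,
                "runoff": flux.runoff,
            }
        )
    return pd.DataFrame(rows)


def drawdown_months(asw_max: float, lai: float, config: WaterConfig = DEFAULT_CONFIG) -> float:
    """30-day months needed to transpire a full store dry at the ceiling rate.

    With zero precipitation and transpiration pinned at the LAI-dependent
    ceiling, depletion time is ASW_max / (ceiling * 30).  An LAI of zero
    transpires nothing, so the store never empties (returns ``inf``).
    """
    if asw_max <= 0:
        raise ValueError(f"asw_max must be > 0, got {asw_max}")
    if lai < 0:
        raise ValueError(f"lai must be >= 0, got {lai}")
    rate = transpiration_ceiling(lai, config)
    if rate == 0.0:
        return math.inf
    return float(asw_max / (rate * 30.0))


GROWING_SEASON_MONTHS = (4, 5, 6, 7, 8, 9)


def _growing_season_supply_ratio(
    lai: float,
    asw_max: float,
    climate_series: Sequence[MonthlyClimate],
    soil_class: str,
    config: WaterConfig,
) -> float:
    """Fraction of unrestricted Apr-Sep transpiration demand the store can meet.

    Simulates the balance, then compares realized growing-season transpiration
    (after one spin-up year) against what the same canopy would transpire with
    no soil-water restriction (f_sw = 1, all else equal).  Monotone
    non-decreasing in ``asw_max``: a larger store carries more wet-season
    water into the dry season.
    """
    site = SiteParams(lai_max=lai, asw_max=asw_max, soil_class=soil_class)
    traj = simulate_fasw(site, climate_series, config=config)
    first_year = climate_series[0].year
    actual = 0.0
    potential = 0.0
    for clim, t_act in zip(climate_series, traj["transpiration"]):
        if clim.year == first_year or clim.month not in GROWING_SEASON_MONTHS:
            continue
        mods = ModifierSet(
            f_temp=temp_modifier(clim.tmean, site.temp_params),
            f_vpd=vpd_modifier(clim.vpd_day, config.k_vpd),
            f_frost=frost_modifier(clim.frost_days, clim.ndays),
            f_sw=1.0,
        )
        actual += t_act
        potential += monthly_transpiration(clim, site, mods, config)
    if potential <= 0.0:
        return 1.0  # no evaporative demand at all: water cannot be limiting
    return float(actual / potential)


def supportable_lai(
    asw_max: float,
    climate_series: Sequence[MonthlyClimate],
    soil_class: str = "sandy_loam",
    config: WaterConfig = DEFAULT_CONFIG,
    lai_bounds: tuple[float, float] = (0.5, 6.0),
    tol: float = 1e-3,
) -> float:
    """Largest LAI able to meet the support threshold of its transpiration demand.

    Denser canopies demand more water and deplete the store further, so the
    fraction of unrestricted growing-season transpiration actually realized is
    decreasing in LAI; the supportable LAI is where it crosses
    ``config.support_threshold``.  Clamped to the satellite-calibrated LAI
    range when the crossing lies outside it.
    """
    lo, hi = lai_bounds
    theta = config.support_threshold
    f = lambda lai: _growing_season_supply_ratio(lai, asw_max, climate_series, soil_class, config) - theta
    if f(hi) >= 0:
        return hi  # even the densest canopy never draws the store down
    if f(lo) <= 0:
        return lo
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if f(mid) >= 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def invert_asw_max(
    lai_obs: float,
    climate_series: Sequence[MonthlyClimate],
    soil_class: str = "sandy_loam",
    config: WaterConfig = DEFAULT_CONFIG,
    asw_bounds: tuple[float, float] = (10.0, 1000.0),
    tol: float = 0.5,
) -> float:
    """Recover ASW_max from an observed LAI_max under a given climate.

    The forward assumption is that a site's canopy grows to the largest LAI
    the soil-water supply can support: at ``lai_obs`` the store meets exactly
    the support-threshold fraction of the canopy's unrestricted growing-season
    transpiration demand.  Since that fraction is increasing in ASW_max (a
    bigger store carries more wet-season water into the dry season), bisection
    finds the matching store size.

    Under a wet, never-limiting climate the estimate collapses to the lower
    search bound (ASW_max is unidentifiable from LAI there).  If even the
    upper bound cannot support ``lai_obs``, raises :class:`NoSolutionError`.
    """
    if not 0.5 <= lai_obs <= 6.0:
        raise ValueError(f"lai_obs must be in [0.5, 6.0], got {lai_obs}")
    lo, hi = asw_bounds
    theta = config.support_threshold
    f = lambda a: _growing_season_supply_ratio(lai_obs, a, climate_series, soil_class, config) - theta
    if f(lo) >= 0:
        return lo  # water never limiting: estimate pinned at the search floor
    if f(hi) < 0:
        raise NoSolutionError(
            f"no ASW_max in [{lo}, {hi}] mm supports LAI {lai_obs} under this climate"
        )
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if f(mid) >= 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)
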