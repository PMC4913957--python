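"""Derived climate forcing: vapor pressure deficit, frost days, seasonal averaging.

The monthly water balance needs two quantities that gridded climate products
rarely ship directly: the mean daytime vapor pressure deficit (VPD) and the
number of days per month with stomata-closing subfreezing temperatures.  Both
are derived here from mean monthly minimum and maximum temperature.  The module
also aggregates monthly soil-water availability (fASW) series into the eight
seasonal mean features the fire classifier consumes.
"""

from __future__ import annotations

import calendar
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MonthlyClimate",
    "SeasonalFeatures",
    "FEATURE_NAMES",
    "saturation_vapor_pressure",
    "derive_vpd",
    "frost_days",
    "season_average",
    "days_in_month",
    "read_climate_csv",
]

#: Canonical ordering of the classifier feature vector.
FEATURE_NAMES = (
    "winter_cur",
    "spring_cur",
    "summer_cur",
    "autumn_cur",
    "winter_prev",
    "spring_prev",
    "summer_prev",
    "autumn_prev",
)

# Months (1-12) belonging to each climatological season.  Winter of year y is
# calendar-contiguous DJF: December of y-1 plus January/February of y.
SEASON_MONTHS = {
    "winter": (12, 1, 2),
    "spring": (3, 4, 5),
    "summer": (6, 7, 8),
    "autumn": (9, 10, 11),
}

#: Subfreezing threshold (deg C) below which stomata close for at least a day.
FROST_THRESHOLD_C = 2.0

#: Logistic rate (per deg C) of the empirical frost-day curve.
FROST_LOGISTIC_RATE = 1.0


def days_in_month(year: int, month: int) -> int:
    return calendar.monthrange(year, month)[1]


def saturation_vapor_pressure(t_c: float) -> float:
    """Saturation vapor pressure in mbar (hPa) at air temperature ``t_c`` (deg C).

    Tetens-type exponential over liquid water::

        e_s(T) = 6.1078 * exp(17.269 * T / (237.3 + T))

    This is the single place the SVP closed form lives; the VPD derivation and
    its test oracle both reference it.
    """
    if isinstance(t_c, (int, float)):
        return 6.1078 * math.exp(17.269 * t_c / (237.3 + t_c))
    t = np.asarray(t_c, dtype=float)
    return 6.1078 * np.exp(17.269 * t / (237.3 + t))


def derive_vpd(tmin: float, tmax: float) -> tuple[float, float]:
    """Monthly maximum and mean-daytime VPD (mbar) from temperature extremes.

    The ambient vapor concentration is assumed to equal saturation at the mean
    minimum temperature, so the maximum VPD is the difference of saturation
    vapor pressures at the mean maximum and minimum temperatures.  Mean daytime
    VPD is two thirds of that maximum.

    Returns ``(vpd_max, vpd_day)``.  Raises ``ValueError`` when tmax < tmin.
    """
    if np.any(np.asarray(tmax) < np.asarray(tmin)):
        raise ValueError(f"tmax ({tmax!r}) must be >= tmin ({tmin!r})")
    vpd_max = saturation_vapor_pressure(tmax) - saturation_vapor_pressure(tmin)
    return vpd_max, (2.0 / 3.0) * vpd_max


def frost_days(tmin: float, month: int, year: int = 2001) -> float:
    """Estimated number of days in ``month`` with subfreezing (<= 2 deg C) minima.

    The curve is an empirical logistic in ``(2 - tmin)`` saturating at the
    number of calendar days in the month, with half-saturation exactly at a
    mean minimum of 2 deg C:

        frost = ndays / (1 + exp(-k * (2 - tmin))),  k = 1 per deg C

    Monotone non-increasing in tmin; ~0 for warm months and the full month for
    tmin far below freezing.
    """
    if not 1 <= int(month) <= 12:
        raise ValueError(f"month must be in 1..12, got {month!r}")
    ndays = days_in_month(year, month)
    z = FROST_LOGISTIC_RATE * (FROST_THRESHOLD_C - float(tmin))
    if z > 0:  # guard exp overflow for very cold months
        return ndays / (1.0 + math.exp(-z))
    ez = math.exp(z)
    return ndays * ez / (1.0 + ez)


@dataclass(frozen=True)
class MonthlyClimate:
    """One month of forcing for one pixel.

    ``vpd_day`` (mbar) and ``frost_days`` are derived from the temperature
    fields on construction when not supplied.
    """

    year: int
    month: int
    precip: float  # mm / month
    tmin: float  # deg C
    tmax: float  # deg C
    radiation: float  # MJ m-2 / month, incoming shortwave
    vpd_day: float = field(default=None)  # type: ignore[assignment]
    frost_days: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not 1 <= self.month <= 12:
            raise ValueError(f"month must be in 1..12, got {self.month}")
        if self.precip < 0:
            raise ValueError(f"precip must be >= 0, got {self.precip}")
        if self.radiation < 0:
            raise ValueError(f"radiation must be >= 0, got {self.radiation}")
        if self.tmax < self.tmin:
            raise ValueError(f"tmax ({self.tmax}) < tmin ({self.tmin})")
        if self.vpd_day is None:
            _, vday = derive_vpd(self.tmin, self.tmax)
            object.__setattr__(self, "vpd_day", float(vday))
        if self.frost_days is None:
            object.__setattr__(
                self, "frost_days", float(frost_days(self.tmin, self.month, self.year))
            )
        ndays = days_in_month(self.year, self.month)
        if not 0 <= self.frost_days <= ndays:
            raise ValueError(
                f"frost_days {self.frost_days} outside [0, {ndays}] for "
                f"{self.year}-{self.month:02d}"
            )

    @property
    def tmean(self) -> float:
        return 0.5 * (self.tmin + self.tmax)

    @property
    def ndays(self) -> int:
        return days_in_month(self.year, self.month)


@dataclass(frozen=True)
class SeasonalFeatures:
    """Eight seasonal mean fASW values for one pixel and one fire year.

    Current-year seasons are those of ``fire_year`` (winter = Dec of
    fire_year-1 through Feb of fire_year); previous-year seasons are shifted
    back one year.
    """

    winter_cur: float
    spring_cur: float
    summer_cur: float
    autumn_cur: float
    winter_prev: float
    spring_prev: float
    summer_prev: float
    autumn_prev: float
    fire_year: int

    def __post_init__(self) -> None:
        for name in FEATURE_NAMES:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values, fire_year: int) -> "SeasonalFeatures":
        values = np.asarray(values, dtype=float)
        if values.shape != (8,):
            raise ValueError(f"expected 8 features, got shape {values.shape}")
        return cls(*values.tolist(), fire_year=fire_year)


def _season_window(season: str, season_year: int) -> list[tuple[int, int]]:
    """(year, month) triple covered by ``season`` of ``season_year``."""
    months = SEASON_MONTHS[season]
    return [(season_year - 1 if m == 12 else season_year, m) for m in months]


def season_average(fasw_series: pd.DataFrame | pd.Series, fire_year: int) -> SeasonalFeatures:
    """Average a monthly fASW series into the eight seasonal features.

    Parameters
    ----------
    fasw_series
        A DataFrame with columns ``year``, ``month``, ``fasw``; a Series
        indexed by ``(year, month)``; or a plain ``{(year, month): fasw}``
        mapping.  Must cover December of
        ``fire_year - 2`` through November of ``fire_year`` with no gaps in
        the needed months.
    fire_year
        The year whose fire occurrence is being predicted.

    Raises ``ValueError`` (missing data) when any required month is absent.
    """
    if isinstance(fasw_series, pd.DataFrame):
        lookup = {
            (int(r.year), int(r.month)): float(r.fasw)
            for r in fasw_series.itertuples(index=False)
        }
    elif isinstance(fasw_series, dict):
        lookup = fasw_series
    else:
        lookup = {
            (int(y), int(m)): float(v) for (y, m), v in fasw_series.items()
        }

    values: dict[str, float] = {}
    for suffix, offset in (("cur", 0), ("prev", 1)):
        for season in ("winter", "spring", "summer", "autumn"):
            window = _season_window(season, fire_year - offset)
            try:
                monthly = [lookup[key] for key in window]
            except KeyError as exc:
                raise ValueError(
                    f"fASW series is missing month {exc.args[0]} needed for "
                    f"{season}_{suffix} of fire year {fire_year}"
                ) from None
            values[f"{season}_{suffix}"] = float(np.mean(monthly))
    return SeasonalFeatures(**values, fire_year=fire_year)


def read_climate_csv(path, site_id=None) -> list[MonthlyClimate]:
    """Read monthly forcing from CSV.

    Expected columns: ``year, month, precip_mm, tmin_c, tmax_c, rad_mj_m2``
    plus an optional ``site_id`` column for long-format multi-site files (in
    which case ``site_id`` selects one site).
    """
    df = pd.read_csv(path)
    if site_id is not None:
        df = df[df["site_id"] == site_id]
    df = df.sort_values(["year", "month"])
    return [
        MonthlyClimate(
            year=int(r.year),
            month=int(r.month),
            precip=float(r.precip_mm),
            tmin=float(r.tmin_c),
            tmax=float(r.tmax_c),
            radiation=float(r.rad_mj_m2),
        )
        for r in df.itertuples(index=False)
    ]
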