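"""Seeded synthetic data: climate forcing, site surfaces, and fire labels.

Every generator is a pure function of its parameters and a seed, so the full
pipeline (forcing -> water balance -> seasonal features -> rules/tree ->
evaluation) is exercisable end-to-end with no external downloads.  Climate is
emulated as sinusoidal seasonal cycles plus seeded noise in three regimes:

* ``mediterranean`` — wet winters, dry summers (< 15 % of annual
  precipitation in June-August), the fire-prone case;
* ``summer_rain`` — continental, modest summer precipitation peak;
* ``wet_maritime`` — heavy year-round rain, cool summers; essentially never
  water-limited, mirroring coastal forests that rarely burn.

Site surfaces draw LAI_max uniformly over the satellite-calibrated 0.5-6.0
range and ASW_max from a shallow/deep mixture (drought vulnerability
concentrates on shallow soils).  Labels are produced by running the scene's
own simulated fASW through the four-rule classifier, then flipping a small
fraction at random to emulate detection noise.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .climate import MonthlyClimate, season_average
from .classify import RuleSet, apply_rules
from .hotspots import LabelGrid
from .water import SiteParams, SOIL_WATER_PARAMS, WaterConfig, DEFAULT_CONFIG, simulate_fasw

__all__ = [
    "ClimateRegime",
    "REGIMES",
    "SyntheticScene",
    "gen_climate",
    "gen_sites",
    "gen_scene",
    "gen_hotspot_grid",
]


@dataclass(frozen=True)
class ClimateRegime:
    """Parameters of a sinusoidal monthly climate with seeded noise.

    Precipitation follows ``(annual/12) * (1 + precip_amp * cos(phase))``
    peaking at ``precip_peak_month``, with multiplicative lognormal noise.
    Temperature is a mean-cycle peaking in July with a fixed diurnal range
    split symmetrically into tmin/tmax plus additive Gaussian noise; incoming
    shortwave follows its own cosine cycle.
    """

    name: str
    annual_precip: float  # mm / yr
    precip_amp: float  # in [0, 1): seasonal amplitude of the precip cycle
    precip_peak_month: float  # month of maximum precipitation
    tmean_annual: float  # deg C
    tmean_amp: float  # deg C, seasonal half-range (peak in July)
    diurnal_range: float = 10.0  # deg C between tmin and tmax
    rad_mean: float = 14.0  # MJ m-2 day-1
    rad_amp: float = 10.0  # MJ m-2 day-1, peak in July
    precip_noise_sigma: float = 0.3  # lognormal sigma
    temp_noise_sigma: float = 1.5  # deg C additive
    rad_noise_sigma: float = 0.1  # lognormal sigma


REGIMES: dict[str, ClimateRegime] = {
    "mediterranean": ClimateRegime(
        name="mediterranean",
        annual_precip=800.0,
        precip_amp=0.9,
        precip_peak_month=1.0,
        tmean_annual=10.0,
        tmean_amp=9.0,
    ),
    "summer_rain": ClimateRegime(
        name="summer_rain",
        annual_precip=500.0,
        precip_amp=0.5,
        precip_peak_month=7.0,
        tmean_annual=6.0,
        tmean_amp=14.0,
    ),
    "wet_maritime": ClimateRegime(
        name="wet_maritime",
        annual_precip=2500.0,
        precip_amp=0.7,
        precip_peak_month=1.0,
        tmean_annual=9.0,
        tmean_amp=5.0,
        rad_amp=8.0,
    ),
}


def gen_climate(
    regime: ClimateRegime | str,
    years: int,
    seed: int,
    start_year: int = 2000,
    noise_scale: float = 1.0,
) -> list[MonthlyClimate]:
    """Generate a contiguous monthly climate series for one site.

    ``noise_scale`` multiplies every noise sigma (0 gives an exactly periodic
    series).  Needs at least two years: one spin-up plus one fire year.
    """
    if isinstance(regime, str):
        regime = REGIMES[regime]
    if years < 2:
        raise ValueError(f"need years >= 2 (spin-up + fire year), got {years}")
    rng = np.random.default_rng(seed)
    out: list[MonthlyClimate] = []
    for yi in range(years):
        year = start_year + yi
        for month in range(1, 13):
            phase = 2.0 * np.pi * (month - regime.precip_peak_month) / 12.0
            p_base = (regime.annual_precip / 12.0) * (1.0 + regime.precip_amp * np.cos(phase))
            p = p_base * np.exp(
                rng.normal(0.0, regime.precip_noise_sigma * noise_scale)
                - 0.5 * (regime.precip_noise_sigma * noise_scale) ** 2
            )
            tphase = 2.0 * np.pi * (month - 7.0) / 12.0
            tmean = (
                regime.tmean_annual
                + regime.tmean_amp * np.cos(tphase)
                + rng.normal(0.0, regime.temp_noise_sigma * noise_scale)
            )
            rad_daily = regime.rad_mean + regime.rad_amp * np.cos(tphase)
            rad_daily *= np.exp(
                rng.normal(0.0, regime.rad_noise_sigma * noise_scale)
                - 0.5 * (regime.rad_noise_sigma * noise_scale) ** 2
            )
            clim = MonthlyClimate(
                year=year,
                month=month,
                precip=float(max(p, 0.0)),
                tmin=float(tmean - 0.5 * regime.diurnal_range),
                tmax=float(tmean + 0.5 * regime.diurnal_range),
                radiation=float(max(rad_daily, 0.5) * _days(year, month)),
            )
            out.append(clim)
    return out


def _days(year: int, month: int) -> int:
    import calendar

    return calendar.monthrange(year, month)[1]


def gen_sites(n: int, seed: int) -> pd.DataFrame:
    """Draw ``n`` site parameter rows.

    LAI_max ~ U(0.5, 6.0); ASW_max from an equal mixture of shallow
    U(50, 100) mm and deep U(200, 400) mm stores; soil class uniform over the
    four texture classes; fertility U(0, 1) (carried, unused by fire logic).
    """
    rng = np.random.default_rng(seed)
    shallow = rng.random(n) < 0.5
    asw = np.where(
        shallow, rng.uniform(50.0, 100.0, n), rng.uniform(200.0, 400.0, n)
    )
    return pd.DataFrame(
        {
            "site_id": np.arange(n),
            "lai_max": rng.uniform(0.5, 6.0, n),
            "asw_max": asw,
            "soil_class": rng.choice(sorted(SOIL_WATER_PARAMS), n),
            "fertility": rng.random(n),
        }
    )


@dataclass(frozen=True)
class SyntheticScene:
    """A fully synthetic study scene on an (ny, nx) lattice.

    ``features`` holds one row per pixel-year: the eight seasonal fASW
    features, the noiseless rule outcome (``true_label``, ``rule_id``) and
    the observed ``label`` after random flips.  Reproducible from
    (parameters, seed).
    """

    shape: tuple[int, int]
    sites: pd.DataFrame
    features: pd.DataFrame
    fire_years: tuple[int, ...]
    rules: RuleSet
    flip_rate: float
    seed: int

    def label_grid(self, fire_year: int, observed: bool = True) -> LabelGrid:
        """Rasterize one fire year's labels onto the scene lattice."""
        ny, nx = self.shape
        values = np.zeros((ny, nx), dtype=np.uint8)
        sel = self.features[self.features["fire_year"] == fire_year]
        if sel.empty:
            raise ValueError(f"fire_year {fire_year} not in scene {self.fire_years}")
        col = "label" if observed else "true_label"
        sid = sel["site_id"].to_numpy()
        values[sid // nx, sid % nx] = sel[col].to_numpy().astype(np.uint8)
        return LabelGrid(values=values, mask=np.ones((ny, nx), bool), year=fire_year)


def gen_scene(
    dims: tuple[int, int],
    regimes: tuple[str, ...] = ("mediterranean", "summer_rain"),
    rules: RuleSet = RuleSet(),
    flip_rate: float = 0.05,
    seed: int = 0,
    n_years: int = 4,
    n_fire_years: int = 2,
    start_year: int = 2000,
    precip_scale_range: tuple[float, float] = (0.55, 1.45),
    water_config: WaterConfig = DEFAULT_CONFIG,
) -> SyntheticScene:
    """Generate a pipeline-consistent synthetic scene.

    Pixels are split evenly among ``regimes`` (interleaved over the lattice)
    with a per-pixel annual-precipitation scaling drawn from
    ``precip_scale_range`` for spatial variety.  Each pixel's climate drives
    the monthly water balance from field capacity (first year = spin-up);
    seasonal features for the last ``n_fire_years`` years are labeled with
    the four-rule classifier, then labels are flipped independently at
    ``flip_rate``.  The noiseless label and matched rule are retained for
    recovery tests.
    """
    ny, nx = dims
    n = ny * nx
    if n_years < n_fire_years + 2:
        raise ValueError(
            "need n_years >= n_fire_years + 2: the first fire year requires a "
            "spin-up year plus its previous year (its features reach back to "
            "December two calendar years earlier)"
        )
    rng = np.random.default_rng(seed)
    sites = gen_sites(n, seed=int(rng.integers(2**31)))
    fire_years = tuple(start_year + n_years - n_fire_years + i for i in range(n_fire_years))

    rows = []
    for site_id in range(n):
        regime = REGIMES[regimes[site_id % len(regimes)]]
        scale = rng.uniform(*precip_scale_range)
        regime = replace(regime, annual_precip=regime.annual_precip * scale)
        clim = gen_climate(
            regime, years=n_years, seed=int(rng.integers(2**31)), start_year=start_year
        )
        srow = sites.iloc[site_id]
        site = SiteParams(
            lai_max=float(srow.lai_max),
            asw_max=float(srow.asw_max),
            soil_class=str(srow.soil_class),
            fertility=float(srow.fertility),
        )
        traj = simulate_fasw(site, clim, config=water_config)
        fasw = {
            (int(y), int(m)): float(v)
            for y, m, v in zip(traj["year"], traj["month"], traj["fasw"])
        }
        for fy in fire_years:
            feats = season_average(fasw, fire_year=fy)
            label, rule_id = apply_rules(feats, rules)
            rows.append(
                {
                    "site_id": site_id,
                    "regime": regime.name,
                    "fire_year": fy,
                    **{name: getattr(feats, name) for name in feats.__dataclass_fields__ if name != "fire_year"},
                    "true_label": label,
                    "rule_id": rule_id,
                }
            )

    features = pd.DataFrame(rows)
    flips = rng.random(len(features)) < flip_rate
    features["label"] = np.where(flips, 1 - features["true_label"], features["true_label"])
    features["flipped"] = flips
    return SyntheticScene(
        shape=dims,
        sites=sites,
        features=features,
        fire_years=fire_years,
        rules=rules,
        flip_rate=flip_rate,
        seed=seed,
    )


def gen_hotspot_grid(
    scene: SyntheticScene,
    isolated_fraction: float,
    seed: int,
    fire_year: int | None = None,
) -> tuple[LabelGrid, list[tuple[int, int]]]:
    """Rasterize a scene year and inject deliberately isolated detections.

    Each injected pixel is placed with its full 3x3 neighborhood fire-free at
    placement time (counting earlier injections), so every injection is
    isolated, abuts no base detection, and the isolation filter must remove
    exactly the injected set on top of whatever it removes from the base
    grid.  The injected pixel list is returned so the removal count is known
    by construction.

    ``isolated_fraction`` is the target number of injections relative to the
    base fire count (capped by available empty space).
    """
    if not 0.0 <= isolated_fraction <= 1.0:
        raise ValueError("isolated_fraction must be in [0, 1]")
    fire_year = fire_year if fire_year is not None else scene.fire_years[-1]
    base = scene.label_grid(fire_year)
    values = base.values.copy()
    ny, nx = values.shape
    rng = np.random.default_rng(seed)

    target = int(round(isolated_fraction * max(base.n_fire, 1)))
    injected: list[tuple[int, int]] = []
    if target > 0:
        occupied = values.astype(bool).copy()
        candidates = [(r, c) for r in range(ny) for c in range(nx) if not occupied[r, c]]
        rng.shuffle(candidates)
        for r, c in candidates:
            if len(injected) >= target:
                break
            r0, r1 = max(r - 1, 0), min(r + 2, ny)
            c0, c1 = max(c - 1, 0), min(c + 2, nx)
            if occupied[r0:r1, c0:c1].any():
                continue
            values[r, c] = 1
            occupied[r, c] = True
            injected.append((r, c))
    return LabelGrid(values=values, mask=base.mask, year=fire_year), injected
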