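import math

import numpy as np
import pytest

from droughtfire.climate import MonthlyClimate
from droughtfire.water import (
    ModifierSet,
    NoSolutionError,
    SiteParams,
    SOIL_WATER_PARAMS,
    WaterBalanceState,
    drawdown_months,
    frost_modifier,
    interception_evap,
    invert_asw_max,
    monthly_transpiration,
    simulate_fasw,
    step_month,
    supportable_lai,
    sw_modifier,
    temp_modifier,
    transpiration_ceiling,
    vpd_modifier,
)
from droughtfire.synthetic import gen_climate


def _month(year=2004, month=7, precip=0.0, tmin=12.0, tmax=28.0, radiation=750.0, **kw):
    return MonthlyClimate(year=year, month=month, precip=precip, tmin=tmin, tmax=tmax, radiation=radiation, **kw)


ALL_OPEN = ModifierSet(f_temp=1.0, f_vpd=1.0, f_frost=1.0, f_sw=1.0)


class TestTempModifier:
    def test_unity_at_optimum(self):
        assert temp_modifier(18.0) == 1.0

    def test_truncated_below_stomatal_shutdown(self):
        assert temp_modifier(-3.0) == 0.0
        assert temp_modifier(-2.5) == 0.0
        assert temp_modifier(-1.9) > 0.0

    def test_closed_form_oracle_values(self):
        # hand evaluation of ((T-Tn)/(To-Tn)) * ((Tx-T)/(Tx-To))^((Tx-To)/(To-Tn))
        assert temp_modifier(0.0) == pytest.approx(0.28 * (40.0 / 22.0) ** 0.88, rel=1e-12)
        assert temp_modifier(0.0) == pytest.approx(0.4738478, abs=1e-6)
        assert temp_modifier(35.0) == pytest.approx((42.0 / 25.0) * (5.0 / 22.0) ** 0.88, rel=1e-12)
        assert temp_modifier(35.0) == pytest.approx(0.4561114, abs=1e-6)

    def test_zero_outside_viable_range(self):
        assert temp_modifier(40.0) == 0.0
        assert temp_modifier(45.0) == 0.0

    def test_degenerate_params_rejected(self):
        with pytest.raises(ValueError):
            temp_modifier(10.0, (18.0, 10.0, 40.0))


class TestSwModifier:
    def test_no_restriction_at_field_capacity(self):
        for soil in SOIL_WATER_PARAMS:
            assert sw_modifier(100.0, 100.0, soil) == 1.0

    @pytest.mark.parametrize(
        "soil", ["sand", "sandy_loam", "clay_loam", "clay"]
    )
    def test_empty_store_matches_closed_form(self, soil):
        c, n = SOIL_WATER_PARAMS[soil]
        expected = 1.0 / (1.0 + (1.0 / c) ** n)
        assert sw_modifier(0.0, 100.0, soil) == pytest.approx(expected, rel=1e-12)

    def test_half_store_sand_oracle(self):
        expected = 1.0 / (1.0 + (0.5 / 0.7) ** 9)  # hand evaluation
        assert sw_modifier(50.0, 100.0, "sand") == pytest.approx(expected, rel=1e-12)

    def test_strictly_increasing_in_stored_fraction(self):
        values = [sw_modifier(a, 100.0, "clay_loam") for a in np.linspace(0, 100, 51)]
        assert all(a < b for a, b in zip(values, values[1:]))

    def test_invalid_capacity_rejected(self):
        with pytest.raises(ValueError):
            sw_modifier(10.0, 0.0)


class TestVpdFrostModifiers:
    def test_vpd_limits_and_oracle(self):
        assert vpd_modifier(0.0) == 1.0
        assert vpd_modifier(10.0, k_vpd=0.05) == pytest.approx(math.exp(-0.5), rel=1e-12)
        assert vpd_modifier(500.0) < 1e-6

    def test_frost_fraction(self):
        assert frost_modifier(0, 30) == 1.0
        assert frost_modifier(30, 30) == 0.0
        assert frost_modifier(10, 31) == pytest.approx(21.0 / 31.0)
        with pytest.raises(ValueError):
            frost_modifier(32, 31)


class TestTranspirationCeiling:
    def test_linear_then_plateau(self):
        assert transpiration_ceiling(0.0) == 0.0
        assert transpiration_ceiling(2.0) == pytest.approx(0.4 * 3.0)
        assert transpiration_ceiling(6.0) == transpiration_ceiling(10.0) == pytest.approx(3.0)


class TestMonthlyTranspiration:
    def test_cap_binds_under_saturating_demand(self):
        clim = _month(radiation=900.0, tmin=15.0, tmax=33.0)
        site = SiteParams(lai_max=5.5, asw_max=300.0)
        t = monthly_transpiration(clim, site, ALL_OPEN)
        assert t == pytest.approx(transpiration_ceiling(5.5) * clim.ndays)

    def test_any_zero_modifier_shuts_transpiration_down(self):
        clim = _month()
        site = SiteParams(lai_max=4.0, asw_max=200.0)
        mods = ModifierSet(f_temp=1.0, f_vpd=1.0, f_frost=0.0, f_sw=1.0)
        assert monthly_transpiration(clim, site, mods) == 0.0

    def test_against_independent_penman_monteith_script(self):
        # independent re-derivation: combination equation with canopy
        # conductance g_c = 0.006 * min(LAI, 5) * prod(modifiers)
        clim = _month(radiation=450.0, tmin=10.0, tmax=24.0)
        site = SiteParams(lai_max=3.0, asw_max=200.0)
        mods = ModifierSet(f_temp=0.9, f_vpd=0.8, f_frost=1.0, f_sw=0.7)
        ndays = clim.ndays
        g_c = 0.006 * 3.0 * 0.9 * 0.8 * 0.7
        rn = -90.0 + 0.8 * clim.radiation * 1e6 / (ndays * 43200.0)
        demand = 1.2 * 2.46e6 * 0.000622 * clim.vpd_day * 0.2
        flux = (2.2 * rn + demand) / (1.0 + 2.2 + 0.2 / g_c)
        expected = min(flux / 2.46e6 * 43200.0, transpiration_ceiling(3.0)) * ndays
        assert monthly_transpiration(clim, site, mods) == pytest.approx(expected, rel=1e-9)


class TestInterception:
    def test_limits_and_arithmetic(self):
        assert interception_evap(0.0, 4.0) == 0.0
        assert interception_evap(50.0, 0.0) == 0.0
        assert interception_evap(100.0, 5.0) == pytest.approx(15.0)
        assert interception_evap(100.0, 2.5) == pytest.approx(7.5)
        assert interception_evap(40.0, 12.0) <= 40.0


class TestStepMonth:
    def test_nothing_in_nothing_out(self):
        site = SiteParams(lai_max=3.0, asw_max=150.0)
        clim = _month(precip=0.0, radiation=0.0, tmin=-9.0, tmax=1.0)  # frozen, dark
        state = WaterBalanceState(asw=80.0)
        new, flux = step_month(state, clim, site)
        assert new.asw == pytest.approx(80.0)
        assert flux.runoff == 0.0
        assert flux.transpiration == 0.0

    def test_overflow_is_lost_as_runoff(self):
        site = SiteParams(lai_max=1.0, asw_max=100.0)
        clim = _month(month=12, precip=400.0, tmin=2.0, tmax=8.0, radiation=100.0)
        state = WaterBalanceState(asw=100.0)
        new, flux = step_month(state, clim, site)
        assert new.asw == pytest.approx(100.0)
        expected_runoff = 400.0 - flux.interception_evap - flux.transpiration
        assert flux.runoff == pytest.approx(expected_runoff)

    def test_store_never_negative_under_extreme_demand(self):
        site = SiteParams(lai_max=6.0, asw_max=50.0)
        clim = _month(precip=0.0, radiation=900.0, tmin=18.0, tmax=36.0)
        new, flux = step_month(WaterBalanceState(asw=5.0), clim, site)
        assert new.asw >= 0.0
        assert flux.transpiration <= 5.0

    def test_trajectory_matches_hand_iterated_bookkeeping(self):
        """12-month fixed forcing: spreadsheet-style iteration of the update."""
        site = SiteParams(lai_max=4.0, asw_max=150.0, soil_class="clay_loam")
        forcing = [
            _month(2004, m, precip=p, tmin=tn, tmax=tn + 12.0, radiation=r)
            for m, p, tn, r in zip(
                range(1, 13),
                [120, 90, 70, 40, 20, 5, 0, 2, 10, 60, 110, 140],
                [-2, 0, 2, 5, 9, 13, 16, 15, 11, 6, 1, -1],
                [150, 220, 350, 500, 650, 720, 760, 650, 480, 300, 170, 120],
            )
        ]
        from droughtfire.water import (
            interception_evap as ie,
            sw_modifier as swm,
            temp_modifier as tm,
            vpd_modifier as vm,
            frost_modifier as fm,
            monthly_transpiration as mt,
        )

        asw, snow = site.asw_max, 0.0
        expected = []
        for clim in forcing:
            if clim.tmean < 0:
                liquid, snow = 0.0, snow + clim.precip
            else:
                liquid, snow = clim.precip + snow, 0.0
            evap = ie(liquid, site.lai_max)
            mods = ModifierSet(
                f_temp=tm(clim.tmean),
                f_vpd=vm(clim.vpd_day),
                f_frost=fm(clim.frost_days, clim.ndays),
                f_sw=swm(asw, site.asw_max, site.soil_class),
            )
            t = min(mt(clim, site, mods), max(asw + liquid - evap, 0.0))
            raw = asw + liquid - evap - t
            asw = min(max(raw, 0.0), site.asw_max)
            expected.append(asw)

        traj = simulate_fasw(site, forcing)
        assert traj["asw_end"].to_numpy() == pytest.approx(np.array(expected), rel=1e-12)


class TestSimulateFasw:
    def test_no_recharge_means_monotone_depletion(self, med_climate):
        site = SiteParams(lai_max=4.0, asw_max=200.0)
        dry = [
            MonthlyClimate(c.year, c.month, 0.0, c.tmin, c.tmax, c.radiation)
            for c in med_climate[:24]
        ]
        traj = simulate_fasw(site, dry)
        fasw = traj["fasw"].to_numpy()
        assert all(a >= b - 1e-12 for a, b in zip(fasw, fasw[1:]))

    def test_saturating_rain_pins_fasw_at_one(self, med_climate):
        site = SiteParams(lai_max=2.0, asw_max=100.0)
        wet = [
            MonthlyClimate(c.year, c.month, 500.0, c.tmin, c.tmax, c.radiation)
            for c in med_climate[:12]
        ]
        traj = simulate_fasw(site, wet)
        assert traj["fasw"].iloc[1:].min() > 0.99
        assert traj["runoff"].iloc[1:].min() > 0.0

    def test_mass_balance_closes_on_random_forcing(self):
        rng = np.random.default_rng(11)
        site = SiteParams(lai_max=3.5, asw_max=120.0)
        series = []
        y, m = 2000, 1
        for _ in range(36):
            tmin = rng.uniform(-15, 18)
            series.append(
                MonthlyClimate(
                    y, m,
                    precip=rng.uniform(0, 250),
                    tmin=tmin,
                    tmax=tmin + rng.uniform(2, 15),
                    radiation=rng.uniform(50, 900),
                )
            )
            y, m = (y + 1, 1) if m == 12 else (y, m + 1)
        traj = simulate_fasw(site, series)
        stored = traj["asw_end"].iloc[-1] + traj["snow_end"].iloc[-1] - site.asw_max
        residual = (
            traj["precip"].sum()
            - traj["transpiration"].sum()
            - traj["interception"].sum()
            - traj["runoff"].sum()
            - stored
        )
        assert abs(residual) < 1e-6 * traj["precip"].sum()

    def test_gap_in_series_is_an_error(self, med_climate):
        site = SiteParams(lai_max=3.0, asw_max=150.0)
        gappy = med_climate[:5] + med_climate[6:]
        with pytest.raises(ValueError, match="gap"):
            simulate_fasw(site, gappy)

    def test_denser_canopy_never_depletes_slower(self, med_climate):
        sparse = SiteParams(lai_max=2.0, asw_max=150.0)
        dense = SiteParams(lai_max=4.5, asw_max=150.0)
        dry = [
            MonthlyClimate(c.year, c.month, 0.0, c.tmin, c.tmax, c.radiation)
            for c in med_climate[:12]
        ]
        a_sparse = simulate_fasw(sparse, dry)["asw_end"].to_numpy()
        a_dense = simulate_fasw(dense, dry)["asw_end"].to_numpy()
        assert np.all(a_dense <= a_sparse + 1e-9)


class TestDrawdown:
    def test_one_month_at_plateau(self):
        assert drawdown_months(90.0, 5.0) == pytest.approx(1.0)

    def test_linear_in_capacity(self):
        assert drawdown_months(400.0, 3.0) == pytest.approx(2 * drawdown_months(200.0, 3.0))

    def test_sparse_stand_needs_over_three_months_for_200mm(self):
        assert drawdown_months(200.0, 2.0) > 3.0

    def test_dense_stand_empties_200mm_in_about_a_month(self):
        months = drawdown_months(200.0, 6.0)
        assert months == pytest.approx(200.0 / 90.0, rel=1e-12)
        assert 1.0 < months < 3.0

    def test_leafless_site_never_draws_down(self):
        assert drawdown_months(200.0, 0.0) == math.inf


class TestInvertAswMax:
    def test_denser_observed_canopy_needs_bigger_store(self, med_climate):
        low = invert_asw_max(2.0, med_climate)
        high = invert_asw_max(5.0, med_climate)
        assert high > low

    def test_round_trip_recovers_capacity_within_5pct(self, med_climate):
        true_asw = 150.0
        lai = supportable_lai(true_asw, med_climate)
        assert 0.5 < lai < 6.0  # interior, so the criterion is identifiable
        estimate = invert_asw_max(lai, med_climate)
        assert estimate == pytest.approx(true_asw, rel=0.05)

    def test_wet_climate_pins_estimate_at_search_floor(self):
        from droughtfire.synthetic import gen_climate

        wet = gen_climate("wet_maritime", years=3, seed=3)
        assert invert_asw_max(3.0, wet) == pytest.approx(10.0)

    def test_unsupportable_site_raises(self, med_climate):
        from droughtfire.water import WaterConfig

        # an impossible support demand cannot be bracketed
        cfg = WaterConfig(support_threshold=0.999999)
        with pytest.raises(NoSolutionError):
            invert_asw_max(6.0, med_climate, config=cfg, asw_bounds=(10.0, 20.0))

    def test_lai_outside_calibrated_range_rejected(self, med_climate):
        with pytest.raises(ValueError):
            invert_asw_max(7.0, med_climate)
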