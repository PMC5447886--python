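"""Seasonal crop simulator: phenology, N uptake, senescence, bookkeeping."""

import math

import numpy as np
import pytest

from photoroutes.routes import build_route
from photoroutes.season import (
    CropState,
    advance_phenology,
    beta_temperature_response,
    cumulative_n_uptake,
    decompose_mass,
    f_root_daily,
    n_determined_lai,
    n_uptake_daily,
    respiration_daily,
    run_season,
    thermal_day_increment,
    update_lai_and_senescence,
    INIT_LEAF_DM, INIT_STEM_DM, INIT_ROOT_DM, CH2O_PER_CO2, S_LA, TC_SENES,
)
from photoroutes.weather import (
    PhenologyParams,
    generate_weather,
    temperate_site,
    tropical_site,
)


@pytest.fixture(scope="module")
def phen():
    return PhenologyParams()  # Tb 8, To 30, Tc 42


class TestThermalTime:
    def test_full_day_at_optimum_gives_one(self, phen):
        assert thermal_day_increment(30.0, 30.0, 13.0, phen) == pytest.approx(1.0)

    def test_below_base_gives_zero(self, phen):
        assert thermal_day_increment(8.0, 4.0, 13.0, phen) == 0.0

    def test_midpoint_matches_closed_form_beta(self, phen):
        # constant T = (Tb+To)/2 = 19: direct evaluation of the beta shape
        t = 19.0
        expect = ((42 - t) / (42 - 30)) * ((t - 8) / (30 - 8)) ** ((30 - 8) / (42 - 30))
        assert beta_temperature_response(t, phen) == pytest.approx(expect)
        assert expect == pytest.approx(0.5379, abs=2e-4)
        assert thermal_day_increment(t, t, 13.0, phen) == pytest.approx(expect)


class TestPhenology:
    def test_flowering_after_mv_optimal_days(self, phen):
        state = CropState()
        days = 0
        while state.stage < 1.0:
            advance_phenology(state, 1.0, phen)
            days += 1
        assert days == phen.m_v  # 70

    def test_maturity_after_mv_plus_mr(self, phen):
        state = CropState()
        days = 0
        while state.stage < 2.0:
            advance_phenology(state, 1.0, phen)
            days += 1
        assert days == phen.m_v + phen.m_r  # 98

    def test_cooler_site_has_longer_season(self):
        """Temperate thermal-day accrual per calendar day is below the
        tropical one, so identical requirements take longer."""
        trop, temp = tropical_site(), temperate_site()
        wt = generate_weather(trop, 1, seed=6).query("year == 1")
        wc = generate_weather(temp, 1, seed=6).query("year == 1")
        inc_t = np.mean([thermal_day_increment(r.tmax_C, r.tmin_C, 12.5, trop.phenology)
                         for r in wt.iloc[trop.phenology.start_day:
                                          trop.phenology.start_day + 90].itertuples()])
        inc_c = np.mean([thermal_day_increment(r.tmax_C, r.tmin_C, 14.0, temp.phenology)
                         for r in wc.iloc[temp.phenology.start_day:
                                          temp.phenology.start_day + 90].itertuples()])
        assert inc_t > inc_c


class TestNitrogenUptake:
    def test_total_at_maturity(self):
        assert cumulative_n_uptake(2.0) == pytest.approx(20.0, abs=0.01)

    def test_rate_nonnegative_over_season(self):
        stages = np.linspace(0, 2, 401)
        for s0, s1 in zip(stages, stages[1:]):
            assert n_uptake_daily(s0, s1) >= 0.0

    def test_single_inflection(self):
        stages = np.linspace(0, 2, 401)
        cum = np.array([cumulative_n_uptake(s) for s in stages])
        second = np.diff(cum, 2)
        signs = np.sign(second[np.abs(second) > 1e-12])
        flips = np.count_nonzero(np.diff(signs))
        assert flips == 1


class TestLaiAndSenescence:
    def test_no_senescence_with_ample_nitrogen(self):
        state = CropState(n_leaf=15.0)
        lai0, senes0 = state.lai_c, state.senes
        update_lai_and_senescence(state, new_leaf_dm=5.0)
        assert state.senes == senes0
        assert state.lai_c == pytest.approx(lai0 + S_LA * 5.0)

    def test_senescence_rate_is_gap_over_time_constant(self):
        # engineer LAI_C - LAI_N = 0.4: decline must be 0.2 per day
        state = CropState(n_leaf=5.0)
        from photoroutes.canopy import diffuse_extinction
        k_n = None
        # choose lai_c to sit 0.4 above the N-determined LAI
        for _ in range(40):
            k_n = diffuse_extinction(65.0, max(state.lai_c, 0.05), 0.2)
            lai_n = n_determined_lai(state.n_leaf, k_n, 0.3)
            state.lai_c = lai_n + 0.4
        lai_before = state.lai_c
        state.n_leaf_before = state.n_leaf
        update_lai_and_senescence(state, new_leaf_dm=0.0)
        assert lai_before - state.lai_c == pytest.approx(0.4 / TC_SENES, rel=1e-3)

    def test_nitrogen_starvation_decays_with_time_constant(self):
        """With no leaf N at all the canopy must collapse exponentially
        with the senescence time constant (2 d)."""
        state = CropState(n_leaf=0.0, lai_c=4.0, leaf_dm=4.0 / S_LA)
        lai = [state.lai_c]
        for _ in range(10):
            update_lai_and_senescence(state, 0.0)
            lai.append(state.lai_c)
        expect = 4.0 * (1.0 - 1.0 / TC_SENES) ** 10
        assert lai[-1] == pytest.approx(expect, rel=1e-9)


class TestRespirationAndPartitioning:
    def test_zero_everything_gives_zero(self):
        g, m = respiration_daily(0.0, 0.0, 25.0)
        assert g == 0.0 and m == 0.0

    def test_growth_respiration_is_quarter_of_allocatable(self):
        g, m = respiration_daily(10.0, 0.0, 25.0)
        assert g == pytest.approx(2.5)

    def test_maintenance_monotone_in_nitrogen(self):
        m1 = respiration_daily(5.0, 5.0, 25.0)[1]
        m2 = respiration_daily(5.0, 10.0, 25.0)[1]
        assert m2 > m1

    def test_root_fraction_bounds_and_carbon_response(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            fr = f_root_daily(rng.uniform(0, 2), rng.uniform(0, 40),
                              rng.uniform(0, 0.5))
            assert 0.05 <= fr <= 0.6
        # carbon surplus at fixed N raises the root fraction
        assert f_root_daily(0.5, 30.0, 0.2) > f_root_daily(0.5, 5.0, 0.2)
        # late-stage balanced crop sits near the baseline minimum
        assert f_root_daily(1.9, 5.0, 0.3) < 0.12


@pytest.fixture(scope="module")
def tropical_run():
    site = tropical_site()
    wx = generate_weather(site, 1, seed=11).query("year == 1")
    pot = run_season(wx, site, build_route(0).params)
    lim = run_season(wx, site, build_route(0).params, water_limited=True)
    return pot, lim


class TestSeasonBookkeeping:
    def test_mass_decomposition_identity(self, tropical_run):
        for res in tropical_run:
            recon, resid = decompose_mass(res)
            assert abs(resid) / res.shoot_mass < 0.01

    def test_carbon_mass_balance(self, tropical_run):
        init = INIT_LEAF_DM + INIT_STEM_DM + INIT_ROOT_DM
        for res in tropical_run:
            growth = (res.shoot_mass + res.dead_mass + res.root_mass) - init
            expect = (res.a_canopy_s - res.resp) * CH2O_PER_CO2
            assert growth == pytest.approx(expect, rel=0.01)

    def test_water_limitation_lowers_mass_raises_wue(self, tropical_run):
        pot, lim = tropical_run
        assert lim.shoot_mass < pot.shoot_mass
        assert lim.wue > pot.wue
        assert lim.transpiration < pot.transpiration

    def test_transpiration_within_supply(self, tropical_run):
        _, lim = tropical_run
        assert lim.transpiration <= lim.water_supply * lim.days_to_maturity * 1.01

    def test_shoot_mass_excludes_dead_leaves(self, tropical_run):
        pot, _ = tropical_run
        assert pot.senes == pytest.approx(pot.dead_mass)
        assert pot.shoot_mass > 0 and pot.dead_mass > 0

    def test_unreachable_maturity_raises(self):
        site = temperate_site()
        wx = generate_weather(site, 1, seed=1).query("year == 1").copy()
        wx["tmax_C"] = 5.0  # below the base temperature all season
        wx["tmin_C"] = 1.0
        with pytest.raises(RuntimeError):
            run_season(wx, site, build_route(0).params)
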