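"""Daily seasonal crop simulation (a deliberately simplified GECROS-style
crop module).

The simulator keeps the mechanisms through which leaf photosynthesis feeds
back on crop growth — canopy expansion from carbon, nitrogen-determined
canopy size, C/N-driven leaf senescence, growth + maintenance respiration,
root/shoot partitioning — while everything the study held fixed (soil
water and nitrogen balances, grain formation) is prescribed:

* phenology: thermal days from a beta-function temperature response between
  the cardinal temperatures, with fixed pre/post-flowering requirements;
* nitrogen: uptake follows a beta-sigmoid of development stage and totals
  20 g N m-2 at maturity;
* water-limited production caps the daily available water at a fraction
  (0.5) of the seasonal mean daily potential transpiration;
* the productivity proxy is shoot mass at maturity excluding dead leaves.

Module constants that the source tables do not fix (growth efficiency,
maintenance coefficient, allocation shapes) are collected below.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .canopy import (
    CanopyState,
    DayCanopyResult,
    DayDrivers,
    GAUSS5_W,
    GAUSS5_X,
    daily_canopy_photosynthesis,
    diffuse_extinction,
    _air_temperature,
)
from .params import PhotoParams
from .weather import PhenologyParams, SiteConfig, daylength_and_radiation

# ---- GECROS-lite module constants (one place) -----------------------------
S_LA = 0.03            # m2 leaf g-1 DM, specific leaf area of new leaves
TC_SENES = 2.0         # d, time constant of C/N-imbalance senescence
N_TOTAL_UPTAKE = 20.0  # g N m-2 at maturity
Y_G = 0.75             # growth efficiency, g structural CH2O per g CH2O
C_MAINT = 0.015        # g CH2O g-1 N d-1, maintenance coefficient at 25 degC
Q10_MAINT = 2.0
CH2O_PER_CO2 = 30.0 / 44.0
WATER_SUPPLY_FRACTION = 0.5  # of seasonal mean daily potential transpiration
MAX_SEASON_DAYS = 250
# allocation shapes (fractions of increments, development-stage dependent)
LEAF_FRAC_A, LEAF_FRAC_B = 0.70, 0.50   # leaf share of shoot growth: a - b*stage
NLEAF_FRAC_A, NLEAF_FRAC_B = 0.62, 0.25  # leaf share of N uptake: a - b*stage
N_ROOT_FRAC = 0.12
FROOT_BASE, FROOT_DECAY = 0.30, 1.2     # baseline root fraction: base*exp(-decay*stage)
FROOT_MIN, FROOT_MAX = 0.05, 0.6
N_SENES = 0.3          # g N m-2 leaf retained in senescing leaves (= n_b)
# initial seedling pools (g DM m-2 / g N m-2)
INIT_LEAF_DM, INIT_STEM_DM, INIT_ROOT_DM = 1.5, 0.5, 0.8
INIT_LEAF_N, INIT_STEM_N, INIT_ROOT_N = 0.10, 0.01, 0.02


def beta_temperature_response(t: float, phen: PhenologyParams) -> float:
    """Unimodal development-rate response: 0 at/below T_base and at/above
    T_ceil, 1 at T_opt (beta-function shape)."""
    tb, to, tc = phen.t_base, phen.t_opt, phen.t_ceil
    if t <= tb or t >= tc:
        return 0.0
    return ((tc - t) / (tc - to)) * ((t - tb) / (to - tb)) ** ((to - tb) / (tc - to))


def thermal_day_increment(tmax: float, tmin: float, daylength: float,
                          phen: PhenologyParams) -> float:
    """Thermal-day accrual of one calendar day (1.0 when the whole diurnal
    course sits at the optimum temperature).

    The diurnal course uses the same dawn-to-dusk sinusoid as the canopy
    integration; overnight the temperature declines linearly from its dusk
    value back to tmin at dawn.  Averaged over Gaussian points spanning 24 h.
    """
    dawn = 12.0 - daylength / 2.0
    dusk = dawn + daylength
    night = max(24.0 - daylength, 1.0e-6)
    t_dusk = _air_temperature(tmin, tmax, daylength, daylength)
    total = 0.0
    for x, w in zip(GAUSS5_X, GAUSS5_W):
        h = 24.0 * x
        if dawn <= h <= dusk:
            t = _air_temperature(tmin, tmax, h - dawn, daylength)
        else:
            since_dusk = (h - dusk) if h > dusk else (h + 24.0 - dusk)
            t = tmin + (t_dusk - tmin) * (1.0 - since_dusk / night)
        total += w * beta_temperature_response(t, phen)
    return total


def cumulative_n_uptake(stage: float, total: float = N_TOTAL_UPTAKE) -> float:
    """Beta-sigmoid cumulative N uptake over development stage (0..2):
    zero at emergence, ``total`` at maturity, single inflection."""
    s = min(max(stage, 0.0), 2.0)
    te, tm = 2.0, 1.0
    return total * (1.0 + (te - s) / (te - tm)) * (s / te) ** (te / (te - tm))


def n_uptake_daily(stage_old: float, stage_new: float,
                   total: float = N_TOTAL_UPTAKE) -> float:
    """Daily N uptake as the increment of the cumulative sigmoid."""
    return max(cumulative_n_uptake(stage_new, total)
               - cumulative_n_uptake(stage_old, total), 0.0)


def n_determined_lai(n_leaf: float, k_n: float, n_b: float) -> float:
    """Nitrogen-determined canopy size: the LAI at which the exponential
    N profile reaches the base leaf N at the canopy bottom,
    ``(1/k_n) ln(1 + k_n N_leaf / n_b)``."""
    if n_leaf <= 0.0:
        return 0.0
    return math.log(1.0 + k_n * n_leaf / n_b) / k_n


def f_root_daily(stage: float, alloc_ch2o: float, n_uptake: float) -> float:
    """Daily root fraction of structural growth: a baseline declining with
    development, raised under carbon surplus relative to N supply
    (functional-equilibrium proxy), bounded in [0.05, 0.6]."""
    base = FROOT_BASE * math.exp(-FROOT_DECAY * min(max(stage, 0.0), 2.0))
    imbalance = max(alloc_ch2o, 0.0) / (max(alloc_ch2o, 0.0) + 40.0 * n_uptake + 1.0e-9)
    return min(max(base * (0.5 + 1.5 * imbalance), FROOT_MIN), FROOT_MAX)


def respiration_daily(assim_ch2o: float, crop_n: float, t_mean: float) -> tuple[float, float]:
    """(growth, maintenance) respiration in g CH2O m-2 d-1.

    Growth respiration is (1 - Y_G) of the positive allocatable assimilate;
    maintenance is N-proportional with a Q10 temperature factor.
    """
    maint = C_MAINT * max(crop_n, 0.0) * Q10_MAINT ** ((t_mean - 25.0) / 10.0)
    alloc = assim_ch2o - maint
    growth = (1.0 - Y_G) * alloc if alloc > 0.0 else 0.0
    return growth, maint


@dataclass
class CropState:
    """Daily-updated crop pools (all per m2 ground)."""

    stage: float = 0.0
    lai_c: float = INIT_LEAF_DM * S_LA    # carbon-determined LAI
    leaf_dm: float = INIT_LEAF_DM
    stem_dm: float = INIT_STEM_DM
    root_dm: float = INIT_ROOT_DM
    dead_leaf_dm: float = 0.0
    n_leaf: float = INIT_LEAF_N
    n_stem: float = INIT_STEM_N
    n_root: float = INIT_ROOT_N
    # cumulative season traits
    a_canopy: float = 0.0     # g CO2 m-2
    par_int: float = 0.0      # MJ m-2
    resp: float = 0.0         # g CO2 m-2
    senes: float = 0.0        # g DM m-2
    transpiration: float = 0.0  # mm
    struct_total: float = 0.0   # g DM m-2 structural growth since emergence
    root_growth: float = 0.0

    @property
    def lai(self) -> float:
        k_n = diffuse_extinction(65.0, max(self.lai_c, 0.05), 0.2)
        return min(self.lai_c, n_determined_lai(self.n_leaf, k_n, N_SENES))

    @property
    def crop_n(self) -> float:
        return self.n_leaf + self.n_stem + self.n_root

    @property
    def shoot_live(self) -> float:
        return self.leaf_dm + self.stem_dm


@dataclass
class SeasonResult:
    """Season-long traits of one simulated crop."""

    days_to_flowering: int
    days_to_maturity: int
    shoot_mass: float        # g DM m-2, excluding dead leaves
    a_canopy_s: float        # g CO2 m-2
    par_int: float           # MJ m-2
    plue: float              # g CO2 MJ-1
    resp: float              # g CO2 m-2
    f_root: float            # cumulative root share of structural growth
    senes: float             # g DM m-2
    transpiration: float     # mm
    wue: float               # g DM m-2 mm-1
    root_mass: float = 0.0
    dead_mass: float = 0.0
    water_supply: float | None = None  # mm d-1 cap used (water-limited runs)

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("days_to_flowering", "days_to_maturity", "shoot_mass",
                 "a_canopy_s", "par_int", "plue", "resp", "f_root", "senes",
                 "transpiration", "wue", "root_mass", "dead_mass")}


def update_lai_and_senescence(state: CropState, new_leaf_dm: float) -> None:
    """Grow the carbon-determined LAI with new leaf mass, then senesce the
    excess of the C-determined over the N-determined LAI with time constant
    ``TC_SENES``; dead mass accumulates into the senescence trait."""
    state.leaf_dm += new_leaf_dm
    state.lai_c += S_LA * new_leaf_dm
    k_n = diffuse_extinction(65.0, max(state.lai_c, 0.05), 0.2)
    lai_n = n_determined_lai(state.n_leaf, k_n, N_SENES)
    if state.lai_c > lai_n:
        d_lai = (state.lai_c - lai_n) / TC_SENES
        d_lai = min(d_lai, state.lai_c)
        dm = min(d_lai / S_LA, state.leaf_dm)
        state.lai_c -= d_lai
        state.leaf_dm -= dm
        state.dead_leaf_dm += dm
        state.senes += dm
        state.n_leaf = max(state.n_leaf - N_SENES * d_lai, 0.0)


def advance_phenology(state: CropState, increment: float,
                      phen: PhenologyParams) -> None:
    """Advance the development stage by one day's thermal increment
    (pre-flowering rate 1/m_V, post-flowering 1/m_R; drought has no
    effect on development)."""
    if state.stage < 1.0:
        state.stage += increment / phen.m_v
    else:
        state.stage += increment / phen.m_r
    # guard against float accumulation drift at the stage milestones
    for milestone in (1.0, 2.0):
        if abs(state.stage - milestone) < 1.0e-9:
            state.stage = milestone


def run_season(weather_year: pd.DataFrame, site: SiteConfig, p: PhotoParams,
               c_a: float = 400.0, water_limited: bool = False,
               water_supply: float | None = None) -> SeasonResult:
    """Simulate one season from emergence to maturity.

    ``weather_year`` is one year of daily weather (columns as produced by
    the synthetic generator).  For water-limited runs the daily water cap
    is ``water_supply`` (mm d-1) if given, otherwise 0.5x the seasonal mean
    daily potential transpiration obtained from an internal potential run
    on the same weather.
    """
    if water_limited and water_supply is None:
        pot = run_season(weather_year, site, p, c_a=c_a, water_limited=False)
        ndays = pot.days_to_maturity
        water_supply = WATER_SUPPLY_FRACTION * pot.transpiration / max(ndays, 1)

    phen = site.phenology
    wx = weather_year.set_index("doy") if "doy" in weather_year.columns else weather_year
    state = CropState()
    day_flower = None
    day = 0
    doy = phen.start_day
    while state.stage < 2.0:
        day += 1
        if day > MAX_SEASON_DAYS or doy not in wx.index:
            raise RuntimeError(
                f"season at {site.name} did not reach maturity "
                f"(day {day}, stage {state.stage:.2f})")
        rec = wx.loc[doy]
        daylength, _ = daylength_and_radiation(site.latitude, doy)
        tmax, tmin = float(rec["tmax_C"]), float(rec["tmin_C"])

        # 1. phenology
        inc = thermal_day_increment(tmax, tmin, daylength, phen)
        stage_old = state.stage
        advance_phenology(state, inc, phen)
        if day_flower is None and state.stage >= 1.0:
            day_flower = day

        # 2. nitrogen uptake and allocation
        du = n_uptake_daily(stage_old, state.stage)
        f_leaf_n = max(NLEAF_FRAC_A - NLEAF_FRAC_B * state.stage, 0.10)
        state.n_leaf += f_leaf_n * du
        state.n_root += N_ROOT_FRAC * du
        state.n_stem += (1.0 - f_leaf_n - N_ROOT_FRAC) * du

        # 3. canopy photosynthesis and transpiration
        lai = state.lai
        if lai > 1.0e-6:
            canopy = CanopyState(lai=lai, n_avg=max(state.n_leaf / lai, 0.0))
            drivers = DayDrivers(radiation_MJ=float(rec["radiation_MJ"]),
                                 tmax=tmax, tmin=tmin,
                                 vap_kPa=float(rec["vap_kPa"]),
                                 wind=float(rec["wind_ms"]), c_a=c_a,
                                 latitude=site.latitude, doy=int(doy))
            res = daily_canopy_photosynthesis(
                drivers, canopy, p,
                water_supply_mm=water_supply if water_limited else None)
        else:
            res = DayCanopyResult(0.0, 0.0, 0.0, 0.0, 0.0)
        p_day = res.a_act if water_limited else res.a_pot  # g CO2 m-2 d-1

        # 4. respiration and structural growth
        t_mean = 0.5 * (tmax + tmin)
        assim_ch2o = p_day * CH2O_PER_CO2
        growth_r, maint_r = respiration_daily(assim_ch2o, state.crop_n, t_mean)
        alloc = assim_ch2o - maint_r
        struct = Y_G * alloc if alloc > 0.0 else alloc

        # 5. partitioning
        if struct > 0.0:
            fr = f_root_daily(state.stage, alloc, du)
            d_root = fr * struct
            d_shoot = struct - d_root
            f_leaf = max(LEAF_FRAC_A - LEAF_FRAC_B * state.stage, 0.0)
            d_leaf = f_leaf * d_shoot
            state.root_dm += d_root
            state.stem_dm += d_shoot - d_leaf
            state.root_growth += d_root
        else:
            d_leaf = 0.0
            state.stem_dm += struct  # deficit days draw on stem reserves
        state.struct_total += struct

        # 6. canopy expansion / senescence
        update_lai_and_senescence(state, d_leaf)

        # 7. bookkeeping
        state.a_canopy += p_day
        state.par_int += res.par_abs_MJ
        state.resp += (growth_r + maint_r) / CH2O_PER_CO2
        state.transpiration += res.e_act if water_limited else res.e_pot
        doy += 1

    f_root = state.root_growth / state.struct_total if state.struct_total > 0 else 0.0
    plue = state.a_canopy / state.par_int if state.par_int > 0 else 0.0
    shoot = state.shoot_live
    return SeasonResult(
        days_to_flowering=day_flower if day_flower is not None else day,
        days_to_maturity=day,
        shoot_mass=shoot,
        a_canopy_s=state.a_canopy,
        par_int=state.par_int,
        plue=plue,
        resp=state.resp,
        f_root=f_root,
        senes=state.senes,
        transpiration=state.transpiration,
        wue=shoot / state.transpiration if state.transpiration > 0 else 0.0,
        root_mass=state.root_dm,
        dead_mass=state.dead_leaf_dm,
        water_supply=water_supply if water_limited else None,
    )


def decompose_mass(result: SeasonResult) -> tuple[float, float]:
    """Reconstruct shoot mass from the trait decomposition
    ``(PAR_int x PLUE - RESP) -> DM, x(1 - F_root), - SENES`` and return
    (reconstructed mass, residual vs the simulated shoot mass)."""
    gross_dm = (result.par_int * result.plue - result.resp) * CH2O_PER_CO2
    recon = gross_dm * (1.0 - result.f_root) - result.senes
    return recon, result.shoot_mass - recon
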