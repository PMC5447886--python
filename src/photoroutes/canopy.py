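"""Sun/shade canopy scaling and daily integration.

The canopy is split into a sunlit and a shaded fraction, each treated as a
big leaf: absorbed PAR follows the beam/diffuse/scattered decomposition of
the sun/shade radiation model, and photosynthetic capacity follows an
exponential leaf-nitrogen profile so each big leaf receives its share of
photosynthetically active nitrogen (above the base n_b).  Because leaf
photosynthesis saturates with light, each big leaf's flux is evaluated with
a three-node Gaussian quadrature over canopy depth (local absorbed light
and local leaf N per node, one leaf temperature per class), which keeps the
two-class model within a few percent of a fine multilayer integration.

Instantaneous fluxes are integrated to daily totals with 5-point Gaussian
quadrature over the photoperiod; diurnal radiation follows the solar
elevation and diurnal temperature a sinusoid peaking 1.5 h after solar
noon.  Under water limitation the available water (which follows the
diurnal radiation course) is split between the two big leaves in proportion
to their potential transpiration; each class's actual transpiration is
turned into an actual stomatal resistance and the fixed-gs biochemical
solver gives the actual assimilation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .energy import (
    MicroMet,
    actual_stomatal_resistance,
    gs_mol_to_rsw,
    isothermal_net_longwave,
    penman_monteith,
    rsw_to_gs_mol,
    saturated_vp,
)
from .leaf import LeafEnv, solve_leaf, solve_leaf_given_gs
from .params import PhotoParams
from .weather import daylength_and_radiation, sin_elevation

# 5-point Gauss-Legendre abscissae/weights on [0, 1] (exact to degree 9)
GAUSS5_X = (0.04691007703066802, 0.23076534494715845, 0.5,
            0.7692346550528415, 0.953089922969332)
GAUSS5_W = (0.11846344252809454, 0.23931433524968324, 0.28444444444444444,
            0.23931433524968324, 0.11846344252809454)
# 3-point Gauss-Legendre on [0, 1] for the within-class depth quadrature
GAUSS3_X = (0.1127016653792583, 0.5, 0.8872983346207417)
GAUSS3_W = (0.2777777777777778, 0.4444444444444444, 0.2777777777777778)

PAR_FRACTION = 0.5          # PAR share of global shortwave
UMOL_PER_J_PAR = 4.6        # umol photons per J PAR
GCO2_PER_UMOL = 44.0e-6     # g CO2 per umol CO2
E_MIN = 1.0e-6              # mm h-1 transpiration floor before Eq-18 transform
T_TOL_CANOPY = 0.01         # degC, class leaf-temperature fixed-point tolerance

# sky sectors for diffuse extinction (Goudriaan three-angle integration)
_SKY_ELEV = (15.0, 45.0, 75.0)
_SKY_W = (0.178, 0.514, 0.308)


@dataclass
class CanopyState:
    """Canopy structure: leaf area, average leaf N, geometry, optics."""

    lai: float                  # m2 leaf m-2 ground
    n_avg: float                # canopy average leaf N, g N m-2 leaf
    leaf_angle: float = 65.0    # degrees from horizontal
    scattering: float = 0.2     # leaf scattering coefficient for PAR

    def __post_init__(self):
        if self.lai < 0:
            raise ValueError("LAI must be >= 0")


@dataclass
class DayDrivers:
    """One day of weather plus the geometry needed for the diurnal courses."""

    radiation_MJ: float         # daily global radiation, MJ m-2 d-1
    tmax: float
    tmin: float
    vap_kPa: float
    wind: float
    c_a: float                  # umol mol-1
    latitude: float
    doy: int
    diffuse_fixed: float | None = None   # fix the diffuse fraction (grid mode)
    t_leaf_fixed: float | None = None    # prescribe leaf temperature (grid mode)

    @property
    def daylength(self) -> float:
        return daylength_and_radiation(self.latitude, self.doy)[0]


def beam_extinction(leaf_angle_deg: float, sin_beta: float) -> float:
    """Black-leaf beam extinction coefficient for a fixed leaf inclination
    (Goudriaan average projection / sin(elevation))."""
    if sin_beta <= 0.0:
        return 60.0
    lam = math.radians(leaf_angle_deg)
    beta = math.asin(min(sin_beta, 1.0))
    if beta >= lam:
        o_av = sin_beta * math.cos(lam)
    else:
        t = math.tan(beta) / math.tan(lam)
        o_av = (2.0 / math.pi) * (sin_beta * math.cos(lam) * math.asin(t)
                                  + math.sqrt(math.sin(lam) ** 2 - sin_beta ** 2))
    return min(o_av / sin_beta, 60.0)


def diffuse_extinction(leaf_angle_deg: float, lai: float, scattering: float) -> float:
    """Scattering-adjusted extinction coefficient for diffuse light,
    integrated over a uniform sky (three-sector quadrature)."""
    sq = math.sqrt(1.0 - scattering)
    if lai <= 1.0e-6:
        return sum(w * beam_extinction(leaf_angle_deg, math.sin(math.radians(e))) * sq
                   for e, w in zip(_SKY_ELEV, _SKY_W))
    tau = sum(w * math.exp(-beam_extinction(leaf_angle_deg, math.sin(math.radians(e)))
                           * sq * lai)
              for e, w in zip(_SKY_ELEV, _SKY_W))
    return -math.log(tau) / lai


def _canopy_reflection(k_b: float, scattering: float) -> float:
    """Canopy reflection coefficient for beam radiation."""
    sq = math.sqrt(1.0 - scattering)
    rho_h = (1.0 - sq) / (1.0 + sq)
    return 1.0 - math.exp(-2.0 * rho_h * k_b / (1.0 + k_b))


@dataclass
class ClassState:
    """Per-big-leaf (sunlit or shaded) aggregates, all per m2 ground."""

    lai: float
    par_abs: float          # absorbed PAR, umol m-2 ground s-1
    n_photo: float          # photosynthetically active N above n_b, g N m-2 ground


class _Optics:
    """Radiation/nitrogen profile coefficients for one canopy and sun
    position, shared by the class aggregates and the depth nodes."""

    __slots__ = ("k_b", "k_b_s", "k_d_s", "rho_cb", "rho_cd", "k_n", "n0",
                 "sig", "L")

    def __init__(self, canopy: CanopyState, sin_beta: float):
        self.L = canopy.lai
        self.sig = canopy.scattering
        sq = math.sqrt(1.0 - self.sig)
        self.k_b = beam_extinction(canopy.leaf_angle, sin_beta)
        self.k_b_s = self.k_b * sq
        self.k_d_s = diffuse_extinction(canopy.leaf_angle, self.L, self.sig)
        self.rho_cb = _canopy_reflection(self.k_b, self.sig)
        self.rho_cd = sum(w * _canopy_reflection(
            beam_extinction(canopy.leaf_angle, math.sin(math.radians(e))), self.sig)
            for e, w in zip(_SKY_ELEV, _SKY_W))
        self.k_n = self.k_d_s
        self.n0 = (canopy.n_avg * self.k_n * self.L
                   / (1.0 - math.exp(-self.k_n * self.L)))

    def shaded_flux_per_leaf(self, par_direct: float, par_diffuse: float,
                             depth: float) -> float:
        q_dif = ((1.0 - self.rho_cd) * par_diffuse * self.k_d_s
                 * math.exp(-self.k_d_s * depth))
        q_sct = ((1.0 - self.rho_cb) * par_direct * self.k_b_s
                 * math.exp(-self.k_b_s * depth)
                 - (1.0 - self.sig) * par_direct * self.k_b
                 * math.exp(-self.k_b * depth))
        return q_dif + max(q_sct, 0.0)

    def beam_flux_per_sunlit_leaf(self, par_direct: float) -> float:
        return (1.0 - self.sig) * self.k_b * par_direct


def sunlit_shaded_partition(canopy: CanopyState, sin_beta: float,
                            par_direct: float, par_diffuse: float,
                            n_b: float) -> tuple[ClassState, ClassState]:
    """Split the canopy into sunlit/shaded big leaves.

    ``par_direct``/``par_diffuse`` are incident fluxes (umol m-2 ground s-1)
    above the canopy.  Absorbed PAR is conserved: sunlit + shaded equals the
    whole-canopy absorbed flux by construction.
    """
    L = canopy.lai
    if L <= 1.0e-9 or sin_beta <= 0.0:
        return (ClassState(L, 0.0, max(canopy.n_avg - n_b, 0.0) * L),
                ClassState(0.0, 0.0, 0.0))
    o = _Optics(canopy, sin_beta)
    total = ((1.0 - o.rho_cb) * par_direct * (1.0 - math.exp(-o.k_b_s * L))
             + (1.0 - o.rho_cd) * par_diffuse * (1.0 - math.exp(-o.k_d_s * L)))
    q_sun_direct = par_direct * (1.0 - o.sig) * (1.0 - math.exp(-o.k_b * L))
    q_sun_diffuse = (par_diffuse * (1.0 - o.rho_cd)
                     * (1.0 - math.exp(-(o.k_d_s + o.k_b) * L))
                     * o.k_d_s / (o.k_d_s + o.k_b))
    q_sun_scatter = par_direct * (
        (1.0 - o.rho_cb) * (1.0 - math.exp(-(o.k_b_s + o.k_b) * L))
        * o.k_b_s / (o.k_b_s + o.k_b)
        - (1.0 - o.sig) * (1.0 - math.exp(-2.0 * o.k_b * L)) / 2.0)
    q_sun = q_sun_direct + q_sun_diffuse + max(q_sun_scatter, 0.0)
    q_sun = min(q_sun, total)

    lai_sun = (1.0 - math.exp(-o.k_b * L)) / o.k_b
    n_tot = max(canopy.n_avg - n_b, 0.0) * L
    n_sun = (o.n0 * (1.0 - math.exp(-(o.k_n + o.k_b) * L)) / (o.k_n + o.k_b)
             - n_b * (1.0 - math.exp(-o.k_b * L)) / o.k_b)
    n_sun = min(max(n_sun, 0.0), n_tot)
    return (ClassState(lai_sun, q_sun, n_sun),
            ClassState(L - lai_sun, total - q_sun, n_tot - n_sun))


def gauss_integrate_day(f, daylength: float) -> float:
    """Integral of ``f(t_since_dawn_hours)`` over the photoperiod by
    5-point Gauss-Legendre quadrature (exact through degree-9 polynomials)."""
    if daylength <= 0.0:
        raise ValueError("daylength must be positive")
    return daylength * sum(w * f(x * daylength)
                           for x, w in zip(GAUSS5_X, GAUSS5_W))


@dataclass
class _ClassFlux:
    """Solved state of one big leaf at one time point (per m2 ground)."""

    lai: float
    a: float            # umol m-2 ground s-1
    gs: float           # mol m-2 ground s-1
    e: float            # mm h-1
    t_l: float
    par_abs: float      # umol m-2 ground s-1


@dataclass
class InstantFlux:
    """Instantaneous canopy totals (per m2 ground) and per-class detail."""

    a: float                 # net assimilation, umol m-2 s-1
    e: float                 # transpiration, mm h-1
    par_abs: float           # absorbed PAR, umol m-2 s-1
    classes: tuple           # (_ClassFlux sunlit, _ClassFlux shaded)


def _class_nodes(optics: _Optics, par_direct: float, par_diffuse: float,
                 sunlit: bool):
    """Depth nodes (weight_lai, absorbed_per_leaf, n_leaf) for one class."""
    L = optics.L
    beam = optics.beam_flux_per_sunlit_leaf(par_direct)
    nodes = []
    for x, w in zip(GAUSS3_X, GAUSS3_W):
        depth = x * L
        f_sun = math.exp(-optics.k_b * depth)
        frac = f_sun if sunlit else 1.0 - f_sun
        if frac <= 1.0e-12:
            continue
        q = optics.shaded_flux_per_leaf(par_direct, par_diffuse, depth)
        if sunlit:
            q += beam
        n_leaf = optics.n0 * math.exp(-optics.k_n * depth)
        nodes.append((w * L * frac, q, n_leaf))
    return nodes


def _solve_class(nodes, p: PhotoParams, t_l: float, vpd: float, c_a: float,
                 gs_scale: float | None = None) -> tuple[float, float]:
    """Class totals (A, gs) per m2 ground by summing the depth nodes at one
    class leaf temperature.  ``gs_scale`` re-solves each node at a scaled
    stomatal conductance (water-limited path)."""
    a_tot = gs_tot = 0.0
    for w, q, n_leaf in nodes:
        env = LeafEnv(c_a=c_a, t_l=t_l, vpd=vpd, n_leaf=n_leaf, i_abs=q,
                      g_b=3.0)
        if gs_scale is None:
            f = solve_leaf(env, p)
        else:
            base = solve_leaf(env, p)
            f = solve_leaf_given_gs(max(base.g_s * gs_scale, 1.0e-6), env, p)
        a_tot += w * f.a
        gs_tot += w * f.g_s
    return a_tot, gs_tot


def _class_micromet(t_air: float, vap: float, wind: float, rn: float,
                    lai_class: float) -> MicroMet:
    mm = MicroMet(t_air=t_air, vapour_pressure=vap, wind=wind,
                  net_radiation_absorbed=rn)
    # big-leaf aggregation: per-leaf boundary layers act in parallel
    scale = max(lai_class, 0.05)
    mm.r_bh = mm.r_bh / scale
    mm.r_bw = mm.r_bw / scale
    return mm


def instantaneous_canopy_flux(canopy: CanopyState, p: PhotoParams,
                              sin_beta: float, par_direct: float,
                              par_diffuse: float, t_air: float, vap: float,
                              wind: float, c_a: float,
                              t_leaf_fixed: float | None = None,
                              t_start: tuple | None = None) -> InstantFlux:
    """Solve both big leaves (with or without the class energy balance) and
    sum their fluxes."""
    sun, shade = sunlit_shaded_partition(canopy, sin_beta, par_direct,
                                         par_diffuse, p.n_b)
    if canopy.lai <= 1.0e-9 or sin_beta <= 0.0:
        empty = _ClassFlux(0.0, 0.0, 0.0, 0.0, t_air, 0.0)
        return InstantFlux(0.0, 0.0, 0.0, (empty, empty))
    optics = _Optics(canopy, sin_beta)
    lw = isothermal_net_longwave(t_air, vap) * (1.0 - math.exp(-0.8 * canopy.lai))
    a_tot = e_tot = 0.0
    classes = []
    for i, (cls, sunlit) in enumerate(((sun, True), (shade, False))):
        if cls.lai <= 1.0e-9:
            classes.append(_ClassFlux(0.0, 0.0, 0.0, 0.0, t_air, 0.0))
            continue
        nodes = _class_nodes(optics, par_direct, par_diffuse, sunlit)
        if t_leaf_fixed is not None:
            vpd = max(saturated_vp(t_leaf_fixed) - vap, 0.0)
            a, gs = _solve_class(nodes, p, t_leaf_fixed, vpd, c_a)
            cf = _ClassFlux(cls.lai, a, gs, 0.0, t_leaf_fixed, cls.par_abs)
        else:
            # shortwave: absorbed NIR taken equal to absorbed PAR
            rn = (2.0 * cls.par_abs / UMOL_PER_J_PAR
                  - lw * cls.lai / canopy.lai)
            mm = _class_micromet(t_air, vap, wind, rn, cls.lai)
            t_l = t_air if t_start is None else t_start[i]
            a = gs = e = 0.0
            for it in range(25):
                vpd = max(saturated_vp(t_l) - vap, 0.0)
                a, gs = _solve_class(nodes, p, t_l, vpd, c_a)
                e, t_new = penman_monteith(max(gs, 1.0e-6), mm)
                if abs(t_new - t_l) < T_TOL_CANOPY:
                    t_l = t_new
                    break
                t_l = t_new if it < 10 else t_l + 0.5 * (t_new - t_l)
            cf = _ClassFlux(cls.lai, a, gs, e, t_l, cls.par_abs)
        a_tot += cf.a
        e_tot += max(cf.e, 0.0)
        classes.append(cf)
    return InstantFlux(a=a_tot, e=e_tot, par_abs=sun.par_abs + shade.par_abs,
                       classes=tuple(classes))


@dataclass
class DayCanopyResult:
    """Daily canopy totals (per m2 ground)."""

    a_pot: float        # potential net canopy photosynthesis, g CO2 m-2 d-1
    a_act: float        # actual (water-limited) value; equals a_pot when unstressed
    e_pot: float        # potential transpiration, mm d-1
    e_act: float        # actual transpiration, mm d-1
    par_abs_MJ: float   # absorbed PAR, MJ m-2 d-1


def diffuse_fraction(transmissivity: float, sin_beta: float) -> float:
    """Diffuse fraction of global radiation from atmospheric transmissivity
    (Spitters-type piecewise relation, floored at 0.15)."""
    tau = transmissivity
    if tau <= 0.22:
        fd = 1.0
    elif tau <= 0.35:
        fd = 1.0 - 6.4 * (tau - 0.22) ** 2
    else:
        fd = 1.47 - 1.66 * tau
    return min(max(fd, 0.15), 1.0)


def _air_temperature(tmin: float, tmax: float, t_since_dawn: float,
                     daylength: float) -> float:
    """Sinusoidal diurnal course: minimum at dawn, maximum 1.5 h after
    solar noon."""
    return tmin + (tmax - tmin) * math.sin(
        math.pi * t_since_dawn / (daylength + 3.0))


def daily_canopy_photosynthesis(drivers: DayDrivers, canopy: CanopyState,
                                p: PhotoParams,
                                water_supply_mm: float | None = None) -> DayCanopyResult:
    """Integrate canopy photosynthesis and transpiration over one day.

    ``water_supply_mm`` switches on the water-limited path: the day's
    available water (mm) follows the diurnal radiation course and is split
    between the big leaves in proportion to potential transpiration.
    """
    D = drivers.daylength
    if D <= 0.0 or drivers.radiation_MJ <= 0.0 or canopy.lai <= 1.0e-9:
        return DayCanopyResult(0.0, 0.0, 0.0, 0.0, 0.0)

    # instantaneous global radiation from the daily total, weighted by solar
    # elevation; Gaussian weights make the diurnal integral close exactly
    dawn = 12.0 - D / 2.0
    hours = [dawn + x * D for x in GAUSS5_X]
    sinb = [max(sin_elevation(drivers.latitude, drivers.doy, h), 0.0) for h in hours]
    wrad = [s * (1.0 + 0.4 * s) for s in sinb]
    norm = sum(w * r for w, r in zip(GAUSS5_W, wrad)) * D * 3600.0
    if norm <= 0.0:
        return DayCanopyResult(0.0, 0.0, 0.0, 0.0, 0.0)
    s_inst = [drivers.radiation_MJ * 1.0e6 * r / norm for r in wrad]  # W m-2

    _, ra_MJ = daylength_and_radiation(drivers.latitude, drivers.doy)
    tau_day = drivers.radiation_MJ / max(ra_MJ, 1.0e-6)

    a_pot = a_act = e_pot = e_act = par_MJ = 0.0
    t_prev: tuple | None = None
    for i, (h, sb, s_w) in enumerate(zip(hours, sinb, s_inst)):
        w_t = GAUSS5_W[i] * D  # hours represented by this node
        if sb <= 0.0 or s_w <= 0.0:
            continue
        t_air = _air_temperature(drivers.tmin, drivers.tmax, h - dawn, D)
        fd = (drivers.diffuse_fixed if drivers.diffuse_fixed is not None
              else diffuse_fraction(tau_day, sb))
        par_umol = PAR_FRACTION * s_w * UMOL_PER_J_PAR
        inst = instantaneous_canopy_flux(
            canopy, p, sb, par_umol * (1.0 - fd), par_umol * fd, t_air,
            drivers.vap_kPa, drivers.wind, drivers.c_a,
            t_leaf_fixed=drivers.t_leaf_fixed, t_start=t_prev)
        t_prev = tuple(c.t_l for c in inst.classes)
        a_pot += inst.a * w_t * 3600.0 * GCO2_PER_UMOL
        e_pot += inst.e * w_t
        par_MJ += inst.par_abs / UMOL_PER_J_PAR * w_t * 3600.0 / 1.0e6

        if water_supply_mm is None:
            continue
        # available water at this node follows the radiation course (mm h-1):
        # W_i = W_day * S_i / integral(S dt), so the day's allowance closes
        w_inst = (water_supply_mm * s_w * 3600.0
                  / (drivers.radiation_MJ * 1.0e6))
        e_p_tot = inst.e
        if e_p_tot <= w_inst + 1.0e-12 or e_p_tot <= E_MIN:
            a_act += inst.a * w_t * 3600.0 * GCO2_PER_UMOL
            e_act += e_p_tot * w_t
            continue
        optics = _Optics(canopy, sb)
        a_node = 0.0
        for cf, sunlit in zip(inst.classes, (True, False)):
            if cf.lai <= 1.0e-9:
                continue
            e_a = max(w_inst * cf.e / e_p_tot, E_MIN)
            e_p_cls = max(cf.e, e_a)
            mm = _class_micromet(t_air, drivers.vap_kPa, drivers.wind, 0.0,
                                 cf.lai)
            r_sw_a = actual_stomatal_resistance(e_p_cls, e_a,
                                                gs_mol_to_rsw(cf.gs), mm)
            gs_a = rsw_to_gs_mol(r_sw_a)
            scale = min(gs_a / max(cf.gs, 1.0e-9), 1.0)
            nodes = _class_nodes(optics, par_umol * (1.0 - fd), par_umol * fd,
                                 sunlit)
            vpd = max(saturated_vp(cf.t_l) - drivers.vap_kPa, 0.0)
            a_cls, _ = _solve_class(nodes, p, cf.t_l, vpd, drivers.c_a,
                                    gs_scale=scale)
            a_node += a_cls
            e_act += e_a * w_t
        a_act += a_node * w_t * 3600.0 * GCO2_PER_UMOL

    if water_supply_mm is None:
        a_act, e_act = a_pot, e_pot
    return DayCanopyResult(a_pot=a_pot, a_act=a_act, e_pot=e_pot, e_act=e_act,
                           par_abs_MJ=par_MJ)


def fig2_style_drivers(radiation_MJ: float, c_a: float = 400.0,
                       t_leaf: float = 25.0, vpd: float = 2.0) -> DayDrivers:
    """Drivers reproducing the daily-canopy grid conditions: 13-h day,
    fixed diffuse fraction 0.2, prescribed leaf temperature 25 degC.

    Latitude/day-of-year are chosen to give a 13-h photoperiod (declination
    ~15 deg), and air humidity set so the leaf-to-air VPD at the prescribed
    temperature is the requested value.
    """
    lat, doy = 26.4, 122
    vap = max(saturated_vp(t_leaf) - vpd, 0.05)
    return DayDrivers(radiation_MJ=radiation_MJ, tmax=t_leaf, tmin=t_leaf,
                      vap_kPa=vap, wind=2.0, c_a=c_a, latitude=lat, doy=doy,
                      diffuse_fixed=0.2, t_leaf_fixed=t_leaf)
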