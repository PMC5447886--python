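"""Leaf energy balance, transpiration and the water-limitation transform.

Couples the leaf photosynthesis solvers to the Penman-Monteith latent-heat
equation: the stomatal conductance solved at a trial leaf temperature feeds
the energy budget, which returns a new leaf temperature; the loop iterates
to a fixed point.  Under water limitation the actual transpiration a leaf is
allowed is converted back into an actual stomatal resistance,

    r_sw,a = (E_p - E_a)(s r_bh + gamma r_bw)/(gamma E_a) + r_sw,p E_p/E_a,

whose conductance is then fed to the fixed-gs biochemical solver.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .leaf import LeafEnv, LeafFlux, solve_leaf
from .params import PhotoParams

LAMBDA = 2.45e6        # latent heat of vaporization, J kg-1
RHO_CP = 1200.0        # volumetric heat capacity of air, J m-3 K-1
PSYCHROMETRIC = 0.067  # kPa K-1 at sea level
MOLAR_AIR = 41.0       # mol air m-3 at ~25 degC, 101 kPa (conductance unit bridge)
LEAF_WIDTH = 0.01      # m, characteristic leaf dimension (rice)
EMISSIVITY = 0.96
STEFAN_BOLTZMANN = 5.67e-8
E_FLOOR_MM_H = 1.0e-6  # transpiration floor before the resistance transform


def saturated_vp(t_c: float) -> float:
    """Saturation vapour pressure (kPa) at air temperature t_c (degC)."""
    return 0.6108 * math.exp(17.27 * t_c / (t_c + 237.3))


def svp_slope(t_c: float) -> float:
    """Slope s of the saturation curve (kPa K-1) at t_c."""
    return 4098.0 * saturated_vp(t_c) / (t_c + 237.3) ** 2


def boundary_layer_resistances(wind: float, leaf_width: float = LEAF_WIDTH) -> tuple[float, float]:
    """Flat-plate boundary-layer resistances to heat and water vapour
    (s m-1) from wind speed (m s-1) and leaf width (m)."""
    u = max(wind, 0.1)
    r_bh = 100.0 * math.sqrt(leaf_width / u)
    return r_bh, 0.93 * r_bh


@dataclass
class MicroMet:
    """Above-leaf micrometeorological state driving the energy budget."""

    t_air: float                # degC
    vapour_pressure: float      # kPa
    wind: float = 2.0           # m s-1
    net_radiation_absorbed: float = 0.0  # W m-2 (shortwave + isothermal longwave)
    gamma_psy: float = PSYCHROMETRIC

    def __post_init__(self):
        self.r_bh, self.r_bw = boundary_layer_resistances(self.wind)
        self.s_slope = svp_slope(self.t_air)

    @property
    def vpd_air(self) -> float:
        return max(saturated_vp(self.t_air) - self.vapour_pressure, 0.0)


def gs_mol_to_rsw(g_s: float) -> float:
    """Stomatal resistance to water vapour (s m-1) from the CO2 stomatal
    conductance (mol m-2 s-1); water conductance is 1.6 g_s."""
    return MOLAR_AIR / (1.6 * max(g_s, 1.0e-9))


def rsw_to_gs_mol(r_sw: float) -> float:
    """Inverse of :func:`gs_mol_to_rsw`."""
    return MOLAR_AIR / (1.6 * max(r_sw, 1.0e-9))


def penman_monteith(g_s: float, mm: MicroMet) -> tuple[float, float]:
    """Latent-heat flux and leaf temperature from the linearized energy
    budget at stomatal conductance ``g_s`` (mol CO2 m-2 s-1).

    Returns ``(E, t_l)`` with E in mm h-1 (may be <= 0 at night).
    """
    if g_s <= 0.0:
        raise ValueError("g_s must be positive")
    r_sw = gs_mol_to_rsw(g_s)
    return penman_monteith_rsw(r_sw, mm)


def penman_monteith_rsw(r_sw: float, mm: MicroMet) -> tuple[float, float]:
    """Penman-Monteith with the stomatal resistance given directly (s m-1)."""
    s, gam = mm.s_slope, mm.gamma_psy
    rn = mm.net_radiation_absorbed
    lam_e = ((s * mm.r_bh * rn + RHO_CP * mm.vpd_air)
             / (gam * (mm.r_bw + r_sw) + s * mm.r_bh))
    t_l = mm.t_air + (rn - lam_e) * mm.r_bh / RHO_CP
    e_mm_h = lam_e / LAMBDA * 3600.0
    return e_mm_h, t_l


@dataclass
class LeafExchange:
    """Converged coupled photosynthesis / energy-balance state."""

    flux: LeafFlux
    e: float           # transpiration, mm h-1
    t_l: float         # degC
    iterations: int


def iterate_leaf(env: LeafEnv, p: PhotoParams, mm: MicroMet,
                 t_tol: float = 0.01, max_iter: int = 50,
                 t_start: float | None = None) -> LeafExchange:
    """Fixed-point iteration of leaf temperature.

    Solves A/gs at the current leaf temperature, feeds gs to the
    Penman-Monteith budget for a new temperature, and repeats until the
    change is below ``t_tol`` (damping 0.5 after ``max_iter`` plain steps).
    """
    t_l = mm.t_air if t_start is None else t_start
    flux = None
    e = 0.0
    for it in range(1, 201):
        env.t_l = t_l
        env.vpd = max(saturated_vp(t_l) - mm.vapour_pressure, 0.0)
        flux = solve_leaf(env, p)
        e, t_new = penman_monteith(max(flux.g_s, 1.0e-6), mm)
        if abs(t_new - t_l) < t_tol:
            return LeafExchange(flux=flux, e=e, t_l=t_new, iterations=it)
        if it >= max_iter:
            t_l = t_l + 0.5 * (t_new - t_l)  # damped update
        else:
            t_l = t_new
    raise ArithmeticError("leaf temperature iteration did not converge")


def actual_stomatal_resistance(e_p: float, e_a: float, r_sw_p: float,
                               mm: MicroMet) -> float:
    """Actual stomatal resistance to water vapour under water limitation.

    ``e_p`` is the potential and ``e_a`` the allowed (actual) transpiration
    (same units, both > 0 with e_a <= e_p); ``r_sw_p`` is the unstressed
    resistance (s m-1).
    """
    if e_a <= 0.0:
        raise ValueError("actual transpiration must be positive "
                         "(floor it before the resistance transform)")
    if e_a > e_p:
        e_a = e_p
    s, gam = mm.s_slope, mm.gamma_psy
    return ((e_p - e_a) * (s * mm.r_bh + gam * mm.r_bw) / (gam * e_a)
            + r_sw_p * e_p / e_a)


def isothermal_net_longwave(t_air: float, vapour_pressure: float) -> float:
    """Clear-sky isothermal net longwave loss (W m-2, positive upward),
    Brunt-type emissivity from vapour pressure."""
    t_k = t_air + 273.15
    emis_net = 0.56 - 0.079 * math.sqrt(10.0 * max(vapour_pressure, 0.0))
    return EMISSIVITY * STEFAN_BOLTZMANN * t_k ** 4 * max(emis_net, 0.05)
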