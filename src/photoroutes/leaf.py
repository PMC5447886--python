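"""Biochemical leaf photosynthesis coupled to stomatal conductance.

Implements three leaf-model families on a shared equation base:

* C3: net assimilation A is the minimum of the Rubisco-limited and
  electron-transport-limited rates (FvCB), with CO2 diffusing from ambient
  air through the boundary layer, stomata and mesophyll (Ca -> Cs -> Ci -> Cc).
* C4: PEP carboxylation in the mesophyll concentrates CO2 into the bundle
  sheath; bundle-sheath conductance g_bs sets the leak L = g_bs (Cc - Ci)
  and A = Vp - L - Rm.
* CCM: the same equation structure re-parameterized for a cyanobacterial
  bicarbonate-transport mechanism (g_bs plays the role of the chloroplast
  envelope conductance, Vp the combined transporter rate, Rm = Rd, and the
  CCM ATP cost phi = 0.75 instead of 2).

The stomatal submodel is the residual-conductance + VPD-response form
(g_s = g0 + (A + Rd) f_vpd / (Ci - Ci*) for C3, the Cs-based analogue for
C4/CCM).  Each limitation branch of the coupled system is solved by a
guarded scalar root-find on A; independent oracles are kept in the tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.optimize import brentq

from .params import C3, C4, CCM, PhotoParams

R_GAS = 8.314  # J K-1 mol-1
_BIG = 1.0e6   # residual value returned for infeasible trial A


# ---------------------------------------------------------------------------
# shared response functions
# ---------------------------------------------------------------------------

def arrhenius(p25: float, e: float, t_l: float) -> float:
    """Arrhenius temperature scaling normalized to 25 degC.

    ``p25 * exp[(1/298 - 1/(273 + t_l)) * e / R]``; applies to Rd, gamma*,
    Vcmax, KmC, KmO and u_oc.
    """
    return p25 * math.exp((1.0 / 298.0 - 1.0 / (273.0 + t_l)) * e / R_GAS)


def _log1pexp(x: float) -> float:
    # log(1 + e^x), overflow-safe
    if x > 35.0:
        return x
    return math.log1p(math.exp(x))


def peaked_arrhenius(p25: float, e: float, d: float, s: float, t_l: float) -> float:
    """Peaked (modified) Arrhenius response, normalized so that it equals
    ``p25`` at 25 degC.  Applies to Jmax, eps_p, g_m and g_bs.

    ``d`` is the deactivation energy, ``s`` the entropy term; evaluated in
    log space so large ``s*298/R`` arguments cannot overflow.
    """
    t_k = 273.0 + t_l
    base = (1.0 / 298.0 - 1.0 / t_k) * e / R_GAS
    corr = _log1pexp((s - d / 298.0) / R_GAS) - _log1pexp((s - d / t_k) / R_GAS)
    return p25 * math.exp(base + corr)


def phi2ll_t_factor(t_opt: float, omega: float, t_l: float) -> float:
    """Gaussian temperature factor on the limiting-light PSII efficiency:
    1 at ``t_opt`` and 1/e at ``t_opt +/- omega``."""
    u = (t_l - t_opt) / omega
    return math.exp(-u * u)


def n_scaled_param25(chi: float, n: float, n_b: float) -> float:
    """Linear nitrogen scaling of a 25 degC capacity: ``chi * max(n - n_b, 0)``."""
    return chi * max(n - n_b, 0.0)


def j2_rate(i_abs: float, jmax: float, phi2ll_t: float, f_cyc: float,
            r2_1: float, theta: float) -> float:
    """PSII electron transport rate from absorbed irradiance.

    Non-rectangular hyperbola between the limiting-light response
    ``alpha2ll * i_abs`` and ``jmax``, where
    ``alpha2ll = phi2ll_t (1 - f_cyc) / (1 - f_cyc + r2_1)`` falls with
    increasing cyclic electron transport.
    """
    if i_abs <= 0.0 or jmax <= 0.0:
        return 0.0
    alpha2ll = phi2ll_t * (1.0 - f_cyc) / (1.0 - f_cyc + r2_1)
    ai = alpha2ll * i_abs
    if theta <= 0.0:
        return ai * jmax / (ai + jmax)
    b = ai + jmax
    disc = b * b - 4.0 * theta * jmax * ai
    return (b - math.sqrt(max(disc, 0.0))) / (2.0 * theta)


def fvpd(vpd: float, a1: float, b1: float) -> float:
    """Humidity-deficit multiplier of the stomatal slope:
    ``1 / (1 / max(a1 - b1 * vpd, 0.01) - 1)``."""
    c = max(a1 - b1 * vpd, 0.01)
    return 1.0 / (1.0 / c - 1.0)


def z_factor(f_q: float, f_cyc: float, h: float) -> float:
    """ATP yield of J2: ``z = (2 + f_q - f_cyc) / [h (1 - f_cyc)]``."""
    return (2.0 + f_q - f_cyc) / (h * (1.0 - f_cyc))


def vp_rate(c_i: float, j2: float, p: "PhotoParams", eps_p: float) -> tuple[float, str]:
    """PEP-carboxylation (or bicarbonate-transport) rate with its limitation.

    ``min(eps_p * c_i, x * j2 * z / phi)``; with phi = 0 the ATP branch is
    unbounded and the enzyme branch is always selected.
    """
    v_enz = eps_p * max(c_i, 0.0)
    if p.phi_ccm <= 0.0:
        return v_enz, "enzyme"
    v_et = p.x_atp * j2 * z_factor(p.f_q, p.f_cyc, p.h) / p.phi_ccm
    if v_enz <= v_et:
        return v_enz, "enzyme"
    return v_et, "e_transport"


# ---------------------------------------------------------------------------
# driving environment and solved state
# ---------------------------------------------------------------------------

@dataclass
class LeafEnv:
    """Driving variables of one leaf (or one canopy big leaf).

    ``i_abs`` overrides ``i_inc * absorptance`` when the absorbed flux is
    known directly (canopy scaling supplies absorbed PAR per big leaf).
    """

    i_inc: float = 0.0          # incident PAR, umol photons m-2 s-1
    c_a: float = 400.0          # ambient CO2, umol mol-1
    t_l: float = 25.0           # leaf temperature, degC
    vpd: float = 1.0            # leaf-to-air vapour pressure deficit, kPa
    n_leaf: float = 2.0         # leaf nitrogen, g N m-2
    o_i: float = 210.0          # intercellular O2, mmol mol-1
    absorptance: float = 0.85
    g_b: float = 3.0            # boundary-layer conductance to CO2, mol m-2 s-1
    i_abs: float | None = None  # absorbed PAR override, umol m-2 s-1

    @property
    def absorbed(self) -> float:
        return self.i_abs if self.i_abs is not None else self.i_inc * self.absorptance


@dataclass
class LeafFlux:
    """Mutually consistent solved leaf state."""

    a: float                    # net CO2 assimilation, umol m-2 s-1
    g_s: float                  # stomatal conductance to CO2, mol m-2 s-1
    c_i: float
    c_c: float
    c_s: float
    j2: float
    limitation: str             # "enzyme" | "e_transport"
    o_bs: float = 0.0           # bundle-sheath O2, mmol mol-1 (C4/CCM)
    v_p: float = 0.0            # PEP carboxylation / transport rate (C4/CCM)
    leak: float = 0.0           # bundle-sheath CO2 leak (C4/CCM)
    rd: float = 0.0             # day respiration at leaf temperature


class _AtT:
    """All temperature- and nitrogen-adjusted parameters at one leaf state."""

    __slots__ = ("vcmax", "jmax", "rd", "rm", "gamma_star", "kmc", "kmo_umol",
                 "gm", "eps_p", "gbs", "u_oc", "phi2", "fv")

    def __init__(self, p: PhotoParams, t_l: float, n_leaf: float, vpd: float):
        dn = max(n_leaf - p.n_b, 0.0)
        self.vcmax = arrhenius(p.chi_vcmax25 * dn, p.e_vcmax, t_l)
        self.jmax = peaked_arrhenius(p.chi_jmax25 * dn, p.e_jmax, p.d_jmax, p.s_jmax, t_l)
        self.rd = arrhenius(p.rd25_factor * p.chi_vcmax25 * dn, p.e_rd, t_l)
        self.rm = p.rm_factor * self.rd
        self.gamma_star = arrhenius(p.gamma_star25, p.e_gamma, t_l)
        self.kmc = arrhenius(p.k_mc25, p.e_kmc, t_l)
        self.kmo_umol = arrhenius(p.k_mo25 * 1000.0, p.e_kmo, t_l)
        self.gm = peaked_arrhenius(p.chi_gm25 * dn, p.e_gm, p.d_gm, p.s_gm, t_l)
        self.eps_p = peaked_arrhenius(p.chi_epsp25 * dn, p.e_epsp, p.d_epsp, p.s_epsp, t_l)
        self.gbs = peaked_arrhenius(p.chi_gbs25 * dn, p.e_gbs, p.d_gbs, p.s_gbs, t_l)
        self.u_oc = arrhenius(p.u_oc25, p.e_uoc, t_l)
        self.phi2 = p.phi2ll * phi2ll_t_factor(p.t_opt, p.omega, t_l)
        self.fv = fvpd(vpd, p.a1, p.b1)


def _aj_x1(j2: float, p: PhotoParams) -> float:
    return (1.0 - p.f_pseudo / (1.0 - p.f_cyc)) * j2 / 4.0


def c3_limited_rate(c_c: float, o_mmol: float, which: str, pt: _AtT,
                    p: PhotoParams, j2: float = 0.0) -> float:
    """Gross-minus-Rd rate of one C3 limitation branch at a given Cc.

    ``which`` is "Ac" (Rubisco) or "Aj" (electron transport); ``o_mmol`` is
    the chloroplast O2 level in mmol mol-1.  The Aj branch needs the PSII
    electron transport rate ``j2``.
    """
    o_umol = o_mmol * 1000.0
    gam = pt.gamma_star * o_umol
    if which == "Ac":
        x1, x2 = pt.vcmax, pt.kmc * (1.0 + o_umol / pt.kmo_umol)
    else:
        x1, x2 = _aj_x1(j2, p), 2.0 * gam
    return (c_c - gam) * x1 / (c_c + x2) - pt.rd


# ---------------------------------------------------------------------------
# C3 solver
# ---------------------------------------------------------------------------


def _solve_branch_c3(x1: float, x2: float, env: LeafEnv, p: PhotoParams,
                     pt: _AtT) -> float:
    """Solve one C3 limitation branch of the coupled A/gs/Ci/Cc system."""
    if x1 <= 0.0:
        return -pt.rd
    gm = pt.gm
    gam = pt.gamma_star * env.o_i * 1000.0
    ci_star = gam - (pt.rd / gm if gm > 0.0 else 0.0)
    g0 = p.g0

    def gs_of(a: float) -> float | None:
        cs = env.c_a - a / env.g_b
        alpha = cs - ci_star
        if alpha <= 1.0e-9:
            return None
        bcoef = a + g0 * alpha + (a + pt.rd) * pt.fv
        disc = bcoef * bcoef - 4.0 * alpha * g0 * a
        if disc < 0.0:
            return None
        return max((bcoef + math.sqrt(disc)) / (2.0 * alpha), 1.0e-9)

    def resid(a: float) -> float:
        gs = gs_of(a)
        if gs is None:
            return _BIG
        ci = env.c_a - a / env.g_b - a / gs
        cc = ci - (a / gm if gm > 0.0 else 0.0)
        den = cc + x2
        if den <= 1.0e-9:
            return _BIG
        rate = (cc - gam) * x1 / den - pt.rd
        return a - rate

    lo = -pt.rd
    r_lo = resid(lo)
    if abs(r_lo) < 1.0e-12:
        return lo
    if r_lo > 0.0:
        # net efflux beyond -Rd (very low Ca); walk the bracket down
        step = max(pt.rd, 0.5)
        while r_lo > 0.0 and lo > -pt.rd - x1 - 10.0:
            lo -= step
            step *= 2.0
            r_lo = resid(lo)
        if r_lo > 0.0:
            return -pt.rd
        hi = lo + step
    else:
        a_diff = env.g_b * (env.c_a - ci_star)
        hi = min(x1 - pt.rd, 0.999 * a_diff) if a_diff > 0 else x1 - pt.rd
        r_hi = resid(hi)
        shrink = 0
        while r_hi < 0.0 and shrink < 60:
            # upper cap was infeasible/too low: move toward the diffusion cap
            hi = hi + 0.5 * (max(a_diff, hi + 1.0) - hi)
            r_hi = resid(hi)
            shrink += 1
        if r_hi < 0.0:
            raise ArithmeticError("C3 leaf solver: no physical root in branch")
    return brentq(resid, lo, hi, xtol=1.0e-10, maxiter=200)


def solve_c3_leaf(env: LeafEnv, p: PhotoParams) -> LeafFlux:
    """Solve the coupled C3 leaf (A, gs, Ci, Cc) at prescribed leaf
    temperature; A is the minimum over the two FvCB limitation branches,
    each solved to full consistency."""
    pt = _AtT(p, env.t_l, env.n_leaf, env.vpd)
    if env.n_leaf <= p.n_b or pt.vcmax <= 0.0:
        return LeafFlux(a=-pt.rd, g_s=p.g0, c_i=env.c_a, c_c=env.c_a,
                        c_s=env.c_a, j2=0.0, limitation="enzyme", rd=pt.rd)
    j2 = j2_rate(env.absorbed, pt.jmax, pt.phi2, p.f_cyc, p.r2_1, p.theta)
    o_umol = env.o_i * 1000.0
    gam = pt.gamma_star * o_umol
    a_c = _solve_branch_c3(pt.vcmax, pt.kmc * (1.0 + o_umol / pt.kmo_umol), env, p, pt)
    a_j = _solve_branch_c3(_aj_x1(j2, p), 2.0 * gam, env, p, pt)
    if a_c <= a_j:
        a, lim = a_c, "enzyme"
    else:
        a, lim = a_j, "e_transport"
    return _c3_flux_from_a(a, env, p, pt, j2, lim)


def _c3_flux_from_a(a: float, env: LeafEnv, p: PhotoParams, pt: _AtT,
                    j2: float, lim: str) -> LeafFlux:
    gam = pt.gamma_star * env.o_i * 1000.0
    ci_star = gam - (pt.rd / pt.gm if pt.gm > 0.0 else 0.0)
    cs = env.c_a - a / env.g_b
    alpha = cs - ci_star
    g0 = p.g0
    if alpha > 1.0e-9:
        bcoef = a + g0 * alpha + (a + pt.rd) * pt.fv
        disc = max(bcoef * bcoef - 4.0 * alpha * g0 * a, 0.0)
        gs = max((bcoef + math.sqrt(disc)) / (2.0 * alpha), g0)
    else:
        gs = g0
    ci = cs - a / gs
    cc = ci - (a / pt.gm if pt.gm > 0.0 else 0.0)
    return LeafFlux(a=a, g_s=gs, c_i=ci, c_c=cc, c_s=cs, j2=j2,
                    limitation=lim, rd=pt.rd)


# ---------------------------------------------------------------------------
# C4 / CCM solver
# ---------------------------------------------------------------------------

def _cs_star(p: PhotoParams, pt: _AtT, o_i_umol: float) -> float:
    """Cs-based compensation point of the C4/CCM stomatal submodel."""
    lump = 1.0 + pt.gamma_star * p.alpha_bs / pt.u_oc
    if p.cs_star_grouping == "rd_minus_rm":
        num = pt.gbs * pt.gamma_star * o_i_umol - lump * (pt.rd - pt.rm)
    else:
        num = pt.gbs * pt.gamma_star * o_i_umol - lump * pt.rd + pt.rm
    return num / (pt.gbs + pt.eps_p)


def _c4_branch_terms(rub: str, vpb: str, p: PhotoParams, pt: _AtT, j2: float):
    if rub == "enzyme":
        x1, x2, x3 = pt.vcmax, pt.kmc / pt.kmo_umol, pt.kmc
    else:
        x1, x2, x3 = _aj_x1(j2, p), 2.0 * pt.gamma_star, 0.0
    if vpb == "enzyme":
        a_vp, b_vp = 1.0 + pt.eps_p / pt.gbs, 0.0
    else:
        b_vp = p.x_atp * j2 * z_factor(p.f_q, p.f_cyc, p.h) / p.phi_ccm
        a_vp = 1.0
    return x1, x2, x3, a_vp, b_vp


def _solve_branch_c4(rub: str, vpb: str, env: LeafEnv, p: PhotoParams,
                     pt: _AtT, j2: float, gs_fixed: float | None = None) -> tuple[float, float]:
    """Solve one (Rubisco-branch, Vp-branch) combination; returns (A, Ci)."""
    x1, x2, x3, a_vp, b_vp = _c4_branch_terms(rub, vpb, p, pt, j2)
    if x1 <= 0.0:
        a = -pt.rd
        gs = gs_fixed if gs_fixed is not None else p.g0
        ci = env.c_a - a * (1.0 / env.g_b + 1.0 / gs)
        return a, ci
    o_i_umol = env.o_i * 1000.0
    cs_star = _cs_star(p, pt, o_i_umol)
    g0 = p.g0
    alpha_f = p.alpha_bs / (pt.u_oc * pt.gbs)

    def ci_of(a: float) -> float | None:
        cs = env.c_a - a / env.g_b
        if gs_fixed is not None:
            return cs - a / gs_fixed
        den = cs - cs_star
        if den <= 1.0e-9:
            return None
        gs = g0 + (a + pt.rd) * pt.fv / den
        if gs <= 1.0e-9:
            gs = 1.0e-9
        return cs - a / gs

    def resid(a: float) -> float:
        ci = ci_of(a)
        if ci is None:
            return _BIG
        o_umol = max(o_i_umol + alpha_f * a, 0.0)
        cc = a_vp * ci + (b_vp - a - pt.rm) / pt.gbs
        den = cc + x2 * o_umol + x3
        if den <= 1.0e-9:
            return _BIG
        rate = (cc - pt.gamma_star * o_umol) * x1 / den - pt.rd
        return a - rate

    lo = -pt.rd
    r_lo = resid(lo)
    if abs(r_lo) < 1.0e-12:
        return lo, ci_of(lo)
    if r_lo > 0.0:
        step = max(pt.rd, 0.5)
        while r_lo > 0.0 and lo > -pt.rd - x1 - 10.0:
            lo -= step
            step *= 2.0
            r_lo = resid(lo)
        if r_lo > 0.0:
            ci = ci_of(-pt.rd)
            return -pt.rd, ci if ci is not None else env.c_a
        hi = lo + step
    else:
        if gs_fixed is not None:
            cap = env.g_b * env.c_a
        else:
            cap = env.g_b * (env.c_a - cs_star)
        hi = min(x1 - pt.rd, 0.999 * cap) if cap > 0 else x1 - pt.rd
        r_hi = resid(hi)
        shrink = 0
        while r_hi < 0.0 and shrink < 60:
            hi = hi + 0.5 * (max(cap, hi + 1.0) - hi)
            r_hi = resid(hi)
            shrink += 1
        if r_hi < 0.0:
            raise ArithmeticError("C4 leaf solver: no physical root in branch "
                                  f"({rub}/{vpb})")
    a = brentq(resid, lo, hi, xtol=1.0e-10, maxiter=200)
    return a, ci_of(a)


def _solve_rub_branch_c4(rub: str, env: LeafEnv, p: PhotoParams, pt: _AtT,
                         j2: float, gs_fixed: float | None = None) -> float:
    """Solve one Rubisco branch with Vp-limitation selection: try the
    PEP-carboxylase branch, switch to the ATP branch when inconsistent."""
    a_enz, ci = _solve_branch_c4(rub, "enzyme", env, p, pt, j2, gs_fixed)
    if p.phi_ccm <= 0.0:
        return a_enz
    v_et = p.x_atp * j2 * z_factor(p.f_q, p.f_cyc, p.h) / p.phi_ccm
    if pt.eps_p * max(ci, 0.0) <= v_et * (1.0 + 1.0e-9):
        return a_enz
    a_et, _ = _solve_branch_c4(rub, "e_transport", env, p, pt, j2, gs_fixed)
    return a_et


def solve_c4_leaf(env: LeafEnv, p: PhotoParams) -> LeafFlux:
    """Solve the coupled C4/CCM leaf (A, gs, Ci, Cs, Cc, O, Vp, L) at
    prescribed leaf temperature."""
    pt = _AtT(p, env.t_l, env.n_leaf, env.vpd)
    if env.n_leaf <= p.n_b or pt.gbs <= 0.0:
        return LeafFlux(a=-pt.rd, g_s=p.g0, c_i=env.c_a, c_c=env.c_a,
                        c_s=env.c_a, j2=0.0, limitation="enzyme",
                        o_bs=env.o_i, rd=pt.rd)
    j2 = j2_rate(env.absorbed, pt.jmax, pt.phi2, p.f_cyc, p.r2_1, p.theta)
    a_c = _solve_rub_branch_c4("enzyme", env, p, pt, j2)
    a_j = _solve_rub_branch_c4("e_transport", env, p, pt, j2)
    if a_c <= a_j:
        a, lim = a_c, "enzyme"
    else:
        a, lim = a_j, "e_transport"
    return _c4_flux_from_a(a, env, p, pt, j2, lim, gs_fixed=None)


def _c4_flux_from_a(a: float, env: LeafEnv, p: PhotoParams, pt: _AtT,
                    j2: float, lim: str, gs_fixed: float | None) -> LeafFlux:
    o_i_umol = env.o_i * 1000.0
    cs = env.c_a - a / env.g_b
    if gs_fixed is not None:
        gs = gs_fixed
    else:
        den = cs - _cs_star(p, pt, o_i_umol)
        gs = p.g0 + (a + pt.rd) * pt.fv / den if den > 1.0e-9 else p.g0
        gs = max(gs, p.g0)
    ci = cs - a / gs
    o_umol = max(o_i_umol + p.alpha_bs * a / (pt.u_oc * pt.gbs), 0.0)
    vp, _vlim = vp_rate(ci, j2, p, pt.eps_p)
    cc = ci + (vp - a - pt.rm) / pt.gbs
    leak = pt.gbs * (cc - ci)
    return LeafFlux(a=a, g_s=gs, c_i=ci, c_c=cc, c_s=cs, j2=j2, limitation=lim,
                    o_bs=o_umol / 1000.0, v_p=vp, leak=leak, rd=pt.rd)


# ---------------------------------------------------------------------------
# dispatch and fixed-gs variants
# ---------------------------------------------------------------------------

def solve_leaf(env: LeafEnv, p: PhotoParams) -> LeafFlux:
    """Solve a leaf with the solver matching ``p.model_family``."""
    if p.model_family == C3:
        return solve_c3_leaf(env, p)
    return solve_c4_leaf(env, p)


def solve_leaf_given_gs(g_s: float, env: LeafEnv, p: PhotoParams) -> LeafFlux:
    """Solve the biochemical + diffusion system at a prescribed stomatal
    conductance (used for water-limited photosynthesis, where gs follows
    from the transpiration that the available water allows)."""
    if g_s <= 0.0:
        raise ValueError("g_s must be positive")
    pt = _AtT(p, env.t_l, env.n_leaf, env.vpd)
    j2 = j2_rate(env.absorbed, pt.jmax, pt.phi2, p.f_cyc, p.r2_1, p.theta)
    if p.model_family == C3:
        if env.n_leaf <= p.n_b or pt.vcmax <= 0.0:
            return LeafFlux(a=-pt.rd, g_s=g_s, c_i=env.c_a, c_c=env.c_a,
                            c_s=env.c_a, j2=0.0, limitation="enzyme", rd=pt.rd)
        o_umol = env.o_i * 1000.0
        gam = pt.gamma_star * o_umol

        def branch(x1: float, x2: float) -> float:
            if x1 <= 0.0:
                return -pt.rd

            def resid(a: float) -> float:
                ci = env.c_a - a * (1.0 / env.g_b + 1.0 / g_s)
                cc = ci - (a / pt.gm if pt.gm > 0.0 else 0.0)
                den = cc + x2
                if den <= 1.0e-9:
                    return _BIG
                return a - ((cc - gam) * x1 / den - pt.rd)

            lo, hi = -pt.rd - x1 - 10.0, x1 - pt.rd
            r_hi = resid(hi)
            while r_hi < 0.0:
                hi *= 2.0
                r_hi = resid(hi)
                if hi > 1.0e7:
                    raise ArithmeticError("C3 fixed-gs solver: no root")
            return brentq(resid, lo, hi, xtol=1.0e-10, maxiter=200)

        a_c = branch(pt.vcmax, pt.kmc * (1.0 + o_umol / pt.kmo_umol))
        a_j = branch(_aj_x1(j2, p), 2.0 * gam)
        a, lim = (a_c, "enzyme") if a_c <= a_j else (a_j, "e_transport")
        ci = env.c_a - a * (1.0 / env.g_b + 1.0 / g_s)
        cc = ci - (a / pt.gm if pt.gm > 0.0 else 0.0)
        return LeafFlux(a=a, g_s=g_s, c_i=ci, c_c=cc,
                        c_s=env.c_a - a / env.g_b, j2=j2, limitation=lim, rd=pt.rd)
    # C4 / CCM
    if env.n_leaf <= p.n_b or pt.gbs <= 0.0:
        return LeafFlux(a=-pt.rd, g_s=g_s, c_i=env.c_a, c_c=env.c_a,
                        c_s=env.c_a, j2=0.0, limitation="enzyme",
                        o_bs=env.o_i, rd=pt.rd)
    a_c = _solve_rub_branch_c4("enzyme", env, p, pt, j2, gs_fixed=g_s)
    a_j = _solve_rub_branch_c4("e_transport", env, p, pt, j2, gs_fixed=g_s)
    a, lim = (a_c, "enzyme") if a_c <= a_j else (a_j, "e_transport")
    return _c4_flux_from_a(a, env, p, pt, j2, lim, gs_fixed=g_s)


def make_ccm_params(base_c3: PhotoParams, elaborate: bool = False,
                    c4_capacity: bool = False) -> PhotoParams:
    """Build a cyanobacterial-CCM parameter set from the C3 defaults.

    The C4 model structure is reused with the chloroplast-envelope reading:
    Vp is the combined bicarbonate-transporter rate (phi = 0.75 ATP per CO2,
    x = 0.2 = 0.75/3.75), cyclic electron transport re-balanced to
    f_cyc = 0.18, and all respiration placed inside the compartment
    (Rm = Rd).  ``elaborate`` selects the carboxysome variant with the low
    envelope conductance slope (0.007 vs 0.125); ``c4_capacity`` adds the
    C4-level capacity slopes (chi_Vcmax25 = 93, chi_Jmax25 = 200).
    """
    from .params import c4_defaults
    c4 = c4_defaults()
    p = base_c3.replace(
        model_family=CCM,
        f_q=c4.f_q,
        h=c4.h,
        alpha_bs=c4.alpha_bs,
        u_oc25=c4.u_oc25,
        e_uoc=c4.e_uoc,
        chi_epsp25=c4.chi_epsp25,
        e_epsp=c4.e_epsp,
        d_epsp=c4.d_epsp,
        s_epsp=c4.s_epsp,
        e_gbs=c4.e_gbs,
        d_gbs=c4.d_gbs,
        s_gbs=c4.s_gbs,
        phi_ccm=0.75,
        x_atp=0.2,
        f_cyc=0.18,
        rm_factor=1.0,
        chi_gbs25=0.007 if elaborate else 0.125,
        chi_gm25=0.0,
    )
    if c4_capacity:
        p = p.replace(chi_vcmax25=93.0, chi_jmax25=200.0)
    return p


def response_curve_table(route_params: dict, i_inc_values, env_template: LeafEnv | None = None):
    """Light-response curves for several routes as a tidy DataFrame
    (columns: route, i_inc, a, gs, ci, cc, limitation)."""
    import pandas as pd

    base = env_template or LeafEnv(c_a=400.0, t_l=25.0, vpd=2.0, n_leaf=2.3)
    rows = []
    for name, p in route_params.items():
        for i_inc in i_inc_values:
            env = LeafEnv(i_inc=float(i_inc), c_a=base.c_a, t_l=base.t_l,
                          vpd=base.vpd, n_leaf=base.n_leaf, o_i=base.o_i,
                          absorptance=base.absorptance, g_b=base.g_b)
            f = solve_leaf(env, p)
            rows.append({"route": name, "i_inc": float(i_inc), "a": f.a,
                         "gs": f.g_s, "ci": f.c_i, "cc": f.c_c,
                         "limitation": f.limitation})
    return pd.DataFrame(rows)
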