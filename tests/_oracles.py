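"""Independent brute-force oracles for the coupled leaf solvers.

These re-derive the leaf models directly from the printed equation set with
a different computational structure than the package: the limitation
minimum is taken *inside* a single monotone residual (instead of solving
branches separately), stomatal conductance is found by inner bisection
(instead of the closed-form quadratic), and the outer root is located by
plain bisection.  They are deliberately slow and simple.
"""

from __future__ import annotations

import math

R = 8.314


def _arr(p25, e, t):
    return p25 * math.exp((1.0 / 298.0 - 1.0 / (273.0 + t)) * e / R)


def _peaked(p25, e, d, s, t):
    tk = 273.0 + t
    num = 1.0 + math.exp((s - d / 298.0) / R)
    den = 1.0 + math.exp((s - d / tk) / R)
    return _arr(p25, e, t) * num / den


class _P:
    """Temperature/N-adjusted parameter bundle, recomputed from scratch."""

    def __init__(self, p, t, n):
        dn = max(n - p.n_b, 0.0)
        self.vcmax = _arr(p.chi_vcmax25 * dn, p.e_vcmax, t)
        self.jmax = _peaked(p.chi_jmax25 * dn, p.e_jmax, p.d_jmax, p.s_jmax, t)
        self.rd = _arr(0.01 * p.chi_vcmax25 * dn, p.e_rd, t)
        self.rm = p.rm_factor * self.rd
        self.gstar = _arr(0.5 / p.s_co25, p.e_gamma, t)
        self.kmc = _arr(p.k_mc25, p.e_kmc, t)
        self.kmo = _arr(p.k_mo25 * 1000.0, p.e_kmo, t)
        self.gm = _peaked(p.chi_gm25 * dn, p.e_gm, p.d_gm, p.s_gm, t)
        self.eps = _peaked(p.chi_epsp25 * dn, p.e_epsp, p.d_epsp, p.s_epsp, t)
        self.gbs = _peaked(p.chi_gbs25 * dn, p.e_gbs, p.d_gbs, p.s_gbs, t)
        self.uoc = _arr(p.u_oc25, p.e_uoc, t)


def _j2(p, t, i_abs, jmax):
    phi2 = p.phi2ll * math.exp(-(((t - p.t_opt) / p.omega) ** 2))
    a2 = phi2 * (1.0 - p.f_cyc) / (1.0 - p.f_cyc + p.r2_1)
    ai = a2 * i_abs
    if ai <= 0 or jmax <= 0:
        return 0.0
    b = ai + jmax
    return (b - math.sqrt(b * b - 4.0 * p.theta * jmax * ai)) / (2.0 * p.theta)


def _fvpd(p, vpd):
    c = max(p.a1 - p.b1 * vpd, 0.01)
    return 1.0 / (1.0 / c - 1.0)


def _bisect(f, lo, hi, n=100):
    flo = f(lo)
    for _ in range(n):
        mid = 0.5 * (lo + hi)
        fm = f(mid)
        if (fm < 0) == (flo < 0):
            lo, flo = mid, fm
        else:
            hi = mid
    return 0.5 * (lo + hi)


def oracle_c3(env, p, tol=1.0e-9):
    """Brute-force C3 solution: outer bisection on A of the residual
    A - min(Ac, Aj)(A), with gs found by inner bisection."""
    pt = _P(p, env.t_l, env.n_leaf)
    if env.n_leaf <= p.n_b or pt.vcmax <= 0:
        return -pt.rd
    fv = _fvpd(p, env.vpd)
    j2 = _j2(p, env.t_l, env.absorbed, pt.jmax)
    o = env.o_i * 1000.0
    gam = pt.gstar * o
    ci_star = gam - (pt.rd / pt.gm if pt.gm > 0 else 0.0)
    x1j = (1.0 - p.f_pseudo / (1.0 - p.f_cyc)) * j2 / 4.0

    def gs_for(a):
        # gs = g0 + (A+Rd) fv / (Ci(gs) - Ci*), Ci = Ca - A/gb - A/gs
        cs = env.c_a - a / env.g_b
        if a + pt.rd <= 0.0:
            return p.g0
        gs_min = a / (cs - ci_star) if cs > ci_star and a > 0 else 1.0e-8

        def f(gs):
            ci = cs - a / gs
            return gs - p.g0 - (a + pt.rd) * fv / (ci - ci_star)

        lo = gs_min * (1.0 + 1.0e-9) + 1.0e-9
        hi = 1.0e3
        if f(hi) < 0:
            return hi
        return _bisect(f, lo, hi, 80)

    def min_rate(a):
        gs = gs_for(a)
        ci = env.c_a - a / env.g_b - a / gs
        cc = ci - (a / pt.gm if pt.gm > 0 else 0.0)
        den_c = cc + pt.kmc * (1.0 + o / pt.kmo)
        rc = ((cc - gam) * pt.vcmax / den_c - pt.rd
              if den_c > 0 else -1.0e9)  # beyond the pole: A unreachable
        den_j = cc + 2.0 * gam
        if x1j > 0:
            rj = ((cc - gam) * x1j / den_j - pt.rd
                  if den_j > 0 else -1.0e9)
        else:
            rj = -pt.rd
        return min(rc, rj)

    def g(a):
        return a - min_rate(a)

    lo, hi = -pt.rd, min(pt.vcmax, env.g_b * (env.c_a - ci_star)) * 0.999
    if g(lo) >= 0:
        return lo
    return _bisect(g, lo, hi, 80)


def oracle_c4(env, p, tol=1.0e-9):
    """Brute-force C4/CCM solution with Vp = min(eps_p Ci, x J2 z / phi)
    substituted directly and the Rubisco minimum inside the residual."""
    pt = _P(p, env.t_l, env.n_leaf)
    if env.n_leaf <= p.n_b or pt.gbs <= 0:
        return -pt.rd
    fv = _fvpd(p, env.vpd)
    j2 = _j2(p, env.t_l, env.absorbed, pt.jmax)
    z = (2.0 + p.f_q - p.f_cyc) / (p.h * (1.0 - p.f_cyc))
    vp_cap = (p.x_atp * j2 * z / p.phi_ccm) if p.phi_ccm > 0 else float("inf")
    oi = env.o_i * 1000.0
    lump = 1.0 + pt.gstar * p.alpha_bs / pt.uoc
    cs_star = (pt.gbs * pt.gstar * oi - lump * pt.rd + pt.rm) / (pt.gbs + pt.eps)
    x1j = (1.0 - p.f_pseudo / (1.0 - p.f_cyc)) * j2 / 4.0

    def min_rate(a):
        cs = env.c_a - a / env.g_b
        den = cs - cs_star
        if den <= 0:
            return -1.0e9  # forces residual positive: A is beyond reach
        gs = max(p.g0 + (a + pt.rd) * fv / den, 1.0e-9)
        ci = cs - a / gs
        o = max(oi + p.alpha_bs * a / (pt.uoc * pt.gbs), 0.0)
        vp = min(pt.eps * max(ci, 0.0), vp_cap)
        cc = ci + (vp - a - pt.rm) / pt.gbs
        den_c = cc + (pt.kmc / pt.kmo) * o + pt.kmc
        rc = ((cc - pt.gstar * o) * pt.vcmax / den_c - pt.rd
              if den_c > 0 else -1.0e9)  # beyond the pole: A unreachable
        den_j = cc + 2.0 * pt.gstar * o
        if x1j > 0:
            rj = ((cc - pt.gstar * o) * x1j / den_j - pt.rd
                  if den_j > 0 else -1.0e9)
        else:
            rj = -pt.rd
        return min(rc, rj)

    def g(a):
        return a - min_rate(a)

    lo = -pt.rd
    hi = min(pt.vcmax, 0.999 * env.g_b * (env.c_a - cs_star))
    if g(lo) >= 0:
        return lo
    return _bisect(g, lo, hi, 80)


def multilayer_canopy_a(canopy, p, sin_beta, par_direct, par_diffuse, t_leaf,
                        vpd, c_a, n_layers=100):
    """Fine multilayer numerical canopy assimilation (prescribed leaf
    temperature), integrating sunlit/shaded leaves layer by layer with the
    same optical coefficients as the sun/shade model."""
    from photoroutes.canopy import (_canopy_reflection, _SKY_ELEV, _SKY_W,
                                    beam_extinction, diffuse_extinction)
    from photoroutes.leaf import LeafEnv, solve_leaf

    L = canopy.lai
    sig = canopy.scattering
    sq = math.sqrt(1.0 - sig)
    k_b = beam_extinction(canopy.leaf_angle, sin_beta)
    k_b_s = k_b * sq
    k_d_s = diffuse_extinction(canopy.leaf_angle, L, sig)
    rho_cb = _canopy_reflection(k_b, sig)
    rho_cd = sum(w * _canopy_reflection(
        beam_extinction(canopy.leaf_angle, math.sin(math.radians(e))), sig)
        for e, w in zip(_SKY_ELEV, _SKY_W))
    k_n = k_d_s
    n0 = canopy.n_avg * k_n * L / (1.0 - math.exp(-k_n * L))

    dl = L / n_layers
    a_tot = 0.0
    for i in range(n_layers):
        depth = (i + 0.5) * dl
        f_sun = math.exp(-k_b * depth)
        # absorbed flux per unit leaf area at this depth
        q_diffuse = (1.0 - rho_cd) * par_diffuse * k_d_s * math.exp(-k_d_s * depth)
        q_scatter = ((1.0 - rho_cb) * par_direct * k_b_s * math.exp(-k_b_s * depth)
                     - (1.0 - sig) * par_direct * k_b * math.exp(-k_b * depth))
        q_shade = q_diffuse + max(q_scatter, 0.0)
        q_sun = q_shade + (1.0 - sig) * k_b * par_direct
        n_leaf = n0 * math.exp(-k_n * depth)
        for q, frac in ((q_sun, f_sun), (q_shade, 1.0 - f_sun)):
            if frac <= 0:
                continue
            env = LeafEnv(c_a=c_a, t_l=t_leaf, vpd=vpd, n_leaf=n_leaf,
                          i_abs=q, g_b=3.0)
            a_tot += solve_leaf(env, p).a * frac * dl
    return a_tot
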