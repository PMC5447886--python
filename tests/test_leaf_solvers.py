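"""Coupled leaf solvers: limit cases, oracle agreement, model consistency."""

import pytest

from photoroutes import (
    LeafEnv,
    build_route,
    c3_defaults,
    make_ccm_params,
    solve_c3_leaf,
    solve_c4_leaf,
    solve_leaf,
    solve_leaf_given_gs,
)
from photoroutes.leaf import _AtT

from _oracles import oracle_c3, oracle_c4
from conftest import fig1_env, random_envs


class TestC3Limits:
    def test_dark_leaf_respires_at_minimum_conductance(self, c3p):
        env = fig1_env(0.0)
        flux = solve_c3_leaf(env, c3p)
        pt = _AtT(c3p, env.t_l, env.n_leaf, env.vpd)
        assert flux.a == pytest.approx(-pt.rd, abs=1e-8)
        assert flux.g_s == pytest.approx(c3p.g0, abs=1e-6)

    def test_base_nitrogen_gives_zero_capacity(self, c3p):
        env = fig1_env(1500.0)
        env.n_leaf = c3p.n_b
        flux = solve_c3_leaf(env, c3p)
        assert flux.a == pytest.approx(0.0, abs=1e-12)  # Rd also scales with n - n_b
        assert flux.g_s == c3p.g0

    def test_removing_diffusion_limits_recovers_cc_at_ca(self, c3p):
        # prescribe huge gs and gm: the diffusion chain collapses, Cc -> Ca
        # and A approaches the closed-form biochemical rate at Cc = Ca
        p = c3p.replace(chi_gm25=1.0e6)
        env = fig1_env(1500.0)
        env.g_b = 1.0e5
        flux = solve_leaf_given_gs(1.0e5, env, p)
        assert flux.c_c == pytest.approx(env.c_a, rel=1e-3)
        pt = _AtT(p, env.t_l, env.n_leaf, env.vpd)
        from photoroutes.leaf import c3_limited_rate, j2_rate
        j2 = j2_rate(env.absorbed, pt.jmax, pt.phi2, p.f_cyc, p.r2_1, p.theta)
        closed = min(c3_limited_rate(env.c_a, env.o_i, "Ac", pt, p),
                     c3_limited_rate(env.c_a, env.o_i, "Aj", pt, p, j2))
        assert flux.a == pytest.approx(closed, rel=1e-3)

    def test_assimilation_monotone_in_light_and_co2(self, c3p):
        a_prev = -1.0e9
        for i_inc in (0, 100, 300, 600, 1000, 1500, 2000):
            a = solve_c3_leaf(fig1_env(i_inc), c3p).a
            assert a >= a_prev - 1e-9
            a_prev = a
        a_prev = -1.0e9
        for c_a in (200, 300, 400, 600, 800):
            env = fig1_env(1200.0)
            env.c_a = c_a
            a = solve_c3_leaf(env, c3p).a
            assert a >= a_prev - 1e-9
            a_prev = a


class TestC4Limits:
    def test_dark_leaf(self, c4p):
        env = fig1_env(0.0)
        flux = solve_c4_leaf(env, c4p)
        pt = _AtT(c4p, env.t_l, env.n_leaf, env.vpd)
        assert flux.a == pytest.approx(-pt.rd, abs=1e-7)

    def test_flux_balance_identity(self, c4p):
        # A = Vp - L - Rm must hold at any converged solution
        for i_inc in (200.0, 800.0, 1500.0):
            env = fig1_env(i_inc)
            flux = solve_c4_leaf(env, c4p)
            pt = _AtT(c4p, env.t_l, env.n_leaf, env.vpd)
            assert flux.a == pytest.approx(flux.v_p - flux.leak - pt.rm, abs=1e-8)

    def test_assimilation_monotone_in_light_all_c4_routes(self):
        for rid in (4, 5, 6, 7, 8, 9):
            p = build_route(rid).params
            a_prev = -1.0e9
            for i_inc in (0, 50, 150, 400, 800, 1500):
                a = solve_c4_leaf(fig1_env(i_inc), p).a
                assert a >= a_prev - 1e-9, f"route {rid} at {i_inc}"
                a_prev = a

    def test_cs_star_grouping_switch_near_equivalent_at_half_rm(self, c4p):
        env = fig1_env(1000.0)
        a_printed = solve_c4_leaf(env, c4p).a
        a_alt = solve_c4_leaf(env, c4p.replace(cs_star_grouping="rd_minus_rm")).a
        assert a_alt == pytest.approx(a_printed, rel=0.02)


class TestOracleAgreement:
    """Analytic-path solutions must match the independent brute-force
    root-finder to 1e-6 umol m-2 s-1."""

    def test_c3_random_environments(self, c3p):
        for env in random_envs(40, seed=101):
            a = solve_c3_leaf(env, c3p).a
            assert a == pytest.approx(oracle_c3(env, c3p), abs=1e-6)

    @pytest.mark.parametrize("rid", [4, 6, 7, 9])
    def test_c4_and_ccm_random_environments(self, rid):
        p = build_route(rid).params
        for env in random_envs(25, seed=200 + rid):
            a = solve_c4_leaf(env, p).a
            assert a == pytest.approx(oracle_c4(env, p), abs=1e-6)


class TestFixedGs:
    def test_round_trip_reproduces_coupled_solution(self):
        for rid in (0, 2, 6, 9):
            p = build_route(rid).params
            for i_inc in (300.0, 1500.0):
                env = fig1_env(i_inc)
                ref = solve_leaf(env, p)
                again = solve_leaf_given_gs(ref.g_s, fig1_env(i_inc), p)
                assert again.a == pytest.approx(ref.a, abs=1e-8), f"route {rid}"

    def test_dark_leaf_at_minimum_gs(self, c3p):
        env = fig1_env(0.0)
        flux = solve_leaf_given_gs(c3p.g0, env, c3p)
        pt = _AtT(c3p, env.t_l, env.n_leaf, env.vpd)
        assert flux.a == pytest.approx(-pt.rd, abs=1e-8)

    def test_rejects_nonpositive_gs(self, c3p):
        with pytest.raises(ValueError):
            solve_leaf_given_gs(0.0, fig1_env(500.0), c3p)


class TestModelFamilyConsistency:
    def test_ccm_with_open_envelope_recovers_c3(self, c3p):
        """With a huge envelope conductance, no CCM ATP cost and the C3
        electron-transport fractions, the C4-structure biochemistry must
        agree with the C3 model (Cc ~ Ci in both when gm is huge).

        Compared at a common prescribed gs: the stomatal submodels of the
        two families are deliberately different empirical forms (Ci- vs
        Cs-based), so the consistency statement is about the biochemistry.
        """
        ccm = make_ccm_params(c3p).replace(
            chi_gbs25=1.0e6, phi_ccm=0.0, x_atp=0.0, f_cyc=0.05,
            f_pseudo=0.10, rm_factor=0.0)
        c3_nogm = c3p.replace(chi_gm25=1.0e6)
        for i_inc in (150.0, 600.0, 1500.0):
            for gs in (0.1, 0.3):
                a_ccm = solve_leaf_given_gs(gs, fig1_env(i_inc), ccm).a
                a_c3 = solve_leaf_given_gs(gs, fig1_env(i_inc), c3_nogm).a
                assert a_ccm == pytest.approx(a_c3, rel=0.02)

    def test_temperature_adjusted_params_equal_25_values_at_25(self, c4p):
        pt = _AtT(c4p, 25.0, 2.3, 1.0)
        dn = 2.3 - c4p.n_b
        assert pt.vcmax == pytest.approx(c4p.chi_vcmax25 * dn, rel=1e-12)
        assert pt.jmax == pytest.approx(c4p.chi_jmax25 * dn, rel=1e-12)
        assert pt.eps_p == pytest.approx(c4p.chi_epsp25 * dn, rel=1e-12)
        assert pt.gbs == pytest.approx(c4p.chi_gbs25 * dn, rel=1e-12)
        assert pt.kmc == pytest.approx(c4p.k_mc25, rel=1e-12)
        assert pt.kmo_umol == pytest.approx(c4p.k_mo25 * 1000.0, rel=1e-12)
        assert pt.u_oc == pytest.approx(c4p.u_oc25, rel=1e-12)


def test_response_curve_table_shape():
    from photoroutes.leaf import response_curve_table

    routes = {rid: build_route(rid).params for rid in (0, 6, 9)}
    df = response_curve_table(routes, [0, 500, 1000, 1500])
    assert len(df) == 12
    assert set(df.columns) == {"route", "i_inc", "a", "gs", "ci", "cc", "limitation"}
    assert (df.groupby("route")["a"].max() > 0).all()
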