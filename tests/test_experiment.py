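"""Factorial orchestration, percent changes, trait regressions."""

import numpy as np
import pandas as pd
import pytest

from photoroutes.experiment import (
    ExperimentConfig,
    fit_mass_regression,
    fit_plue_regression,
    mean_over_years,
    percent_change_table,
    run_experiment,
    trait_decomposition,
    TRAITS,
)


@pytest.fixture(scope="module")
def mini_factorial():
    cfg = ExperimentConfig(sites=("tropical",), n_years=2,
                           route_ids=(0, 6), seed=5)
    return run_experiment(cfg)


class TestFactorial:
    def test_complete_row_count(self, mini_factorial):
        # 1 site x 2 climates x 2 water modes x 2 routes x 2 years
        assert len(mini_factorial) == 16
        counts = mini_factorial.groupby(["site", "climate", "water", "route"]).size()
        assert (counts == 2).all()

    def test_paired_weather_within_stratum(self, mini_factorial):
        """Route contrasts must be computed on identical weather: the
        weather checksum is constant within each (site, climate) stratum."""
        for _, grp in mini_factorial.groupby(["site", "climate"]):
            assert grp["weather_checksum"].nunique() == 1

    def test_deterministic_for_seed(self):
        cfg = ExperimentConfig(sites=("tropical",), climates=("present",),
                               water_modes=("potential",), n_years=1,
                               route_ids=(0,), seed=9)
        a = run_experiment(cfg)
        b = run_experiment(cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_empty_factor_rejected(self):
        with pytest.raises(ValueError):
            ExperimentConfig(route_ids=())


class TestPercentChange:
    def test_baseline_route_is_zero_everywhere(self, mini_factorial):
        pct = percent_change_table(mini_factorial)
        base = pct[pct["route"] == 0]
        for t in TRAITS:
            assert np.allclose(base[t], 0.0)

    def test_synthetic_fifty_percent_change(self):
        rows = []
        for route, scale in ((0, 1.0), (1, 1.5)):
            for year in (1, 2):
                rows.append({"site": "s", "climate": "present",
                             "water": "potential", "route": route,
                             "year": year, "days_to_flowering": 80,
                             "days_to_maturity": 110,
                             **{t: scale * (10.0 + i) for i, t in enumerate(TRAITS)}})
        pct = percent_change_table(pd.DataFrame(rows))
        r1 = pct[pct["route"] == 1].iloc[0]
        for t in TRAITS:
            assert r1[t] == pytest.approx(50.0)

    def test_means_taken_over_years_first(self):
        # years 10 and 30 vs baseline years 10 and 10: mean-first gives
        # 100*(20-10)/10 = 100%, not the mean of per-year changes (0%, 200%)
        rows = []
        for route, vals in ((0, (10.0, 10.0)), (1, (10.0, 30.0))):
            for year, v in enumerate(vals, start=1):
                rows.append({"site": "s", "climate": "present",
                             "water": "potential", "route": route,
                             "year": year, "days_to_flowering": 80,
                             "days_to_maturity": 110,
                             **{t: v for t in TRAITS}})
        pct = percent_change_table(pd.DataFrame(rows))
        assert pct[pct["route"] == 1].iloc[0]["shoot_mass"] == pytest.approx(100.0)


class TestDecomposition:
    def test_residual_small_on_simulated_output(self, mini_factorial):
        aug = trait_decomposition(mini_factorial)
        rel = (aug["mass_residual"].abs() / aug["shoot_mass"]).max()
        assert rel < 0.01

    def test_plue_perturbation_propagates_exactly(self, mini_factorial):
        from photoroutes.season import CH2O_PER_CO2

        aug = trait_decomposition(mini_factorial)
        row = aug.iloc[0]
        bumped = mini_factorial.iloc[[0]].copy()
        bumped["plue"] = bumped["plue"] * 1.1
        recon2 = trait_decomposition(bumped)["mass_reconstructed"].iloc[0]
        delta_expected = (0.1 * row["par_int"] * row["plue"] * CH2O_PER_CO2
                          * (1.0 - row["f_root"]))
        assert recon2 - row["mass_reconstructed"] == pytest.approx(delta_expected)


def _synthetic_trait_table(b, n_sites=3, n_routes=10, seed=0):
    """Noiseless trait table generated from a known coefficient vector."""
    rng = np.random.default_rng(seed)
    rows = []
    for si in range(n_sites):
        for route in range(n_routes):
            x = rng.uniform(0.5, 2.0, size=5)
            mass = b[0] + float(np.dot(b[1:], x))
            rows.append({"site": f"s{si}", "climate": "present",
                         "water": "potential", "route": route, "year": 1,
                         "days_to_flowering": 80, "days_to_maturity": 110,
                         "shoot_mass": mass, "a_canopy_s": 1.0,
                         "par_int": x[0], "plue": x[1], "resp": x[2],
                         "f_root": x[3], "senes": x[4],
                         "transpiration": 1.0, "wue": 1.0})
    return pd.DataFrame(rows)


class TestMassRegression:
    def test_exact_recovery_of_planted_coefficients(self):
        b = np.array([-1500.0, 4.5, 400.0, -0.5, -1000.0, -1.2])
        fits = fit_mass_regression(_synthetic_trait_table(b))
        fit = fits["potential"]
        assert fit.params["const"] == pytest.approx(b[0], abs=1e-8)
        for i, name in enumerate(["par_int", "plue", "resp", "f_root", "senes"]):
            assert fit.params[name] == pytest.approx(b[i + 1], abs=1e-8)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(3)
        df = _synthetic_trait_table(np.array([0.0, 1, 1, 1, 1, 1]), seed=4)
        df["shoot_mass"] = rng.normal(1000.0, 100.0, len(df))
        fit = fit_mass_regression(df)["potential"]
        x = np.column_stack([np.ones(len(df))]
                            + [df[c] for c in ("par_int", "plue", "resp",
                                               "f_root", "senes")])
        beta = np.linalg.solve(x.T @ x, x.T @ df["shoot_mass"].to_numpy())
        assert np.allclose(fit.params.to_numpy(), beta, atol=1e-8)

    def test_collinear_design_raises(self):
        df = _synthetic_trait_table(np.array([0.0, 1, 1, 1, 1, 1]))
        df["senes"] = 2.0 * df["par_int"]  # exact collinearity
        with pytest.raises(ValueError, match="rank"):
            fit_mass_regression(df)


class TestPlueRegression:
    def test_reference_site_dummy_coding(self, mini_factorial):
        cfg = ExperimentConfig(sites=("tropical", "subtropical"),
                               climates=("present",),
                               water_modes=("potential",),
                               route_ids=(4, 5, 6, 9), n_years=1, seed=5)
        df = run_experiment(cfg)
        fits = fit_plue_regression(df, reference_site="tropical")
        fit = fits[("potential", "present")]
        assert "site_tropical" not in fit.params.index
        assert "site_subtropical" in fit.params.index

    def test_noiseless_planted_coefficients_recovered(self):
        rows = []
        specs = {4: (0.125, 5.0, 200.0), 5: (0.007, 5.0, 100.0),
                 6: (0.007, 5.0, 200.0), 7: (0.125, 3.75, 100.0),
                 8: (0.007, 3.75, 100.0), 9: (0.007, 3.75, 200.0)}
        b = {"const": 12.0, "gbs": -12.0, "atp": -1.2, "jmax": 0.016}
        for site in ("tropical", "subtropical", "temperate"):
            for route, (gbs, atp, jmax) in specs.items():
                plue = (b["const"] + b["gbs"] * gbs + b["atp"] * atp
                        + b["jmax"] * jmax)
                rows.append({"site": site, "climate": "present",
                             "water": "potential", "route": route, "year": 1,
                             "days_to_flowering": 80, "days_to_maturity": 110,
                             "shoot_mass": 1.0, "a_canopy_s": 1.0,
                             "par_int": 1.0, "plue": plue, "resp": 1.0,
                             "f_root": 0.1, "senes": 1.0,
                             "transpiration": 1.0, "wue": 1.0})
        fits = fit_plue_regression(pd.DataFrame(rows))
        fit = fits[("potential", "present")]
        assert fit.params["const"] == pytest.approx(b["const"], abs=1e-8)
        assert fit.params["chi_gbs25"] == pytest.approx(b["gbs"], abs=1e-8)
        assert fit.params["atp_req"] == pytest.approx(b["atp"], abs=1e-8)
        assert fit.params["chi_jmax25"] == pytest.approx(b["jmax"], abs=1e-8)
        # planted model has no site effect: dummies must vanish
        assert fit.params["site_subtropical"] == pytest.approx(0.0, abs=1e-8)


def test_mean_over_years_shape(mini_factorial):
    m = mean_over_years(mini_factorial)
    assert len(m) == 8  # 2 climates x 2 water x 2 routes
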