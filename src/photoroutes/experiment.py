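"""Factorial scenario experiment and trait analysis.

Runs the full simulation factorial — sites x climates x water regimes x
routes x years — with paired weather (every route in a (site, climate)
stratum sees the identical daily series, so route contrasts are purely
parametric), and provides the summary analyses:

* percentage change of n-year mean traits relative to the default route,
* the shoot-mass decomposition (PAR_int x PLUE - RESP)(1 - F_root) - SENES,
* OLS regression of mean shoot mass on the five component traits,
* OLS regression of mean PLUE on the biochemical CCM descriptors
  (chi_gbs25, total ATP requirement per CO2, chi_Jmax25) with site
  covariates, over the C4-family routes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .routes import build_route
from .season import CH2O_PER_CO2, run_season
from .weather import (
    CO2_PRESENT,
    DEFAULT_SITES,
    SiteConfig,
    apply_climate_2050,
    generate_weather,
)

TRAITS = ("shoot_mass", "a_canopy_s", "par_int", "plue", "resp", "f_root",
          "senes", "transpiration", "wue")


@dataclass
class ExperimentConfig:
    """Factors of the scenario experiment."""

    sites: tuple = ("tropical", "subtropical", "temperate")
    climates: tuple = ("present", "2050")
    water_modes: tuple = ("potential", "limited")
    route_ids: tuple = tuple(range(10))
    n_years: int = 5
    seed: int = 1

    def __post_init__(self):
        for name in ("sites", "climates", "water_modes", "route_ids"):
            if not getattr(self, name):
                raise ValueError(f"experiment factor {name} is empty")


def run_experiment(config: ExperimentConfig,
                   site_objects: dict[str, SiteConfig] | None = None) -> pd.DataFrame:
    """Simulate every factorial cell; returns one row per
    (site, climate, water, route, year) with all season traits.

    Weather is generated once per (site, climate) stratum; the water-limited
    cell of a (site, year, climate, route) reuses the water cap derived from
    its own potential run, so each route's drought supply follows the
    50%-of-potential-transpiration rule.
    """
    rows = []
    for si, site_name in enumerate(config.sites):
        site = (site_objects or {}).get(site_name) or DEFAULT_SITES[site_name]()
        wx_base = generate_weather(site, config.n_years,
                                   seed=config.seed * 1000 + si)
        for climate in config.climates:
            if climate == "2050":
                wx, c_a = apply_climate_2050(wx_base)
            else:
                wx, c_a = wx_base, CO2_PRESENT
            checksum = float(np.round(wx["radiation_MJ"].sum()
                                      + wx["tmax_C"].sum(), 6))
            for year, wx_year in wx.groupby("year"):
                for rid in config.route_ids:
                    route = build_route(rid)
                    pot = run_season(wx_year, site, route.params, c_a=c_a)
                    cells = {"potential": pot}
                    if "limited" in config.water_modes:
                        supply = (0.5 * pot.transpiration
                                  / max(pot.days_to_maturity, 1))
                        cells["limited"] = run_season(
                            wx_year, site, route.params, c_a=c_a,
                            water_limited=True, water_supply=supply)
                    for water in config.water_modes:
                        r = cells[water]
                        row = {"site": site_name, "climate": climate,
                               "water": water, "route": rid,
                               "year": int(year),
                               "weather_checksum": checksum,
                               "days_to_flowering": r.days_to_flowering,
                               "days_to_maturity": r.days_to_maturity}
                        row.update({t: getattr(r, t) for t in TRAITS})
                        rows.append(row)
    df = pd.DataFrame(rows)
    expected = (len(config.sites) * len(config.climates)
                * len(config.water_modes) * len(config.route_ids)
                * config.n_years)
    if len(df) != expected:
        raise RuntimeError(f"factorial incomplete: {len(df)} rows, "
                           f"expected {expected}")
    return df


def mean_over_years(traits: pd.DataFrame) -> pd.DataFrame:
    """n-year mean of every trait per (site, climate, water, route)."""
    cols = list(TRAITS) + ["days_to_flowering", "days_to_maturity"]
    return (traits.groupby(["site", "climate", "water", "route"])[cols]
            .mean().reset_index())


def percent_change_table(traits: pd.DataFrame, baseline_route: int = 0) -> pd.DataFrame:
    """Percentage change of the n-year mean of each trait for each route
    relative to the baseline route, per (site, climate, water) stratum.

    Means are taken over years first; strata whose baseline mean is zero
    are flagged with NaN.
    """
    means = mean_over_years(traits)
    strata = ["site", "climate", "water"]
    base = means[means["route"] == baseline_route]
    if base.empty:
        raise ValueError("baseline route absent from the trait table")
    base = base.set_index(strata)
    out = []
    for key, grp in means.groupby(strata):
        b = base.loc[key]
        for _, row in grp.iterrows():
            rec = dict(zip(strata, key))
            rec["route"] = int(row["route"])
            for t in TRAITS:
                denom = b[t]
                rec[t] = (100.0 * (row[t] - denom) / denom
                          if abs(denom) > 1.0e-12 else float("nan"))
            out.append(rec)
    return pd.DataFrame(out)


def trait_decomposition(traits: pd.DataFrame) -> pd.DataFrame:
    """Add the reconstructed shoot mass
    ``(PAR_int x PLUE - RESP) * 30/44 * (1 - F_root) - SENES`` and its
    residual against the simulated mass."""
    out = traits.copy()
    gross_dm = (out["par_int"] * out["plue"] - out["resp"]) * CH2O_PER_CO2
    out["mass_reconstructed"] = gross_dm * (1.0 - out["f_root"]) - out["senes"]
    out["mass_residual"] = out["shoot_mass"] - out["mass_reconstructed"]
    return out


_MASS_REGRESSORS = ["par_int", "plue", "resp", "f_root", "senes"]


def _check_rank(x: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        cond = np.linalg.cond(x)
        raise ValueError(f"rank-deficient design (rank {rank} of "
                         f"{x.shape[1]}, cond {cond:.2e}); columns: {names}")


@dataclass
class RegressionResult:
    params: pd.Series
    pvalues: pd.Series
    r_squared: float
    n_obs: int
    condition_number: float = float("nan")


def fit_mass_regression(traits: pd.DataFrame) -> dict[str, RegressionResult]:
    """OLS of n-year mean shoot mass on the five component traits, fitted
    for the potential stratum, the water-limited stratum, and pooled."""
    means = mean_over_years(traits)
    results = {}
    for label, sub in (("potential", means[means["water"] == "potential"]),
                       ("limited", means[means["water"] == "limited"]),
                       ("pooled", means)):
        if len(sub) < len(_MASS_REGRESSORS) + 2:
            continue
        x = sm.add_constant(sub[_MASS_REGRESSORS])
        _check_rank(np.asarray(x, dtype=float), list(x.columns))
        fit = sm.OLS(sub["shoot_mass"], x).fit()
        results[label] = RegressionResult(
            params=fit.params, pvalues=fit.pvalues,
            r_squared=fit.rsquared, n_obs=int(fit.nobs),
            condition_number=float(fit.condition_number))
    return results


C4_FAMILY_ROUTES = (4, 5, 6, 7, 8, 9)


def fit_plue_regression(traits: pd.DataFrame, reference_site: str = "tropical",
                        routes: tuple = C4_FAMILY_ROUTES) -> dict[tuple, RegressionResult]:
    """OLS of n-year mean PLUE on (site dummies, chi_gbs25, ATP_req,
    chi_Jmax25) over the C4-family routes, per (water, climate) stratum.

    The reference site carries a zero coefficient (dummy coding).
    """
    specs = {rid: build_route(rid) for rid in routes}
    means = mean_over_years(traits)
    means = means[means["route"].isin(routes)].copy()
    means["chi_gbs25"] = means["route"].map(lambda r: specs[r].chi_gbs25)
    means["atp_req"] = means["route"].map(lambda r: specs[r].atp_req)
    means["chi_jmax25"] = means["route"].map(lambda r: specs[r].chi_jmax25)
    site_dummies = pd.get_dummies(means["site"], prefix="site", dtype=float)
    ref_col = f"site_{reference_site}"
    if ref_col in site_dummies:
        site_dummies = site_dummies.drop(columns=ref_col)
    means = pd.concat([means, site_dummies], axis=1)
    regressors = list(site_dummies.columns) + ["chi_gbs25", "atp_req", "chi_jmax25"]

    results = {}
    for (water, climate), sub in means.groupby(["water", "climate"]):
        x = sm.add_constant(sub[regressors])
        _check_rank(np.asarray(x, dtype=float), list(x.columns))
        fit = sm.OLS(sub["plue"], x).fit()
        results[(water, climate)] = RegressionResult(
            params=fit.params, pvalues=fit.pvalues,
            r_squared=fit.rsquared, n_obs=int(fit.nobs),
            condition_number=float(fit.condition_number))
    return results
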