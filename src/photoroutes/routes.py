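"""Registry of the ten leaf-model configurations compared in the study.

Route 0 is the unmodified C3 rice leaf; Routes 1-9 are engineering targets:

1. tripled mesophyll-conductance slope (chi_gm25 0.125 -> 0.375)
2. red-algal Rubisco specificity (S_c/o25 3022 -> 4427)
3. both 1 and 2
4. C4 biochemistry without an effective sheath (chi_gbs25 = 0.125)
5. effective Kranz anatomy with C3 enzymes (chi_gbs25 = 0.007)
6. the complete C4 mechanism
7. cyanobacterial bicarbonate transporters only (leaky envelope, phi = 0.75)
8. carboxysome-based CCM (tight envelope, chi_gbs25 = 0.007)
9. complete cyanobacterial CCM with C4-level capacity slopes
   (chi_Vcmax25 = 93, chi_Jmax25 = 200)
"""

from __future__ import annotations

from dataclasses import dataclass, field

from scipy.optimize import brentq

from .leaf import make_ccm_params, z_factor
from .params import C3, PhotoParams, c3_defaults, c4_defaults

CALVIN_ATP_PER_CO2 = 3.0

#: ATP per transport event of the two characterized single-gene
#: bicarbonate transporters; their sum is the CCM cost phi = 0.75.
BICA_ATP = 0.25
SBTA_ATP = 0.50

ROUTE_LABELS = {
    0: "default C3",
    1: "improved g_m",
    2: "improved S_c/o",
    3: "improved g_m + S_c/o",
    4: "C4 biochemistry",
    5: "C4 Kranz anatomy",
    6: "complete C4",
    7: "bicarbonate transporters",
    8: "elaborate cyanobacterial CCM",
    9: "complete cyanobacterial CCM",
}


def x_from_phi(phi: float) -> float:
    """ATP fraction routed to the CCM: ``phi / (3 + phi)`` (3 = Calvin-cycle
    ATP per CO2)."""
    if phi < 0:
        raise ValueError("phi must be >= 0")
    return phi / (CALVIN_ATP_PER_CO2 + phi)


def atp_requirement(phi: float) -> float:
    """Total ATP needed per CO2 assimilated: ``3 + phi``."""
    if phi < 0:
        raise ValueError("phi must be >= 0")
    return CALVIN_ATP_PER_CO2 + phi


def bicarbonate_transporter_atp() -> float:
    """Combined ATP cost per CO2 of the BicA + SbtA transporter pair."""
    return BICA_ATP + SBTA_ATP


@dataclass
class RouteSpec:
    """One model configuration: family, label and the parameter overrides it
    applies on top of the family defaults."""

    route_id: int
    model_family: str
    label: str
    overrides: dict = field(default_factory=dict)
    params: PhotoParams = field(default_factory=c3_defaults)

    @property
    def chi_gbs25(self) -> float:
        return self.params.chi_gbs25

    @property
    def chi_jmax25(self) -> float:
        return self.params.chi_jmax25

    @property
    def atp_req(self) -> float:
        """Total ATP per CO2 (3 for plain C3, 3 + phi with a CCM)."""
        if self.model_family == C3:
            return CALVIN_ATP_PER_CO2
        return atp_requirement(self.params.phi_ccm)

    def to_dict(self) -> dict:
        return {"route_id": self.route_id, "model_family": self.model_family,
                "label": self.label, "overrides": dict(self.overrides)}


# C3 temperature constants that travel with the C3 enzyme kinetics when a
# C4-structure route keeps "C3 enzymatic parameters" (Route 5).
_C3_ENZYME_BLOCK = {
    "s_co25": 3022.0, "e_gamma": 24460.0,
    "k_mc25": 291.0, "e_kmc": 80990.0,
    "k_mo25": 194.0, "e_kmo": 23720.0,
    "chi_vcmax25": 75.0, "e_vcmax": 65330.0,
    "chi_jmax25": 100.0, "e_jmax": 88380.0, "d_jmax": 200000.0, "s_jmax": 650.0,
    "e_rd": 46390.0,
    "t_opt": 23.0, "omega": 36.8,
}


def build_route(route_id: int) -> RouteSpec:
    """Construct the exact parameter set of one route."""
    if route_id == 0:
        return RouteSpec(0, C3, ROUTE_LABELS[0], {}, c3_defaults())
    if route_id == 1:
        ov = {"chi_gm25": 0.375}
    elif route_id == 2:
        ov = {"s_co25": 4427.0}
    elif route_id == 3:
        ov = {"chi_gm25": 0.375, "s_co25": 4427.0}
    elif route_id == 4:
        p = c4_defaults().replace(chi_gbs25=0.125)
        return RouteSpec(4, p.model_family, ROUTE_LABELS[4],
                         {"chi_gbs25": 0.125}, p)
    elif route_id == 5:
        ov = dict(_C3_ENZYME_BLOCK, chi_gbs25=0.007)
        p = c4_defaults().replace(**ov)
        return RouteSpec(5, p.model_family, ROUTE_LABELS[5], ov, p)
    elif route_id == 6:
        return RouteSpec(6, "C4", ROUTE_LABELS[6], {}, c4_defaults())
    elif route_id == 7:
        p = make_ccm_params(c3_defaults(), elaborate=False)
        return RouteSpec(7, p.model_family, ROUTE_LABELS[7],
                         {"chi_gbs25": 0.125, "phi_ccm": 0.75, "x_atp": 0.2,
                          "f_cyc": 0.18, "rm_factor": 1.0}, p)
    elif route_id == 8:
        p = make_ccm_params(c3_defaults(), elaborate=True)
        return RouteSpec(8, p.model_family, ROUTE_LABELS[8],
                         {"chi_gbs25": 0.007, "phi_ccm": 0.75, "x_atp": 0.2,
                          "f_cyc": 0.18, "rm_factor": 1.0}, p)
    elif route_id == 9:
        p = make_ccm_params(c3_defaults(), elaborate=True, c4_capacity=True)
        return RouteSpec(9, p.model_family, ROUTE_LABELS[9],
                         {"chi_gbs25": 0.007, "phi_ccm": 0.75, "x_atp": 0.2,
                          "f_cyc": 0.18, "rm_factor": 1.0,
                          "chi_vcmax25": 93.0, "chi_jmax25": 200.0}, p)
    else:
        raise ValueError(f"unknown route id {route_id!r}")
    p = c3_defaults().replace(**ov)
    return RouteSpec(route_id, C3, ROUTE_LABELS[route_id], ov, p)


def all_routes() -> list[RouteSpec]:
    return [build_route(i) for i in range(10)]


def _balanced_f_cyc(phi: float, f_pseudo: float, f_q: float, h: float) -> float:
    """Cyclic-flow fraction at which ATP and NADPH supply match demand.

    Demand ratio per CO2 is (3 + phi) ATP : 2 NADPH; supply ratio is
    ``2 z / (1 - f_pseudo / (1 - f_cyc))`` with z the ATP yield of J2.
    """
    target = atp_requirement(phi) / 2.0

    def gap(f_cyc: float) -> float:
        supply = 2.0 * z_factor(f_q, f_cyc, h) / (1.0 - f_pseudo / (1.0 - f_cyc))
        return supply - target

    return brentq(gap, 1.0e-6, 0.75, xtol=1.0e-10)


def atp_cost_sweep(route9: RouteSpec, phi_values, rebalance_f_cyc: bool = False) -> list[RouteSpec]:
    """Variants of the complete cyanobacterial-CCM route across CCM ATP
    costs (phi); x is recomputed as phi/(3+phi) and, optionally, f_cyc is
    re-solved for a balanced NADPH:ATP budget."""
    out = []
    for phi in phi_values:
        ov = {"phi_ccm": float(phi), "x_atp": x_from_phi(phi)}
        if rebalance_f_cyc:
            ov["f_cyc"] = _balanced_f_cyc(phi, route9.params.f_pseudo,
                                          route9.params.f_q, route9.params.h)
        p = route9.params.replace(**ov)
        out.append(RouteSpec(route9.route_id, route9.model_family,
                             f"{route9.label} (phi={phi:g})",
                             dict(route9.overrides, **ov), p))
    return out
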