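"""Parameter sets for the biochemical leaf photosynthesis models.

Holds every input of the C3 (FvCB), C4 (von Caemmerer-type with explicit
bundle-sheath leakage) and cyanobacterial-CCM leaf models: electron-transport
fractions, Rubisco kinetics, nitrogen slopes of capacities and conductances,
stomatal-response constants, and the Arrhenius / peaked-Arrhenius temperature
constants of each temperature-dependent quantity.

Units follow the mole-fraction convention throughout: CO2 in umol mol-1,
O2 in mmol mol-1, conductances in mol m-2 s-1, leaf nitrogen in g N m-2.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass


C3 = "C3"
C4 = "C4"
CCM = "CCM"


@dataclass
class PhotoParams:
    """One complete leaf-model parameterization.

    ``model_family`` selects the solver: "C3" uses the mesophyll-conductance
    diffusion chain; "C4" and "CCM" use the PEP-carboxylation /
    bicarbonate-transport model with bundle-sheath (or chloroplast-envelope)
    conductance.  Fields that a family does not use are ignored by its solver.
    """

    model_family: str = C3

    # electron transport
    phi2ll: float = 0.78        # quantum efficiency of PSII e- transport, limiting light, at T_opt (mol mol-1)
    r2_1: float = 0.85          # ratio of PSII to PSI limiting-light quantum efficiency (-)
    theta: float = 0.8          # convexity of the J2 light response (-)
    f_cyc: float = 0.05         # fraction of PSI e- flux that is cyclic (-)
    f_pseudo: float = 0.10      # fraction of PSI e- flux that is pseudocyclic (-)
    f_q: float = 1.0            # fraction of plastoquinone e- flux through the Q-cycle (-) [C4/CCM]
    h: float = 4.0              # H+ per ATP (mol mol-1) [C4/CCM]
    t_opt: float = 23.0         # optimum temperature of phi2ll (degC)
    omega: float = 36.8         # width of the phi2ll temperature response (degC)

    # CCM energetics [C4/CCM]
    alpha_bs: float = 0.0       # fraction of O2 evolution in the bundle sheath (-)
    x_atp: float = 0.0          # fraction of ATP partitioned to the CCM (-)
    phi_ccm: float = 0.0        # extra ATP per CO2 fixed spent on the CCM (mol mol-1)

    # Rubisco kinetics
    s_co25: float = 3022.0      # relative CO2/O2 specificity at 25 degC (mol mol-1)
    k_mc25: float = 291.0       # Km for CO2 at 25 degC (umol mol-1)
    k_mo25: float = 194.0       # Km for O2 at 25 degC (mmol mol-1)

    # nitrogen slopes of capacities (per (n - n_b), Eq-16-type scaling)
    chi_vcmax25: float = 75.0   # umol s-1 g-1 N
    chi_jmax25: float = 100.0   # umol s-1 g-1 N
    chi_epsp25: float = 0.0     # PEP carboxylation efficiency slope (mol s-1 g-1 N) [C4/CCM]

    # respiration
    rd25_factor: float = 0.01   # Rd25 as a fraction of Vcmax25 (-)
    rm_factor: float = 0.0      # mesophyll respiration Rm as a fraction of Rd (-) [C4/CCM]

    # CO2 diffusion and stomata
    g0: float = 0.01            # residual stomatal conductance (mol m-2 s-1)
    a1: float = 0.9             # Ci:Ca at saturating humidity (-)
    b1: float = 0.15            # VPD slope of the Ci:Ca ratio (kPa-1)
    chi_gm25: float = 0.125     # mesophyll conductance N slope (mol s-1 g-1 N) [C3]
    chi_gbs25: float = 0.0      # bundle-sheath conductance N slope (mol s-1 g-1 N) [C4/CCM]
    u_oc25: float = 0.047       # lumped CO2/O2 diffusivity-solubility ratio (-) [C4/CCM]

    # temperature-response constants (J mol-1; entropy terms J K-1 mol-1)
    e_gamma: float = 24460.0
    e_vcmax: float = 65330.0
    e_kmc: float = 80990.0
    e_kmo: float = 23720.0
    e_rd: float = 46390.0
    e_jmax: float = 88380.0
    d_jmax: float = 200000.0
    s_jmax: float = 650.0
    e_epsp: float = 0.0
    d_epsp: float = 1.0
    s_epsp: float = 0.0
    e_gm: float = 49600.0
    d_gm: float = 437400.0
    s_gm: float = 1400.0
    e_gbs: float = 0.0
    d_gbs: float = 1.0
    s_gbs: float = 0.0
    e_uoc: float = 0.0

    # base leaf nitrogen, below which photosynthesis is zero
    n_b: float = 0.3            # g N m-2

    # printed grouping of the Cs* numerator uses (-Rd + Rm); the alternative
    # reading groups it as -(Rd - Rm).  Both coincide for Rm = Rd.
    cs_star_grouping: str = "as_printed"

    @property
    def gamma_star25(self) -> float:
        """Half the reciprocal of Rubisco specificity (mol CO2 per mol O2)."""
        return 0.5 / self.s_co25

    def replace(self, **kwargs) -> "PhotoParams":
        return dataclasses.replace(self, **kwargs)

    def validate(self) -> None:
        for name in ("phi2ll", "f_cyc", "f_pseudo", "theta", "x_atp", "alpha_bs"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.f_cyc + self.f_pseudo >= 1.0:
            raise ValueError("f_cyc + f_pseudo must be < 1")
        if self.s_co25 <= 0:
            raise ValueError("s_co25 must be positive")
        if not self.theta > 0:
            raise ValueError("theta must be in (0, 1]")
        if self.phi_ccm < 0:
            raise ValueError("phi_ccm must be >= 0")
        for name in ("chi_vcmax25", "chi_jmax25", "chi_epsp25", "chi_gm25", "chi_gbs25"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def c3_defaults() -> PhotoParams:
    """Default C3 (rice) parameter set."""
    return PhotoParams(model_family=C3)


def c4_defaults() -> PhotoParams:
    """Default C4 (maize/sorghum NADP-ME type) parameter set."""
    return PhotoParams(
        model_family=C4,
        f_cyc=0.45,
        f_pseudo=0.05,
        f_q=1.0,
        h=4.0,
        t_opt=34.0,
        omega=38.4,
        alpha_bs=0.1,
        x_atp=0.4,
        phi_ccm=2.0,
        s_co25=2862.0,
        k_mc25=485.0,
        k_mo25=146.0,
        chi_vcmax25=93.0,
        chi_jmax25=200.0,
        chi_epsp25=0.791,
        rm_factor=0.5,
        chi_gm25=0.0,
        chi_gbs25=0.007,
        u_oc25=0.047,
        e_gamma=27417.0,
        e_vcmax=53400.0,
        e_kmc=35600.0,
        e_kmo=15100.0,
        e_rd=41853.0,
        e_jmax=116439.0,
        d_jmax=135982.0,
        s_jmax=458.7,
        e_epsp=51029.0,
        d_epsp=130363.0,
        s_epsp=425.6,
        e_gm=0.0,
        d_gm=1.0,
        s_gm=0.0,
        e_gbs=116767.0,
        d_gbs=264604.0,
        s_gbs=860.0,
        e_uoc=-1630.0,
    )
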