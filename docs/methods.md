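# Methods

This note documents the models, the numerical choices, and the decisions
taken where the design was genuinely open. Units follow one convention
throughout: CO2 as μmol mol⁻¹ and O2 as mmol mol⁻¹ mole fractions (never
partial pressures), conductances in mol m⁻² s⁻¹, leaf nitrogen in g N m⁻²,
fluxes in μmol CO2 m⁻² s⁻¹ at the leaf and g CO2 m⁻² d⁻¹ at the canopy.

## Leaf models

All three families share the response functions in `leaf.py`:

* Arrhenius scaling normalized to 25 °C for R_d, γ\*, V_cmax, K_mC, K_mO
  and u_oc; the peaked (deactivation/entropy) form for J_max, ε_p, g_m and
  g_bs, evaluated in log space so large S·298/R cannot overflow.
* PSII electron transport J₂: non-rectangular hyperbola (convexity
  θ = 0.8) between α_2LL·I_abs and J_max, with
  α_2LL = Φ_2LL(1 − f_cyc)/(1 − f_cyc + r_2/1); Φ_2LL carries a Gaussian
  temperature factor that is 1 at T_opt and 1/e at T_opt ± Ω. θ = 0 is
  handled as the product-over-sum limit.
* Stomatal humidity response f_vpd = 1/(1/max(a₁ − b₁·VPD, 0.01) − 1); the
  printed clamp at 0.01 guarantees definedness at any VPD.
* Capacities at 25 °C scale as χ·max(n − n_b, 0); at or below the base
  nitrogen n_b = 0.3 g m⁻² every capacity (including R_d, which is
  0.01·V_cmax25 of the route's own χ_Vcmax25) is zero and the leaf returns
  A = −R_d = 0 at g_s = g₀.

**C3.** A = min over the Rubisco- and e⁻-transport-limited branches;
C_i\* in the stomatal equation is computed as Γ\* − R_d/g_m, which is the
intercellular CO2 at which A + R_d = 0 once the mesophyll drawdown is
accounted for. **C4/CCM.** The Cs-based stomatal form is used with C_s\*
as printed, numerator g_bs·γ\*·O_i − (1 + γ\*α/u_oc)·R_d + R_m; because the
printed sign grouping is ambiguous, `PhotoParams.cs_star_grouping =
"rd_minus_rm"` switches to the −(R_d − R_m) reading (for R_m = R_d/2 the
two differ by well under 2 % in A; for the CCM routes R_m = R_d and they
coincide up to the standalone +R_m term). Bundle-sheath O2 is
O = O_i + αA/(u_oc·g_bs) and ambient O_i defaults to 210 mmol mol⁻¹ (the
standard atmospheric value; the sources leave it unstated).

**Solver.** Each limitation branch (and for C4, each V_p branch) reduces to
one scalar equation in A: the stomatal/diffusion chain gives (g_s, C_i,
C_c) explicitly — for C3 via the positive root of a quadratic in g_s — and
the residual A − rate(C_c) is solved with a guarded Brent root-find
(xtol 1e-10). Guards return a large positive residual when a trial A is
infeasible (C_s below the compensation point, or the rate hyperbola's pole
crossed), which keeps the bracket valid. A = min over consistent branches;
for V_p the PEP-carboxylase branch is accepted only if ε_p·C_i does not
exceed the ATP-limited cap at the solution, else the ATP branch is used.
The test suite holds an independent oracle (bisection on a single monotone
residual with the minima taken inside, inner bisection for g_s) and the
solvers agree with it to |ΔA| < 1e-6 over 1000 random environments.

The two stomatal submodels (Ci-based for C3, Cs-based for C4/CCM) are
different empirical forms; with an open envelope and zero CCM cost the
CCM biochemistry reproduces the C3 model to < 2 % at a common prescribed
g_s, but the coupled solutions can differ by ~5 % in dim light. This is a
property of the printed equations, not a solver artifact.

## Routes

Route 0 is the C3 default column; routes 1–9 override exactly the named
parameters. Choices where the table rows are terse:

* Route 4 uses the maize capacity slopes (χ_Vcmax25 = 93, χ_Jmax25 = 200)
  to represent the full C4 biochemistry package.
* Route 5 ("C3 enzymes in a working Kranz anatomy") keeps the C3 enzyme
  kinetics together with their C3 temperature constants (S_c/o, K_mC,
  K_mO, χ_Vcmax, χ_Jmax, E/D/S of each, E_Rd, and the C3 Φ_2LL optimum),
  while the C4 energetics block (f_cyc = 0.45, f_Q, h, x, φ, α, ε_p, g_bs,
  u_oc, R_m) is retained because the C4 cycle needs it to run.
* CCM routes 7–9 are built from the C3 defaults plus the C4-only machinery
  (ε_p, g_bs, u_oc, f_Q, h, α with their C4 temperature constants) with
  φ = 0.75, x = 0.2, f_cyc = 0.18, R_m = R_d; χ_gbs25 = 0.125 for the
  leaky-envelope route 7 and 0.007 for routes 8–9; route 9 adds the C4
  capacity slopes but keeps the C3 J_max temperature response (only the
  stated overrides change).
* The ATP-cost sweep recomputes x = φ/(3+φ) and can optionally re-solve
  f_cyc from the supply/demand balance
  2z/(1 − f_pseudo/(1 − f_cyc)) = (3+φ)/2 (with h = 4 this reproduces
  f_cyc ≈ 0.44 at the C4 cost, near the C4 default 0.45); the published
  0.18 at φ = 0.75 is taken as a constant, not re-derived.

## Energy balance and water limitation

Leaf temperature solves the linearized Penman–Monteith budget:
λE = (s·r_bh·R_n + ρc_p·VPD)/(γ(r_bw + r_sw) + s·r_bh),
T_l = T_air + (R_n − λE)r_bh/ρc_p, so the energy budget closes by
construction. Boundary-layer resistances use the flat-plate relation
r_bh = 100·√(d/u) with leaf width d = 0.01 m and r_bw = 0.93·r_bh; the
water-vapour stomatal resistance is 1/(1.6·g_s) with mol↔velocity
conversion at 41 mol m⁻³; net radiation is absorbed shortwave minus an
isothermal Brunt-type longwave loss (emissivity 0.96). The T_l fixed point
iterates to |ΔT_l| < 0.01 °C (damping 0.5 engages after the plain
iterations; hard failure after 200) — tolerances are this package's
choices, the sources state none. Night/negative transpiration is floored
at 1e-6 mm h⁻¹ before the actual-resistance transform to avoid division by
zero.

## Canopy

Beam extinction follows the Goudriaan projection of a fixed 65° leaf
inclination; diffuse extinction integrates the beam coefficient over three
sky sectors (15/45/75°, weights 0.178/0.514/0.308); scattering 0.2 for
PAR; canopy reflection 1 − exp(−2ρ_h k_b/(1+k_b)). The nitrogen extinction
coefficient is set equal to the scattering-adjusted diffuse-light
extinction, so leaf N tracks the long-term light profile. Sunlit LAI is
(1 − e^(−k_b L))/k_b and per-class absorbed PAR uses the standard
direct/diffuse/scattered decomposition; conservation (sunlit + shaded =
total) holds by construction.

Each big leaf's flux is evaluated by a 3-node Gauss–Legendre quadrature
over canopy depth with local absorbed light and local leaf N per node and
a single leaf temperature per class. A plain two-big-leaf lumping
overestimates a 100-layer reference by 6–14 % (saturation is concave in
light), the depth-quadrature form stays within ~4 % (C3) and ~2 %
(C4/CCM); the 100-layer model remains a test oracle only.

Daily integration uses 5-point Gauss–Legendre over the photoperiod (the
original model family uses Gaussian integration without printing the
order; 5 was chosen and is recorded here). Diurnal radiation is
proportional to sinβ(1 + 0.4 sinβ) and normalized through the same
quadrature so the daily energy integral closes exactly; diurnal
temperature is a sinusoid from t_min at dawn peaking 1.5 h after noon,
declining linearly overnight back to t_min. The diffuse fraction comes
from a Spitters-type transmissivity relation (floored at 0.15) in
weather-driven runs and is fixed at 0.2 in grid-reproduction mode, which
also prescribes T_l = 25 °C and a 13-h photoperiod (latitude 26.4°,
day 122, declination ≈ 15°).

Water-limited days: the day's allowance follows the diurnal radiation
course, is split between classes in proportion to potential transpiration,
converted per class to an actual stomatal resistance, and the actual
assimilation is re-solved at the proportionally scaled node conductances
and the potential-run leaf temperature (drought re-warming of the leaf is
not fed back within the day).

Known behaviour: the route/default daily-canopy ratio rises with radiation
and falls with LAI for all C4-family routes (4–9); the C3 routes do not
all share this pattern (improved Rubisco specificity helps relatively most
in dim, light-limited canopies, so route 2's ratio falls with radiation) —
a direct consequence of where each mechanism acts on the light response.

## Season simulator

The crop module is deliberately simplified ("GECROS-lite"): phenology, N
supply and water supply are prescribed, and the mechanisms that feed
photosynthesis back into canopy dynamics are kept. Module constants not
fixed by the source tables are collected at the top of `season.py`:

| constant | value | role |
|---|---|---|
| Y_G | 0.75 | growth efficiency (g structural CH2O per g CH2O) |
| c_m | 0.015 g CH2O g⁻¹ N d⁻¹ | maintenance coefficient at 25 °C, Q10 = 2 |
| CH2O:CO2 | 30/44 | carbon bookkeeping conversion |
| leaf fraction | 0.70 − 0.50·stage | leaf share of shoot growth |
| leaf-N fraction | 0.62 − 0.25·stage (≥ 0.10) | leaf share of N uptake; roots 0.12 |
| F_root | 0.30·e^(−1.2·stage), ×(0.5 + 1.5·imbalance), clamped [0.05, 0.6] | root partitioning with functional-equilibrium response |
| initial pools | 1.5/0.5/0.8 g DM leaf/stem/root | seedling at emergence |

Thermal days use the beta response
((T_c − T)/(T_c − T_o))·((T − T_b)/(T_o − T_b))^((T_o−T_b)/(T_c−T_o)) with
T_b/T_o/T_c = 8/30/42 °C, integrated over the diurnal course; one day at
T_o accrues exactly 1. Development advances by increment/m_V before
flowering and increment/m_R after; drought does not alter phenology. N
uptake follows a beta-sigmoid of stage (inflection at flowering) reaching
exactly 20 g N m⁻² at maturity. The carbon-determined LAI accrues
S_la·(new leaf mass) with S_la = 0.03 m² g⁻¹; the nitrogen-determined LAI
is (1/k_N)·ln(1 + k_N·N_leaf/n_b) (the logarithmic form reproduces the
N-limited canopy behaviour of the parent model, which cites but does not
print it); when LAI_C exceeds LAI_N the excess senesces with time constant
2 d, the dead mass accumulating into SENES and carrying N at the base
concentration. Deficit days (assimilate below maintenance) draw on stem
reserves with no growth respiration, which keeps the carbon balance exact.

Bookkeeping identities — shoot = (PAR_int×PLUE − RESP)·(30/44)·(1 − F_root)
− SENES and the crop carbon balance — close to well under 1 % on every
completed season (the only residual is the 2.8 g seedling).

Water-limited seasons cap the daily supply at 0.5 × the seasonal mean
daily potential transpiration computed from a potential run on the same
weather and route, mirroring the study's 50 % rule (their caps: 1.97,
1.63, 1.34 mm d⁻¹ for the three sites with the real weather).

Stored but unused: plant height and grain parameters (grain formation is
out of scope; shoot mass excluding dead leaves is the productivity proxy).

## Synthetic weather

Each archetype is a seasonal temperature sinusoid plus AR(1) daily
anomalies (coefficient 0.6, innovation SD 1.6 °C — constants chosen as
typical mid-latitude day-to-day persistence, not fitted to any record),
radiation as a clipped-Gaussian clearness index times extraterrestrial
radiation from standard solar geometry, vapour pressure from a mean
relative humidity capped near saturation at t_min, and Gaussian wind. The
archetypes use the latitudes and crop calendars of the three study
regions (14.1/32.9/39.7 °N; emergence days 10/145/125; thermal-day
requirements 70+28, 85+32, 48+22) and climatologies chosen from public
normals for those regions. The 2050 transform adds exactly +2.0 °C to both
temperature extremes, sets CO2 to 550 μmol mol⁻¹, and rescales vapour
pressure along the saturation curve so relative humidity is preserved
(documented choice; radiation and wind untouched).

What the generator does not emulate: real interannual variability
structure, monsoon cloud seasonality, typhoons/heat waves, and any
rainfall process (irrelevant here because water limitation is a fixed
fraction of simulated potential transpiration). Passing tests on this
weather therefore demonstrate internal consistency and directional
behaviour, not agreement with any station record.

## Experiment and analysis

The factorial runs every (site, climate, water, route, year) cell with
paired weather — identical daily series within a (site, climate) stratum —
so route contrasts are purely parametric. Percent changes are computed on
n-year means (means first, then the ratio). The mass regression is OLS of
mean shoot mass on PAR_int, PLUE, RESP, F_root and SENES per production
stratum; the PLUE regression is OLS on site dummies (tropical reference),
χ_gbs25, ATP_req = 3+φ and χ_Jmax25 over the six C4-family routes.
Probabilities are plain t-tests; no multiple-testing correction is
applied. Rank-deficient designs raise an error naming the columns and the
condition number is reported (mass and SENES are nearly collinear in
simulated data, as in the source analysis; exact significance values are
not reproduced).

Default problem sizes: the shipped factorial uses 5 weather years per
site (600 seasonal simulations), which resolves all the directional
contrasts; single analyses use 1–3 years. These sizes are the package's
defaults, chosen so a full factorial completes in minutes on one core.

## Known limitations

* Absolute seasonal masses and their tabulated changes depend on the real
  1980–2010 station weather and the full parent crop model (soil coupling,
  reserve dynamics, leaf-N redistribution) and are not reproduced; only
  identities, orderings and directions are asserted.
* Photoperiod sensitivity is out of scope. In the parent model it delays
  temperate-site flowering into the cool autumn; without it the simulated
  temperate season is ~10 days shorter and the +2 °C shortening of the
  temperate site (~16 d) no longer clearly exceeds the subtropical one
  (~16 d) — the published gradient is 20 vs 10 d. The shortening itself
  and the tropical minimum are reproduced.
* The sun/shade model with depth quadrature still sits ~4 % above the
  multilayer reference for C3 canopies at high LAI.
* Within-day drought feedback on leaf temperature is not iterated, and
  class-level g₀ is not scaled with LAI.
* Stem/reserve nitrogen is pooled with documented simplifications; the
  parent model's leaf-N vertical redistribution is represented only
  through the exponential profile assumption.
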