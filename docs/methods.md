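# Methods

`floodplume` simulates a sediment-laden river flood entering a
salt-stratified, microtidal bay on a two-dimensional vertical slice
(x–z) along the plume axis, and analyses how the suspended sediment
load and grain size flip the plume between hypopycnal (buoyant,
surface-trapped) and hyperpycnal/homopycnal (sinking or vertically
mixing) regimes, relative to a reference simulation without sediment
(WOS).  This note documents the model, the synthetic study conditions,
the numerical choices, and the limits of what the scaled configuration
can show.

## Dynamical core

The slice is incompressible Boussinesq under a rigid lid.  Prognostic
fields on an Arakawa-C staggered grid: along-slice velocity u (x-faces),
vertical velocity w (z-faces), and cell-centred temperature T, salinity
S, suspended sediment C, and the four nitrogen pools N, P, Z, D.  An
optional transverse velocity v with constant Coriolis parameter f gives
a 2.5-D rotation mode; the default is f = 0 because the regime physics
(plunging, estuarine exchange, vertical mixing) is vertical-plane
dynamics.

Density couples sediment to the flow through

    rho = rho_w(T, S) + (1 − rho_w/rho_sed) · C,
    rho_w = rho0 (1 − alpha (T − T0) + beta (S − S0)),

with rho0 = 1025 kg/m³, alpha = 2.0e-4 /°C, beta = 7.8e-4 /psu and
grain density rho_sed = 2650 kg/m³.  The linear EOS keeps the
hyperpycnal threshold analytically invertible: river water (S = 0,
temperature T_riv) matches ambient density at

    C* = (rho_w(T_amb, S_amb) − rho_w(T_riv, 0)) / (1 − rho_w(T_riv, 0)/rho_sed),

about 40 kg/m³ for the default September stratification.

Momentum uses third-order upwind-biased advection horizontally,
first-order upwind vertically, explicit eddy viscosity (Ah = 5 m²/s,
Av = 1e-3 m²/s), quadratic bottom drag (Cd = 2.5e-3), and buoyancy
b = −g(rho − rho0)/rho0 on w-faces.  The explicit terms are stepped with
variable-step Adams–Bashforth-2 (offset 0.51 for stability).  A pressure
projection enforces discrete incompressibility each step: the Neumann
Poisson problem on the wet cells is LU-factorised once per grid and the
direct solve leaves max |div u| at round-off (~1e-13 1/s, far below the
1e-8 health bound the stepper asserts).  Boundary-normal velocities are
prescribed: river inflow over the top two layers at the inshore end, a
uniform compensating outflow at the open end (rigid lid ⇒ instantaneous
volume balance), solid walls elsewhere.

Tracers use unsplit flux-form advection with van-Leer-limited upwind
fluxes (TVD): constants are preserved exactly under discretely
divergence-free flow, no new extrema are created, non-negative fields
stay non-negative, and closed-domain integrals telescope to round-off.
Diffusion is explicit and conservative (Kh = 5 m²/s, Kv = 5e-5 m²/s).
Vertical mixing closure is deliberately simple: constant coefficients
plus instantaneous convective adjustment (thickness-weighted pairwise
mixing iterated to a residual density inversion below 5e-13 kg/m³),
which is also the pathway by which a hyperpycnal plume plunges.

The time step is the safety factor (0.5) times the minimum of three
closed-form bounds: advective CFL (including the settling speed when
sediment is present), the explicit diffusion bound, and an internal-wave
CFL using a mode-1 speed estimated from the instantaneous density range.
Buoyancy can spike |w| within one step during plunge onset; the
integrator then retries the step at half the size (deterministically).
The settling speed enters the CFL bound only when the sediment field is
nonzero, so a case with ssm_mult = 0 follows the WOS trajectory bitwise.

There is no random number generator anywhere in the pipeline: a
configuration fixes every output byte.  The seed recorded in the config
governs optional perturbations only, and the default scenario has none.

## Sediment

Grain fall speed follows Rubey's relation, bridging the Stokes and
inertial regimes; at the study grain sizes it gives ws ≈ 8.6e-5 m/s
(0.01 mm) and 2.1e-3 m/s (0.05 mm) — residence times in the ~2 m surface
slab of days versus minutes, which is what differentiates the regimes.
One size class per run; molecular viscosity fixed at 1e-6 m²/s; no
flocculation or hindered settling, so the formulation is valid for
C ≪ rho_sed.  Settling is a donor-cell downward flux, sub-stepped to
unit Courant number; mass crossing the deepest wet face is deposited
permanently in a per-column ledger (no resuspension, no critical shear
stress), and sinking detritus is remineralised into bottom-cell nitrate
instead, which keeps the nitrogen budget closed.

Budgets are first-class: the model books river input, open-boundary
export, sponge exchange (the relaxation layer stands in for the far
field) and deposition per tracer every step, and every run reports
salt / total-nitrogen / SSM closure; the suite requires ≤ 1e-8 relative
and the model delivers round-off (~1e-14).

## Ecosystem

A nitrogen-currency NPZD model:

    uptake  = Vmax · e^(kT·T) · N/(N + Ks) · L(I) · P
    grazing = Rmax · max(0, 1 − e^(−λ(P − P0))) · Z
    L(I)    = (I/Iopt) · e^(1 − I/Iopt)          (Steele, Iopt = 65 W/m²)

with linear phytoplankton mortality, quadratic zooplankton mortality,
assimilation efficiency γ = 0.7 and detritus remineralisation
rD = 0.1 /day; the four tendencies sum to zero identically.  A per-cell
limiter scales the whole tendency vector so no pool can be driven
negative within a step (the scaling preserves the zero sum).  Light
decays with background attenuation kw = 0.15 /m plus phytoplankton
self-shading kp = 60 /m per mol N/m³; suspended sediment does not
attenuate light — turbidity shading is deliberately excluded, so the
simulated phytoplankton response isolates the density/transport pathway.
Surface forcing is a constant daily-mean PAR of 80 W/m².

Vmax = 0.2 /day at 0 °C with Eppley factor e^(0.0693 T) gives a net
specific growth around 0.5–0.8 /day at 24 °C under flood conditions, so
a bloom needs roughly five days to develop — the timescale observed for
flood-driven coastal blooms — and the few-day sediment–physics
interaction window is therefore transport-dominated, as intended.
Chlorophyll is diagnosed as 1.59 µg chl-a per µmol N (Redfield C:N =
6.625 mol/mol with a carbon-to-chlorophyll mass ratio of 50).
Riverine phytoplankton input is zero (rivers carry negligible marine
phytoplankton).

## Synthetic study conditions

All inputs are generated; nothing is downloaded.

* Hydrograph: base flow 62.46 m³/s (the river's annual mean) with one
  raised-cosine flood pulse — rise 10 h, fall 14 h (a ~1-day flood),
  peak 3000 m³/s at t = 24 h, run window 120 h (≥ 3 days past the peak,
  long enough to watch the interaction decay).  The peak value is a
  typhoon-flood magnitude chosen for a river of this size; it is
  configurable and no observed value is asserted.
* River inputs: nutrient 0.046 mol N/m³ × multiplier (the standard
  case's concentration), sediment C = ssm_mult · a·Q^b with b = 1.3 (a
  typical rating-curve exponent).  The coefficient a is a *calibration*:
  it is fixed so that the predicted river–sea density difference at peak
  flow crosses zero at 5× the standard load, placing the regime
  transition between multipliers 4 and 6.  It is not an observed value.
* Initial ocean: horizontally uniform tanh stratification (surface
  24 °C/32 psu over 16 °C/33.8 psu; halocline at 8 m), nutrient-depleted
  surface (5e-4 mol/m³) over a nutrient-rich sub-surface (4e-3 mol/m³),
  and a sub-surface chlorophyll maximum at 10 m — the configuration in
  which hyperpycnal mixing raises surface phytoplankton.  Static
  stability is validated at construction.
* Spinup: 3 days of constant base flow (no sediment) per nutrient
  multiplier, shared by every case at that multiplier so the WOS
  comparison starts from an identical state.  Three days suffices for
  quasi-steadiness of the base plume at this domain scale (the suite
  includes a doubling-convergence check); the spinup length is a
  configuration choice.
* Case grid: cartesian product of SSM multipliers × diameters ×
  nutrient multipliers (all within [0, 10]×), plus one WOS per nutrient
  level; multiplier 0 is folded into the WOS.  The default campaign is
  ssm {0,1,2,4,6,8,10} × d {10,20,50} µm × nutrient {0.1,1,10}
  (57 runs); a full-size grid is a configuration choice.  The typical
  regime presets are (4×, 0.05 mm, 1×) and (10×, 0.01 mm, 1×).

The slice's one genuinely free scale is the effective plume width W
that maps river discharge [m³/s] to slice forcing [m²/s].  W = 30 km —
roughly the lateral scale a major flood plume occupies around a bay of
this size — makes the flood's freshwater volume per width comparable to
a bay-scale dilution; much smaller W drowns the whole slice in
freshwater.  W is the main knob controlling absolute response
magnitudes and is documented as such.

Domain: 16 km × 40 m (64 × 250 m columns; 11 layers, top two 1 m thick
so the "top two layers" diagnostic slab is ~2 m), with a linear shelf
from 10 m at the mouth.  The last 2 km are a sponge relaxing toward the
pre-flood profiles (quadratic ramp, 30-min innermost timescale), which
absorbs the plume instead of letting it reflect at the open boundary.

## Diagnostics

The river plume is the set of cells in the top two layers with S ≤ 28
(inclusive).  By default the mask is taken from the *reference* (WOS)
run, following the convention that defines the plume area once from the
standard case; per-case masking is available by flag.  Plume means are
volume-weighted (the top-two-layers choice makes this nearly identical
to area weighting; volume weighting is exact on non-uniform layers).
Differences ΔX(t) = mean_case − mean_WOS at matched hourly outputs;
times where the mask is empty are recorded missing, never zero, and
excluded from extremum searches.  A case's regime label comes from the
sign of ΔS at the time of its largest magnitude, with a ±0.01 psu
neutral dead-band; homopycnal behaviour is grouped with hyperpycnal
(both mix surface and sub-surface water).  The regime map also carries
the diameter-independent predicted density-difference axis and the
bracketing multiplier interval where the sign flips.  The decay
diagnostic reads |ΔS| on the last valid sample in the fourth day after
the peak; a dissolved plume counts as fully decayed.

## Scaled configuration: what it shows and what it cannot

The default problem sizes — 64 × 11 cells, 5-day window, 57-case
campaign — are the package's own desk-scale choice.  On them the model
reproduces the mechanism structurally: the hypopycnal preset freshens
the plume and raises its nutrients; the hyperpycnal preset salinises
and depletes it; the phytoplankton difference is non-negative in both
(sub-surface chlorophyll entrainment versus nutrient retention); the
hyperpycnal salinity effect is several-fold stronger; and both effects
decay within days of the peak.

Quantities a 2-D slice cannot be expected to match:

* Absolute ΔS magnitudes run high by a factor of a few, because in the
  slice the *entire* discharge passes through the plunge region, whereas
  a real bay sinks only a near-mouth fraction of a laterally spreading
  plume ("a hole in the plume lens").
* Timing collapses: the hypopycnal extremum tracks the SSM input almost
  instantaneously (anomaly transit across a 16-km slice takes ~2 h), so
  the ~8 h lag seen at full bay scale, and the ordering of the two
  regimes' extremum times, are at or below this configuration's
  resolution.
* The lock-exchange benchmark front runs at ~0.68 of the inviscid
  0.5·sqrt(g'H) estimate (laboratory currents reach ~0.88).  The
  interior exchange flow is accurate — the two-layer seiche period
  matches linear theory to ~1% — but interfacial momentum mixing
  retards the nose of a thin (~4-cell) current.  This bias is converged
  (insensitive to resolution, limiter, viscosity and time scheme) and
  is inherited by plunge-front propagation speeds.

Also outside scope by design: realistic bathymetry, tides (microtidal
bay), wind, atmospheric heat flux, sediment resuspension (deposition is
terminal, so hyperpycnal persistence is underestimated), turbidity
shading of photosynthesis, and any 3-D flow-axis extraction.

## Degenerate inputs and numerical policies

Negative concentrations, non-finite fields, unstable requested initial
profiles, out-of-range multipliers, empty plume masks and mismatched
output time grids all raise typed errors rather than propagating.
Positivity clipping after a step is logged and must stay at round-off
(the default campaign logs exactly zero).  The Poisson gauge is pinned
at one cell; RHS compatibility is enforced by construction (balanced
inflow/outflow) plus a volume-weighted round-off correction, so the
pinned row's residual vanishes identically.
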