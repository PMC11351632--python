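# Methods

`oviductsim` replaces a full finite-element / CFD treatment of gamete
transport in the fallopian tube with a reduced-order model on the tube's
arclength backbone. This note records the model, its assumptions, the
calibration protocol, the numerical choices, and what the synthetic
experiments do and do not show.

## Coordinates and geometry

The tube is parameterized by arclength `s` from the uterine (intramural)
end (`s = 0`) to the fimbrial end (`s = L`), azimuth `θ ∈ [0, 2π)` and a
fractional radial coordinate `r ∈ [0, 1]`. Four portions tile `[0, L]`
in the order intramural → isthmus → ampulla → infundibulum with fractions
8 / 20 / 62 / 10 % of L. The ampulla share is chosen so that four lesions
spaced exactly 17 mm apart (a 51 mm span) fit inside the ampulla even in
the shortest (40s, L = 85 mm) tube; the published per-age region tables
this geometry abstracts are not reproduced here, only the printed
constraints (L = 85–105 mm, luminal area 5–40 mm², tapering intramural
segment, convoluted ampulla).

Aging enters the geometry four ways, all overridable: total length
105/95/85 mm, a lumen radius scale 1.0/0.95/0.90 (the muscle layer
stiffens and the inner diameter shrinks), mucosal fold depth
0.10/0.08/0.06 mm (columnar → cuboidal epithelium), and ciliated-cell
density 2000/1600/1400 mm⁻².

Lesions are elliptic-paraboloid luminal bumps with the canonical
10 × 5 mm footprint. Protrusion depth is not a published quantity; the
default is 40 % of the local resting radius and is the geometric lever of
lesion trapping. Lesion azimuths alternate sides (0, π, 0, π, 0).

## Wall mechanics and flow

The mucosa is a compressible neo-Hookean solid with strain energy

    W = (μ/2)(I₁ − 3) + μ ln J + (λ/2)(ln J)²,
    μ = Lκ / (2A(1+ν)),   λ = νLκ / ((1+ν)(1−2ν)A),

κ = 12–14 kPa (default 13), ν = 0.49. The `+μ ln J` sign follows the
constitutive statement this model implements; note the textbook
compressible neo-Hookean form carries `−μ ln J`. W is exercised as the
material law and in tests; the traveling-wave wall displacement uses a
linear compliance `ΔR = p·R₀ / (c_w·μ)` (dimensionless geometric factor
c_w = 3) rather than solving the full boundary-value problem, clamped at
90 % of the resting radius.

Two contraction waves (20 mmHg, 1.5 min⁻¹, wavelength = half the ampulla
length, waveform (1 + cos)/2 so the squeeze is purely inward) travel
simultaneously pro-ovary from the intramural end and pro-uterus from the
fimbrial end; their phase offsets are configuration values because no
coordination schedule is published. Axial flow follows from lubrication
theory: `Q(s, t) = −∫₀ˢ ∂A/∂t ds'` with `Q(0, t) = 0` (no net flux
through the uterotubal junction), mean velocity `Q/A`, and a Poiseuille
radial profile `2(1 − r²)`. Mass conservation `∂Q/∂s + ∂A/∂t = 0` holds
to discretization tolerance by construction and is asserted in tests.

Cilia contribute a steady (beat-averaged) pro-uterus slip velocity
`v_c = c_cal · ρ_cilia · f_beat · ℓ²` at the wall, decaying linearly to
zero at r = 0.6. The cilium length ℓ = 7 µm is literature-typical; the
single calibration constant c_cal = 7.2×10⁻³ absorbs stroke efficiency
and metachronal geometry and is set so that a normal 20s-tube oocyte
completes transit well within the 80 h window (typical transit 10–16 h,
maximum ≈ 17 h). Although cilia physically assist both cell types, the
net slip is pro-uterus; sperm progress pro-ovary by self-propulsion.

Mucus rheology is the affine law `η = 0.02 γ̇ + 0.98 Pa·s` evaluated at
the Poiseuille wall shear rate (note the positive slope as stated; a
shear-thinning fit would carry a negative one). Density 1007 kg/m³;
specific heat and thermal conductivity are stored but unused — the model
is isothermal.

## Sperm

The beat is generated from 100 dynein motor sites at equal arclength
intervals: site curvature `κᵢ = k_F·F·sin(2π n_w ξᵢ − φ) + κ_asym` with
sliding force F = 2×10⁻⁶ µN (normal) or 5×10⁻⁶ µN (hyperactivated), so
the oscillatory curvature amplitude ratio between modes is exactly 2.5.
The 3D shape integrates the Frenet–Serret frame along the flagellum
(midpoint rule, 4 substeps per motor interval, Gram–Schmidt
re-orthonormalization each substep), preserving arclength to < 0.1 %.

Propulsion uses Gray–Hancock resistive-force theory: slender-body drag
coefficients `C_t = 2πη/(ln(2L/a) − ½)`, `C_n = 4πη/(ln(2L/a) + ½)`, a
planar force/torque balance per beat phase for the rigid-body motion
(the prolate head and midpiece contribute drag only), and integration of
the body path over four beats. Shape velocities are differentiated
spectrally in beat phase — the mean swimming speed is second order in
amplitude and finite differences drown it in discretization noise. The
calibration constants k_F = 7×10⁴ µm⁻¹/µN, n_w = 1.5 wavelengths,
torsion 0.01 µm⁻¹ and beat frequency 10 Hz put the normal-mode
progressive speed at 33.5 µm/s (physiological 25–50 µm/s). The
hyperactivated mode (κ_asym = 0.02 µm⁻¹) is slower on its mean path
(30.2 µm/s) with roughly double the lateral excursion — the large
asymmetric beat trades progression for search. Agents switch to the
hyperactivated mode on first ampulla entry (configurable to `always`).

## Oocyte

A passive rigid sphere: corona radiata diameter 0.4 mm until shedding at
12 h, zona pellucida 0.12 mm after. Advection is the local flow velocity
times a confined-sphere hindrance `H = (1 − (d/D)²)^1.5`. The corona also
doubles the sticking probability while attached (roughness factor 2).
Elasticity (10 ± 5 kPa) enters only the squeeze rule: the oocyte passes a
lesion constriction of open diameter `D_open` iff `d ≤ D_open(1 + ε)`
with `ε = 0.2 · (10 kPa / E)`; at the default protrusion the canonical
lumen never occludes, so this rule matters for parameter studies, not the
canonical statistics. A `fertilized` flag exists for bookkeeping and
changes no mechanics. The radial position relaxes toward r = 0.85 with a
2×10⁻⁴ s⁻¹ rate (the dense oocyte settles against the mucosa) — without
this, agents that wander below the ciliary slip layer stall indefinitely,
which contradicts the near-wall transport the model represents.

## Transport and randomness

Time stepping is explicit Euler with dt = 1 s for sperm and dt = 10 s for
oocytes (beat dynamics enter only as averaged propulsion, so no
sub-cycling). Sticking is specified as hazard rates per second and
converted per step as `1 − exp(−rate·dt)`; states `stuck` and
`reached_goal` are absorbing. The fertilization-site goal is the
arclength at 70 % of the ampulla; the uterine-cavity goal is crossing
`s = 0`. Sperm near the wall (r > 0.75) stick at an age-calibrated rate,
amplified inside lesion capture zones (footprint in s and θ, r > 0.70)
and by a local-density crowding multiplier `1 + 0.2·max(ρ/ρ_ref − 1, 0)`
(5 mm bins) standing in for cell-to-cell and cell-to-surface collisions;
pairwise collisions are not simulated at n = 10⁴. An age-dependent
friction factor (1.0 / 0.80 / 0.65) slows near-wall sperm progression as
the muscle layer stiffens with age.

All randomness is drawn from a counter-based generator: each variate is
a splitmix64 hash of (master seed, agent id, step, channel), so outcomes
are bitwise reproducible and independent of agent batching or execution
order. Sub-seeds for replicate runs stay below 2³¹.

## Calibration protocol

The FEM/CFD internals the reduced model replaces are not recoverable, so
the printed outcome set defines the operating point. Free parameters:
the oocyte wall-sticking rate and lesion multiplier, the per-age sperm
wall-sticking rates and lesion multipliers, and c_cal (fixed first, by
the transit-time criterion above). `scripts/calibrate.py` fits each by
monotone bisection in log-rate space with common random numbers against:

* oocyte arrivals 98 % (20s normal) and 91 % (20s endometriosis);
* sperm normal-tube arrivals 90 / 70 / 40 % for 20s/30s/40s — the
  normal-tube sperm percentages are not published numerically, so this
  monotone-decreasing operating point is a modeling choice — and
  endometriosis arrivals implied by the published reduction rates
  4.8 / 33.3 / 81.8 %.

The remaining oocyte conditions (30s/40s) are *not* fitted; their
decline emerges from slower ciliary transport (lower density), narrower
lumens and longer hazard exposure, and lands inside the published
92–98 % (normal) and 74–91 % (endometriosis) ranges. Per-age sperm
lesion multipliers are needed because a single multiplier cannot produce
the published five-fold age amplification of the reduction rate on top
of the normal-tube decline.

The oocyte reduction rate computed as (normal − endo)/normal × 100 from
the arrival percentages is ≈ 7 % for the 20s group; the published oocyte
reduction figures (≈ 22/30/32 %) are not consistent with that formula
applied to the published percentages, and no alternative definition is
guessed — only the sperm reduction rates are calibration targets.

## Problem sizes

The canonical design (10,000 sperm, dt = 1 s, 80 h) is supported and
runs in tens of minutes; the shipped replicated experiments use 1,000
sperm × 10 seeds and 100 oocyte runs × 20 seeds per condition, sizes at
which the replicate-mean percentages carry sub-half-point standard
errors while a full condition grid completes in minutes on one core.
Early termination applies once every agent is absorbed (sperm resolve
within ~1 h of simulated time; oocytes within ~17 h).

## Known limitations

* No 3D Navier–Stokes or fluid–structure interaction: peristaltic flow
  is kinematic (mass conservation), and its second-order Lagrangian
  drift, not a resolved velocity field, is what agents feel.
* Sperm chemotaxis/thermotaxis, capacitation biochemistry, fertilization
  events and sperm–oocyte interaction are out of scope; sperm and oocyte
  simulations are independent, as in the canonical designs.
* The sticking hazards are phenomenological; their values are an
  operating point fitted to published outcome statistics, not measured
  adhesion kinetics. Transfer to real tissue is therefore qualitative
  (directions and orderings), not quantitative.
* The synthetic experiments share one geometry per age group; anatomical
  variability between individuals is not represented, so SEM error bars
  reflect initial-position and hazard randomness only.
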