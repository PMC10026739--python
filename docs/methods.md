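# Methods

This note documents the model, its parameters, the numerical choices and
the calibration behind `coweda`, in the package's own words.  Everything
quantitative stated here is computed by the test suite or by
`scripts/acceptance.py`; nothing is asserted beyond what the code
reproduces.

## Body model

**Geometry.** The body is six cylinders — head, trunk, arms, legs, hands,
feet — each split into concentric core, muscle, fat and skin shells.
Whole-body surface area uses the DuBois formula; whole-body volume follows
from the two-compartment (Siri) density relation with fat at 900 and lean
tissue at 1100 kg/m³, so the fat fraction is physiologically consequential:
it thickens the subcutaneous fat shell of every segment (fat volume is
apportioned uniformly by segment volume) and therefore raises shell
insulation.  Area and volume reach the segments through distribution
factors stored as data (`distribution` section of
`data/default_params.json`; trunk 0.36 of area, head 0.07, hands 0.05,
feet 0.07, …).  Given a segment's area/volume pair the cylinder length and
radius are determined exactly, and the shell boundary radii follow from
the shell volumes: skin from a fixed per-segment thickness (1.5–2 mm),
fat from the body fat-volume fraction, the interior split core/muscle by a
fixed per-segment fraction.  Segments assigned zero factors are kept at a
benign tiny size and flagged `degenerate` instead of producing 0/0
geometry.

**Passive heat balance.** Each node carries
`C dT/dt = q_met + q_shiv + conduction + blood convection − environmental loss`.
Radial conduction between neighbouring shells uses log-annulus
conductances evaluated between equal-area node centres, with
per-compartment conductivities (core 0.54, muscle 0.42, fat 0.21, skin
0.34 W/m·K).  A uniform 0.42 W/m·K was considered and rejected: it makes
fat no better an insulator than muscle and erases the fat–survival effect
the immersion variant depends on.  Tissue specific heat is 3500 J/kg·K;
the blood pool (70 mL/kg at 1060 kg/m³, 3850 J/kg·K) has its mass carved
out of the tissue so total heat capacity stays consistent with body mass.

**Blood.** A single well-mixed central pool exchanges with every perfused
compartment.  Deep (core/muscle) perfusion is proportional to local heat
production (3 W/K per W), which automatically perfuses shivering and
exercising muscle; limb and extremity interiors additionally vasoconstrict
in the cold (see controller).  An arterial tree is deliberately not
modelled.

**Metabolic heat.** Basal production is 45.8 W/m² of body surface,
distributed by segment factors and a within-segment split (80 % core,
14 % muscle, 1 % fat, 5 % skin).  The basal share carries a Q10 = 2
temperature dependence (`q10^((T−37)/10)`): cooling tissue produces less
heat, the slow positive feedback that makes late hypothermia progressive
rather than asymptotic.  Heat above basal (exercise) is deposited in
working muscle (legs 65 %, trunk 20 %, arms 15 %).  Respiratory loss is
the standard ventilation-proportional dry+latent form
(`0.0014·M·(34−T_a) + 0.0173·M·(5.87−P_a)`, terms clamped at zero),
charged to the trunk core; it is needed for whole-body energy closure in
cold air.

## Controller

Two error signals: a weighted core temperature (head 0.15 / trunk 0.85)
and an area-weighted mean skin temperature, each minus its setpoint
(core 37.0 °C, skin 33.0 °C; negative = cold).

**Shivering** is bilinear in the cold errors,
`g_s·colds* + g_p·coldc·colds*` (the pure-core gain is zero by default),
with three physiological modifiers: the skin cold signal saturates at 6 °C
below setpoint (receptor/recruitment ceiling), the total is hard-capped at
4.5 × basal rate, and an efficacy factor ramps from 1 at core 36.5 °C to 0
at core 32 °C (hypothermic impairment of shivering).  The saturation keeps
endurance times monotone in air temperature — without it, colder air
recruits more shivering than it adds heat loss and the predicted
hypothermia time can lengthen as conditions worsen.  The impairment term
turns near-threshold equilibria into slow declines, which is what makes
deep-cold outcomes progressive; it is a state (core-temperature)
dependence, not a fatigue process — there is no time-dependent adaptation
anywhere in the controller.

**Vasomotor tone.** Per-segment skin blood flow is basal flow divided by a
constriction term `1 + f_i (1.5·coldc + 0.25·colds)` with per-segment
factors (head 0.3 … hands/feet 2.5) plus a dilation term in the warm
errors, clamped between per-segment floors (hands/feet 0.02 L/h) and
ceilings.  The same cold drive, with stronger extremity factors (6.0),
divides the metabolism-proportional interior perfusion of limbs and
extremities: without interior constriction the tiny hand segment receives
several W/K of warm blood and never approaches the frostbite-risk
threshold, contrary to everyday experience of bare hands at −10 °C.

**Sweating** is the product form `warms·(g_w·warmc)` capped at 25 g/min
and converted to per-segment wettedness (required evaporation over maximal
evaporation, floored at the 0.06 insensible-diffusion wettedness).  The
product form has two consequences: sweating needs both a warm core and
warm skin, which guarantees shivering and sweating are never simultaneously
active during cold exposure (asserted along trajectories in the tests),
and the comfort criterion (wettedness 0.5) is reachable only by active
sweating, never by the diffusion floor.

**During immersion** shivering is capped at a sustainable 1.2 × basal rate
instead of the 4.5 × peak.  Sustaining near-maximal shivering for tens of
hours is not physiological, and with an unbounded cap the model holds core
temperature indefinitely in 20 °C water; a constant sustainable ceiling is
the simplest state-independent way to bound long-duration thermogenesis
without introducing a fatigue state.

## Clothing and environment

Garments carry per-covered-segment intrinsic thermal (m²·K/W) and
evaporative (m²·Pa/W) resistances; an ensemble is a layer-ordered stack
whose per-segment resistance is the series sum (no clothing-area-factor or
air-gap correction — the schema stores per-segment values so a corrected
rule can replace the function without touching data).  Whole-body
insulation is the area-weighted mean in clo.  The air boundary film
combines `h_c = 8.3·v^0.6` with a radiative 4.7 W/m²·K, per-segment film
factors (extremities 1.2, head 1.1), a still-air wind floor of 0.15 m/s
and a high-wind resistance floor of 0.012 m²·K/W; evaporative film via the
Lewis relation (0.0165 K/Pa).  At the 0.4 m/s reference this gives a
whole-body mean film of ≈0.104 m²·K/W.

In water the film is `1/h_w` with `h_w = 100 W/m²·K` (quiescent
immersion), evaporation is impossible (the evaporative path is closed with
an effectively infinite resistance), and flooded clothing retains 80 % of
its dry thermal resistance.  That retention models a *still* victim — the
scenario excludes swimming — where the flooded fabric plus trapped
unstirred water remains an effective barrier; for flushed or swimming
conditions the conventional ~0.1 retention should be configured instead.
Both values are single parameters in the configuration file.

Activity levels map to 105 / 250 / 400 / 600 W (rest, light, moderate,
heavy); users can pass explicit rates.  The Wind Chill Temperature uses
the published regression (wind in km/h) with the chart's frostbite-time
bands stored as data; out-of-range inputs are flagged, not raised, so
comparison tables can span warm columns.

## Numerics

Fixed-step classical RK4 with a 30 s reporting step (configurable within
(0.1, 120] s).  Inside each step the integrator takes the number of equal
substeps a conservative stability bound requires (fastest node rate from
conduction + environmental conductance + maximal perfusion); thin shells
on lean extremities in cold water are the stiffest case.  An energy audit
runs every step: the stored-energy change (Σ C·ΔT including the blood
pool) is compared with the net heat input integrated with the same RK4
weights; since conduction and blood exchange must cancel internally, any
assembly error appears directly in the residual.  Observed residuals are
at machine precision (≲1e-13 W); the documented guarantee, verified in the
tests, is ≤1 % of the larger balance term.  Endurance times are stable to
<1 % under timestep halving.

Threshold crossings are located by linear interpolation between bracketing
samples; a trajectory already beyond its threshold at t = 0 reports 0 min.
Human-facing tables print frostbite/manual criteria in minutes and
hypothermia in hours; machine output is always minutes (survival in
hours).  The manual-performance curve is piecewise linear through
(≥33 °C, 1.00), (15 °C, 0.80), (5 °C, 0.50), clamped below.  The hand
criterion uses the hand-segment skin node as a finger proxy — a
six-cylinder body has no finger node, and hand predictions are accordingly
the least certain output of this resolution class.

**Neutral initial state.** The documented initial condition (core
≈37.0 °C, skin ≈33.4–34.7 °C graded, hands/feet coolest) is the solved
closed-loop equilibrium of the model at the thermoneutral reference — 30 °C
air, 50 % RH, 0.4 m/s, resting, light ensemble — frozen into the parameter
file to 1e-4 °C.  This represents a person entering the cold from shelter,
makes the thermoneutral scenario an exact fixed point (drift < 1e-4 °C
over 2 h), and avoids a pre-equilibration run before every simulation.

## Calibration

Parameter values the literature does not fix were set, once, against the
package's own anchor scenarios, and are frozen in
`data/default_params.json`:

- the shivering gains/saturation against the cold-air reference cell
  (combat-uniform ensemble, −9 °C, 2 m/s, rest): hand frostbite-risk time
  ≈ 0.5 h and hypothermia onset ≈ 4.4 h, with 2 °C air reaching no
  hypothermia within 24 h and times shortening monotonically toward
  −43 °C;
- the water film coefficient, wet-clothing retention and sustainable
  shivering cap against the immersion medians: ≈3 h at 0 °C, ≈5 h at
  10 °C and ≈21 h at 20 °C water for the default population (n = 100),
  strictly increasing across 0/5/10/15/20 °C;
- the moderate cold weather fixture ensemble is constructed to aggregate
  to 1.90 clo whole-body intrinsic insulation.

These are calibrations of free constants, not fits to any held-out data;
the test suite re-derives each anchor from scratch.

## Synthetic data

**Garment fixture database** (12 garments, `data/garments.csv` and
`fixtures.default_garments()`): a base layer, fleece and wind layers, shell
pants, hat and balaclava, boots, a one-piece combat-uniform-like garment
with patrol cap, and three gloves of strictly increasing hand insulation.
Values are plausible per-segment resistances (evaporative resistance
derived from a per-garment permeability index), but they are synthetic: no
measured garment data ships with the package, so absolute endurance
numbers transfer to real clothing only after substituting measured
resistances.  Named ensembles: `light` (~0.5 clo), `acu` (~0.9 clo),
`moderate_cold` (~1.9 clo).

**Population generator**: truncated normal anthropometry, height 175 ±
10 cm, mass 78 ± 12 kg, fat fraction 0.20 ± 0.06, bounds inside the
validity ranges, rejection sampling, a single seeded generator.  It
emulates inter-individual variation in body size and composition only —
no age, sex structure, fitness, clothing fit or behavioural variation —
so passing population tests demonstrate the model's sensitivity to
anthropometry, not demographic realism.

## Known limitations

- Six segments, four shells: no finger/toe nodes (hand/foot skin is the
  extremity proxy), no counter-current limb heat exchange, no
  left/right asymmetry.
- Static receptor errors only; no rate (dynamic) receptor terms,
  acclimatisation, circadian drift or time-dependent shivering fatigue.
- No solar radiation, precipitation, wet-cold degradation in air, altitude,
  or clothing pumping/ventilation with motion.
- Immersion assumes full-body immersion of a still victim; cold shock,
  swimming failure, drift and rescue are out of scope, and the dehydration
  counter is a simple fluid-loss threshold with no drinking-water model.
- Below deep-hypothermia core temperatures the simulation continues as a
  passive cooling body; trajectories past the survival endpoint are not
  physiological predictions.
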