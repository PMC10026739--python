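# coweda — cold weather ensemble decision aid

`coweda` predicts how long a clothed person can stay safe in the cold.  It
couples a six-cylinder human thermoregulatory model to a clothing-ensemble
biophysics layer and reports **endurance times** — the time until a
physiological criterion is crossed:

| criterion | trajectory | threshold |
|---|---|---|
| finger / toe frostbite risk | hand / foot skin temperature | 5 °C |
| hypothermia onset | weighted core temperature | 36 °C |
| comfort (overdressing) limit | skin wettedness | 0.5 |
| effective manual performance | hand skin temperature | 15 °C |

An immersion variant predicts **hypothermia survival times** (core → 28 °C)
for individuals and sampled populations in cold water, producing survival
curves and medians per water temperature.  The intended users are
planners of cold-weather work — military planners, industrial hygienists,
occupational-medicine and search-and-rescue analysts — and modellers who
need a transparent, fully parameterised baseline.

## The model

The body is six cylinders (head, trunk, arms, legs, hands, feet), each with
four concentric compartments (core, muscle, fat, skin).  Geometry follows
from anthropometry: DuBois surface area
`A_D = 0.007184 · H^0.725 · M^0.425`, body volume from the two-compartment
density relation, both distributed over segments by configurable factors.
Each node obeys a Pennes-style heat balance

```
C_ij dT_ij/dt = q_met + q_shiv + K_radial ΔT + ṁ_b c_b (T_blood − T_ij) − q_env
```

with radial conduction between shells (log-annulus conductances), a single
central blood pool, Q10 temperature dependence of basal heat production and
dry + evaporative + respiratory losses at the boundary.  A bilinear
controller maps the weighted core and mean-skin errors to shivering
(skin-signal saturation, hypothermic impairment, hard cap), per-segment
vasomotor tone (extremities constrict hardest) and sweating.

Clothing is a per-segment stack: intrinsic resistances of the covering
layers add in series, the whole-body value is the area-weighted mean in clo
(1 clo = 0.155 m²·K/W), and a wind-dependent boundary film (h_c = 8.3 v^0.6
plus a radiative coefficient) completes the total.  In water the film is a
thin convective layer and flooded clothing keeps a documented fraction of
its dry insulation.  The NWS Wind Chill Temperature chart is implemented as
a comparison baseline.

Details, parameter tables and calibration rationale: [docs/methods.md](docs/methods.md).

## Worked example

Endurance of a combat-uniform-like ensemble (bare hands) at −9 °C, 2 m/s,
resting, for the 180 cm / 74.4 kg / 15 % fat reference adult:

```bash
$ coweda endurance --ensemble acu --temps=-9 --winds=2 --horizon 360
ensemble  air_temp  wind_speed  finger_frostbite_risk_min ...  hypothermia_h
     acu      -9.0         2.0                  37.333057 ...        4.41573
```

Manual performance has dropped 20 % after 12.3 min (hand skin at 15 °C),
the hand reaches the 5 °C frostbite-risk threshold after 37 min, and
hypothermia onset (core 36 °C) arrives after 4.4 h — cold injury risk is
real at a temperature where the wind-chill chart shows no frostbite risk at
all (`coweda wct` prints the side-by-side table).  Swapping in the ~1.9 clo
moderate cold weather ensemble (`--ensemble moderate_cold`) removes the
hypothermia risk entirely at this cell; that contrast is the decision the
tool is built to support.

Cold-water survival for a small population:

```bash
$ coweda survival --n 5 --water-temps 0,10 --seed 1
# population survival report (n=5, seed=1)
 water_temp_C  median_survival_h
          0.0              3.050
         10.0              4.775
```

Library use mirrors the CLI: `build_segments`, `aggregate_ensemble`,
`simulate`, `endurance_times`, `population_survival`; see the module
docstrings.

## Scope notes

The clothing values shipped here are a synthetic fixture database with
physically plausible resistances — the military manikin measurements the
approach was developed with are not public.  No solar load, precipitation,
wet-cold (rain) degradation in air, cold-shock or swimming-failure
mortality, and no tissue-freezing model: the 5 °C extremity threshold is a
conservative risk proxy chosen so rewarming can begin well before actual
freezing (< 0.5 °C) is a concern.
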