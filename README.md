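# ssbtax

Simulation of the expected population-health impact of Mexico's
1-peso-per-litre excise tax on sugar-sweetened beverages (SSB): body-mass
index and obesity via a dynamic energy-balance model, and diagnosed
type-2 diabetes via a multi-cohort Markov projection.

The package is aimed at epidemiologists and health-policy modellers who
want a tested, fully reproducible implementation of the tax-to-health
modelling chain without access to the restricted survey microdata it was
designed around: a synthetic-population generator calibrated to the
printed marginals of the 2012 National Health and Nutrition Survey
(ENSANUT) stands in for the microdata, and every downstream stage runs on
it deterministically.

## The modelling chain

1. **Consumption shock.** Observed post-tax changes in beverage purchases,
   stratified by socioeconomic status (SES), are applied as permanent
   reductions to each individual's taxed-SSB volume. Four scenarios:
   the 2014 average effect (−9.1 / −5.6 / −5.5 % for low/medium/high SES),
   the December-2014 peak monthly effect (−17.4 / −13.1 / −6.8 %), and a
   hypothetical doubled tax (exactly 2× either set). Volume converts to
   energy at 0.388 kcal/ml and to servings at 355 ml.

2. **Weight dynamics.** The Chow–Hall energy-balance ODE partitions the
   caloric deficit between fat mass *F* and lean tissue *L* along the
   Forbes relationship (d*L*/d*F* = *C*/*F*, *C* = 10.4 kg), with glycogen
   and extracellular-fluid transients, adaptive thermogenesis, and total
   expenditure

   *E* = *K* + γ_F·*F* + γ_L·*L* + δ·BW + β_TEF·*I* + AT + η_F·d*F*/d*t* + η_L·d*L*/d*t*,

   calibrated so each individual is in energy balance at their measured
   weight with a sedentary physical activity level (PAL 1.5). Fixed-step
   RK4 integration; BMI is reported at 1 and 10 years.

3. **Obesity accounting.** WHO cut-offs (normal < 25, overweight 25–29.99,
   obese ≥ 30 kg/m²), survey-weighted, stratified by sex, age group, SES
   and consumption quartile, with relative percent changes vs baseline.

4. **Diabetes projection.** A sex × SES × age multi-cohort Markov model
   (susceptible → diagnosed → dead, annual cycles, 2010–2050) under three
   secular incidence scenarios. The tax counterfactual scales the
   incidence hazard by RR^Δservings with RR = 1.26 per daily serving
   (95% CI 1.12–1.41); averted cases are cumulative incident-case
   differences between arms.

5. **Comparative-risk-assessment sensitivity.** Meta-analytic annual BMI
   change per serving/day coefficients (0.11–2.12 kg/m²) bracket the
   dynamic-model result without mechanistic assumptions.

## Worked example

```python
from ssbtax import (PopulationConfig, generate_population, apply_tax,
                    initialize_state, bmi_at_times, weighted_mean,
                    mexico_like_structure, project, link_from_changes,
                    averted_cases, generate_incidence_schedule, generate_births)
from ssbtax.rates import default_mortality_schedules

pop = generate_population(PopulationConfig(n=10_000, seed=12345))
w = pop["svy_weight"]
changes = apply_tax(pop, "avg10")          # observed average 10%-tax effect

state = initialize_state(pop)
base_bmi = (pop.weight_kg / pop.height_m**2).to_numpy()
bmis = bmi_at_times(state, changes.delta_kcal.to_numpy(), at_years=(10.0,))

structure, mort = mexico_like_structure(), default_mortality_schedules()
births, inc = generate_births(), generate_incidence_schedule("intermediate")
base = project(structure, inc, mort, births)
cf = project(structure, inc, mort, births, link=link_from_changes(pop, changes))
```

Output of the accompanying printing statements:

```
baseline consumption: 321.2 ml/day
mean change under avg10: -8.29 kcal/day
mean 10-year BMI reduction: 0.160 kg/m2
obesity prevalence: 38.68% -> 37.35% (-3.44% relative)
2050 diabetes prevalence: 15.6% -> 15.5%
averted cases by 2030: 111 thousand
```

Reading: a 10,000-person synthetic population consumes ~321 ml of taxed
beverages per person-day; the average tax effect removes ~8.3 kcal/day,
which the energy-balance model turns into a 0.16 kg/m² mean BMI reduction
after ten years and a 3.4% relative drop in obesity prevalence. Feeding
the same consumption change into the diabetes projection averts ~111
thousand diagnosed cases by 2030 under the intermediate incidence
scenario.

The same chain runs end-to-end from one config via the CLI:

```sh
ssbtax all --outdir out/           # writes the full table set + manifest
ssbtax generate --n 10000 --seed 1 --out pop.csv
```

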