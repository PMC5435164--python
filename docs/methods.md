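# Methods

This note documents the models implemented in `ssbtax`, the parameter
defaults and why they were chosen, the numerical choices, and what the
synthetic-data generator does and does not emulate.

## Pipeline

Individual-level microdata (sex, age, height, weight, SES tertile, daily
taxed-SSB volume, survey expansion weight) flows through four stages:
SES-stratified consumption reduction → caloric change → dynamic weight
model → weighted outcome tables; in parallel, the SES-group mean servings
change scales diabetes incidence in a population-level Markov projection.
A single root seed fans out to per-stage child seeds
(`numpy.random.SeedSequence`), so identical configuration and seed give
byte-identical outputs.

## Synthetic population

The generator emulates the printed marginal structure of the adult (20+)
Mexican population in the 2012 national nutrition survey:

* sex split 44.87/55.13, age bands 20–39/40–59/60+ at 47.21/34.20/18.59%,
  SES tertiles 33.65/32.91/33.43%;
* mean BMI 28.40 kg/m², with additive sex/age/SES offsets taken from the
  published stratum means (e.g. men −0.85, women +0.69); these offsets are
  mutually consistent with the marginal shares to within 0.001 kg/m²;
* taxed-SSB consumption with mean 323.49 ml/day, SD 520.44, and quartile
  cuts 33.94 / 129.64 / 402.86 ml/day.

**Consumption distribution.** A single zero-inflated log-normal cannot
reproduce mean, SD and all three quartile cuts simultaneously: matching
mean and SD forces σ ≈ 1.03–1.08, which places the 25th percentile near
50–70 ml/day, twice the published cut; matching the quartiles forces
σ ≈ 1.3–1.4 and inflates the SD to ~700. The generator therefore uses a
zero-inflated **two-component** log-normal mixture — a 5% point mass at
zero, a light-consumer component (w = 0.576, μ = 4.008, σ = 1.199 log-ml)
and a heavy-consumer component (μ = 6.163, σ = 0.788) — calibrated by
deterministic least squares on the analytic moments and CDF. All five
targets are met within 0.4%.

**Consumption gradients.** Multiplicative sex, age-group and SES shifts,
each renormalised to population mean 1, redistribute consumption without
moving the overall mean. The sex (male 1.15) and age (young 1.25 / 0.90 /
0.55) shifts reproduce the published pattern of heavier consumption among
men and the young. The SES shifts (low 0.948, medium 1.080, high 0.974)
are *derived*, not assumed: they are the unique solution making the
SES-weighted effective overall reductions match the published deltas for
both observed scenarios (21.62/323.49 = 6.68% under the average effect
and 40.18/323.49 = 12.42% under the peak effect, given the SES-specific
reductions and tertile shares). Notably this solution has medium-SES
consumption highest — a near-flat gradient, consistent with the published
quartile-by-SES table.

**What the generator does not emulate.** BMI is conditionally normal
(SD 5 kg/m², truncated to 17–55), so weight-category prevalences differ
from the published ones (obesity comes out several points above 34.05%
because the real BMI distribution is right-skewed); only the stratum
means are calibrated. Heights are sex-specific truncated normals
(male 1.64 ± 0.068 m, female 1.52 ± 0.062 m) — synthetic conventions
chosen for a realistic mean height², not survey values. BMI is drawn
independently of consumption given the strata, mirroring the published
near-flat baseline BMI across consumption quartiles. Survey design
(strata, PSUs, replicate weights) is not modelled; expansion weights
default to 1 and all statistics are weight-scale invariant. Passing tests
therefore demonstrate correctness of the *method* on a population with
this marginal structure, not agreement with the restricted microdata.

**Weighted quantiles.** Each observation is a mass w at plotting position
(C − w/2)/W (cumulative-weight midpoint) with linear interpolation — the
Hazen convention for unit weights, exactly invariant under weight
rescaling. Quartile assignment sends boundary values to the lower
quartile. The test suite checks agreement with a brute-force
replicate-expansion oracle through the step-CDF envelope.

## Weight-change model

The Chow–Hall energy-balance system tracks fat mass F, lean tissue L,
glycogen G and extracellular fluid ECF, with body weight
BW = F + L + (1 + h)G + ECF (h = 2.7 kg water per kg glycogen).

| parameter | value | units | role |
|---|---|---|---|
| ρ_F, ρ_L | 9440, 1807 | kcal/kg | tissue energy densities |
| γ_F, γ_L | 3.2, 22.0 | kcal/kg/d | resting expenditure per tissue |
| η_F, η_L | 180, 230 | kcal/kg | deposition/mobilisation costs |
| C (Forbes) | 10.4 | kg | lean/fat partition constant |
| β_AT, τ_AT | 0.14, 14 | –, d | adaptive thermogenesis |
| β_TEF | 0.10 | – | thermic effect of food |
| PAL | 1.5 | – | sedentary activity level |
| ρ_G, G₀ | 4180, 0.5 | kcal/kg, kg | glycogen pool |

These are the standard values used with this model in the energy-balance
literature; they are shipped as explicit defaults, not survey estimates.
The Forbes curve L = C·ln F + const lives in mass space, so the lean
share of the *energy* flux is p(F) = C′/(C′ + F) with C′ = C·ρ_L/ρ_F —
using C directly in p would overweight lean tissue five-fold and push the
steady-state response below the physiological range.

**Initialisation.** Baseline fat mass comes from a sex-specific linear
regression of percent body fat on BMI and age (women higher than men at
equal BMI), capped at a physiologic maximum of 60%; compositions leaving
no room for positive lean tissue raise an error rather than being
clamped. Baseline intake is PAL × resting metabolic rate
(Mifflin–St Jeor); the activity cost per kg is
δ = ((1 − β_TEF)·PAL − 1)·RMR/BW, and the constant K is solved so
expenditure equals intake at the measured weight — a zero perturbation
is therefore an exact steady state of the integrator.

**Perturbation.** The tax-induced caloric change is a permanent step at
t = 0, treated as carbohydrate (sugar water), which drives the glycogen
and fluid transients; both settle within days and are negligible at the
1- and 10-year reporting horizons. Adaptive thermogenesis follows the
intake step with a 14-day first-order lag.

**Numerics.** Fixed-step classical RK4 at dt = 1 day (the fastest time
constant, glycogen, is ~1 day, well inside RK4's stability region); the
10-year weight changes by < 0.01% between dt = 1 and dt = 0.1. The test
suite verifies the integrator against an independent scalar forward-Euler
implementation at dt = 0.01 day (agreement within 0.1%) and against the
closed-form algebraic steady state along the Forbes trajectory (50-year
integration within 2%; agreement to ~1e-8 in practice). The steady-state
response for reference adults is 0.043–0.051 kg per kcal/day, inside the
0.035–0.055 band implied by the familiar ~24 kcal/day-per-kg rule.

## BMI outcomes

WHO cut-offs, lower-inclusive (25.0 → overweight, 30.0 → obese).
Prevalence changes are *relative* percent changes against baseline
prevalence, matching the published table convention. Only endpoint
classification is reported (individuals crossing a category boundary
mid-horizon are classified where they end). Age groups are fixed at
20–39 / 40–59 / 60+.

## Diabetes projection

A deterministic multi-cohort recursion over sex × SES tertile × single
year of age (0–100, open top bin), annual cycles 2010–2050. Cycle order:
death first (1 − exp(−μ(a)); an optional hazard ratio multiplies μ for
the diagnosed state, default 1.0 since the source treatment of excess
mortality is not reproduced — raising it lowers prevalence levels), then
diagnosis among surviving susceptibles (1 − exp(−m·λ(a))), then ageing
and births. No half-cycle correction (available as future work; not part
of the published description). The counterfactual multiplier
m = RR^Δservings (RR = 1.26/serving, 355 ml serving) applies on the
*hazard* — the standard choice; applying it to the annual probability
would differ only at third order here — to the SES-group mean servings
change, from 2015 onward with no lag.

**Demographic stand-ins and calibration.** Mortality is Gompertz by sex
(levels 1.05/0.70 × 10⁻⁴, slopes 0.082/0.085 — life-table-like adult
hazards); births decline linearly from 2.2 M to 1.9 M over 2010–2050 with
51.2% male; the launch pyramid is quasi-stable (cohort size ∝
exp(−0.022·age) × survival), scaled to 112 M. Incidence is logistic in
age (plateau 0.035/person-year, midpoint 52 y, slope 0.105/y), zero below
age 20, with secular-scenario multipliers 0.60/0.80/1.00
(optimistic/intermediate/pessimistic); launch-year diagnosed prevalence
is logistic in age (maximum 0.34, midpoint 57 y, slope 0.09/y). The
incidence plateau and initial-prevalence maximum were calibrated jointly
so that (a) launch-year adult diagnosed prevalence is ≈ 9.5%, matching
the ~9.2% surveyed in 2012, and (b) the intermediate no-tax 2050 adult
prevalence falls inside the published 13.6–22.5% projection band. The
recursion is person-conserving exactly (alive + dead = launched + born,
checked every cycle) and is cross-validated in the tests against a
pencil-and-paper constant-hazard cohort table and a seeded
individual-level Bernoulli microsimulation (agreement within 3 binomial
standard errors).

## Comparative risk assessment

`crm_bmi_change` is exactly linear: ΔBMI = β·Δservings. The meta-analytic
coefficients (experimental 0.85, observational pooled 0.22, single-study
0.11/1.09/2.12 kg/m² per serving/day) express *annual* BMI change for a
sustained consumption change; the sensitivity table accumulates them
linearly over the reporting horizon (default 10 years) so the entries are
commensurate with the dynamic model's 10-year change, which they bracket.
Coefficients are applied unweighted across subgroups.

## Design choices on open questions

* **Serving size** for the RR link: 355 ml (one can), configurable; the
  source analysis does not state the serving used.
* **Caloric density** 0.388 kcal/ml, the ratio of the published baseline
  caloric to volume intake (125.50/323.49), configurable.
* **Caloric substitution**: none by default (substitution is toward
  untaxed non-caloric beverages); an exploratory fraction knob exists.
* **Chronic disease**: all individuals are simulated with the same
  weight-change model.

## Problem sizes

Default runs and the acceptance script use n = 10,000 individuals,
10-year RK4 integration at dt = 1 day, and the full 2010–2050 projection;
the whole test suite and the acceptance script each complete in a few
minutes on one CPU.

## Known limitations

Tax effects on purchases are fixed inputs, not estimated; undiagnosed
diabetes, children, cardiovascular outcomes and costs are out of scope.
The obesity-prevalence *levels* of the synthetic population exceed the
published ones (normal-BMI skewness is not modelled); stratified *changes*
are the meaningful outputs. Averted-case counts scale with the assumed
112 M launch population and the synthetic demography, so they are
indicative rather than registry-grade.
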