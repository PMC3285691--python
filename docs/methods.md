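# Model and methods

`tobaccosim` is a deterministic, discrete-time, multi-state population
model for comparing tobacco-control policies, in the DYNAMO-HIA tradition
of health impact assessment.  This note documents the model, its
assumptions, the numerical conventions, and what the synthetic inputs do
and do not establish.

## The population model

The population is partitioned by single year of age (0..`age_max`,
default 105, closed at the top: survivors of the last age exit the model),
sex (two levels), and smoking class.  The smoking classes are *never
smoker*, *current smoker*, and *former smoker by whole years since
quitting*; the quit strata are `former_0 .. former_{K-1}` with the last
open-ended (default `K = 11`, i.e. 0, 1, ..., 9, 10+ years).  Each cell
additionally carries, for every modelled disease, the fraction of the cell
with that disease.

One projection step is one calendar year and applies, in this order:

1. **Smoking transitions.**  Never smokers start with annual probability
   `start(a, s)`; current smokers quit into `former_0` with probability
   `quit(a, s)`; every former class restarts into current smoking with
   probability `restart(a, s)`; surviving former smokers advance one
   time-since-quit class, the top class being absorbing.  People who
   change class carry their disease prevalence with them: an instant
   change in smoking status does not change existing disease.
2. **Disease incidence.**  For each disease the input is a
   population-average incidence rate `I_pop(a, s)` plus incidence relative
   risks per smoking class (never = 1).  The never-smoker rate is
   calibrated once as `I_never = I_pop / Σ_c w_c RR_c` (with `w_c` the
   baseline class shares), class `c` receives `RR_c · I_never`, and
   incidence acts on the disease-free fraction of each cell.  The
   share-weighted class rates reproduce `I_pop` exactly at baseline.
3. **Mortality.**  Total mortality is decomposed additively.  Class-level
   all-cause rates are `M_c = RR^ac_c · m_total / Σ_c w_c RR^ac_c`, using
   the all-cause relative risks of smoking; this captures smoking's effect
   on deaths from causes *outside* the modelled disease list.  Each
   class's *other-cause* rate is `M_c` minus its baseline disease-specific
   mortality (excess mortality of the diseased fraction, summed over
   diseases); a negative remainder means the disease inputs contradict the
   all-cause inputs and is rejected as infeasible.  During projection a
   cell's death probability is its fixed other-cause rate plus the excess
   rates of the diseases its members currently carry.
4. **Ageing.**  Everyone advances one year of age; newborns enter at age 0
   as disease-free never smokers; survivors of the top age exit (these
   exits are tracked separately from deaths, and the top age is treated as
   `q = 1` in life tables).

Smoking prevalence after the baseline year is an *outcome*: it is never
re-imposed, only the transition rates (and, for the price policy, the
year-0 distribution) differ between scenarios.

### Event ordering and time convention

The within-year order (transitions → incidence → mortality → ageing) is a
modelling choice; alternative orders change results at the order of
rate-products (O(p·q)), which matters in principle and is therefore fixed
and stated.  All inputs are annual probabilities applied once per step,
not continuous-time hazards, because transition inputs of this kind are
reported as annual probabilities.

### Calibration is scenario-invariant

`I_never`, the class mortality split, and the baseline class-specific
disease prevalence are calibrated once from the *reference* bundle's
baseline smoking distribution and reused for every scenario.  The
epidemiology (how dangerous smoking is, how lethal a disease is) does not
change because an intervention changes who smokes; only exposure does.
Baseline disease prevalence is split across smoking classes in proportion
to the incidence relative risks (a chronic disease present at baseline was
accumulated roughly in proportion to incidence), normalised so the
share-weighted mean reproduces the input prevalence.  Diseases evolve
independently within a cell; "at least one disease" uses the independence
product `1 − Π_d (1 − prev_d)`.  Remission is zero; there is no migration.

## Net initiation rates (`lifetable`)

Adolescent surveys distinguish only smoker vs non-smoker, so gross start
and quit flows cannot be separated at those ages.  The non-smoker
prevalence curve is read as a life table of a cohort of non-smokers
shrinking only through *net* uptake: `s(a) = (p(a) − p(a+1)) / p(a)`.
Quit and restart are held at 0 below the hand-off age (default 16) where
survey-based adult rates take over.  Adjacent increases in non-smoker
prevalence (sampling noise) would imply negative uptake; they are clamped
to 0 with a warning, since net uptake cannot be negative in the cohort
model.  The same algebra applied to a *scaled* curve yields start rates
that hold a post-intervention adolescent prevalence in place for future
cohorts; the forward identity `l(a+1) = l(a)(1 − s(a))` reproduces either
curve to 1e-12.

## Scenarios (`scenarios`)

Three intervention families, each in a maximum and a realistic variant
(the shipped `table1_*` presets):

- **Cessation** (adults 18+): an odds ratio (default 2.0) on the annual
  quit probability, `q' = σ(OR · odds(q))`; for small `q` this roughly
  doubles the quit rate.  Maximum reach 100%; realistic reach 20%
  (40% of smokers want to quit × 50% participation).
- **Initiation** (school ages 10–18): proportional cut of the start rate,
  50% (maximum) or 20% at 50% reach (realistic).
- **Population-wide price policy**: a price increase of 95% (maximum) or
  20% (realistic) acting through prevalence elasticities, −0.7 up to age
  20 and −0.4 from 21, giving prevalence reductions of 66.5%/38%
  (maximum) and 14%/8% (realistic).  Adults quit immediately: the removed
  current-smoker mass enters `former_0` and their elevated `former_0`
  risks then decay along the quit strata; their start and quit rates are
  unchanged.  Youth never start: the removed mass enters the never class,
  and adolescent start rates are re-derived from the scaled non-smoker
  curve so future cohorts hold the lower prevalence.  Restart rates are
  scaled everywhere.

Reach is deterministic population mixing — a fraction ρ experiences the
transformed rate, the rest the reference rate — because a compartmental
model has no individual identity.  Effects are therefore linear in ρ
between the reference and the maximum variant.

The preset restart multipliers are 0.30 (maximum) and 0.80 (realistic).
Note these are *not* equal to one minus the youth prevalence reduction
(0.335 / 0.86), which is what the rule "scale restart like the start
rates" would give; both readings are defensible, so the presets carry the
published multipliers and `restart_multiplier="derived"` selects the rule
instead.

## Outcomes (`outcomes`)

Smoking prevalence series report never/current/former (aggregated over
quit strata) as fractions of the living population.  Comparison tables
use `difference = reference − scenario`, so positive numbers are cases or
deaths averted.  Life expectancy is a *period* (cross-sectional) life
table per calendar year built from that year's simulated deaths over the
start-of-year population, with the midpoint person-year convention
`L(a) = (l(a) + l(a+1))/2` and the top age closed.  "Disease-free life
expectancy" weights `L(a)` by the fraction free of every modelled disease
(Sullivan method).  This is deliberately labelled *disease-free* rather
than "healthy" life expectancy: no severity weighting is applied, and the
measure depends on which diseases a bundle includes.

Note that under a cessation scenario the never-smoker *counts* are
exactly unchanged (nothing creates or destroys never smokers), but their
prevalence *share* shifts at the third decimal because the intervention
keeps quitters alive longer — selective mortality changes the
denominator.  Exact-equality checks are therefore stated on counts.

## Synthetic inputs (`synthetic`)

The generator emits complete, validated bundles with the statistical
structure of national data, so the whole pipeline is testable without
non-redistributable national tables.  All curves are smooth parametric
shapes with fully controlled ground truth:

- **Mortality**: Gompertz (`4e-5 · e^{0.095a}` for men, women at 0.55×),
  plus a flat 4e-4 accident-type background and a small infant bump,
  capped at 0.6/year.  The baseline population is the stationary
  population of this schedule with a constant birth cohort (default
  200,000/year, giving a Netherlands-sized ~15.6M population).
- **Smoking**: logistic uptake over ages 10–20 to an adult plateau at the
  configured target (default 27%, women at 0.95×), declining after 55
  (quitting plus selective mortality); former-smoker mass rises with age
  to ~1.45× the target, split over quit strata with recent quitters
  dominating young adults and the open-ended stratum dominating old age.
  Start rates over the uptake window are derived from the uptake curve
  via the net-initiation life table, so the life-table identity holds by
  construction; adult quit rates are 2–6%/year, restart rates decay from
  8%/year.
- **Diseases** (defaults): a lung-cancer-like disease (RR 10, rare,
  highly fatal), a COPD-like disease (RR 6, common in old age) and an
  IHD-like disease (RR 2, very common), each with a gamma-shaped
  incidence curve rising from an onset age, prevalence proportional to
  the same shape, and case fatality ramping in slowly with age (over
  three times the incidence width) so that midlife disease mortality
  stays inside the still-low all-cause rate.  Former-smoker RRs decay
  exponentially toward 1, halving every 5 quit strata; the all-cause RR
  of current smoking is 1.8 with the same decay.
- **Seed-to-seed variation**: small log-normal factors (σ = 0.015) on the
  mortality, smoking and incidence levels.  The generator validates every
  bundle and re-derives the mortality calibration before returning, so an
  infeasible configuration fails loudly rather than emitting.

What the synthetic bundle does *not* emulate: real cohort smoking
histories (period–cohort structure), migration, trends in incidence or
mortality, correlated comorbidity, and the actual Dutch age profiles.
Passing the property suite on synthetic data therefore establishes the
*mechanics* of the pipeline (conservation, calibration contracts,
scenario orderings, timing patterns), not quantitative agreement with any
national projection.  Published national headline numbers are kept in
`tobaccosim.external_targets` as documentation for users who obtain the
national DYNAMO-HIA input database; nothing in the package computes or
tunes against them.

## The microsimulation oracle

`synthetic.microsim_oracle` is a person-level stochastic re-implementation
of the engine's update rules: per-person coin flips for transitions,
disease onset (class-specific rates) and death (other-cause plus the
excess rates of the diseases the person carries), in the engine's exact
event order.  `oracle_pair` starts the deterministic engine from the
microsimulation's *sampled* year-0 population with newborn inflows
rescaled to person units, so any post-baseline discrepancy is pure
Monte-Carlo noise; class occupancies and deaths agree within 3 binomial
standard errors at n = 10,000.  The oracle exists only for validation —
population-level output of the package is always the deterministic
engine.

## Numerical conventions and problem sizes

- Class fractions must sum to 1 within 1e-9; mass conservation per step
  holds to 1e-9 relative; life-table round trips to 1e-12; RR recovery
  from calibrated incidence to 1e-9.
- Degenerate cells (zero population) yield zero prevalence and are
  excluded from division; a zero-population age truncates a life table
  with a warning.
- Floats round-trip losslessly through the CSV format (`%.17g` written,
  round-trip parsing on read), so write→read is the identity and repeated
  runs are byte-identical.
- The test suite uses the pinned fixture configuration (ages 0..50, 3
  quit strata, 2 diseases, ~95k population) for engine-level checks and a
  full-size synthetic bundle (ages 0..105, 11 strata, 3 diseases, ~15.6M
  population) with 25–30 year horizons for scenario-level checks; these
  sizes make the whole suite run in seconds while leaving every code path
  exercised at full array dimensionality.

## Known limitations

- No migration, no birth-rate feedback, no remission, no comorbidity
  correlation, no time trends in epidemiology.
- Uncertainty is not quantified (the engine is expected-value; the
  microsimulation is a validation device, not an uncertainty engine).
- Combined interventions are out of scope; scenario effects are held
  constant over the projection period.
- The odds-ratio reading of cessation effectiveness and the immediate-
  quitting reading of the adult price response are modelling choices;
  both are stated rather than estimated.
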