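"""Synthetic input bundles with the statistical structure of national data.

The generator produces complete, valid bundles so every pipeline stage is
testable without the (non-redistributable) national tables: a stationary
population pyramid driven by Gompertz mortality, adult current-smoker
prevalence near the configured target (default 27%, the Dutch level at the
time the scenarios address) declining at old age, adolescent uptake
concentrated at ages 10-20 with start rates tied to the prevalence curve
through the non-smoker life-table identity, and smoking-related diseases
whose incidence rises with age and whose relative risks decay toward 1
with time since quitting.

All curves are smooth parametric shapes (logistic uptake, Gompertz
mortality, gamma-like incidence by age), not resampled data: the ground
truth is fully controlled, so parameter-recovery tests are exact.

The module also houses the person-level stochastic microsimulation used as
an independent oracle for the deterministic compartmental engine: the same
event ordering, but per-person coin flips.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .engine import Calibration, PopulationState, ProjectionResult
from .lifetable import NonSmokerPrevalenceCurve, net_start_rates_from_prevalence
from .types import (CURRENT, FORMER0, NEVER, AgeSexTable, Demography,
                    DiseaseDefinition, InputBundle, MortalitySpec,
                    ScenarioSpec, SmokingStateDistribution,
                    TransitionRateSet, REFERENCE)

__all__ = ["DiseaseParams", "SyntheticConfig", "generate_bundle",
           "fixture_config", "fixture_bundle", "microsim_oracle", "oracle_pair"]


@dataclass(frozen=True)
class DiseaseParams:
    """Shape parameters for one synthetic smoking-related disease.

    The incidence curve is a gamma-like bump ``((a - onset)/w)^2
    exp(-(a - onset)/w)`` scaled to ``incidence_peak`` at its mode
    (onset + 2w); prevalence uses the same shape with its own peak value.
    ``female_factor`` scales female incidence/prevalence (smoking-related
    disease burden has historically been lower in women).
    """

    name: str
    rr_current: float
    onset_age: int
    width: float
    incidence_peak: float
    prevalence_peak: float
    excess_mortality: float
    female_factor: float = 0.6


DEFAULT_DISEASES = (
    # lung-cancer-like: rare, very high RR, highly fatal
    DiseaseParams("lung_cancer", rr_current=10.0, onset_age=35, width=17.5,
                  incidence_peak=0.002, prevalence_peak=0.008,
                  excess_mortality=0.20),
    # COPD-like: common at old age, high RR, moderate excess mortality
    DiseaseParams("copd", rr_current=6.0, onset_age=30, width=20.0,
                  incidence_peak=0.006, prevalence_peak=0.07,
                  excess_mortality=0.03),
    # IHD-like: very common, modest RR
    DiseaseParams("ihd", rr_current=2.0, onset_age=30, width=20.0,
                  incidence_peak=0.008, prevalence_peak=0.10,
                  excess_mortality=0.03),
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Everything the generator needs; same config + seed => identical bundle.

    ``adult_smoking_target`` is the current-smoker fraction the adult
    plateau aims at; ``quit_rr_halflife`` is the number of time-since-quit
    classes over which the excess relative risk halves.
    """

    seed: int = 0
    age_max: int = 105
    n_quit_classes: int = 11
    population_scale: float = 200_000.0   # annual birth cohort size (both sexes)
    baseline_year: int = 2010
    adult_smoking_target: float = 0.27
    female_smoking_factor: float = 0.95
    uptake_ages: tuple[int, int] = (10, 20)
    gompertz_intercept: float = 4e-5      # male hazard at age 0
    gompertz_slope: float = 0.095         # per year of age
    female_mortality_factor: float = 0.55
    infant_mortality: float = 0.004
    background_mortality: float = 4e-4    # flat accident-type component
    rr_allcause_current: float = 1.8
    quit_rr_halflife: float = 5.0
    diseases: tuple[DiseaseParams, ...] = DEFAULT_DISEASES
    jitter: float = 0.015                 # sd of log-scale seed-to-seed noise

    def __post_init__(self):
        if not 0.0 <= self.adult_smoking_target <= 1.0:
            raise ValueError("adult_smoking_target must be in [0, 1]")
        if self.n_quit_classes < 1 or self.age_max < self.uptake_ages[1] + 1:
            raise ValueError("inconsistent age/class configuration")


# ---------------------------------------------------------------------------
# curve building blocks
# ---------------------------------------------------------------------------

def _gamma_bump(ages: np.ndarray, onset: float, width: float) -> np.ndarray:
    """Zero before onset, rising to 1 at onset + 2*width, then decaying."""
    x = np.clip((ages - onset) / width, 0.0, None)
    shape = x ** 2 * np.exp(-x)
    return shape / (4.0 * np.exp(-2.0))     # value at the mode x = 2


def _mortality_curve(cfg: SyntheticConfig, factor: float, sex_i: int) -> np.ndarray:
    ages = np.arange(cfg.age_max + 1)
    sex_f = 1.0 if sex_i == 0 else cfg.female_mortality_factor
    m = cfg.gompertz_intercept * np.exp(cfg.gompertz_slope * ages) * sex_f
    m = m + cfg.background_mortality * sex_f
    m = m + cfg.infant_mortality * np.exp(-ages)   # infant bump
    return np.clip(m * factor, 0.0, 0.6)


def _current_smoker_curve(cfg: SyntheticConfig, factor: float, sex_i: int
                          ) -> np.ndarray:
    """Logistic adolescent uptake, adult plateau, decline at old age."""
    ages = np.arange(cfg.age_max + 1)
    lo, hi = cfg.uptake_ages
    mid = 0.5 * (lo + hi) + 0.5
    uptake = 1.0 / (1.0 + np.exp(-(ages - mid) / 1.6))
    uptake = np.where(ages < lo, 0.0, uptake)
    decline = np.where(ages > 55, np.exp(-(ages - 55) / 35.0), 1.0)
    target = cfg.adult_smoking_target * factor
    if sex_i == 1:
        target *= cfg.female_smoking_factor
    return np.clip(target * uptake * decline, 0.0, 1.0)


def _former_total_curve(cfg: SyntheticConfig, factor: float, sex_i: int
                        ) -> np.ndarray:
    """Former-smoker mass: zero through the uptake window, rising with age."""
    ages = np.arange(cfg.age_max + 1)
    start_age = cfg.uptake_ages[1] + 1
    level = 1.45 * cfg.adult_smoking_target * factor
    if sex_i == 1:
        level *= cfg.female_smoking_factor
    rise = 1.0 - np.exp(-np.clip(ages - start_age, 0.0, None) / 18.0)
    return np.clip(level * rise, 0.0, 1.0)


def _former_class_weights(cfg: SyntheticConfig) -> np.ndarray:
    """Split former mass over time-since-quit classes, by age.

    Young adults are mostly recent quitters; at old age the mass sits in
    the open-ended top class.  Shape (n_ages, n_quit_classes), rows sum
    to 1.
    """
    A, K = cfg.age_max + 1, cfg.n_quit_classes
    k = np.arange(K)
    recent = 0.6 ** k
    longq = 0.6 ** (K - 1 - k)
    w_age = np.clip((np.arange(A) - cfg.uptake_ages[1]) / 60.0, 0.0, 1.0)
    w = (1.0 - w_age)[:, None] * recent[None] + w_age[:, None] * longq[None]
    return w / w.sum(axis=1, keepdims=True)


def _rr_decay(rr_current: float, K: int, halflife: float) -> np.ndarray:
    """Former-class RRs: excess risk halves every ``halflife`` classes."""
    k = np.arange(K)
    return 1.0 + (rr_current - 1.0) * 0.5 ** ((k + 1) / halflife)


# ---------------------------------------------------------------------------
# bundle generation
# ---------------------------------------------------------------------------

def generate_bundle(config: SyntheticConfig | None = None,
                    seed: int | None = None) -> InputBundle:
    """Generate a complete, validated synthetic input bundle.

    ``seed`` overrides ``config.seed``.  The bundle always passes
    validation; an infeasible configuration (disease mortality exceeding
    what the all-cause inputs allow) raises before anything is returned.
    """
    cfg = config or SyntheticConfig()
    if seed is not None:
        cfg = replace(cfg, seed=int(seed))
    rng = np.random.default_rng(cfg.seed)
    A = cfg.age_max + 1
    ages = np.arange(A)

    mort_f = np.exp(rng.normal(0.0, cfg.jitter, size=2))
    smoke_f = np.exp(rng.normal(0.0, cfg.jitter, size=2))
    dis_f = np.exp(rng.normal(0.0, cfg.jitter, size=len(cfg.diseases)))

    m_total = np.column_stack([_mortality_curve(cfg, mort_f[i], i) for i in (0, 1)])

    current = np.column_stack([_current_smoker_curve(cfg, smoke_f[i], i)
                               for i in (0, 1)])
    former_tot = np.column_stack([_former_total_curve(cfg, smoke_f[i], i)
                                  for i in (0, 1)])
    weights = _former_class_weights(cfg)
    former = former_tot[:, :, None] * weights[:, None, :]
    never = 1.0 - current - former_tot
    if np.any(never < 0):
        raise ValueError("smoking prevalence target leaves negative never mass")
    smoking = SmokingStateDistribution(never, current, former)

    # start rates: adolescent window from the non-smoker life-table identity
    start = np.zeros((A, 2))
    lo, hi = cfg.uptake_ages
    if cfg.adult_smoking_target > 0:
        window = np.arange(lo, hi + 2)   # need one successor age
        for i in (0, 1):
            curve = NonSmokerPrevalenceCurve(
                ages=window, p_ns=1.0 - current[window, i], sex=("male", "female")[i])
            start[window[:-1], i] = net_start_rates_from_prevalence(curve)
        quit = np.where(ages[:, None] >= 16,
                        np.clip(0.02 + 5e-4 * (ages[:, None] - 16), 0.0, 0.06),
                        0.0) * np.ones((1, 2))
        restart = np.where(ages[:, None] >= 16,
                           0.08 * np.exp(-np.clip(ages[:, None] - 16, 0, None) / 25.0),
                           0.0) * np.ones((1, 2))
    else:
        quit = np.zeros((A, 2))
        restart = np.zeros((A, 2))
    rates = TransitionRateSet(AgeSexTable(start), AgeSexTable(quit),
                              AgeSexTable(restart))

    diseases = []
    for dp, f in zip(cfg.diseases, dis_f):
        bump = _gamma_bump(ages, dp.onset_age, dp.width)
        sexmul = np.array([1.0, dp.female_factor])
        inc = dp.incidence_peak * f * bump[:, None] * sexmul[None]
        prev = dp.prevalence_peak * f * bump[:, None] * sexmul[None]
        # case fatality ramps in slowly with age so that midlife smokers'
        # disease mortality stays inside their (still low) all-cause rate
        ramp = np.clip((ages - dp.onset_age) / (3.0 * dp.width), 0.0, 1.0)
        em = dp.excess_mortality * ramp[:, None] * np.ones((1, 2))
        rr_cur = np.full(A, dp.rr_current)
        rr_for = np.tile(_rr_decay(dp.rr_current, cfg.n_quit_classes,
                                   cfg.quit_rr_halflife), (A, 1))
        diseases.append(DiseaseDefinition(
            dp.name, AgeSexTable(inc), AgeSexTable(np.clip(prev, 0.0, 1.0)),
            AgeSexTable(em), rr_cur, rr_for))

    mortality = MortalitySpec(
        AgeSexTable(m_total),
        np.full(A, cfg.rr_allcause_current),
        np.tile(_rr_decay(cfg.rr_allcause_current, cfg.n_quit_classes,
                          cfg.quit_rr_halflife), (A, 1)))

    # stationary population: each birth cohort thinned by the mortality curve
    births = cfg.population_scale / 2.0
    surv = np.concatenate([np.ones((1, 2)),
                           np.cumprod(1.0 - m_total[:-1], axis=0)], axis=0)
    population = AgeSexTable(births * surv)
    newborns = np.array([[births, births]])
    demography = Demography(population, newborns)

    bundle = InputBundle(demography=demography, smoking=smoking, rates=rates,
                         diseases=tuple(diseases), mortality=mortality,
                         baseline_year=cfg.baseline_year)

    from .validate import raise_on_errors, validate_bundle
    raise_on_errors(validate_bundle(bundle))
    Calibration.from_bundle(bundle)   # raises InfeasibleInputError if inconsistent
    return bundle


def fixture_config() -> SyntheticConfig:
    """Small, fast configuration pinned for regression and oracle tests.

    Ages 0..50 with early-onset diseases so disease dynamics are exercised
    inside the short age range; 3 time-since-quit classes; 2 diseases.
    """
    return SyntheticConfig(
        seed=0, age_max=50, n_quit_classes=3, population_scale=2000.0,
        uptake_ages=(10, 18),
        gompertz_intercept=4e-4, gompertz_slope=0.09,
        diseases=(
            DiseaseParams("copd", rr_current=6.0, onset_age=20, width=10.0,
                          incidence_peak=0.006, prevalence_peak=0.05,
                          excess_mortality=0.01),
            DiseaseParams("ihd", rr_current=2.0, onset_age=20, width=10.0,
                          incidence_peak=0.008, prevalence_peak=0.08,
                          excess_mortality=0.01),
        ),
    )


def fixture_bundle() -> InputBundle:
    return generate_bundle(fixture_config())


# ---------------------------------------------------------------------------
# stochastic person-level oracle
# ---------------------------------------------------------------------------

def microsim_oracle(bundle: InputBundle, scenario: ScenarioSpec | None = None,
                    n_persons: int = 10_000, seed: int = 0,
                    horizon: int = 10) -> ProjectionResult:
    """Person-by-person stochastic simulation with the engine's event order.

    Samples ``n_persons`` individuals from the scenario's baseline joint
    (age, sex, class, disease) distribution, then flips per-person coins
    each year for smoking transitions, disease onset and death, in exactly
    the order the compartmental engine applies them.  Counts are in person
    units (scale the deterministic run by ``n_persons / population`` to
    compare); newborn entries are made integer by stochastic rounding so
    their expectation matches the deterministic inflow.

    Returns a :class:`ProjectionResult` whose ``states[0]`` is the sampled
    empirical population — feed it to
    :func:`tobaccosim.engine.run_projection_from_state` for a
    variance-free comparison of everything after year 0.
    """
    from .engine import initial_state
    from .scenarios import build_scenario_bundle

    if n_persons > 100_000:
        raise ValueError("microsimulation oracle is meant for small n (<= 1e5)")
    spec = scenario if scenario is not None else REFERENCE
    rng = np.random.default_rng(seed)
    calib = Calibration.from_bundle(bundle)
    sbundle = build_scenario_bundle(bundle, spec)
    base = initial_state(bundle, sbundle, calib)

    A, S, C = base.count.shape
    D = len(bundle.diseases)
    scale = n_persons / base.count.sum()

    # --- sample individuals
    p = (base.count / base.count.sum()).ravel()
    cells = rng.choice(p.size, size=n_persons, p=p)
    age, sex, cls = np.unravel_index(cells, (A, S, C))
    age, sex, cls = age.astype(int), sex.astype(int), cls.astype(int)
    disease = np.zeros((n_persons, D), dtype=bool)
    for j in range(D):
        disease[:, j] = rng.random(n_persons) < base.disease_prev[j, age, sex, cls]
    alive = np.ones(n_persons, dtype=bool)

    start_r = sbundle.rates.start.values
    quit_r = sbundle.rates.quit.values
    restart_r = sbundle.rates.restart.values
    em = calib.excess_mortality

    def snapshot(year):
        cnt = np.zeros((A, S, C))
        np.add.at(cnt, (age[alive], sex[alive], cls[alive]), 1.0)
        dc = np.zeros((D, A, S, C))
        for j in range(D):
            m = alive & disease[:, j]
            np.add.at(dc[j], (age[m], sex[m], cls[m]), 1.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            prev = np.where(cnt > 0, dc / cnt, 0.0)
        return PopulationState(cnt, prev, year)

    states = [snapshot(bundle.baseline_year)]
    deaths = np.zeros((horizon, A, S))
    exits = np.zeros((horizon, S))

    for t in range(horizon):
        n_now = age.size
        age = np.minimum(age, A - 1)   # exited persons: index safely, masks exclude them
        u = rng.random(n_now)
        is_never = alive & (cls == NEVER)
        is_cur = alive & (cls == CURRENT)
        is_for = alive & (cls >= FORMER0)
        new_cls = cls.copy()
        # never -> current
        starts = is_never & (u < start_r[age, sex])
        new_cls[starts] = CURRENT
        # current -> former_0
        quits = is_cur & (u < quit_r[age, sex])
        new_cls[quits] = FORMER0
        # former: restart or advance one time-since-quit year (top absorbs)
        restarts = is_for & (u < restart_r[age, sex])
        new_cls[restarts] = CURRENT
        advances = is_for & ~restarts
        new_cls[advances] = np.minimum(cls[advances] + 1, C - 1)
        cls = new_cls

        for j in range(D):
            healthy = alive & ~disease[:, j]
            onset = rng.random(n_now) < calib.incidence_by_class[j, age, sex, cls]
            disease[healthy & onset, j] = True

        p_death = calib.other_cause[age, sex, cls] + \
            (disease * em[:, age, sex].T).sum(axis=1)
        dies = alive & (rng.random(n_now) < np.clip(p_death, 0.0, 1.0))
        np.add.at(deaths[t], (age[dies], sex[dies]), 1.0)
        alive &= ~dies

        age = age + 1
        out = alive & (age > A - 1)
        np.add.at(exits[t], sex[out], 1.0)
        alive &= ~out

        # stochastically rounded newborn entries (unbiased integer counts)
        nb = sbundle.demography.newborns_in_step(t + 1) * scale
        n_new = np.floor(nb).astype(int) + (rng.random(2) < (nb - np.floor(nb)))
        if n_new.sum() > 0:
            age = np.concatenate([age, np.zeros(n_new.sum(), int)])
            sex = np.concatenate([sex, np.repeat([0, 1], n_new)])
            cls = np.concatenate([cls, np.full(n_new.sum(), NEVER)])
            disease = np.concatenate(
                [disease, np.zeros((n_new.sum(), D), bool)], axis=0)
            alive = np.concatenate([alive, np.ones(n_new.sum(), bool)])

        states.append(snapshot(bundle.baseline_year + t + 1))

    years = bundle.baseline_year + np.arange(horizon + 1)
    return ProjectionResult(years=years, states=states, deaths=deaths,
                            exits=exits, scenario=spec,
                            disease_names=bundle.disease_names())


def oracle_pair(bundle: InputBundle, scenario: ScenarioSpec | None = None,
                n_persons: int = 10_000, seed: int = 0, horizon: int = 10
                ) -> tuple[ProjectionResult, ProjectionResult]:
    """Matched (microsimulation, engine) runs for oracle comparisons.

    Both runs are in person units and start from the *same* sampled
    population (the microsimulation's empirical year-0 state), so every
    difference after year 0 is pure Monte-Carlo noise in the
    microsimulation; newborn inflows are rescaled to person units for the
    deterministic run.
    """
    from .engine import run_projection_from_state

    micro = microsim_oracle(bundle, scenario, n_persons=n_persons, seed=seed,
                            horizon=horizon)
    scale = micro.states[0].count.sum() / bundle.demography.population.values.sum()
    scaled = bundle.copy()
    scaled.demography.newborns *= scale
    eng = run_projection_from_state(scaled, micro.scenario, micro.states[0],
                                    horizon)
    return micro, eng
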