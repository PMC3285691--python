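"""Annual-step compartmental projection of smoking states, disease and death.

The population is partitioned by single year of age, sex and smoking class
(never / current / former by time since quitting).  Each projection year
applies, in order:

1. smoking transitions — never -> current (start), current -> former_0
   (quit), former_k -> current (restart); surviving former classes advance
   one time-since-quit year, the top class being absorbing;
2. disease incidence — per class, applied to the disease-free fraction,
   with class rates calibrated so never smokers are the reference and the
   share-weighted mean reproduces the population-average input rate;
3. mortality — per-disease excess mortality of the diseased fraction plus
   class-specific other-cause mortality, the latter derived from all-cause
   mortality and the all-cause relative risks of smoking under additive
   mortality;
4. ageing — everyone advances one year of age, newborns enter at age 0 as
   disease-free never smokers, and survivors of the top age exit.

The engine is deterministic (expected values).  A change in smoking
exposure therefore propagates along the causal chain exposure -> incidence
-> prevalence -> mortality; smoking prevalence after the baseline year is
an *outcome*, never re-imposed except through transition rates.

People who change smoking class carry their disease prevalence with them:
quitting does not cure, and the elevated former_0 risks then decay along
the time-since-quit classes.  Diseases evolve independently within a cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import (CURRENT, FORMER0, NEVER, InputBundle, ScenarioSpec,
                    TransitionRateSet, REFERENCE)

_TOL = 1e-12


class InfeasibleInputError(ValueError):
    """Inputs are mutually inconsistent (e.g. negative other-cause mortality)."""


# ---------------------------------------------------------------------------
# calibration primitives
# ---------------------------------------------------------------------------

def calibrate_class_specific_incidence(i_pop, shares, rr):
    """Split a population-average incidence rate into per-class rates.

    Given class occupancy ``shares`` (summing to 1 over the last axis) and
    incidence relative risks ``rr`` (never smokers = 1), the never-smoker
    rate is ``i_pop / sum_c shares_c rr_c`` and class ``c`` gets ``rr_c``
    times that, so the share-weighted mean reproduces ``i_pop`` exactly.

    All arguments broadcast; the class axis is the last one.
    """
    i_pop = np.asarray(i_pop, float)
    shares = np.asarray(shares, float)
    rr = np.asarray(rr, float)
    denom = np.sum(shares * rr, axis=-1)
    if np.any(denom <= 0):
        raise InfeasibleInputError(
            "share-weighted relative risk is zero; class-specific incidence "
            "is undefined")
    i_never = i_pop / denom
    return rr * i_never[..., None]


def derive_other_cause_mortality(m_total, disease_mortality):
    """Other-cause rate under additive mortality: total minus disease part."""
    m_total = np.asarray(m_total, float)
    disease_mortality = np.asarray(disease_mortality, float)
    other = m_total - disease_mortality
    if np.any(other < -_TOL):
        idx = np.argwhere(other < -_TOL)[0]
        raise InfeasibleInputError(
            f"disease-specific mortality exceeds total mortality at index "
            f"{tuple(int(i) for i in idx)}: other-cause rate would be negative")
    return np.clip(other, 0.0, None)


def derive_state_specific_mortality(m_total, rr_allcause, shares,
                                    disease_mortality_by_class):
    """Class-specific total and other-cause mortality rates.

    The class totals ``M_c = rr_c * m_total / sum_c shares_c rr_c`` satisfy
    (i) ``sum_c shares_c M_c == m_total`` and (ii) ``M_c / M_never == rr_c``.
    The other-cause component is ``M_c`` minus the class's disease-specific
    mortality; a negative component means the disease inputs are
    inconsistent with the all-cause inputs.

    Returns ``(total_by_class, other_by_class)``; the class axis is last.
    """
    m_total = np.asarray(m_total, float)
    rr = np.asarray(rr_allcause, float)
    shares = np.asarray(shares, float)
    denom = np.sum(shares * rr, axis=-1)
    if np.any(denom <= 0):
        raise InfeasibleInputError("share-weighted all-cause RR is zero")
    total = rr * (m_total / denom)[..., None]
    other = derive_other_cause_mortality(total, disease_mortality_by_class)
    return total, other


# ---------------------------------------------------------------------------
# state containers
# ---------------------------------------------------------------------------

@dataclass
class PopulationState:
    """Counts and per-disease prevalence by (age, sex, smoking class).

    ``count`` has shape (n_ages, 2, n_classes); ``disease_prev`` has shape
    (n_diseases, n_ages, 2, n_classes) and holds the fraction of each cell
    with the disease.
    """

    count: np.ndarray
    disease_prev: np.ndarray
    year: int

    @property
    def n_classes(self) -> int:
        return self.count.shape[2]

    def living(self) -> np.ndarray:
        """Total living population by (age, sex)."""
        return self.count.sum(axis=2)

    def disease_count(self) -> np.ndarray:
        """Diseased persons by (disease, age, sex, class)."""
        return self.count[None] * self.disease_prev

    def copy(self) -> "PopulationState":
        return PopulationState(self.count.copy(), self.disease_prev.copy(), self.year)


@dataclass
class ProjectionResult:
    """One scenario run: annual states plus death and top-age exit counts.

    ``states[i]`` is the population at the start of ``years[i]``;
    ``deaths[i, a, s]`` are deaths during that year among people aged ``a``
    at its start, and ``exits[i, s]`` are the survivors of the top age who
    leave the modelled range at its end.
    """

    years: np.ndarray
    states: list[PopulationState]
    deaths: np.ndarray
    exits: np.ndarray
    scenario: ScenarioSpec
    disease_names: list[str]
    bundle_hash: str = ""

    @property
    def baseline_year(self) -> int:
        return int(self.years[0])

    @property
    def horizon(self) -> int:
        return len(self.years) - 1

    def state_at(self, year: int) -> PopulationState:
        i = int(year) - self.baseline_year
        if not 0 <= i <= self.horizon:
            raise KeyError(f"year {year} outside projection {self.years[0]}..{self.years[-1]}")
        return self.states[i]


# ---------------------------------------------------------------------------
# baseline calibration
# ---------------------------------------------------------------------------

@dataclass
class Calibration:
    """Scenario-invariant quantities fixed from the reference baseline.

    ``incidence_by_class`` (D, A, S, C) and ``other_cause`` (A, S, C) are
    calibrated once from the reference bundle's baseline smoking shares and
    held constant: the underlying epidemiology does not change because an
    intervention changes who smokes.  ``prev0_by_class`` splits the
    population-average baseline disease prevalence across classes in
    proportion to the incidence relative risks (a disease accumulated
    roughly in proportion to its incidence), normalised so the
    share-weighted mean reproduces the input prevalence.
    """

    incidence_by_class: np.ndarray
    prev0_by_class: np.ndarray
    excess_mortality: np.ndarray
    other_cause: np.ndarray
    total_by_class: np.ndarray

    @classmethod
    def from_bundle(cls, bundle: InputBundle) -> "Calibration":
        shares = bundle.smoking.as_matrix()              # (A, S, C)
        D = len(bundle.diseases)
        A, S, C = shares.shape
        inc = np.empty((D, A, S, C))
        prev0 = np.empty((D, A, S, C))
        em = np.empty((D, A, S))
        for j, d in enumerate(bundle.diseases):
            rr = d.rr_by_class()[:, None, :]             # (A, 1, C)
            inc[j] = calibrate_class_specific_incidence(d.incidence.values, shares, rr)
            prev0[j] = calibrate_class_specific_incidence(d.prevalence.values, shares, rr)
            em[j] = d.excess_mortality.values
        if np.any(prev0 > 1.0 + 1e-9):
            raise InfeasibleInputError(
                "baseline disease prevalence calibrated above 1 in some "
                "smoking class; reduce prevalence or relative risks")
        prev0 = np.clip(prev0, 0.0, 1.0)
        dis_mort = np.einsum("dasc,das->asc", prev0, em)
        rr_ac = bundle.mortality.rr_by_class()[:, None, :]
        total, other = derive_state_specific_mortality(
            bundle.mortality.m_total.values, rr_ac, shares, dis_mort)
        return cls(incidence_by_class=inc, prev0_by_class=prev0,
                   excess_mortality=em, other_cause=other, total_by_class=total)


# ---------------------------------------------------------------------------
# annual step
# ---------------------------------------------------------------------------

def _apply_transitions(count, dcount, rates: TransitionRateSet):
    """Move counts (and disease counts, proportionally) between classes."""
    s = rates.start.values          # (A, S)
    q = rates.quit.values
    r = rates.restart.values

    def move(x):
        # x: (..., A, S, C) with class axis last
        out = np.empty_like(x)
        never, cur, former = x[..., NEVER], x[..., CURRENT], x[..., FORMER0:]
        out[..., NEVER] = never * (1.0 - s)
        out[..., CURRENT] = (cur * (1.0 - q) + never * s
                             + (former * r[..., None]).sum(axis=-1))
        stay = former * (1.0 - r[..., None])
        out[..., FORMER0] = cur * q
        out[..., FORMER0 + 1:] = stay[..., :-1]
        out[..., -1] += stay[..., -1]        # top time-since-quit class absorbs
        return out

    return move(count), move(dcount)


def step_year(state: PopulationState, bundle: InputBundle, calib: Calibration,
              rates: TransitionRateSet | None = None):
    """Advance the population one calendar year.

    Returns ``(next_state, deaths, exits)`` where ``deaths`` is (A, S) by
    age at the start of the year and ``exits`` (S,) counts top-age
    survivors leaving the modelled age range.
    """
    if rates is None:
        rates = bundle.rates
    N = state.count
    DC = state.disease_count()

    # 1. smoking transitions (movers carry their disease prevalence)
    N, DC = _apply_transitions(N, DC, rates)

    # 2. incidence on the disease-free fraction, class-specific rates
    healthy = np.clip(N[None] - DC, 0.0, None)
    DC = DC + healthy * calib.incidence_by_class

    # 3. mortality: other-cause per class + excess mortality of the diseased
    with np.errstate(invalid="ignore", divide="ignore"):
        prev = np.where(N[None] > 0, DC / N[None], 0.0)
    dis_mort = np.einsum("dasc,das->asc", prev, calib.excess_mortality)
    cell_death = np.clip(calib.other_cause + dis_mort, 0.0, 1.0)
    survivors = N * (1.0 - cell_death)
    # per-disease survival: a person's death probability is other-cause plus
    # the excess rates of the diseases they carry (independent diseases)
    em = calib.excess_mortality[:, :, :, None]
    death_d = np.clip(calib.other_cause[None] + em + (dis_mort[None] - prev * em),
                      0.0, 1.0)
    DC = DC * (1.0 - death_d)
    deaths = (N - survivors).sum(axis=2)

    # 4. ageing: shift up one year, newborns in, top age out
    A = N.shape[0]
    new_N = np.zeros_like(N)
    new_DC = np.zeros_like(DC)
    new_N[1:] = survivors[:-1]
    new_DC[:, 1:] = DC[:, :-1]
    exits = survivors[-1].sum(axis=-1)
    t_next = state.year + 1
    step = t_next - bundle.baseline_year
    new_N[0, :, NEVER] = bundle.demography.newborns_in_step(step)

    with np.errstate(invalid="ignore", divide="ignore"):
        new_prev = np.where(new_N[None] > 0, new_DC / new_N[None], 0.0)
    new_prev = np.clip(new_prev, 0.0, 1.0)
    return PopulationState(new_N, new_prev, t_next), deaths, exits


# ---------------------------------------------------------------------------
# initial state and full projection
# ---------------------------------------------------------------------------

def initial_state(reference: InputBundle, scenario_bundle: InputBundle,
                  calib: Calibration) -> PopulationState:
    """Baseline population state, honouring year-0 prevalence shifts.

    Counts follow the scenario bundle's smoking shares.  Disease prevalence
    per class starts from the reference calibration; where a scenario moves
    mass between classes at year 0 (a price shock turning current smokers
    into former_0 or never), the movers keep the donor class's disease
    prevalence — an instant change in smoking status does not change
    existing disease.
    """
    pop = reference.demography.population.values          # (A, S)
    ref_shares = reference.smoking.as_matrix()
    scen_shares = scenario_bundle.smoking.as_matrix()
    N_ref = pop[:, :, None] * ref_shares
    N_scen = pop[:, :, None] * scen_shares
    DC_ref = N_ref[None] * calib.prev0_by_class

    delta = N_scen - N_ref
    outflow = np.clip(-delta, 0.0, None)                  # (A, S, C)
    inflow = np.clip(delta, 0.0, None)
    moved = outflow.sum(axis=-1)                          # (A, S)
    # donors lose mass at unchanged prevalence; receivers gain at the
    # count-weighted donor prevalence
    with np.errstate(invalid="ignore", divide="ignore"):
        keep = np.where(N_ref > 0, np.clip(N_scen, 0, None) / np.where(N_ref > 0, N_ref, 1.0), 0.0)
    keep = np.minimum(keep, 1.0)
    DC = np.where(outflow[None] > 0, DC_ref * keep[None], DC_ref)
    with np.errstate(invalid="ignore", divide="ignore"):
        donor_prev = np.where(
            moved[None] > 0,
            np.sum(outflow[None] * calib.prev0_by_class, axis=-1)
            / np.where(moved > 0, moved, 1.0)[None], 0.0)     # (D, A, S)
    DC = DC + inflow[None] * donor_prev[..., None]

    with np.errstate(invalid="ignore", divide="ignore"):
        prev = np.where(N_scen[None] > 0, DC / N_scen[None], 0.0)
    prev = np.clip(prev, 0.0, 1.0)
    return PopulationState(N_scen, prev, scenario_bundle.baseline_year)


def run_projection(bundle: InputBundle, scenario: ScenarioSpec | None = None,
                   horizon: int | None = None) -> ProjectionResult:
    """Project a scenario forward from the baseline year.

    ``bundle`` is always the *reference* bundle; the scenario transform is
    applied internally so that incidence and mortality stay calibrated to
    the reference baseline.  ``horizon`` overrides
    ``scenario.horizon_years``.
    """
    from .scenarios import build_scenario_bundle  # local import: no cycle at load

    spec = scenario if scenario is not None else REFERENCE
    h = int(horizon if horizon is not None else spec.horizon_years)
    if h < 0:
        raise ValueError("horizon must be >= 0")

    calib = Calibration.from_bundle(bundle)
    sbundle = build_scenario_bundle(bundle, spec)
    state = initial_state(bundle, sbundle, calib)
    return _iterate(bundle, sbundle, calib, state, h, spec)


def run_projection_from_state(bundle: InputBundle, scenario: ScenarioSpec,
                              state0: PopulationState, horizon: int
                              ) -> ProjectionResult:
    """Project from an explicit starting state (e.g. an empirical sample).

    Calibration still comes from the reference ``bundle``; the scenario
    contributes its transformed transition rates.  Used to compare the
    deterministic engine against a stochastic microsimulation started from
    the identical sampled population.
    """
    from .scenarios import build_scenario_bundle

    calib = Calibration.from_bundle(bundle)
    sbundle = build_scenario_bundle(bundle, scenario)
    return _iterate(bundle, sbundle, calib, state0.copy(), int(horizon), scenario)


def _iterate(bundle, sbundle, calib, state, h, spec):
    A = bundle.age_max + 1
    deaths = np.zeros((h, A, 2))
    exits = np.zeros((h, 2))
    states = [state]
    for i in range(h):
        state, d, x = step_year(state, sbundle, calib)
        deaths[i] = d
        exits[i] = x
        states.append(state)
    years = bundle.baseline_year + np.arange(h + 1)
    return ProjectionResult(years=years, states=states, deaths=deaths,
                            exits=exits, scenario=spec,
                            disease_names=bundle.disease_names())
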