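"""Core domain containers for the smoking multi-state projection model.

Everything "by age and sex" lives in an :class:`AgeSexTable`: a dense float
array over single years of age ``0..age_max`` (closed at ``age_max``;
everyone alive there exits at the end of that year) and a two-level sex
category (``male``, ``female``).

Smoking status is a partition of each (age, sex) cell into never smokers,
current smokers, and former smokers stratified by whole years since
quitting.  The last time-since-quit class is open-ended (e.g. "10+ years"),
so with ``n_quit_classes = 11`` the strata are 0, 1, ..., 9, 10+.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
import numpy as np

SEXES: tuple[str, str] = ("male", "female")
DEFAULT_AGE_MAX = 105
DEFAULT_N_QUIT_CLASSES = 11

#: indices of the fixed smoking classes in any class-stacked array
NEVER, CURRENT, FORMER0 = 0, 1, 2


def sex_index(sex: str) -> int:
    try:
        return SEXES.index(sex)
    except ValueError:
        raise KeyError(f"unknown sex {sex!r}; expected one of {SEXES}") from None


def class_labels(n_quit_classes: int) -> list[str]:
    """Ordered labels: never, current, former_0, ..., former_{n-1}."""
    return ["never", "current"] + [f"former_{k}" for k in range(n_quit_classes)]


def _arrays_equal(a, b) -> bool:
    if isinstance(a, np.ndarray) or isinstance(b, np.ndarray):
        return isinstance(a, np.ndarray) and isinstance(b, np.ndarray) and \
            a.shape == b.shape and np.array_equal(a, b)
    if isinstance(a, (tuple, list)) and isinstance(b, (tuple, list)):
        return len(a) == len(b) and all(_arrays_equal(x, y) for x, y in zip(a, b))
    return a == b


class _ArrayEqMixin:
    """Field-by-field equality that treats numpy arrays elementwise."""

    def __eq__(self, other):
        if type(other) is not type(self):
            return NotImplemented
        return all(
            _arrays_equal(getattr(self, f.name), getattr(other, f.name))
            for f in fields(self)
        )

    __hash__ = None


@dataclass(eq=False)
class AgeSexTable(_ArrayEqMixin):
    """A real value per (age, sex) cell.

    Parameters
    ----------
    values : ndarray, shape (age_max + 1, 2)
        Column 0 is male, column 1 is female.
    """

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 2:
            raise ValueError(
                f"AgeSexTable expects shape (n_ages, 2), got {self.values.shape}"
            )

    @property
    def age_max(self) -> int:
        return self.values.shape[0] - 1

    @property
    def ages(self) -> np.ndarray:
        return np.arange(self.values.shape[0])

    def __getitem__(self, key) -> float:
        age, sex = key
        return float(self.values[age, sex_index(sex)])

    @classmethod
    def constant(cls, value: float, age_max: int = DEFAULT_AGE_MAX) -> "AgeSexTable":
        return cls(np.full((age_max + 1, 2), float(value)))

    @classmethod
    def from_function(cls, fn, age_max: int = DEFAULT_AGE_MAX) -> "AgeSexTable":
        """Build from ``fn(ages, sex_label) -> array`` evaluated per sex."""
        ages = np.arange(age_max + 1)
        cols = [np.broadcast_to(np.asarray(fn(ages, s), float), ages.shape)
                for s in SEXES]
        return cls(np.column_stack(cols))

    def copy(self) -> "AgeSexTable":
        return AgeSexTable(self.values.copy())


@dataclass(eq=False)
class SmokingStateDistribution(_ArrayEqMixin):
    """Per (age, sex) fractions over the smoking classes.

    ``former`` has shape (n_ages, 2, n_quit_classes); below the adult-data
    age the whole former mass may be zero (youth surveys distinguish only
    smoker vs non-smoker).
    """

    never: np.ndarray
    current: np.ndarray
    former: np.ndarray

    def __post_init__(self):
        self.never = np.asarray(self.never, float)
        self.current = np.asarray(self.current, float)
        self.former = np.asarray(self.former, float)
        if self.former.shape[:2] != self.never.shape or \
                self.current.shape != self.never.shape:
            raise ValueError("inconsistent array shapes in SmokingStateDistribution")

    @property
    def age_max(self) -> int:
        return self.never.shape[0] - 1

    @property
    def n_quit_classes(self) -> int:
        return self.former.shape[2]

    @property
    def n_classes(self) -> int:
        return 2 + self.n_quit_classes

    def former_total(self) -> np.ndarray:
        return self.former.sum(axis=2)

    def as_matrix(self) -> np.ndarray:
        """Stack to shape (n_ages, 2, n_classes): never, current, former_k."""
        return np.concatenate(
            [self.never[:, :, None], self.current[:, :, None], self.former], axis=2
        )

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "SmokingStateDistribution":
        return cls(m[:, :, NEVER], m[:, :, CURRENT], m[:, :, FORMER0:].copy())

    def copy(self) -> "SmokingStateDistribution":
        return SmokingStateDistribution(
            self.never.copy(), self.current.copy(), self.former.copy()
        )


@dataclass(eq=False)
class TransitionRateSet(_ArrayEqMixin):
    """Annual transition probabilities between smoking classes.

    ``start`` moves never -> current (a *net* uptake rate at adolescent
    ages), ``quit`` moves current -> former_0, ``restart`` moves any former
    class back to current.
    """

    start: AgeSexTable
    quit: AgeSexTable
    restart: AgeSexTable

    def copy(self) -> "TransitionRateSet":
        return TransitionRateSet(self.start.copy(), self.quit.copy(), self.restart.copy())


@dataclass(eq=False)
class DiseaseDefinition(_ArrayEqMixin):
    """One chronic disease: IPM tables plus incidence relative risks.

    ``incidence`` is the population-average rate (events per person-year);
    the engine calibrates the never-smoker rate so that the share-weighted
    class rates reproduce it.  ``excess_mortality`` is the additional death
    rate among the diseased over the disease-free.  Relative risks are per
    age (shared across sexes): ``rr_current`` shape (n_ages,), ``rr_former``
    shape (n_ages, n_quit_classes); never smokers are the reference (RR 1).
    """

    name: str
    incidence: AgeSexTable
    prevalence: AgeSexTable
    excess_mortality: AgeSexTable
    rr_current: np.ndarray
    rr_former: np.ndarray

    def __post_init__(self):
        self.rr_current = np.asarray(self.rr_current, float)
        self.rr_former = np.asarray(self.rr_former, float)

    def rr_by_class(self) -> np.ndarray:
        """Relative risks stacked to shape (n_ages, n_classes)."""
        ones = np.ones_like(self.rr_current)
        return np.column_stack([ones, self.rr_current, self.rr_former])


@dataclass(eq=False)
class MortalitySpec(_ArrayEqMixin):
    """All-cause mortality and the all-cause relative risks of smoking.

    The all-cause RRs capture the mortality effect of smoking through
    diseases *not* modelled explicitly; the engine splits total mortality
    into class-specific totals that are consistent with both the
    population-average rate and these RRs.
    """

    m_total: AgeSexTable
    rr_allcause_current: np.ndarray
    rr_allcause_former: np.ndarray

    def __post_init__(self):
        self.rr_allcause_current = np.asarray(self.rr_allcause_current, float)
        self.rr_allcause_former = np.asarray(self.rr_allcause_former, float)

    def rr_by_class(self) -> np.ndarray:
        ones = np.ones_like(self.rr_allcause_current)
        return np.column_stack([ones, self.rr_allcause_current, self.rr_allcause_former])


@dataclass(eq=False)
class Demography(_ArrayEqMixin):
    """Baseline population counts and future newborn counts.

    ``newborns`` has shape (n_years, 2): row ``t - 1`` enters at age 0 in
    projection year ``baseline_year + t``.  Projections longer than the
    table repeat the last row.
    """

    population: AgeSexTable
    newborns: np.ndarray

    def __post_init__(self):
        self.newborns = np.atleast_2d(np.asarray(self.newborns, float))

    def newborns_in_step(self, t: int) -> np.ndarray:
        """Newborn counts (male, female) entering at the end of step t >= 1."""
        i = min(t - 1, self.newborns.shape[0] - 1)
        return self.newborns[i]


@dataclass(eq=False)
class InputBundle(_ArrayEqMixin):
    """Everything a projection needs, by age and sex."""

    demography: Demography
    smoking: SmokingStateDistribution
    rates: TransitionRateSet
    diseases: tuple[DiseaseDefinition, ...]
    mortality: MortalitySpec
    baseline_year: int = 2010

    def __post_init__(self):
        self.diseases = tuple(self.diseases)

    @property
    def age_max(self) -> int:
        return self.smoking.age_max

    @property
    def n_quit_classes(self) -> int:
        return self.smoking.n_quit_classes

    @property
    def n_classes(self) -> int:
        return self.smoking.n_classes

    def disease(self, name: str) -> DiseaseDefinition:
        for d in self.diseases:
            if d.name == name:
                return d
        raise KeyError(f"no disease named {name!r}")

    def disease_names(self) -> list[str]:
        return [d.name for d in self.diseases]

    def copy(self) -> "InputBundle":
        return InputBundle(
            demography=Demography(self.demography.population.copy(),
                                  self.demography.newborns.copy()),
            smoking=self.smoking.copy(),
            rates=self.rates.copy(),
            diseases=tuple(
                DiseaseDefinition(d.name, d.incidence.copy(), d.prevalence.copy(),
                                  d.excess_mortality.copy(), d.rr_current.copy(),
                                  d.rr_former.copy())
                for d in self.diseases
            ),
            mortality=MortalitySpec(self.mortality.m_total.copy(),
                                    self.mortality.rr_allcause_current.copy(),
                                    self.mortality.rr_allcause_former.copy()),
            baseline_year=self.baseline_year,
        )


VARIANTS = ("reference", "cessation", "initiation", "price_policy")


@dataclass
class ScenarioSpec:
    """Declarative description of one intervention scenario.

    Only the fields relevant to ``variant`` are used:

    - ``cessation``: ``quit_or`` (odds ratio on the annual quit
      probability), ``reach``, ``target_ages``.
    - ``initiation``: ``start_reduction`` (proportional cut of the start
      rate), ``reach``, ``target_ages``.
    - ``price_policy``: ``price_increase`` (proportional price change),
      youth/adult prevalence elasticities, ``youth_max_age`` (last age using
      the youth elasticity), and ``restart_multiplier`` (Table-style scaling
      of restart rates; the string ``"derived"`` uses one minus the youth
      prevalence reduction instead).
    """

    variant: str = "reference"
    quit_or: float = 1.0
    start_reduction: float = 0.0
    price_increase: float = 0.0
    elasticity_youth: float = -0.7
    elasticity_adult: float = -0.4
    youth_max_age: int = 20
    restart_multiplier: float | str = "derived"
    reach: float = 1.0
    target_ages: tuple[int, int] = (0, DEFAULT_AGE_MAX)
    horizon_years: int = 50
    name: str = ""

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown scenario variant {self.variant!r}")
        if not 0.0 <= self.reach <= 1.0:
            raise ValueError("reach must be in [0, 1]")
        if self.variant == "cessation" and self.quit_or <= 0:
            raise ValueError("quit_or must be > 0")
        if self.variant == "initiation" and not 0.0 <= self.start_reduction <= 1.0:
            raise ValueError("start_reduction must be in [0, 1]")
        if self.variant == "price_policy":
            if self.price_increase < 0:
                raise ValueError("price_increase must be >= 0")
            for e in (self.elasticity_youth, self.elasticity_adult):
                if abs(e) * self.price_increase > 1.0 + 1e-12:
                    raise ValueError(
                        "elasticity x price_increase implies a prevalence "
                        "reduction above 100%"
                    )
            if self.restart_multiplier != "derived" and not \
                    0.0 <= float(self.restart_multiplier) <= 1.0:
                raise ValueError("restart_multiplier must be in [0, 1] or 'derived'")
        self.target_ages = (int(self.target_ages[0]), int(self.target_ages[1]))

    def to_dict(self) -> dict:
        d = {"variant": self.variant, "reach": self.reach,
             "target_ages": list(self.target_ages),
             "horizon_years": self.horizon_years}
        if self.name:
            d["name"] = self.name
        if self.variant == "cessation":
            d["quit_or"] = self.quit_or
        elif self.variant == "initiation":
            d["start_reduction"] = self.start_reduction
        elif self.variant == "price_policy":
            d.update(price_increase=self.price_increase,
                     elasticity_youth=self.elasticity_youth,
                     elasticity_adult=self.elasticity_adult,
                     youth_max_age=self.youth_max_age,
                     restart_multiplier=self.restart_multiplier)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioSpec":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown scenario fields: {sorted(unknown)}")
        d = dict(d)
        if "target_ages" in d:
            d["target_ages"] = tuple(d["target_ages"])
        return cls(**d)


REFERENCE = ScenarioSpec(variant="reference", name="reference")
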