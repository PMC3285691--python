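"""Reduce projection results to reporting surfaces.

Smoking-prevalence series and age profiles, disease point prevalence
(including "at least one disease" under independence), excess deaths
versus the reference run, and period (disease-free) life expectancy via
the Sullivan method.

Sign convention for comparisons: ``difference = reference - scenario``, so
positive numbers are cases or deaths averted by the intervention.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .engine import ProjectionResult
from .types import FORMER0, sex_index

__all__ = [
    "smoking_prevalence_series", "smoking_prevalence_by_age",
    "disease_point_prevalence", "at_least_one_disease",
    "at_least_one_fraction_by_age", "excess_deaths_series",
    "period_life_expectancy", "life_expectancy", "comparison_table",
]


def _class_counts(state, age_range=None):
    counts = state.count
    if age_range is not None:
        lo, hi = age_range
        counts = counts[lo:hi + 1]
    return counts


def smoking_prevalence_series(result: ProjectionResult,
                              age_range: tuple[int, int] | None = None
                              ) -> pd.DataFrame:
    """Never/current/former fractions of the living population per year.

    ``former`` aggregates all time-since-quit classes.  ``age_range``
    restricts the population (inclusive bounds), e.g. ``(15, 105)`` for the
    adult series.
    """
    rows = []
    for year, state in zip(result.years, result.states):
        c = _class_counts(state, age_range).sum(axis=(0, 1))
        total = c.sum()
        frac = c / total if total > 0 else np.zeros_like(c)
        rows.append({"year": int(year), "never": frac[0], "current": frac[1],
                     "former": frac[FORMER0:].sum()})
    return pd.DataFrame(rows).set_index("year")


def smoking_prevalence_by_age(result: ProjectionResult, year: int) -> pd.DataFrame:
    """Age profile of the three aggregated smoking classes in one year."""
    state = result.state_at(year)
    c = state.count.sum(axis=1)                      # (A, C)
    total = c.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, c / total, 0.0)
    return pd.DataFrame({
        "age": np.arange(c.shape[0]),
        "never": frac[:, 0], "current": frac[:, 1],
        "former": frac[:, FORMER0:].sum(axis=1),
    }).set_index("age")


def disease_point_prevalence(result: ProjectionResult, year: int,
                             disease: str) -> float:
    """Number of prevalent cases of one disease at the start of ``year``."""
    try:
        j = result.disease_names.index(disease)
    except ValueError:
        raise KeyError(f"no disease named {disease!r} in this projection") from None
    state = result.state_at(year)
    return float((state.count * state.disease_prev[j]).sum())


def at_least_one_fraction_by_age(result: ProjectionResult, year: int,
                                 sex: str | None = None) -> np.ndarray:
    """Fraction of each age with at least one modelled disease.

    Diseases are combined under within-cell independence:
    ``1 - prod_d (1 - prev_d)``.
    """
    state = result.state_at(year)
    frac_cell = 1.0 - np.prod(1.0 - state.disease_prev, axis=0)   # (A, S, C)
    counts = state.count
    if sex is not None:
        si = sex_index(sex)
        counts = counts[:, si:si + 1]
        frac_cell = frac_cell[:, si:si + 1]
    num = (counts * frac_cell).sum(axis=(1, 2))
    den = counts.sum(axis=(1, 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, 0.0)


def at_least_one_disease(result: ProjectionResult, year: int) -> float:
    """Number of people with at least one modelled disease at ``year``."""
    if not result.disease_names:
        return 0.0
    state = result.state_at(year)
    frac_cell = 1.0 - np.prod(1.0 - state.disease_prev, axis=0)
    return float((state.count * frac_cell).sum())


def excess_deaths_series(scenario_result: ProjectionResult,
                         reference_result: ProjectionResult) -> pd.Series:
    """Per-year difference in total deaths, scenario minus reference.

    Negative values mean the intervention saves lives that year; the series
    typically rises back toward zero later as the saved, older population
    eventually dies of something.
    """
    if scenario_result.horizon != reference_result.horizon or \
            scenario_result.baseline_year != reference_result.baseline_year:
        raise ValueError("projections cover different year ranges")
    diff = scenario_result.deaths.sum(axis=(1, 2)) - \
        reference_result.deaths.sum(axis=(1, 2))
    years = scenario_result.years[:-1]
    return pd.Series(diff, index=pd.Index(years, name="year"), name="excess_deaths")


def period_life_expectancy(q: np.ndarray, health_weights: np.ndarray | None = None
                           ) -> float:
    """Life expectancy at age 0 from age-specific death probabilities.

    Standard period life table with the midpoint person-year convention
    ``L(a) = (l(a) + l(a+1)) / 2``.  ``health_weights`` (Sullivan method)
    multiply each ``L(a)`` by the fraction of that age in good health,
    giving health-weighted (here: disease-free) life expectancy.
    """
    q = np.clip(np.asarray(q, float), 0.0, 1.0)
    survival = np.concatenate([[1.0], np.cumprod(1.0 - q)])
    L = 0.5 * (survival[:-1] + survival[1:])
    if health_weights is not None:
        L = L * np.clip(np.asarray(health_weights, float), 0.0, 1.0)
    return float(L.sum())


def life_expectancy(result: ProjectionResult, year: int, sex: str,
                    mode: str = "total") -> float:
    """Period (disease-free) life expectancy at birth in one projection year.

    Death probabilities are that year's simulated deaths over the
    start-of-year population; the top age is closed (probability 1).
    ``mode="disease_free"`` weights person-years by the fraction free of
    every modelled disease (Sullivan method).  Requires ``year`` strictly
    inside the horizon, since deaths during the final projected year are
    not simulated.
    """
    if mode not in ("total", "disease_free"):
        raise ValueError("mode must be 'total' or 'disease_free'")
    i = int(year) - result.baseline_year
    if not 0 <= i < result.horizon:
        raise KeyError(
            f"year {year} has no simulated deaths (projection "
            f"{result.baseline_year}..{result.baseline_year + result.horizon - 1})")
    si = sex_index(sex)
    pop = result.states[i].count[:, si].sum(axis=1)
    deaths = result.deaths[i, :, si]
    if np.any(pop <= 0):
        first_zero = int(np.argmax(pop <= 0))
        warnings.warn(
            f"zero population at age {first_zero}; life table truncated there",
            stacklevel=2)
        pop = pop[:first_zero]
        deaths = deaths[:first_zero]
        if first_zero == 0:
            return 0.0
    q = np.clip(deaths / pop, 0.0, 1.0)
    q[-1] = 1.0                       # closed top age: everyone exits
    weights = None
    if mode == "disease_free":
        weights = 1.0 - at_least_one_fraction_by_age(result, year, sex)[:len(q)]
    return period_life_expectancy(q, weights)


def comparison_table(reference_result: ProjectionResult,
                     scenario_result: ProjectionResult,
                     diseases: list[str], years: list[int]) -> pd.DataFrame:
    """Reference vs scenario point prevalence with cases averted.

    One row per (year, outcome); outcomes are the requested diseases plus
    ``"at_least_one_disease"``.  ``difference = reference - scenario``.
    """
    rows = []
    for year in years:
        for name in diseases:
            ref = disease_point_prevalence(reference_result, year, name)
            scen = disease_point_prevalence(scenario_result, year, name)
            rows.append({"year": year, "outcome": name,
                         "reference": ref, "scenario": scen,
                         "difference": ref - scen})
        ref = at_least_one_disease(reference_result, year)
        scen = at_least_one_disease(scenario_result, year)
        rows.append({"year": year, "outcome": "at_least_one_disease",
                     "reference": ref, "scenario": scen,
                     "difference": ref - scen})
    return pd.DataFrame(rows)
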