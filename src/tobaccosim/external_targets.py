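"""Published Dutch national results usable only as external validation.

The original Dutch application of this model family reported headline
numbers computed from the national DYNAMO-HIA database (baseline
demography, smoking prevalence and transition rates, and nine-disease IPM
tables with their relative risks).  Those inputs are not redistributable
and are not bundled here, so the numbers below CANNOT be recomputed from
this package alone: they are documentation for anyone who obtains the
national input bundle (www.dynamo-hia.eu) and wants to cross-check a run.

Every entry has ``requires_national_data=True``; nothing in this package
computes, fits or calibrates against these values.  The shipped validation
surface is instead the qualitative property suite on the synthetic bundle
(scenario ordering, timing patterns, sign shapes), which does not depend
on the national data.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ExternalTarget:
    """One published number, with the inputs needed to reproduce it."""

    description: str
    value: float
    units: str
    requires_national_data: bool = True


EXTERNAL_VALIDATION_TARGETS: dict[str, ExternalTarget] = {
    "baseline_lung_cancer_prevalence_2010": ExternalTarget(
        "Point prevalence of lung cancer in the Netherlands at baseline",
        12_863, "persons"),
    "baseline_copd_prevalence_2010": ExternalTarget(
        "Point prevalence of COPD at baseline", 211_798, "persons"),
    "baseline_ihd_prevalence_2010": ExternalTarget(
        "Point prevalence of ischemic heart disease at baseline",
        508_596, "persons"),
    "baseline_at_least_one_disease_2010": ExternalTarget(
        "Persons with at least one of the nine modelled diseases at baseline",
        1_483_769, "persons"),
    "baseline_deaths_2010": ExternalTarget(
        "All-cause deaths in the baseline year", 125_650, "deaths/year"),
    "smoker_prevalence_2035_reference": ExternalTarget(
        "Current-smoker prevalence in 2035, business-as-usual",
        0.20, "fraction"),
    "smoker_prevalence_2035_cessation_max": ExternalTarget(
        "Current-smoker prevalence in 2035 under the maximum cessation "
        "intervention", 0.14, "fraction"),
    "lung_cancer_cases_averted_2035_cessation_max": ExternalTarget(
        "Lung-cancer point-prevalence reduction vs reference in 2035, "
        "maximum cessation scenario", 2_957, "persons"),
    "lung_cancer_cases_averted_2035_initiation_max": ExternalTarget(
        "Lung-cancer point-prevalence reduction vs reference in 2035, "
        "maximum initiation scenario", 3, "persons"),
    "lung_cancer_cases_averted_2035_price_max": ExternalTarget(
        "Lung-cancer point-prevalence reduction vs reference in 2035, "
        "maximum population-wide price policy", 5_044, "persons"),
    "hle_men_2010_baseline": ExternalTarget(
        "Healthy life expectancy of men at baseline", 68.26, "years"),
    "hle_women_2010_baseline": ExternalTarget(
        "Healthy life expectancy of women at baseline", 71.45, "years"),
    "hle_men_2035_price_max": ExternalTarget(
        "Healthy life expectancy of men in 2035 under the maximum price "
        "policy", 70.79, "years"),
}
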