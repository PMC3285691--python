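"""Turn a reference input bundle into an intervention bundle.

Three intervention families are supported, mirroring the classic tobacco
control repertoire:

- **cessation** — an intervention raising the odds of quitting among adult
  smokers (odds ratio on the annual quit probability);
- **initiation** — a school-based programme proportionally cutting the
  adolescent smoking start rate;
- **price_policy** — a population-wide price increase acting through
  prevalence elasticities: an immediate prevalence shock (adults quit into
  the freshest time-since-quit class, adolescents stay never smokers),
  start rates re-derived so future cohorts keep the lower adolescent
  prevalence, and restart rates scaled down.

Reach (the fraction of the target population actually exposed) enters as a
deterministic mixture: a fraction ``reach`` experiences the transformed
rate, the rest keeps the reference rate.  Effects therefore interpolate
linearly between the reference (reach 0) and the maximum scenario
(reach 1).
"""

from __future__ import annotations

import numpy as np

from . import lifetable
from .types import AgeSexTable, InputBundle, ScenarioSpec, SEXES

__all__ = [
    "transform_quit_rates_or", "transform_start_rates",
    "prevalence_reduction_from_price", "apply_price_policy",
    "build_scenario_bundle", "PRESETS", "get_preset",
]


def _age_mask(ages: np.ndarray, target_ages: tuple[int, int]) -> np.ndarray:
    lo, hi = target_ages
    return (ages >= lo) & (ages <= hi)


def transform_quit_rates_or(quit: AgeSexTable, quit_or: float, reach: float = 1.0,
                            target_ages: tuple[int, int] = (0, 10**9)) -> AgeSexTable:
    """Apply an odds ratio to annual quit probabilities within target ages.

    Each probability ``q`` becomes ``sigma(quit_or * odds(q))`` where
    ``odds(q) = q / (1 - q)`` and ``sigma`` is its inverse; for small ``q``
    an OR of 2 roughly doubles the quit rate.  With partial ``reach`` the
    result is the mixture ``reach * q_transformed + (1 - reach) * q``.
    """
    if quit_or <= 0:
        raise ValueError("quit_or must be > 0")
    q = quit.values
    mask = _age_mask(quit.ages, target_ages)[:, None]
    if np.any((q >= 1.0) & mask):
        raise ValueError("quit probability of 1 has undefined odds")
    with np.errstate(divide="ignore", invalid="ignore"):
        odds = np.where(q < 1.0, q / (1.0 - q), np.inf)
    q_new = (quit_or * odds) / (1.0 + quit_or * odds)
    mixed = reach * q_new + (1.0 - reach) * q
    return AgeSexTable(np.where(mask, mixed, q))


def transform_start_rates(start: AgeSexTable, start_reduction: float,
                          reach: float = 1.0,
                          target_ages: tuple[int, int] = (0, 10**9)) -> AgeSexTable:
    """Proportionally reduce start rates: ``s' = (1 - reach*reduction) s``."""
    if not 0.0 <= start_reduction <= 1.0:
        raise ValueError("start_reduction must be in [0, 1]")
    mask = _age_mask(start.ages, target_ages)[:, None]
    s = start.values
    return AgeSexTable(np.where(mask, (1.0 - reach * start_reduction) * s, s))


def prevalence_reduction_from_price(price_increase: float, elasticity: float) -> float:
    """Proportional drop in smoking prevalence implied by a price increase.

    A prevalence elasticity of e.g. -0.4 means a 95% price increase lowers
    prevalence by 0.4 * 0.95 = 38%.
    """
    reduction = abs(elasticity) * price_increase
    if reduction > 1.0 + 1e-12:
        raise ValueError(
            f"elasticity {elasticity} at price increase {price_increase:+.0%} "
            "implies a prevalence reduction above 100%")
    return reduction


def apply_price_policy(bundle: InputBundle, spec: ScenarioSpec) -> InputBundle:
    """Population-wide price increase acting on prevalence and rates.

    Adults (above ``youth_max_age``) quit immediately: the current-smoker
    fraction shrinks by the adult reduction and the removed mass enters
    former_0; their start and quit rates are untouched.  Adolescents and
    young adults never start: current shrinks by the youth reduction, the
    mass moves to never, and adolescent start rates are re-derived from the
    scaled non-smoker curve so future cohorts hold the lower prevalence.
    Restart rates are scaled by ``restart_multiplier`` everywhere
    ("derived" uses one minus the youth reduction, i.e. the same
    proportional cut as the start rates).
    """
    if spec.variant != "price_policy":
        raise ValueError("spec.variant must be 'price_policy'")
    r_youth = spec.reach * prevalence_reduction_from_price(
        spec.price_increase, spec.elasticity_youth)
    r_adult = spec.reach * prevalence_reduction_from_price(
        spec.price_increase, spec.elasticity_adult)
    if r_youth == 0.0 and r_adult == 0.0:
        return bundle.copy()

    out = bundle.copy()
    ages = out.rates.start.ages
    youth = ages <= spec.youth_max_age

    cur = out.smoking.current
    removed_y = cur * r_youth * youth[:, None]
    removed_a = cur * r_adult * (~youth)[:, None]
    out.smoking.current = cur - removed_y - removed_a
    out.smoking.never = out.smoking.never + removed_y
    out.smoking.former[:, :, 0] += removed_a[:, :]

    # adolescent start rates consistent with the scaled smoker prevalence
    lo = lifetable.DEFAULT_ADOLESCENT_AGES[0]
    hi = spec.youth_max_age
    window = np.arange(lo, hi + 1)
    for si, sex in enumerate(SEXES):
        smoker_ref = bundle.smoking.current[window, si]
        target = lifetable.NonSmokerPrevalenceCurve(
            ages=window, p_ns=1.0 - (1.0 - r_youth) * smoker_ref, sex=sex)
        rates = lifetable.start_rates_for_target_prevalence(target)
        out.rates.start.values[window[:-1], si] = rates

    mult = (1.0 - r_youth) if spec.restart_multiplier == "derived" else \
        spec.reach * float(spec.restart_multiplier) + (1.0 - spec.reach)
    out.rates.restart.values *= mult
    return out


def build_scenario_bundle(bundle: InputBundle, spec: ScenarioSpec) -> InputBundle:
    """Dispatch a scenario transform; the reference passes through untouched.

    Cessation touches only quit rates, initiation only start rates, the
    price policy touches year-0 prevalence plus start and restart rates.
    All transformed rates are constant over the projection period.
    """
    if spec.variant == "reference":
        return bundle.copy()
    if spec.variant == "cessation":
        out = bundle.copy()
        out.rates.quit = transform_quit_rates_or(
            bundle.rates.quit, spec.quit_or, spec.reach, spec.target_ages)
        return out
    if spec.variant == "initiation":
        out = bundle.copy()
        out.rates.start = transform_start_rates(
            bundle.rates.start, spec.start_reduction, spec.reach, spec.target_ages)
        return out
    if spec.variant == "price_policy":
        return apply_price_policy(bundle, spec)
    raise ValueError(f"unknown scenario variant {spec.variant!r}")


def _presets() -> dict[str, ScenarioSpec]:
    """Shipped scenario presets: maximum and realistic variants of each type.

    The realistic cessation reach of 20% combines 40% of smokers wanting to
    quit with 50% of those actually participating; the price policy reaches
    the whole population in both variants.
    """
    return {
        "table1_max_cessation": ScenarioSpec(
            variant="cessation", quit_or=2.0, reach=1.0,
            target_ages=(18, 105), name="table1_max_cessation"),
        "table1_realistic_cessation": ScenarioSpec(
            variant="cessation", quit_or=2.0, reach=0.40 * 0.50,
            target_ages=(18, 105), name="table1_realistic_cessation"),
        "table1_max_initiation": ScenarioSpec(
            variant="initiation", start_reduction=0.5, reach=1.0,
            target_ages=(10, 18), name="table1_max_initiation"),
        "table1_realistic_initiation": ScenarioSpec(
            variant="initiation", start_reduction=0.2, reach=0.5,
            target_ages=(10, 18), name="table1_realistic_initiation"),
        "table1_max_price": ScenarioSpec(
            variant="price_policy", price_increase=0.95,
            restart_multiplier=0.30, reach=1.0,
            name="table1_max_price"),
        "table1_realistic_price": ScenarioSpec(
            variant="price_policy", price_increase=0.20,
            restart_multiplier=0.80, reach=1.0,
            name="table1_realistic_price"),
    }


PRESETS = _presets()


def get_preset(name: str) -> ScenarioSpec:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None
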