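"""Net smoking-initiation rates from adolescent non-smoker prevalence.

Adolescent surveys report only smoker vs non-smoker status, so gross start
and quit flows cannot be separated.  Instead the cross-sectional non-smoker
prevalence curve is read as a life table of a cohort of non-smokers whose
membership shrinks only through (net) smoking uptake:

    l(a + 1) = l(a) * (1 - s(a))   =>   s(a) = (p(a) - p(a + 1)) / p(a)

where ``p(a)`` is the non-smoker fraction at age ``a``.  "Net" means
quitting at these ages is folded in: if 100 adolescents start and 4 quit,
the modelled uptake is 96.  The same algebra, applied to a scaled target
curve, yields the start rates that keep a post-intervention adolescent
smoking prevalence in place for future cohorts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

#: first age at which survey-based adult transition rates take over
DEFAULT_HANDOFF_AGE = 16
#: default adolescent estimation window (inclusive)
DEFAULT_ADOLESCENT_AGES = (10, 18)


@dataclass
class NonSmokerPrevalenceCurve:
    """Non-smoker fraction over a contiguous adolescent age range."""

    ages: np.ndarray
    p_ns: np.ndarray
    sex: str = "male"

    def __post_init__(self):
        self.ages = np.asarray(self.ages, int)
        self.p_ns = np.asarray(self.p_ns, float)
        if self.ages.shape != self.p_ns.shape or self.ages.ndim != 1:
            raise ValueError("ages and p_ns must be 1-d arrays of equal length")
        if self.ages.size < 2:
            raise ValueError("need at least two ages to estimate a rate")
        if np.any(np.diff(self.ages) != 1):
            raise ValueError("ages must be contiguous single years")
        if np.any((self.p_ns < 0) | (self.p_ns > 1)) or not np.all(np.isfinite(self.p_ns)):
            raise ValueError("p_ns values must be fractions in [0, 1]")


def net_start_rates_from_prevalence(curve: NonSmokerPrevalenceCurve) -> np.ndarray:
    """Annual net uptake probabilities ``s(a)`` for each age but the last.

    Returns an array aligned with ``curve.ages[:-1]``.  The rates are scale
    free (only prevalence ratios matter) and reproduce the input curve
    exactly when run forward as ``l(a+1) = l(a) (1 - s(a))``.

    Adjacent *increases* in non-smoker prevalence (sampling noise in survey
    data) would imply negative uptake; those rates are clamped to zero with
    a warning, since net uptake cannot be negative in the cohort model.
    """
    p = curve.p_ns
    if np.any(p[:-1] <= 0):
        bad = curve.ages[:-1][p[:-1] <= 0]
        raise ZeroDivisionError(
            f"non-smoker prevalence is 0 at age(s) {bad.tolist()} but a "
            "successor age exists; the start rate there is undefined")
    s = (p[:-1] - p[1:]) / p[:-1]
    if np.any(s < 0):
        ages = curve.ages[:-1][s < 0]
        warnings.warn(
            f"non-smoker prevalence increases after age(s) {ages.tolist()}; "
            "clamping implied negative start rates to 0", stacklevel=2)
        s = np.clip(s, 0.0, None)
    return s


def start_rates_for_target_prevalence(target: NonSmokerPrevalenceCurve) -> np.ndarray:
    """Start rates consistent with a target (post-intervention) curve.

    Identical algebra to :func:`net_start_rates_from_prevalence`; the
    argument is the scaled non-smoker curve an intervention aims to hold.
    Running the returned rates forward keeps each future cohort's adolescent
    smoking prevalence at the target level.
    """
    return net_start_rates_from_prevalence(target)


def cohort_prevalence_from_rates(p0: float, rates: np.ndarray) -> np.ndarray:
    """Forward life table: non-smoker fractions implied by start rates.

    Returns the full curve of length ``len(rates) + 1`` beginning at ``p0``.
    """
    out = np.empty(len(rates) + 1)
    out[0] = p0
    out[1:] = p0 * np.cumprod(1.0 - np.asarray(rates, float))
    return out
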