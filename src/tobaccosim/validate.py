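"""Input-bundle validation.

`validate_bundle` walks every invariant of the bundle and returns a report
of violations rather than raising, so callers can show everything wrong at
once.  `load_bundle` raises a :class:`BundleValidationError` wrapping the
report.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import SEXES, InputBundle

#: tolerance for smoking-class fractions summing to one
_SUM_TOL = 1e-9


@dataclass(frozen=True)
class Violation:
    """One invariant failure (or soft warning) located in a named table."""

    table: str
    location: str
    message: str
    warning: bool = False

    def __str__(self) -> str:
        kind = "warning" if self.warning else "error"
        return f"[{kind}] {self.table} at {self.location}: {self.message}"


class BundleValidationError(ValueError):
    def __init__(self, violations: list[Violation]):
        self.violations = violations
        lines = "\n".join(str(v) for v in violations)
        super().__init__(f"input bundle failed validation:\n{lines}")


def _check_range(report, table, values, lo=None, hi=None, sexed=True):
    values = np.asarray(values, float)
    bad = ~np.isfinite(values)
    if lo is not None:
        bad |= values < lo
    if hi is not None:
        bad |= values > hi
    for idx in np.argwhere(bad):
        age = int(idx[0])
        loc = f"age {age}"
        if sexed and len(idx) > 1:
            loc += f", {SEXES[int(idx[1])]}"
        bound = f"[{lo}, {hi}]" if hi is not None else f">= {lo}"
        report.append(Violation(table, loc, f"value {values[tuple(idx)]:g} out of {bound}"))


def validate_bundle(bundle: InputBundle) -> list[Violation]:
    """Check every bundle invariant; empty list means the bundle is valid.

    Non-monotone former-smoker relative risks produce warnings (real
    appendix tables are noisy), everything else is an error.
    """
    report: list[Violation] = []
    A = bundle.age_max

    shapes = {
        "population": bundle.demography.population.age_max,
        "mortality": bundle.mortality.m_total.age_max,
        "start": bundle.rates.start.age_max,
        "quit": bundle.rates.quit.age_max,
        "restart": bundle.rates.restart.age_max,
    }
    for d in bundle.diseases:
        shapes[f"{d.name}.incidence"] = d.incidence.age_max
    for name, amax in shapes.items():
        if amax != A:
            report.append(Violation(name, "shape", f"age_max {amax} != {A}"))
    if any(v.table == "shape" or v.location == "shape" for v in report):
        return report  # further checks would crash on misaligned arrays

    _check_range(report, "population", bundle.demography.population.values, lo=0.0)
    _check_range(report, "newborns", bundle.demography.newborns, lo=0.0, sexed=False)
    _check_range(report, "mortality", bundle.mortality.m_total.values, 0.0, 1.0)
    for rname in ("start", "quit", "restart"):
        _check_range(report, rname, getattr(bundle.rates, rname).values, 0.0, 1.0)

    m = bundle.smoking.as_matrix()
    _check_range(report, "smoking", m.min(axis=2), lo=0.0)
    _check_range(report, "smoking", m.max(axis=2), hi=1.0)
    sums = m.sum(axis=2)
    for idx in np.argwhere(np.abs(sums - 1.0) > _SUM_TOL):
        a, s = int(idx[0]), int(idx[1])
        report.append(Violation(
            "smoking", f"age {a}, {SEXES[s]}",
            f"class fractions sum to {sums[a, s]:.10g}, expected 1"))

    for d in bundle.diseases:
        _check_range(report, f"{d.name}.incidence", d.incidence.values, lo=0.0)
        _check_range(report, f"{d.name}.prevalence", d.prevalence.values, 0.0, 1.0)
        _check_range(report, f"{d.name}.excess_mortality", d.excess_mortality.values, 0.0, 1.0)
        _check_range(report, f"{d.name}.rr_current", d.rr_current[:, None], lo=0.0)
        _check_range(report, f"{d.name}.rr_former", d.rr_former, lo=0.0, sexed=False)
        # soft check: former-class RRs should decay from rr_current toward 1
        rr = np.column_stack([d.rr_current, d.rr_former, np.ones(A + 1)])
        rising = np.any(np.diff(rr, axis=1) > 1e-12, axis=1)
        lo_side = np.minimum(1.0, d.rr_current)[:, None]
        hi_side = np.maximum(1.0, d.rr_current)[:, None]
        outside = np.any((d.rr_former < lo_side - 1e-12) |
                         (d.rr_former > hi_side + 1e-12), axis=1)
        for a in np.flatnonzero(rising | outside):
            report.append(Violation(
                f"{d.name}.rr_former", f"age {int(a)}",
                "former-smoker RRs do not decay monotonically from "
                "rr_current toward 1", warning=True))

    _check_range(report, "rr_allcause_current",
                 bundle.mortality.rr_allcause_current[:, None], lo=0.0)
    _check_range(report, "rr_allcause_former",
                 bundle.mortality.rr_allcause_former, lo=0.0, sexed=False)
    return report


def errors_only(report: list[Violation]) -> list[Violation]:
    return [v for v in report if not v.warning]


def raise_on_errors(report: list[Violation]) -> None:
    errs = errors_only(report)
    if errs:
        raise BundleValidationError(errs)
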