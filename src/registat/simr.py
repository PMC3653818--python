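"""Standardized incidence / mortality ratio (SIR / SMR).

The ratio SIMR = D / E compares the observed event count D in a target
population with the count E expected if the target experienced the
age-specific rates of a reference population:

    E = sum_i r_ref,i * Y_target,i

E is the classical indirect-standardization expectation and is treated
as a known constant (no sampling error from the reference).  The default
confidence interval is the exact Poisson interval for D (chi-square
inversion); Byar's approximation is available for cross-checking against
software that uses it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import CoverageError, RegistatError, SchemeMismatchError

__all__ = ["SIMRResult", "expected_events", "simr_with_ci", "compare_populations"]


@dataclass(frozen=True)
class SIMRResult:
    observed: int
    expected: float
    simr: float
    ci_low: float
    ci_high: float
    level: float = 0.95
    method: str = "exact"

    @property
    def significant(self) -> bool:
        """True when the CI excludes the null ratio 1."""
        return not (self.ci_low <= 1.0 <= self.ci_high)

    def summary(self) -> str:
        flag = "significant" if self.significant else "not significant"
        return (
            f"SIMR = {self.simr:.3f} (D = {self.observed}, E = {self.expected:.2f})\n"
            f"  {int(self.level * 100)}% CI ({self.method}): "
            f"({self.ci_low:.3f}, {self.ci_high:.3f}) — {flag}"
        )


def expected_events(
    reference: pd.DataFrame,
    target_person_years: Mapping[int, float] | pd.Series,
) -> float:
    """Expected events in the target under the reference's age-specific
    rates: ``E = sum_i (C_ref,i / Y_ref,i) * Y_target,i``.

    ``reference`` is a counts slice (one sex/disease) with age_group,
    cases and person_years, pooled over its years; every target age group
    with positive person-years must have a reference rate.
    """
    pooled = (reference.groupby("age_group")[["cases", "person_years"]]
              .sum().sort_index())
    tpy = pd.Series(target_person_years, dtype=float).sort_index()
    active = tpy[tpy > 0]
    missing = active.index.difference(pooled.index)
    if len(missing):
        raise CoverageError(
            f"reference rates missing for target age group(s) "
            f"{missing.tolist()}")
    if (pooled.loc[active.index, "person_years"] <= 0).any():
        raise CoverageError("reference person-years must be > 0")
    rates = pooled["cases"] / pooled["person_years"]
    return float((rates.loc[active.index] * active).sum())


def _exact_poisson_ci(d: int, level: float) -> tuple[float, float]:
    a = 1.0 - level
    lo = 0.0 if d == 0 else stats.chi2.ppf(a / 2, 2 * d) / 2.0
    hi = stats.chi2.ppf(1 - a / 2, 2 * (d + 1)) / 2.0
    return lo, hi


def _byar_ci(d: int, level: float) -> tuple[float, float]:
    z = stats.norm.ppf(0.5 + level / 2)
    if d == 0:
        lo = 0.0
    else:
        lo = d * (1 - 1 / (9 * d) - z / (3 * np.sqrt(d))) ** 3
    dd = d + 1
    hi = dd * (1 - 1 / (9 * dd) + z / (3 * np.sqrt(dd))) ** 3
    return lo, hi


def simr_with_ci(observed: int, expected: float, *, level: float = 0.95,
                 method: str = "exact") -> SIMRResult:
    """Ratio D/E with a Poisson confidence interval for D/E.

    ``method='exact'`` inverts the chi-square (gamma) relation for a
    Poisson count; ``method='byar'`` uses Byar's cube-root approximation.
    """
    if expected <= 0:
        raise RegistatError(f"expected events must be > 0, got {expected}")
    if observed < 0:
        raise RegistatError("observed events must be >= 0")
    if method == "exact":
        lo, hi = _exact_poisson_ci(observed, level)
    elif method == "byar":
        lo, hi = _byar_ci(observed, level)
    else:
        raise ValueError("method must be 'exact' or 'byar'")
    return SIMRResult(
        observed=int(observed), expected=float(expected),
        simr=observed / expected,
        ci_low=lo / expected, ci_high=hi / expected,
        level=level, method=method,
    )


def compare_populations(reference: pd.DataFrame, target: pd.DataFrame,
                        *, level: float = 0.95, method: str = "exact"
                        ) -> SIMRResult:
    """SIMR of a target counts slice against a reference counts slice.

    Both slices must use the same age-group scheme; mismatched age-group
    sets are an error rather than silently re-binned.
    """
    ref_ages = set(reference["age_group"].unique())
    tgt = (target.groupby("age_group")[["cases", "person_years"]]
           .sum().sort_index())
    if not set(tgt.index).issubset(ref_ages):
        extra = sorted(set(tgt.index) - ref_ages)
        raise SchemeMismatchError(
            f"target age group(s) {extra} absent from the reference scheme")
    e = expected_events(reference, tgt["person_years"])
    d = int(tgt["cases"].sum())
    return simr_with_ci(d, e, level=level, method=method)
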