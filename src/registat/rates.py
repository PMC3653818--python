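"""Descriptive rate statistics for registry counts.

Implements the classical summary measures of descriptive epidemiology:

* crude rate ``CR = X / N`` (per 100,000 person-years);
* age-specific rates per age group;
* directly age-standardized rate ``ASR = sum(w_i r_i) / sum(w_i)`` using a
  standard population's age weights;
* truncated ASR over ages 35-64;
* cumulative rate ``CumR = sum(r_i * width_i)`` over ages 0-74 and the
  cumulative risk ``1 - exp(-CumR)``.

Rates are reported per 100,000 person-years; the cumulative rate is kept
on the proportion (dimensionless) scale so that ``risk = 1 - exp(-CumR)``
holds directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import CoverageError, RegistatError
from .io import AgeGroupScheme

__all__ = [
    "SEGI_WORLD_STANDARD",
    "RateSummary",
    "crude_rate",
    "age_specific_rates",
    "direct_standardized_rate",
    "truncated_rate",
    "cumulative_rate_and_risk",
    "rate_summary",
]

PER = 100_000.0

# Segi world standard population, 18 five-year age groups 0-4 ... 85+
# (weights sum to 100,000).  Used as the default for direct
# standardization; a user-supplied standard-population file overrides it.
SEGI_WORLD_STANDARD = pd.Series(
    [12000, 10000, 9000, 9000, 8000, 8000, 6000, 6000, 6000,
     6000, 5000, 4000, 4000, 3000, 2000, 1000, 500, 500],
    index=pd.RangeIndex(1, 19),
    name="weight",
    dtype=float,
)


def crude_rate(cases: float, person_years: float, *, per: float = PER) -> float:
    """Crude rate: cases over person-years, scaled per 100,000."""
    if person_years <= 0:
        raise RegistatError(f"person_years must be > 0, got {person_years}")
    if cases < 0:
        raise RegistatError(f"cases must be >= 0, got {cases}")
    return per * cases / person_years


def _pool_by_age(counts: pd.DataFrame) -> pd.DataFrame:
    """Pool a counts slice over years (and anything else) per age group."""
    return (counts.groupby("age_group")[["cases", "person_years"]]
            .sum().sort_index())


def age_specific_rates(counts: pd.DataFrame, *, per: float = PER) -> pd.Series:
    """Age-specific rates (per 100,000) from a counts slice for one
    sex/disease, pooled over the slice's years."""
    pooled = _pool_by_age(counts)
    if (pooled["person_years"] <= 0).any():
        bad = pooled.index[pooled["person_years"] <= 0].tolist()
        raise RegistatError(f"zero person-years in age group(s) {bad}")
    return per * pooled["cases"] / pooled["person_years"]


def direct_standardized_rate(
    counts: pd.DataFrame,
    std: pd.Series | None = None,
    *,
    per: float = PER,
) -> float:
    """Directly standardized rate: weighted mean of age-specific rates.

    ``std`` holds one positive weight per 1-based age-group index; the
    embedded world standard is the default.  An age group carrying
    positive weight must be present with positive person-years; groups
    absent from the weights (or weighted zero) are skipped.
    """
    std = SEGI_WORLD_STANDARD if std is None else std
    pooled = _pool_by_age(counts)
    std = std[std > 0]
    missing = std.index.difference(pooled.index)
    if len(missing):
        raise CoverageError(
            f"age group(s) {missing.tolist()} carry standard weight but are "
            "absent from the data"
        )
    sub = pooled.loc[std.index]
    if (sub["person_years"] <= 0).any():
        bad = sub.index[sub["person_years"] <= 0].tolist()
        raise CoverageError(
            f"age group(s) {bad} carry standard weight but have zero "
            "person-years")
    rates = per * sub["cases"] / sub["person_years"]
    return float((std * rates).sum() / std.sum())


def truncated_rate(
    counts: pd.DataFrame,
    std: pd.Series | None = None,
    scheme: AgeGroupScheme | None = None,
    *,
    lower: int = 35,
    upper: int = 64,
    per: float = PER,
) -> float:
    """ASR restricted to age groups fully inside ``[lower, upper + 1)``.

    The default 35-64 window is the conventional truncation used where
    diagnosis recording in the elderly is uncertain.  Standard weights are
    re-normalized within the window.
    """
    std = SEGI_WORLD_STANDARD if std is None else std
    scheme = scheme or AgeGroupScheme.default()
    keep = scheme.groups_within(lower, upper + 1)
    sub_counts = counts[counts["age_group"].isin(keep)]
    sub_std = std[std.index.isin(keep)]
    return direct_standardized_rate(sub_counts, sub_std, per=per)


def cumulative_rate_and_risk(
    counts: pd.DataFrame,
    scheme: AgeGroupScheme | None = None,
    *,
    max_age: int = 74,
) -> tuple[float, float]:
    """Cumulative rate over ages 0..max_age and the implied lifetime risk.

    ``CumR`` is the sum of age-specific rates (on the proportion scale,
    cases per person-year) times the group widths in years; the
    cumulative risk is ``1 - exp(-CumR)`` — the probability of developing
    the event before ``max_age + 1`` absent competing mortality.
    """
    from .exceptions import AlignmentError

    scheme = scheme or AgeGroupScheme.default()
    keep = scheme.groups_within(0, max_age + 1)
    covered = sum(scheme.width(k) for k in keep)
    if covered != max_age + 1:
        raise AlignmentError(
            f"scheme does not cover [0, {max_age + 1}) in closed intervals")
    pooled = _pool_by_age(counts)
    missing = [k for k in keep if k not in pooled.index]
    if missing:
        raise CoverageError(f"age group(s) {missing} absent from the data")
    cum = 0.0
    for k in keep:
        row = pooled.loc[k]
        if row["person_years"] <= 0:
            raise CoverageError(f"zero person-years in age group {k}")
        cum += scheme.width(k) * row["cases"] / row["person_years"]
    return float(cum), float(1.0 - np.exp(-cum))


@dataclass
class RateSummary:
    """Descriptive-rate summary for one sex x disease slice."""

    cases: int
    person_years: float
    crude_rate: float
    age_specific_rates: pd.Series = field(repr=False)
    asr: float
    truncated_asr: float
    cumulative_rate_0_74: float
    cumulative_risk_0_74: float

    def to_row(self) -> dict:
        return {
            "cases": self.cases,
            "person_years": self.person_years,
            "crude_rate": self.crude_rate,
            "asr": self.asr,
            "truncated_asr_35_64": self.truncated_asr,
            "cumulative_rate_0_74": self.cumulative_rate_0_74,
            "cumulative_risk_0_74": self.cumulative_risk_0_74,
        }


def rate_summary(
    counts: pd.DataFrame,
    std: pd.Series | None = None,
    scheme: AgeGroupScheme | None = None,
) -> RateSummary:
    """Full descriptive summary of one sex/disease slice (pooled over its
    years): crude rate, age-specific rates, ASR, truncated ASR 35-64,
    cumulative rate and risk to age 74."""
    cases = int(counts["cases"].sum())
    py = float(counts["person_years"].sum())
    cumr, risk = cumulative_rate_and_risk(counts, scheme)
    return RateSummary(
        cases=cases,
        person_years=py,
        crude_rate=crude_rate(cases, py),
        age_specific_rates=age_specific_rates(counts),
        asr=direct_standardized_rate(counts, std),
        truncated_asr=truncated_rate(counts, std, scheme),
        cumulative_rate_0_74=cumr,
        cumulative_risk_0_74=risk,
    )
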