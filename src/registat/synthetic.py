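"""Synthetic disease-registry generator with known ground truth.

Produces, from a compact :class:`RegistrySpec`, the full set of files the
analysis modules consume — individual records, aggregated counts,
population distribution, life table, age-group scheme and standard
population — together with a manifest of the analytic ground truth
implied by the generating parameters:

* case counts per sex x age-group x year cell are Poisson with mean
  ``rate_i * change^(year - first_year) * person_years``, so the true
  annual percent change of rates is ``(change - 1) * 100`` and the true
  between-period incidence ratio and net-change decomposition follow in
  closed form from the expected counts;
* each case receives a death time from an additive-hazard model —
  constant background hazard ``-log(background_survival)`` (matching the
  emitted life table exactly) plus a constant excess hazard — and is
  censored at the study end, so true relative survival is
  ``exp(-excess_hazard * t)``.

One global seed fans out to independent per-purpose streams (counts,
demographics, survival) so that each output is reproducible on its own;
a fixed seed yields byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as rio
from .exceptions import RegistatError
from .io import AgeGroupScheme
from .rates import SEGI_WORLD_STANDARD

__all__ = ["RegistrySpec", "SyntheticRegistry", "simulate_registry"]

_LIFETABLE_MAX_AGE = 105


def _default_base_rates() -> tuple[float, ...]:
    # age profile loosely shaped like an adult-onset carcinoma: negligible
    # below 30, rising steeply to a plateau in the elderly (per person-year)
    return tuple(
        [1e-6, 1e-6, 2e-6, 3e-6, 5e-6, 1e-5, 3e-5, 8e-5, 2e-4,
         4e-4, 8e-4, 1.4e-3, 2.2e-3, 3.0e-3, 3.6e-3, 3.8e-3, 3.6e-3, 3.0e-3]
    )


def _default_population() -> tuple[float, ...]:
    # person-years per sex x age-group x year, a mid-size region's pyramid
    return tuple(
        [28000, 30000, 32000, 34000, 36000, 38000, 40000, 38000, 35000,
         32000, 28000, 24000, 21000, 18000, 15000, 11000, 7000, 4000]
    )


@dataclass
class RegistrySpec:
    """Generating parameters of a synthetic registry.

    Attributes
    ----------
    years
        Inclusive calendar range of diagnoses.
    base_rates
        Incidence rate per person-year for each age group in the first
        year.
    annual_rate_change
        Multiplicative change of every rate per calendar year; the true
        EAPC is ``(annual_rate_change - 1) * 100``.
    population
        Person-years per age group (same for both sexes), optionally
        grown by ``population_growth`` per year.
    excess_hazard
        Constant disease-attributable death hazard per year; true
        relative survival is ``exp(-excess_hazard * t)``.
    background_survival
        General-population annual survival probability, constant over
        sex/age/year, written to the life table.
    """

    years: tuple[int, int] = (1995, 2004)
    scheme: AgeGroupScheme = field(default_factory=AgeGroupScheme.default)
    base_rates: tuple[float, ...] = field(default_factory=_default_base_rates)
    annual_rate_change: float = 1.0
    population: tuple[float, ...] = field(default_factory=_default_population)
    population_growth: float = 1.0
    excess_hazard: float = 0.25
    background_survival: float = 0.97
    study_end: tuple[int, int] = (2007, 12)
    disease: str = "Synthetic"
    sexes: tuple[int, ...] = (1, 2)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.base_rates) != len(self.scheme):
            raise RegistatError("base_rates must have one entry per age group")
        if len(self.population) != len(self.scheme):
            raise RegistatError("population must have one entry per age group")
        if any(r < 0 for r in self.base_rates):
            raise RegistatError("rates must be >= 0")
        if not (0 < self.background_survival <= 1):
            raise RegistatError("background_survival must lie in (0, 1]")
        if self.excess_hazard < 0:
            raise RegistatError("excess_hazard must be >= 0")
        if self.annual_rate_change <= 0 or self.population_growth <= 0:
            raise RegistatError("multiplicative changes must be > 0")


@dataclass
class SyntheticRegistry:
    """Generated registry: in-memory tables plus the ground-truth manifest."""

    spec: RegistrySpec
    individuals: pd.DataFrame
    aggregated: pd.DataFrame
    population: pd.DataFrame
    life_table: pd.Series = field(repr=False)
    standard: pd.Series = field(repr=False)
    manifest: dict

    def write(self, outdir: str | Path, *, delimiter: str = ",") -> dict[str, Path]:
        """Write the six files + manifest.json; returns the paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "individuals": outdir / "individual_records.csv",
            "aggregated": outdir / "aggregated.csv",
            "population": outdir / "population.csv",
            "life_table": outdir / "life_table.csv",
            "age_groups": outdir / "age_groups.csv",
            "standard": outdir / "standard_population.csv",
            "manifest": outdir / "manifest.json",
        }
        ind = self.individuals.rename(columns=dict(rio.DEFAULT_INDIVIDUAL_SCHEMA))
        ind.to_csv(paths["individuals"], sep=delimiter, index=False)
        rio.write_aggregated(self.aggregated, paths["aggregated"],
                             delimiter=delimiter)
        rio.write_population_distribution(self.population, paths["population"],
                                          delimiter=delimiter)
        rio.write_life_table(self.life_table, paths["life_table"],
                             delimiter=delimiter)
        rio.write_age_groups(self.spec.scheme, paths["age_groups"],
                             delimiter=delimiter)
        rio.write_standard_population(self.standard, paths["standard"],
                                      delimiter=delimiter)
        with open(paths["manifest"], "w", encoding="utf-8") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return paths


def _expected_counts(spec: RegistrySpec) -> pd.DataFrame:
    """Expected (noise-free) cases and person-years per cell."""
    y0, y1 = spec.years
    rows = []
    for sex in spec.sexes:
        for year in range(y0, y1 + 1):
            for k in spec.scheme.indices:
                rate = spec.base_rates[k - 1] * spec.annual_rate_change ** (year - y0)
                py = spec.population[k - 1] * spec.population_growth ** (year - y0)
                rows.append({"sex": sex, "age_group": k, "year": year,
                             "rate": rate, "person_years": py,
                             "mean_cases": rate * py})
    return pd.DataFrame(rows)


def _true_manifest(spec: RegistrySpec, expected: pd.DataFrame) -> dict:
    y0, y1 = spec.years
    mid = (y0 + y1 + 1) // 2
    ref = expected[expected["year"] < mid]
    tgt = expected[expected["year"] >= mid]

    def _pool(df: pd.DataFrame) -> pd.DataFrame:
        return (df.groupby("age_group")[["mean_cases", "person_years"]]
                .sum().sort_index())

    p1, p2 = _pool(ref), _pool(tgt)
    r1 = p1["mean_cases"] / p1["person_years"]
    e_under_ref = float((r1 * p2["person_years"]).sum())
    d2 = float(p2["mean_cases"].sum())
    d1 = float(p1["mean_cases"].sum())
    n1 = float(p1["person_years"].sum())
    n2 = float(p2["person_years"].sum())
    decomposition_pct = None
    if d1 > 0:
        decomposition_pct = {
            "net": (d2 - d1) / d1 * 100.0,
            "size": (n2 / n1 - 1.0) * 100.0,
            "structure": (e_under_ref - d1 * n2 / n1) / d1 * 100.0,
            "risk": (d2 - e_under_ref) / d1 * 100.0,
        }
    return {
        "seed": spec.seed,
        "years": list(spec.years),
        "true_eapc_pct": (spec.annual_rate_change - 1.0) * 100.0,
        "true_simr_second_vs_first_half": (d2 / e_under_ref
                                           if e_under_ref > 0 else None),
        "period_split_year": mid,
        "true_decomposition_pct": decomposition_pct,
        "true_excess_hazard": spec.excess_hazard,
        "true_rs_5y": float(np.exp(-5.0 * spec.excess_hazard)),
        "background_survival": spec.background_survival,
    }


def simulate_registry(spec: RegistrySpec) -> SyntheticRegistry:
    """Draw a synthetic registry from the spec; see the module docstring
    for the generating model and the manifest's ground truths."""
    ss = np.random.SeedSequence(spec.seed)
    s_counts, s_demo, s_surv = ss.spawn(3)
    rng_counts = np.random.default_rng(s_counts)
    rng_demo = np.random.default_rng(s_demo)
    rng_surv = np.random.default_rng(s_surv)

    expected = _expected_counts(spec)
    cases = rng_counts.poisson(expected["mean_cases"].to_numpy())
    agg = expected[["sex", "age_group", "year", "person_years"]].copy()
    agg["cases"] = cases
    agg["group"] = spec.disease
    agg = agg[["sex", "age_group", "year", "group", "cases", "person_years"]]

    # follow-up closes at the *end* of the study-end month
    end_y, end_m = spec.study_end
    end_time = end_y + end_m / 12.0
    h_bg = -np.log(spec.background_survival)
    h_tot = h_bg + spec.excess_hazard

    rows = []
    pid = 0
    for rec in agg.itertuples(index=False):
        if rec.cases == 0:
            continue
        lo = spec.scheme.lower(rec.age_group)
        up = spec.scheme.upper(rec.age_group)
        hi = (up - 1) if up is not None else min(lo + 9, _LIFETABLE_MAX_AGE)
        ages = rng_demo.integers(lo, hi + 1, size=rec.cases)
        months = rng_demo.integers(1, 13, size=rec.cases)
        death_t = (rng_surv.exponential(1.0 / h_tot, size=rec.cases)
                   if h_tot > 0 else np.full(rec.cases, np.inf))
        for a, m, dt in zip(ages, months, death_t):
            pid += 1
            diag = rec.year + (m - 1) / 12.0
            tau = max(0.0, end_time - diag)
            dead = dt <= tau
            fu = round(float(dt if dead else tau), 2)
            # end date advances by whole elapsed months so the redundant
            # date pair stays within one month of the follow-up time
            months_elapsed = int(np.floor(fu * 12 + 1e-9))
            month_index = (int(m) - 1) + months_elapsed
            f_year = int(rec.year) + month_index // 12
            f_month = month_index % 12 + 1
            rows.append({
                "patient_id": str(pid), "sex": int(rec.sex),
                "group": rec.group, "age": int(a),
                "diag_month": int(m), "diag_year": int(rec.year),
                "end_month": f_month, "end_year": f_year,
                "status": int(dead), "follow_up": fu,
            })
    individuals = pd.DataFrame(
        rows, columns=list(rio.INDIVIDUAL_COLUMNS))

    population = expected[["sex", "age_group", "year", "person_years"]].copy()

    lt_years = range(spec.years[0], end_y + 2)
    idx = pd.MultiIndex.from_product(
        [list(spec.sexes), range(0, _LIFETABLE_MAX_AGE + 1), list(lt_years)],
        names=["sex", "age", "year"])
    life_table = pd.Series(spec.background_survival, index=idx, name="prob")

    standard = SEGI_WORLD_STANDARD.copy() if len(spec.scheme) == 18 else \
        pd.Series(1.0, index=pd.RangeIndex(1, len(spec.scheme) + 1),
                  name="weight")

    manifest = _true_manifest(spec, expected)
    manifest["n_cases"] = int(agg["cases"].sum())
    return SyntheticRegistry(
        spec=spec, individuals=individuals, aggregated=agg.reset_index(drop=True),
        population=population, life_table=life_table, standard=standard,
        manifest=manifest,
    )
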