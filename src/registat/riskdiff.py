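"""Decomposition of the change in case counts between two populations.

Given age-specific cases and person-years for a reference period/area
(C1_i, Y1_i) and a target (C2_i, Y2_i), the net change in total cases is
partitioned into three additive components (Bashir-Esteve partition):

* **size** — what the change would be if only the overall population
  size had changed:          size = sum(C1) * (N2/N1 - 1)
* **structure** — the further change from the shifted age distribution,
  applying the reference age-specific rates r_i = C1_i/Y1_i to the
  target pyramid:     structure = sum(r_i * Y2_i) - sum(C1) * N2/N1
* **risk** — the residual change not explained by demography:
                       risk = sum(C2) - sum(r_i * Y2_i)

so that net = sum(C2) - sum(C1) = risk + size + structure exactly.  The
ordering convention (size first, structure second, risk as residual) is
fixed; component values depend on it.

Three reporting scales are produced: absolute cases, crude rate per
100,000 (where the size term vanishes because both crude rates already
divide by their own population), and percent of the reference case
count.  No confidence intervals are produced: the partition is a
deterministic identity, and inference for its components is out of
scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import RegistatError, SchemeMismatchError
from .rates import PER

__all__ = ["NetChangeDecomposition", "decompose_net_change"]

SCALES = ("absolute_cases", "crude_rate_per_100k", "percent")


@dataclass(frozen=True)
class NetChangeDecomposition:
    """Additive partition net = risk + size + structure on one scale."""

    scale: str
    net: float
    risk: float
    size: float
    structure: float

    @property
    def population(self) -> float:
        """Combined demographic component (size + structure)."""
        return self.size + self.structure

    def summary(self) -> str:
        return (
            f"[{self.scale}] net = {self.net:.4f} | "
            f"risk = {self.risk:.4f}, size = {self.size:.4f}, "
            f"structure = {self.structure:.4f}"
        )


def _as_arrays(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    pooled = (df.groupby("age_group")[["cases", "person_years"]]
              .sum().sort_index())
    return (pooled.index.values, pooled["cases"].values.astype(float),
            pooled["person_years"].values.astype(float))


def decompose_net_change(
    reference: pd.DataFrame,
    target: pd.DataFrame,
    *,
    scales: tuple[str, ...] = SCALES,
) -> dict[str, NetChangeDecomposition]:
    """Partition the target-minus-reference change in cases into risk,
    population-size and population-structure components.

    Both inputs are counts slices with age_group, cases, person_years
    (pooled over their years — rates are treated as constant within each
    period).  Returns one :class:`NetChangeDecomposition` per requested
    scale: ``absolute_cases``, ``crude_rate_per_100k`` and ``percent``.
    The percent scale divides by the reference case count and is an
    error when that count is zero.
    """
    unknown = set(scales) - set(SCALES)
    if unknown:
        raise ValueError(f"unknown scale(s) {sorted(unknown)}")
    ages1, c1, y1 = _as_arrays(reference)
    ages2, c2, y2 = _as_arrays(target)
    if not np.array_equal(ages1, ages2):
        raise SchemeMismatchError(
            "the two periods use different age-group schemes: "
            f"{ages1.tolist()} vs {ages2.tolist()}")
    if (y1 <= 0).any() or (y2 <= 0).any():
        raise RegistatError("person-years must be > 0 in every age group")

    n1, n2 = y1.sum(), y2.sum()
    tot1, tot2 = c1.sum(), c2.sum()
    r1 = c1 / y1                       # reference age-specific rates
    expected2 = float((r1 * y2).sum())  # reference rates on target pyramid

    net_abs = tot2 - tot1
    size_abs = tot1 * (n2 / n1 - 1.0)
    structure_abs = expected2 - tot1 * (n2 / n1)
    risk_abs = tot2 - expected2

    out: dict[str, NetChangeDecomposition] = {}
    if "absolute_cases" in scales:
        out["absolute_cases"] = NetChangeDecomposition(
            "absolute_cases", float(net_abs), float(risk_abs),
            float(size_abs), float(structure_abs))

    if "crude_rate_per_100k" in scales:
        cr1 = PER * tot1 / n1
        cr2 = PER * tot2 / n2
        expected_cr2 = PER * expected2 / n2  # structure-shifted crude rate
        out["crude_rate_per_100k"] = NetChangeDecomposition(
            "crude_rate_per_100k",
            net=float(cr2 - cr1),
            risk=float(cr2 - expected_cr2),
            size=0.0,
            structure=float(expected_cr2 - cr1),
        )

    if "percent" in scales:
        if tot1 == 0:
            raise RegistatError(
                "percent scale undefined: reference period has zero cases")
        pct = 100.0 / tot1
        out["percent"] = NetChangeDecomposition(
            "percent", float(net_abs * pct), float(risk_abs * pct),
            float(size_abs * pct), float(structure_abs * pct))
    return out
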