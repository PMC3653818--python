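"""Cohort relative survival: Kaplan-Meier over Hakulinen expected survival.

Relative survival RS(T) = S_o(T) / S_E(T) compares the all-cause
(observed) survival of a patient cohort with the survival the same
cohort would have experienced under general-population mortality,
treating the disease as the only source of excess death.  S_o is the
Kaplan-Meier product-limit estimate on exact follow-up times; S_E comes
from sex/age/calendar-year life tables combined over the cohort with the
Hakulinen estimator, in which every patient contributes expected
survival for as long as they are *potentially* under follow-up
(diagnosis to study end), regardless of actual death or loss — the
feature that distinguishes Hakulinen from the Ederer estimators and
removes the bias of heterogeneous follow-up.

Confidence intervals for RS use the standard error of log S_o
(Greenwood), with S_E treated as a constant:

    CI = exp(log S_o +/- z * se_log_So) / S_E

The lower bound is clipped at 0; RS itself may exceed 1 and is never
clipped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import CoverageError, RegistatError

logger = logging.getLogger(__name__)

__all__ = [
    "km_observed",
    "hakulinen_expected",
    "relative_survival",
    "SurvivalCurve",
    "RelativeSurvivalModel",
    "report_table",
]


def km_observed(
    times: Sequence[float],
    events: Sequence[int],
    grid: Sequence[float],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Kaplan-Meier survival at the grid points.

    Parameters
    ----------
    times, events
        Exact follow-up times in years and vital status (1 = dead,
        0 = censored at that time).
    grid
        Evaluation time points (years from diagnosis).

    Returns
    -------
    (os, var_log_os, n_at_risk)
        Product-limit survival, Greenwood variance of log S_o, and the
        number still at risk, each evaluated at the grid points.
        ``n_at_risk(T)`` counts subjects with follow-up >= T.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    grid = np.asarray(grid, dtype=float)
    if times.size == 0:
        raise RegistatError("empty cohort")
    if (times < 0).any():
        raise RegistatError("negative follow-up time")

    order = np.argsort(times, kind="stable")
    t_sorted = times[order]
    e_sorted = events[order]
    n = len(t_sorted)

    # step function over unique event times
    event_times = np.unique(t_sorted[e_sorted == 1])
    surv_steps = []      # (time, S, var_log_S)
    s = 1.0
    greenwood = 0.0
    for t in event_times:
        at_risk = n - np.searchsorted(t_sorted, t, side="left")
        d = int(((t_sorted == t) & (e_sorted == 1)).sum())
        s *= 1.0 - d / at_risk
        if at_risk > d:
            greenwood += d / (at_risk * (at_risk - d))
        else:
            greenwood = np.inf  # everyone at risk died; log S undefined
        surv_steps.append((t, s, greenwood))

    os_ = np.empty_like(grid)
    var_ = np.empty_like(grid)
    risk_ = np.empty(len(grid), dtype=int)
    for j, g in enumerate(grid):
        s, v = 1.0, 0.0
        for t, st, gv in surv_steps:
            if t <= g:
                s, v = st, gv
            else:
                break
        os_[j] = s
        var_[j] = v
        risk_[j] = n - np.searchsorted(t_sorted, g, side="left")
    return os_, var_, risk_


class LifeTableLookup:
    """Annual survival probability lookup with last-age carry-forward."""

    def __init__(self, table: pd.Series):
        # dict lookup: the estimator queries one cell per patient per year
        self._dict = {tuple(int(v) for v in k): float(p)
                      for k, p in table.items()}
        self._max_age = {s: int(table.loc[s].index.get_level_values("age").max())
                         for s in table.index.get_level_values("sex").unique()}
        self._warned = False

    def prob(self, sex: int, age: int, year: int) -> float:
        if sex not in self._max_age:
            raise CoverageError(f"life table has no sex={sex}")
        max_age = self._max_age[sex]
        if age > max_age:
            if not self._warned:
                logger.warning(
                    "attained age %d beyond life-table maximum %d; reusing "
                    "the last available age row", age, max_age)
                self._warned = True
            age = max_age
        try:
            return self._dict[(sex, age, year)]
        except KeyError:
            raise CoverageError(
                f"life table lacks cell (sex={sex}, age={age}, year={year})"
            ) from None


def hakulinen_expected(
    patients: pd.DataFrame,
    life_table: pd.Series,
    grid: Sequence[float],
) -> np.ndarray:
    """Hakulinen cohort expected survival at the (annual) grid points.

    ``patients`` needs columns sex, age, diag_year and potential_fu
    (years from diagnosis to study end).  For each annual interval
    ``k``, the cohort's conditional expected survival is the weighted
    average of the patients' life-table annual probabilities

        p_bar(k) = sum_i w_ik S_i(k-1) p_i(k) / sum_i w_ik S_i(k-1)

    where p_i(k) is the life-table probability at the attained age and
    calendar year, S_i the individual cumulative expected survival and
    w_ik the fraction of interval k inside patient i's *potential*
    follow-up (1 while fully potentially observed, fractional in the
    year follow-up ends, 0 after).  The cohort curve is the running
    product of p_bar and is evaluated at the grid by raising the current
    year's p_bar to the fractional power (constant hazard within years).
    """
    lt = LifeTableLookup(life_table)
    grid = np.asarray(grid, dtype=float)
    sexes = patients["sex"].to_numpy(int)
    ages = patients["age"].to_numpy(int)
    years = patients["diag_year"].to_numpy(int)
    tau = patients["potential_fu"].to_numpy(float)
    npat = len(patients)
    if npat == 0:
        raise RegistatError("empty cohort")
    max_t = float(grid.max()) if grid.size else 0.0
    kmax = int(np.ceil(max_t))

    cum_ind = np.ones(npat)          # S_i(k-1)
    es_annual = [1.0]                # ES at integer times 0, 1, ..., kmax
    pbar = np.ones(kmax)
    for k in range(1, kmax + 1):
        w = np.clip(tau - (k - 1), 0.0, 1.0)
        # life-table cells are only ever needed while the patient is still
        # potentially under follow-up; afterwards their weight stays 0
        p = np.array([lt.prob(sexes[i], ages[i] + k - 1, years[i] + k - 1)
                      if w[i] > 0 else 1.0
                      for i in range(npat)])
        weight = w * cum_ind
        wsum = weight.sum()
        if wsum > 0:
            pbar[k - 1] = float((weight * p).sum() / wsum)
        else:
            # nobody potentially under follow-up: carry the curve flat
            pbar[k - 1] = 1.0
        es_annual.append(es_annual[-1] * pbar[k - 1])
        # advance individual cumulative expected survival a full year
        cum_ind *= p

    es = np.empty_like(grid)
    for j, g in enumerate(grid):
        k = int(np.floor(g))
        frac = g - k
        val = es_annual[min(k, kmax)]
        if frac > 0 and k < kmax:
            val *= pbar[k] ** frac
        es[j] = val
    return es


def relative_survival(
    os_: np.ndarray,
    es: np.ndarray,
    var_log_os: np.ndarray,
    *,
    level: float = 0.95,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """RS = S_o / S_E with log-transform CI, S_E held constant.

    Returns (rs, ci_low, ci_high); the lower bound is clipped at 0, RS
    itself is not clipped (registry RS can exceed 1).
    """
    os_ = np.asarray(os_, dtype=float)
    es = np.asarray(es, dtype=float)
    var = np.asarray(var_log_os, dtype=float)
    if (es <= 0).any():
        raise RegistatError("expected survival must be > 0 at every point")
    z = stats.norm.ppf(0.5 + level / 2)
    rs = os_ / es
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(var)
        lo = np.where(os_ > 0, np.exp(np.log(np.where(os_ > 0, os_, 1.0))
                                      - z * se) / es, 0.0)
        hi = np.where(os_ > 0, np.exp(np.log(np.where(os_ > 0, os_, 1.0))
                                      + z * se) / es, 0.0)
    lo = np.clip(lo, 0.0, None)
    lo = np.where(np.isfinite(lo), lo, 0.0)
    hi = np.where(np.isfinite(hi), hi, np.inf)
    return rs, lo, hi


@dataclass
class SurvivalCurve:
    """Observed, expected and relative survival on an annual grid."""

    time_points: np.ndarray = field(repr=False)
    n_at_risk: np.ndarray = field(repr=False)
    os: np.ndarray = field(repr=False)
    es: np.ndarray = field(repr=False)
    rs: np.ndarray = field(repr=False)
    ci_low: np.ndarray = field(repr=False)
    ci_high: np.ndarray = field(repr=False)
    level: float = 0.95

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "Risk": self.n_at_risk, "T": self.time_points,
            "RS": self.rs, "LCI": self.ci_low, "UCI": self.ci_high,
            "OS": self.os, "ES": self.es,
        })

    def summary(self) -> str:
        df = report_table(self)
        head = (f"Relative survival ({int(self.level * 100)}% CI, "
                f"{len(self.time_points)} annual points)")
        return head + "\n" + df.to_string(index=False)


def report_table(curve: SurvivalCurve) -> pd.DataFrame:
    """Annual report rows: Risk, T, RS, LCI, UCI, OS (3 decimals)."""
    df = curve.to_frame()[["Risk", "T", "RS", "LCI", "UCI", "OS"]].copy()
    for c in ("RS", "LCI", "UCI", "OS"):
        df[c] = df[c].round(3)
    df["T"] = df["T"].astype(int) if np.allclose(
        curve.time_points, np.round(curve.time_points)) else df["T"]
    return df


class RelativeSurvivalModel:
    """Cohort relative-survival model from individual records.

    Parameters
    ----------
    records
        Canonical individual-records DataFrame (sex, age, diag_month,
        diag_year, status, follow_up; see :mod:`registat.io`).
    life_table
        Series indexed by (sex, age, year) of annual survival
        probabilities.
    study_end
        ``(year, month)`` closing date of the registry follow-up; fixes
        every patient's *potential* follow-up time for the Hakulinen
        estimator.
    max_time
        Largest annual report point; defaults to the floor of the
        longest follow-up.
    """

    def __init__(self, records: pd.DataFrame, life_table: pd.Series,
                 study_end: tuple[int, int], *, max_time: int | None = None):
        if len(records) == 0:
            raise RegistatError("empty cohort")
        self.records = records.reset_index(drop=True)
        self.life_table = life_table
        self.study_end = study_end
        fu = self.records["follow_up"].to_numpy(float)
        if max_time is None:
            max_time = max(1, int(np.floor(fu.max())))
        self.grid = np.arange(0, max_time + 1, dtype=float)

    def _potential_followup(self) -> np.ndarray:
        end_y, end_m = self.study_end
        end = end_y + end_m / 12.0
        diag = (self.records["diag_year"].to_numpy(float)
                + (self.records["diag_month"].to_numpy(float) - 1) / 12.0)
        tau = end - diag
        if (tau < 0).any():
            raise RegistatError("diagnosis after the study end date")
        return tau

    def fit(self, *, level: float = 0.95) -> SurvivalCurve:
        times = self.records["follow_up"].to_numpy(float)
        events = self.records["status"].to_numpy(int)
        os_, var_log, n_risk = km_observed(times, events, self.grid)
        pats = pd.DataFrame({
            "sex": self.records["sex"],
            "age": self.records["age"],
            "diag_year": self.records["diag_year"],
            "potential_fu": self._potential_followup(),
        })
        es = hakulinen_expected(pats, self.life_table, self.grid)
        rs, lo, hi = relative_survival(os_, es, var_log, level=level)
        return SurvivalCurve(
            time_points=self.grid, n_at_risk=n_risk, os=os_, es=es,
            rs=rs, ci_low=lo, ci_high=hi, level=level,
        )
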