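"""Estimated annual percent change (EAPC) of rate time series.

The EAPC summarises a trend under the assumption that the rate changes by
a constant percentage each year, i.e. a Gaussian log-linear model

    log(ASR_T) = alpha + beta * T

fitted by ordinary least squares, with EAPC = (exp(beta) - 1) * 100.  The
confidence interval is computed on the beta scale (t-distribution with
n - 2 degrees of freedom by default) and transformed, so it is never
symmetric around the EAPC but always contains it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .exceptions import InsufficientDataError, ZeroRateError

__all__ = ["EAPCResult", "EAPCModel", "fit_eapc", "interpret_eapc"]


@dataclass(frozen=True)
class EAPCResult:
    """OLS log-linear trend fit and its percent-change transform."""

    beta: float
    se_beta: float
    eapc_pct: float
    ci_low_pct: float
    ci_high_pct: float
    n_years: int
    level: float = 0.95
    ci_method: str = "t"

    @property
    def trend(self) -> str:
        """'increasing' / 'decreasing' / 'stable' by whether the CI
        excludes zero."""
        if self.ci_low_pct > 0:
            return "increasing"
        if self.ci_high_pct < 0:
            return "decreasing"
        return "stable"

    def summary(self) -> str:
        lines = [
            "Estimated annual percent change (log-linear OLS)",
            f"  n years:       {self.n_years}",
            f"  beta (log/yr): {self.beta:.6f} (se {self.se_beta:.6f})",
            f"  EAPC:          {self.eapc_pct:.2f}%  "
            f"{int(self.level * 100)}% CI "
            f"({self.ci_low_pct:.2f}%, {self.ci_high_pct:.2f}%)",
            f"  trend:         {self.trend}",
        ]
        return "\n".join(lines)


class EAPCModel:
    """Log-linear trend model for an annual rate series.

    Parameters
    ----------
    years, rates
        Calendar years and the corresponding (already standardized)
        rates.  All rates must be positive: a zero rate makes the log
        model undefined and raises :class:`ZeroRateError` naming the
        year, unless ``drop_zero_years=True`` explicitly removes them.
    """

    def __init__(self, years: Sequence[float], rates: Sequence[float],
                 *, drop_zero_years: bool = False):
        years = np.asarray(years, dtype=float)
        rates = np.asarray(rates, dtype=float)
        if years.shape != rates.shape:
            raise ValueError("years and rates must have the same length")
        if drop_zero_years:
            keep = rates > 0
            years, rates = years[keep], rates[keep]
        elif (rates <= 0).any():
            bad = years[rates <= 0].astype(int).tolist()
            raise ZeroRateError(
                f"non-positive rate in year(s) {bad}; a log-linear trend is "
                "undefined (pass drop_zero_years=True to drop them)")
        if len(years) < 3:
            raise InsufficientDataError(
                f"need at least 3 positive-rate years, got {len(years)}")
        self.years = years
        self.rates = rates

    def fit(self, *, level: float = 0.95, ci_method: str = "t") -> EAPCResult:
        """OLS of log(rate) on year; CI on beta transformed to percent."""
        if ci_method not in ("t", "normal"):
            raise ValueError("ci_method must be 't' or 'normal'")
        x = self.years
        y = np.log(self.rates)
        n = len(x)
        xb, yb = x.mean(), y.mean()
        sxx = float(((x - xb) ** 2).sum())
        beta = float(((x - xb) * (y - yb)).sum() / sxx)
        alpha = yb - beta * xb
        resid = y - (alpha + beta * x)
        s2 = float((resid ** 2).sum()) / (n - 2)
        se = float(np.sqrt(max(s2, 0.0) / sxx))
        if ci_method == "t":
            q = stats.t.ppf(0.5 + level / 2, df=n - 2)
        else:
            q = stats.norm.ppf(0.5 + level / 2)
        lo, hi = beta - q * se, beta + q * se
        to_pct = lambda b: (np.exp(b) - 1.0) * 100.0
        return EAPCResult(
            beta=beta, se_beta=se,
            eapc_pct=float(to_pct(beta)),
            ci_low_pct=float(to_pct(lo)), ci_high_pct=float(to_pct(hi)),
            n_years=n, level=level, ci_method=ci_method,
        )


def fit_eapc(series: Sequence[tuple[float, float]], *,
             level: float = 0.95, ci_method: str = "t",
             drop_zero_years: bool = False) -> EAPCResult:
    """Fit the EAPC of a ``[(year, rate), ...]`` series."""
    years, rates = zip(*series) if len(series) else ((), ())
    return EAPCModel(years, rates, drop_zero_years=drop_zero_years
                     ).fit(level=level, ci_method=ci_method)


def interpret_eapc(result: EAPCResult) -> str:
    """Trend label: stable iff the CI contains 0, otherwise the sign."""
    return result.trend
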