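"""Projection of future case counts from log-linear count models.

Four candidate models for the age x year count table are fitted, all with
log person-years as exposure offset:

* age-specific slopes:  log(C_iT / Y_iT) = alpha_i + beta_i (T - T0)
* common drift ("age-drift"): log(C_iT / Y_iT) = alpha_i + beta (T - T0)

each under a Poisson or a negative-binomial (NB2) count distribution,
the latter absorbing overdispersion through an extra dispersion
parameter.  Candidates are compared by AIC (ties broken toward fewer
parameters), with a Pearson chi-square goodness-of-fit statistic
reported as a diagnostic alongside.

Projection to a future year F plugs F and the future person-years into
the fitted linear predictor: E[C_iF] = Y_iF * exp(alpha_i + beta_i (F - T0)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .exceptions import CoverageError, FitError, InsufficientDataError
from .rates import direct_standardized_rate

logger = logging.getLogger(__name__)

__all__ = [
    "CountModelFit",
    "PredictionResult",
    "CaseTrendModel",
    "fit_count_model",
    "fit_all_models",
    "select_model",
    "predict_cases",
    "selection_table",
]

FAMILIES = ("poisson", "negative_binomial")
SLOPE_TYPES = ("drift", "age_specific")


@dataclass
class CountModelFit:
    """One fitted count-trend candidate."""

    family: str
    slope_type: str
    t0: int
    age_groups: tuple[int, ...]
    excluded_age_groups: tuple[int, ...]
    alpha: pd.Series = field(repr=False)          # log-rate at T0 per age group
    beta: float | pd.Series = field(repr=False)   # drift slope or per-age slopes
    beta_se: float | pd.Series = field(repr=False)
    dispersion: float | None
    loglike: float
    n_params: int
    n_cells: int
    aic: float
    gof_chi2: float
    gof_df: int
    gof_p: float

    @property
    def converged(self) -> bool:
        return np.isfinite(self.aic)

    def linear_predictor(self, age_group: int, year: float) -> float:
        """alpha_i + beta_i * (year - t0) for one age group."""
        b = (float(self.beta) if np.isscalar(self.beta)
             else float(self.beta.loc[age_group]))
        return float(self.alpha.loc[age_group]) + b * (year - self.t0)

    def summary(self) -> str:
        lines = [
            f"Count trend model: {self.family}, {self.slope_type}"
            f" (T0 = {self.t0})",
            f"  cells: {self.n_cells}, parameters: {self.n_params}",
            f"  log-likelihood: {self.loglike:.3f}   AIC: {self.aic:.3f}",
            f"  Pearson X2: {self.gof_chi2:.3f} on {self.gof_df} df"
            f" (p = {self.gof_p:.4f})",
        ]
        if self.dispersion is not None:
            lines.append(f"  NB dispersion: {self.dispersion:.4f}")
        if self.excluded_age_groups:
            lines.append(
                f"  age groups with all-zero counts, predicted as 0: "
                f"{list(self.excluded_age_groups)}")
        return "\n".join(lines)


@dataclass
class PredictionResult:
    """Expected cases in a future year under a fitted count model."""

    model: CountModelFit
    future_year: int
    expected_cases_by_age: pd.Series = field(repr=False)
    expected_total: float
    projected_asr: float | None

    def summary(self) -> str:
        lines = [
            f"Projection to {self.future_year} "
            f"({self.model.family}, {self.model.slope_type})",
            f"  expected total cases: {self.expected_total:.1f}",
        ]
        if self.projected_asr is not None:
            lines.append(f"  projected ASR: {self.projected_asr:.2f} per 100,000")
        return "\n".join(lines)


class CaseTrendModel:
    """Log-linear count-trend model over a sex/disease counts slice.

    The slice must hold one row per (age_group, year) with ``cases`` and
    ``person_years``.  Age groups whose counts are zero in every year
    cannot be represented on the log scale; they are excluded from the
    fit, recorded on the result, and projected as zero.
    """

    def __init__(self, counts: pd.DataFrame, *, family: str = "poisson",
                 slope_type: str = "drift", t0: int | None = None):
        if family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}")
        if slope_type not in SLOPE_TYPES:
            raise ValueError(f"slope_type must be one of {SLOPE_TYPES}")
        pooled = (counts.groupby(["age_group", "year"])
                  [["cases", "person_years"]].sum().reset_index())
        if pooled["year"].nunique() < 2:
            raise InsufficientDataError("need at least 2 distinct years")
        if (pooled["person_years"] <= 0).any():
            raise InsufficientDataError("person_years must be > 0 in all cells")
        totals = pooled.groupby("age_group")["cases"].sum()
        excluded = tuple(int(a) for a in totals.index[totals == 0])
        if excluded:
            logger.info("age group(s) %s have zero counts in all years; "
                        "excluded from fit and predicted as 0", list(excluded))
        self.data = pooled[~pooled["age_group"].isin(excluded)].reset_index(
            drop=True)
        self.excluded = excluded
        self.family = family
        self.slope_type = slope_type
        self.t0 = int(t0 if t0 is not None else pooled["year"].max())
        self.age_groups = tuple(int(a) for a in
                                sorted(self.data["age_group"].unique()))

    def _design(self) -> np.ndarray:
        ages = self.data["age_group"].values
        t = self.data["year"].values - self.t0
        dummies = np.column_stack([(ages == a).astype(float)
                                   for a in self.age_groups])
        if self.slope_type == "drift":
            return np.column_stack([dummies, t])
        return np.column_stack([dummies, dummies * t[:, None]])

    @staticmethod
    def _fit_negbin(y, X, exposure, maxiter):
        """NB2 MLE, dispersion profiled jointly; seeded from the Poisson
        solution because equidispersed data push alpha to its boundary."""
        import warnings

        pois = sm.Poisson(y, X, exposure=exposure).fit(disp=0, maxiter=maxiter)
        start = np.append(np.asarray(pois.params), 0.05)
        model = sm.NegativeBinomial(y, X, exposure=exposure)
        last_exc: Exception | None = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for method, it in (("bfgs", maxiter), ("nm", 10 * maxiter)):
                try:
                    res = model.fit(start_params=start, method=method,
                                    maxiter=it, disp=0)
                except Exception as exc:  # keep trying the next optimizer
                    last_exc = exc
                    continue
                if not np.all(np.isfinite(np.asarray(res.params))):
                    continue
                if res.mle_retvals.get("converged", False):
                    return res
                # equidispersed data drive alpha to its boundary and the
                # line search reports precision loss there; a vanishing
                # score still marks a genuine optimum
                grad = res.mle_retvals.get("gopt")
                if grad is not None and np.max(np.abs(grad)) < 1e-3:
                    res.mle_retvals["converged"] = True
                    return res
        if last_exc is not None:
            raise FitError(f"negative binomial fit failed: {last_exc}")
        raise FitError("negative binomial fit failed to converge")

    def fit(self, *, maxiter: int = 200) -> CountModelFit:
        y = self.data["cases"].values.astype(float)
        exposure = self.data["person_years"].values.astype(float)
        X = self._design()
        try:
            if self.family == "poisson":
                res = sm.Poisson(y, X, exposure=exposure).fit(
                    disp=0, maxiter=maxiter)
            else:
                res = self._fit_negbin(y, X, exposure, maxiter)
            if not res.mle_retvals.get("converged", True):
                raise FitError(
                    f"{self.family}/{self.slope_type}: no convergence")
            params = np.asarray(res.params, dtype=float)
            if not np.all(np.isfinite(params)):
                raise FitError(f"{self.family}/{self.slope_type}: "
                               "non-finite parameters")
        except FitError:
            raise
        except Exception as exc:  # statsmodels raises various numeric errors
            raise FitError(
                f"{self.family}/{self.slope_type}: {exc}") from exc
        A = len(self.age_groups)
        bse = np.asarray(res.bse, dtype=float)
        alpha = pd.Series(params[:A], index=list(self.age_groups), name="alpha")
        if self.slope_type == "drift":
            beta: float | pd.Series = float(params[A])
            beta_se: float | pd.Series = float(bse[A])
        else:
            beta = pd.Series(params[A:2 * A], index=list(self.age_groups),
                             name="beta")
            beta_se = pd.Series(bse[A:2 * A], index=list(self.age_groups),
                                name="beta_se")
        dispersion = None
        if self.family == "negative_binomial":
            dispersion = float(params[-1])
        k = len(params)  # includes NB dispersion
        mu = np.asarray(res.predict(X, exposure=exposure), dtype=float)
        var = mu if dispersion is None else mu * (1.0 + dispersion * mu)
        gof_chi2 = float(((y - mu) ** 2 / var).sum())
        gof_df = len(y) - k
        gof_p = float(stats.chi2.sf(gof_chi2, gof_df)) if gof_df > 0 else np.nan
        return CountModelFit(
            family=self.family, slope_type=self.slope_type, t0=self.t0,
            age_groups=self.age_groups, excluded_age_groups=self.excluded,
            alpha=alpha, beta=beta, beta_se=beta_se, dispersion=dispersion,
            loglike=float(res.llf), n_params=k, n_cells=len(y),
            aic=float(-2.0 * res.llf + 2.0 * k),
            gof_chi2=gof_chi2, gof_df=gof_df, gof_p=gof_p,
        )


def fit_count_model(counts: pd.DataFrame, family: str, slope_type: str,
                    t0: int | None = None) -> CountModelFit:
    """Fit one candidate (family x slope type) count-trend model."""
    return CaseTrendModel(counts, family=family, slope_type=slope_type,
                          t0=t0).fit()


def fit_all_models(counts: pd.DataFrame, t0: int | None = None
                   ) -> list[CountModelFit | FitError]:
    """Fit all four candidates; a failed fit is recorded as the FitError."""
    out: list[CountModelFit | FitError] = []
    for family in FAMILIES:
        for slope_type in SLOPE_TYPES:
            try:
                out.append(fit_count_model(counts, family, slope_type, t0))
            except FitError as exc:
                logger.warning("candidate failed: %s", exc)
                out.append(exc)
    return out


def _rank_key(fit: CountModelFit) -> tuple:
    # ties: fewer parameters first (drift before age-specific), then
    # Poisson before NB
    return (fit.aic, fit.n_params, 0 if fit.family == "poisson" else 1)


def select_model(fits: Sequence[CountModelFit | FitError]) -> CountModelFit:
    """Minimum-AIC candidate; ties broken toward fewer parameters and
    Poisson.  A warning is logged when the winner fails the chi-square
    goodness-of-fit test at the 0.05 level."""
    valid = [f for f in fits if isinstance(f, CountModelFit) and f.converged]
    if not valid:
        raise FitError("all candidate models failed to fit")
    best = sorted(valid, key=_rank_key)[0]
    if np.isfinite(best.gof_p) and best.gof_p < 0.05:
        logger.warning(
            "selected model (%s, %s) fails Pearson GOF at 0.05 (p = %.4g)",
            best.family, best.slope_type, best.gof_p)
    return best


def selection_table(fits: Sequence[CountModelFit | FitError]) -> pd.DataFrame:
    """One row per candidate: family, slope type, AIC, GOF diagnostics."""
    rows = []
    i = 0
    for family in FAMILIES:
        for slope_type in SLOPE_TYPES:
            f = fits[i]
            i += 1
            if isinstance(f, CountModelFit):
                rows.append({"family": f.family, "slope_type": f.slope_type,
                             "n_params": f.n_params, "aic": f.aic,
                             "gof_chi2": f.gof_chi2, "gof_df": f.gof_df,
                             "gof_p": f.gof_p})
            else:
                rows.append({"family": family, "slope_type": slope_type,
                             "n_params": np.nan, "aic": np.nan,
                             "gof_chi2": np.nan, "gof_df": np.nan,
                             "gof_p": np.nan})
    return pd.DataFrame(rows)


def predict_cases(
    fit: CountModelFit,
    future_year: int,
    future_person_years: Mapping[int, float] | pd.Series,
    std: pd.Series | None = None,
) -> PredictionResult:
    """Expected cases per age group at ``future_year``.

    ``future_person_years`` maps every fitted age group (1-based index)
    to its projected person-years.  Excluded (all-zero) age groups are
    projected as zero.  When ``std`` standard weights are given the
    projected ASR is computed from the projected age-specific rates.
    """
    fpy = pd.Series(future_person_years, dtype=float).sort_index()
    needed = set(fit.age_groups)
    missing = needed.difference(fpy.index)
    if missing:
        raise CoverageError(
            f"future person-years missing for age group(s) {sorted(missing)}")
    if (fpy <= 0).any():
        raise CoverageError("future person-years must be > 0")
    cells = {}
    for a in fit.age_groups:
        cells[a] = fpy.loc[a] * np.exp(fit.linear_predictor(a, future_year))
    for a in fit.excluded_age_groups:
        if a in fpy.index:
            cells[a] = 0.0
    expected = pd.Series(cells, name="expected_cases").sort_index()
    asr = None
    if std is not None:
        proj = pd.DataFrame({
            "age_group": expected.index,
            "cases": expected.values,
            "person_years": fpy.loc[expected.index].values,
        })
        asr = direct_standardized_rate(proj, std[std.index.isin(expected.index)])
    return PredictionResult(
        model=fit, future_year=int(future_year),
        expected_cases_by_age=expected,
        expected_total=float(expected.sum()),
        projected_asr=asr,
    )
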