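import warnings

import numpy as np
import pandas as pd
import pytest

from registat import (
    fit_all_models,
    fit_count_model,
    predict_cases,
    select_model,
)
from registat.exceptions import CoverageError, FitError, InsufficientDataError
from registat.prediction import CountModelFit, selection_table

warnings.filterwarnings("ignore", message=".*Perfect separation.*")


def _table(age_groups, years, counts, person_years):
    rows = []
    for i, a in enumerate(age_groups):
        for j, y in enumerate(years):
            rows.append({"age_group": a, "year": y, "cases": counts[i][j],
                         "person_years": person_years})
    return pd.DataFrame(rows)


def _simulate_drift(rng, alpha, beta, years, py=1e5, t0=None):
    ages = range(1, len(alpha) + 1)
    t0 = t0 if t0 is not None else max(years)
    rows = []
    for i, a in enumerate(ages):
        for y in years:
            mu = py * np.exp(alpha[i] + beta * (y - t0))
            rows.append({"age_group": a, "year": y,
                         "cases": rng.poisson(mu), "person_years": py})
    return pd.DataFrame(rows)


ALPHA18 = np.linspace(-10.5, -5.5, 18)   # log-rates spanning rare to common


class TestFitting:
    def test_noiseless_self_consistency(self):
        # expected counts plugged in as observed: MLE recovers the truth
        alpha, beta = [-8.0, -7.0, -6.0], 0.02
        years = range(2000, 2008)
        counts = [[1e5 * np.exp(a + beta * (y - 2007)) for y in years]
                  for a in alpha]
        df = _table([1, 2, 3], years, counts, 1e5)
        fit = fit_count_model(df, "poisson", "drift", t0=2007)
        assert fit.beta == pytest.approx(beta, abs=1e-6)
        assert np.allclose(fit.alpha.values, alpha, atol=1e-6)

    def test_two_point_saturated_closed_form(self):
        df = _table([1], [2000, 2001], [[10, 20]], 1000.0)
        fit = fit_count_model(df, "poisson", "drift", t0=2000)
        assert fit.beta == pytest.approx(np.log(2), abs=1e-8)

    def test_simulation_recovery_within_three_se(self):
        rng = np.random.default_rng(2024)
        df = _simulate_drift(rng, ALPHA18, 0.02, range(2000, 2010))
        fit = fit_count_model(df, "poisson", "drift")
        assert abs(fit.beta - 0.02) < 3 * fit.beta_se

    def test_all_zero_age_group_excluded_and_predicted_zero(self):
        df = _table([1, 2], [2000, 2001], [[10, 12], [0, 0]], 1000.0)
        fit = fit_count_model(df, "poisson", "drift")
        assert fit.excluded_age_groups == (2,)
        pred = predict_cases(fit, 2002, {1: 1000.0, 2: 1000.0})
        assert pred.expected_cases_by_age.loc[2] == 0.0

    def test_insufficient_years(self):
        df = _table([1], [2000], [[5]], 1000.0)
        with pytest.raises(InsufficientDataError):
            fit_count_model(df, "poisson", "drift")

    def test_nb_aic_close_to_poisson_on_equidispersed_data(self):
        # NB nests Poisson: as the dispersion goes to 0 its AIC can only
        # exceed Poisson's by (about) the 2-point parameter penalty
        rng = np.random.default_rng(77)
        df = _simulate_drift(rng, np.linspace(-8, -6, 5), 0.01,
                             range(2000, 2008))
        pois = fit_count_model(df, "poisson", "drift")
        nb = fit_count_model(df, "negative_binomial", "drift")
        assert nb.aic >= pois.aic - 2.0
        assert nb.aic <= pois.aic + 2.0 + 1e-3

    def test_overdispersed_data_prefers_nb(self):
        rng = np.random.default_rng(5)
        rows = []
        for a in range(1, 7):
            for y in range(2000, 2010):
                lam = rng.gamma(2.0, 50.0)  # heavy extra-Poisson variation
                rows.append({"age_group": a, "year": y,
                             "cases": rng.poisson(lam), "person_years": 1e5})
        fits = fit_all_models(pd.DataFrame(rows))
        assert select_model(fits).family == "negative_binomial"


def _dummy_fit(family, slope_type, aic, n_params):
    return CountModelFit(
        family=family, slope_type=slope_type, t0=2000, age_groups=(1,),
        excluded_age_groups=(), alpha=pd.Series([0.0], index=[1]),
        beta=0.0, beta_se=0.0, dispersion=None, loglike=0.0,
        n_params=n_params, n_cells=10, aic=aic, gof_chi2=1.0, gof_df=5,
        gof_p=0.5)


class TestSelection:
    def test_tie_broken_toward_drift(self):
        fits = [_dummy_fit("poisson", "age_specific", 100.0, 8),
                _dummy_fit("poisson", "drift", 100.0, 5)]
        assert select_model(fits).slope_type == "drift"

    def test_tie_broken_toward_poisson(self):
        fits = [_dummy_fit("negative_binomial", "drift", 100.0, 6),
                _dummy_fit("poisson", "drift", 100.0, 5)]
        assert select_model(fits).family == "poisson"

    def test_failed_candidates_skipped(self):
        fits = [FitError("poisson/drift: boom"),
                _dummy_fit("poisson", "age_specific", 120.0, 8),
                _dummy_fit("negative_binomial", "drift", 110.0, 6)]
        best = select_model(fits)
        assert (best.family, best.slope_type) == ("negative_binomial", "drift")

    def test_all_failed_is_an_error(self):
        with pytest.raises(FitError):
            select_model([FitError("a"), FitError("b")])

    def test_drift_truth_selected_in_majority(self):
        rng = np.random.default_rng(31)
        wins = 0
        n_rep = 30
        for _ in range(n_rep):
            df = _simulate_drift(rng, np.linspace(-8, -6, 6), 0.02,
                                 range(2000, 2008))
            best = select_model(fit_all_models(df))
            wins += best.slope_type == "drift"
        assert wins > n_rep / 2

    def test_selection_table_lists_all_candidates(self):
        rng = np.random.default_rng(8)
        df = _simulate_drift(rng, np.linspace(-8, -7, 4), 0.0,
                             range(2000, 2006))
        table = selection_table(fit_all_models(df))
        assert len(table) == 4
        assert set(table["family"]) == {"poisson", "negative_binomial"}


class TestPrediction:
    @pytest.fixture()
    def drift_fit(self):
        rng = np.random.default_rng(4)
        df = _simulate_drift(rng, np.linspace(-8, -6, 5), 0.03,
                             range(2000, 2010))
        return fit_count_model(df, "poisson", "drift")

    def test_identity_at_reference_year(self, drift_fit):
        py = {a: 1e5 for a in drift_fit.age_groups}
        pred = predict_cases(drift_fit, drift_fit.t0, py)
        fitted = {a: 1e5 * np.exp(drift_fit.alpha.loc[a])
                  for a in drift_fit.age_groups}
        assert np.allclose(pred.expected_cases_by_age.values,
                           list(fitted.values()))

    def test_exposure_linearity(self, drift_fit):
        py1 = pd.Series({a: 1e5 for a in drift_fit.age_groups})
        p1 = predict_cases(drift_fit, 2012, py1)
        p2 = predict_cases(drift_fit, 2012, 2 * py1)
        assert np.allclose(2 * p1.expected_cases_by_age.values,
                           p2.expected_cases_by_age.values)
        assert p2.expected_total == pytest.approx(2 * p1.expected_total)
        std = pd.Series(1.0, index=list(drift_fit.age_groups))
        a1 = predict_cases(drift_fit, 2012, py1, std).projected_asr
        a2 = predict_cases(drift_fit, 2012, 2 * py1, std).projected_asr
        assert a1 == pytest.approx(a2, rel=1e-12)

    def test_one_year_growth_factor(self):
        df = _table([1], [2000, 2001, 2002],
                    [[100, 101, 102.01]], 1e5)
        fit = fit_count_model(df, "poisson", "drift", t0=2002)
        py = {1: 1e5}
        p0 = predict_cases(fit, 2002, py)
        p1 = predict_cases(fit, 2003, py)
        assert p1.expected_total / p0.expected_total == pytest.approx(
            np.exp(fit.beta), rel=1e-10)

    def test_missing_future_age_group(self, drift_fit):
        with pytest.raises(CoverageError):
            predict_cases(drift_fit, 2012, {1: 1e5})
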