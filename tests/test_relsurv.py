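import numpy as np
import pandas as pd
import pytest

from registat import (
    RelativeSurvivalModel,
    hakulinen_expected,
    km_observed,
    relative_survival,
    report_table,
)
from registat.relsurv import SurvivalCurve
from registat.exceptions import CoverageError, RegistatError


def _unit_life_table(sexes=(1, 2), ages=(0, 110), years=(1990, 2020), p=1.0):
    idx = pd.MultiIndex.from_product(
        [list(sexes), range(ages[0], ages[1]), range(years[0], years[1])],
        names=["sex", "age", "year"])
    return pd.Series(p, index=idx, name="prob")


def _records(n, *, sex=1, age=60, month=1, year=1995, status=1, follow_up=1.0):
    def col(v):
        return list(v) if np.iterable(v) and not isinstance(v, str) else [v] * n
    return pd.DataFrame({
        "patient_id": [str(i) for i in range(n)],
        "sex": col(sex), "group": "D", "age": col(age),
        "diag_month": col(month), "diag_year": col(year),
        "end_month": 1, "end_year": 2005,
        "status": col(status), "follow_up": col(follow_up),
    })


class TestKaplanMeier:
    def test_no_deaths_means_survival_one(self):
        os_, var, risk = km_observed([6.0] * 10, [0] * 10, [1, 2, 3, 4, 5])
        assert (os_ == 1.0).all()
        assert (var == 0.0).all()
        assert (risk == 10).all()

    def test_hand_product_limit(self):
        # deaths at 1 and 2, censorings at 1.5 and 3:
        # S(2) = (3/4) * (1/2) = 0.375
        os_, _, _ = km_observed([1, 1.5, 2, 3], [1, 0, 1, 0], [0, 1, 2, 3])
        assert os_.tolist() == [1.0, 0.75, 0.375, 0.375]

    def test_single_patient_dead(self):
        os_, _, _ = km_observed([0.5], [1], [0.25, 0.5, 1, 2])
        assert os_.tolist() == [1.0, 0.0, 0.0, 0.0]

    def test_empty_cohort_rejected(self):
        with pytest.raises(RegistatError):
            km_observed([], [], [1])

    def test_matches_lifelines(self):
        # independent oracle: lifelines' product-limit estimator
        from lifelines import KaplanMeierFitter
        rng = np.random.default_rng(10)
        t = rng.exponential(2.0, 80)
        e = rng.integers(0, 2, 80)
        grid = [0.5, 1, 2, 3, 5]
        os_, _, _ = km_observed(t, e, grid)
        kmf = KaplanMeierFitter().fit(t, e)
        expected = kmf.survival_function_at_times(grid).values
        assert np.allclose(os_, expected, atol=1e-12)


class TestHakulinen:
    def test_homogeneous_full_followup_is_product(self):
        lt = _unit_life_table(p=0.9)
        pats = pd.DataFrame({"sex": [1] * 7, "age": [60] * 7,
                             "diag_year": [1995] * 7,
                             "potential_fu": [10.0] * 7})
        es = hakulinen_expected(pats, lt, [0, 1, 2, 3, 4, 5])
        assert np.allclose(es, 0.9 ** np.arange(6), atol=1e-12)

    def test_two_strata_mixture(self):
        lt = _unit_life_table(p=0.95)
        lt.loc[(slice(None), slice(80, None), slice(None))] = 0.7
        pats = pd.DataFrame({"sex": [1, 1, 1], "age": [60, 85, 85],
                             "diag_year": [1995] * 3,
                             "potential_fu": [10.0] * 3})
        es = hakulinen_expected(pats, lt, [4])
        want = (0.95 ** 4 + 2 * 0.7 ** 4) / 3
        assert es[0] == pytest.approx(want, abs=1e-12)

    def test_fractional_grid_uses_constant_hazard_within_year(self):
        lt = _unit_life_table(p=0.9)
        pats = pd.DataFrame({"sex": [1], "age": [60], "diag_year": [1995],
                             "potential_fu": [10.0]})
        es = hakulinen_expected(pats, lt, [0.5, 1.5])
        assert es[0] == pytest.approx(0.9 ** 0.5)
        assert es[1] == pytest.approx(0.9 ** 1.5)

    def test_life_table_gap_is_named(self):
        lt = _unit_life_table(years=(1990, 1996))
        pats = pd.DataFrame({"sex": [1], "age": [60], "diag_year": [1995],
                             "potential_fu": [5.0]})
        with pytest.raises(CoverageError, match="1996"):
            hakulinen_expected(pats, lt, [0, 1, 2])

    def test_age_beyond_table_reuses_last_row(self):
        lt = _unit_life_table(ages=(0, 100), p=0.9)
        pats = pd.DataFrame({"sex": [1], "age": [99], "diag_year": [1995],
                             "potential_fu": [5.0]})
        es = hakulinen_expected(pats, lt, [3])
        assert es[0] == pytest.approx(0.9 ** 3)


class TestRelativeSurvival:
    def test_equal_observed_and_expected_gives_one(self):
        rs, lo, hi = relative_survival(np.array([0.8]), np.array([0.8]),
                                       np.array([0.0]))
        assert rs[0] == 1.0
        assert lo[0] == hi[0] == pytest.approx(1.0)

    def test_round_trips_published_row(self):
        # published report row: OS 0.282 with RS 0.292 at one year implies
        # ES = 0.282/0.292; the ratio must round-trip
        es = 0.282 / 0.292
        rs, _, _ = relative_survival(np.array([0.282]), np.array([es]),
                                     np.array([0.001]))
        assert rs[0] == pytest.approx(0.292, abs=1e-12)

    def test_zero_variance_ci_degenerates_to_point(self):
        rs, lo, hi = relative_survival(np.array([0.5]), np.array([0.9]),
                                       np.array([0.0]))
        assert lo[0] == hi[0] == rs[0]

    def test_rs_may_exceed_one_and_is_not_clipped(self):
        rs, lo, hi = relative_survival(np.array([0.99]), np.array([0.9]),
                                       np.array([0.01]))
        assert rs[0] > 1.0
        assert hi[0] > rs[0] > lo[0] >= 0.0

    def test_zero_expected_survival_rejected(self):
        with pytest.raises(RegistatError):
            relative_survival(np.array([0.5]), np.array([0.0]),
                              np.array([0.0]))


class TestModel:
    def test_unit_life_table_makes_rs_equal_os(self):
        rng = np.random.default_rng(6)
        n = 60
        fu = rng.exponential(3.0, n).round(2)
        fu = np.minimum(fu, 8.0)
        status = (fu < 8.0).astype(int)
        recs = _records(n, follow_up=list(fu), status=list(status))
        curve = RelativeSurvivalModel(recs, _unit_life_table(), (2007, 12),
                                      max_time=5).fit()
        assert np.allclose(curve.rs, curve.os, atol=1e-12)
        assert (curve.es == 1.0).all()

    def test_curves_are_monotone_and_consistent(self):
        rng = np.random.default_rng(13)
        n = 100
        fu = np.minimum(rng.exponential(4.0, n), 10.0).round(2)
        status = rng.integers(0, 2, n)
        recs = _records(n, age=list(rng.integers(40, 90, n)),
                        follow_up=list(fu), status=list(status))
        lt = _unit_life_table(p=0.95)
        curve = RelativeSurvivalModel(recs, lt, (2007, 12), max_time=6).fit()
        assert (np.diff(curve.os) <= 1e-12).all()
        assert (np.diff(curve.es) <= 1e-12).all()
        assert (np.diff(curve.n_at_risk) <= 0).all()
        assert np.allclose(curve.rs, curve.os / curve.es)
        assert (curve.ci_low <= curve.rs + 1e-12).all()
        assert (curve.rs <= curve.ci_high + 1e-12).all()


class TestReportTable:
    def test_all_ones_when_no_deaths_and_unit_table(self):
        recs = _records(5, follow_up=6.0, status=0)
        curve = RelativeSurvivalModel(recs, _unit_life_table(), (2007, 12),
                                      max_time=4).fit()
        table = report_table(curve)
        assert list(table.columns) == ["Risk", "T", "RS", "LCI", "UCI", "OS"]
        assert (table["RS"] == 1.0).all()

    def test_km_hand_example_in_table(self):
        recs = _records(4, follow_up=[1, 1.5, 2, 3], status=[1, 0, 1, 0])
        curve = RelativeSurvivalModel(recs, _unit_life_table(), (2007, 12),
                                      max_time=3).fit()
        table = report_table(curve)
        assert table["OS"].tolist() == [1.0, 0.75, 0.375, 0.375]

    def test_empty_grid_gives_header_only(self):
        curve = SurvivalCurve(
            time_points=np.array([]), n_at_risk=np.array([], dtype=int),
            os=np.array([]), es=np.array([]), rs=np.array([]),
            ci_low=np.array([]), ci_high=np.array([]))
        assert len(report_table(curve)) == 0


def test_null_excess_hazard_recovers_rs_one(null_registry):
    """With background mortality only, relative survival stays at 1."""
    spec = null_registry.spec
    m = RelativeSurvivalModel(null_registry.individuals,
                              null_registry.life_table, spec.study_end,
                              max_time=5)
    curve = m.fit()
    assert curve.rs[-1] == pytest.approx(1.0, abs=0.05)
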